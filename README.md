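# dendrostand

Stand-level dendroecology in Python: how much of a tree's year-to-year
radial growth is set by climate, and how much by the neighbours crowding
it?

`dendrostand` implements the full analysis chain used to answer that
question for a mapped forest plot with increment cores:

1. **Chronology** — Tucson/RWL ring-width series are detrended (cubic-type
   smoothing spline, modified negative exponential, or series mean) into
   dimensionless ring-width indices, averaged year-wise with Tukey's
   biweight robust mean into a standard (STD) chronology, and summarized
   with the classical statistics block: mean sensitivity
   MS = mean of 2|xₜ − xₜ₋₁|/(xₜ + xₜ₋₁), standard deviation, mean
   interseries correlation r̄, SNR = N·r̄/(1 − r̄), expressed population
   signal EPS = N·r̄/(N·r̄ + 1 − r̄), and lag-1 autocorrelation. A
   leave-one-out master-correlation QC pass flags mis-dated cores.
2. **Growth** — ring widths are reconciled with each tree's DBH and bark
   to an annual inside-bark radius series, giving the basal area increment
   BAI&#8239;=&#8239;π(Rₜ² − Rₜ₋₁²) and its 5/10/15-year cumulative sums.
3. **Competition** — the distance-dependent Hegyi index
   CI_i = Σ_j (D_j/D_i)/L_ij over neighbours within 8 m with DBH ≥ 5 cm,
   with edge bias removed by a nested design (targets in a 30 × 30 m core
   of a 50 × 50 m plot), and the decreasing power law y = a·x^(−b) fitted
   between cumulative BAI and CI.
4. **Climate response** — bootstrap Pearson correlation functions between
   the chronology and monthly climate (T, Tmax, Tmin, P, VPD, scPDSI)
   from June of the previous year through the current growing season.
5. **Mixed model** — a random-intercept linear mixed model, fitted by a
   direct REML implementation,

   BAI_it = a + b·CI_i + c·Age_it + d·scPDSI_t + d′·VPD_t
   + e·CI_i·scPDSI_t + u_i + ε_it,  u_i ~ N(0, τ₀₀), ε_it ~ N(0, σ²),

   reported with Wald intervals, variance components, ICC = τ₀₀/(τ₀₀+σ²)
   and marginal/conditional R².
6. **Synthetic data** — a seeded generator producing stem maps, monthly
   climate with semi-arid continental seasonality, and ring widths forced
   by age, May–July drought (scPDSI) and vapour-pressure deficit,
   competition, tree random effects and AR(1) noise — so the whole
   pipeline is testable end-to-end without field data.

Intended users: dendroecologists and forest scientists analyzing mapped
plots with increment cores, and methodologists who want a transparent,
tested reference for the chronology statistics and the growth model.

## Worked example

```python
from dendrostand import SimulationConfig, simulate_dataset, hegyi_ci_all, ci_summary
from dendrostand.chronology import detrend_series, build_chronology, chronology_stats
from dendrostand.growth import bai_series, reconstruct_radii
from dendrostand.io_formats import average_cores_by_tree
from dendrostand.mixed_model import build_design, fit_lmm

climate, stand, rings, truth = simulate_dataset(SimulationConfig(seed=1))
series = [detrend_series(s) for s in rings]
stats = chronology_stats(series, build_chronology(series))
print(f"chronology {stats.period[0]}-{stats.period[1]}: "
      f"trees/cores {stats.n_trees}/{stats.n_cores}  MS={stats.ms:.3f}  "
      f"SD={stats.sd:.3f}  rbar={stats.rbar:.3f}  SNR={stats.snr:.1f}  "
      f"EPS={stats.eps:.3f}  AC1={stats.ac1:.3f}")
ci = hegyi_ci_all(stand)
s = ci_summary(ci)
print(f"Hegyi CI over {s['n']} targets: mean {s['mean']:.2f}, sd {s['sd']:.2f}, "
      f"range {s['min']:.2f}-{s['max']:.2f}")
bai = {t.tree_id: bai_series(reconstruct_radii(t, float(stand.tree(t.tree_id)["dbh"])))
       for t in average_cores_by_tree(rings)}
fit = fit_lmm(build_design(bai, ci, climate, (1993, 2016)))
print(fit.summary())
```

prints (seed 1):

```
chronology 1975-2016: trees/cores 52/104  MS=0.166  SD=0.217  rbar=0.493  SNR=73.4  EPS=0.987  AC1=0.288
Hegyi CI over 52 targets: mean 2.49, sd 1.07, range 0.78-6.73

Random-intercept linear mixed model (REML)
                                estimate                   95% CI         p
Intercept                        3551.97  [  3211.09,   3892.85]    <0.001
age                               -10.10  [   -12.26,     -7.95]    <0.001
ci                               -336.35  [  -419.95,   -252.75]    <0.001
mjj_scpdsi                        251.38  [   207.25,    295.52]    <0.001
mjj_vpd                          -871.45  [ -1042.11,   -700.78]    <0.001
ci:mjj_scpdsi                     -46.03  [   -62.31,    -29.74]    <0.001

sigma^2 (residual)              69056.19
tau00 (tree intercept)         103371.89
ICC                                 0.60
N (trees)                             52
observations                        1248
marginal R2                        0.481
conditional R2                     0.792
```

Reading it: the chronology's EPS of 0.987 clears the conventional 0.85
quality bar, so the stand shares a strong common signal. Growth falls
with crowding (negative `ci`), rises in wet years (positive `mjj_scpdsi`,
units mm² BAI per scPDSI unit), falls under atmospheric drought (negative
`mjj_vpd`, per kPa), and the negative interaction says heavily crowded
trees profit less from wet years. 60% of the residual-free variance is
between-tree (ICC), and fixed effects alone explain 48% of the total
(marginal R²).

A command-line interface wraps the same stages:

```sh
dendrostand simulate --seed 1 --out demo/
dendrostand run-all --config demo/cfg.yml
```

writes `chronology.csv`, `chronology_stats.csv`, `qc_report.csv`,
`ci.csv`, `bai.csv`, `cumulative_bai.csv`, `power_fits.csv`,
`correlations.csv`, `lmm_fixed.csv`, `lmm_random.csv`, `lmm_report.txt`
and a `run_log.txt` recording every setting, under `demo/results/`.

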
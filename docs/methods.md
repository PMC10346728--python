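# Methods

This note documents the models and numerical choices behind
`dendrostand`, the design decisions taken where the methodology is
genuinely open, and what the synthetic-data tests do and do not
demonstrate about real data.

## Chronology construction

**Detrending.** The default growth-curve model is a smoothing curve from
a second-difference roughness penalty: the fitted curve g solves
(I + λDᵀD)g = w, with D the second-difference operator. The smoothing
parameter is set from the curve's frequency response,
λ = 1/(2 − 2cos(2π/p))², so that a sinusoid of period p passes with 50%
amplitude; p defaults to 0.67 × series length, the conservative choice
for short (~40-year) series, keeping decadal variation in the curve and
leaving interannual variation in the index. The system is pentadiagonal
and solved with a banded Cholesky; the test suite checks it against an
independent dense-matrix solve of the same equations. Alternatives:
modified negative exponential a·e^(−bt) + k (a, b > 0, k ≥ 0; falls back
to a non-increasing line, then the mean, when the fit fails or turns
non-positive) and the series mean. Indices are ratios (width/curve), the
standard choice for STD chronologies; division keeps the index
dimensionless, positive, and mean ≈ 1.

**Averaging.** Per-year values are Tukey biweight robust means (c = 9,
median/MAD start; the median itself when the MAD is zero). Sample depth
is recorded per year.

**Statistics.** MS, SD and AC1 are computed on the chronology over the
common period (maximal contiguous span with ≥ 2 trees); a mean of
series-level MS is reported alongside since either convention appears in
the literature. r̄ is the mean of all pairwise core correlations
(complete-overlap fast path, pairwise-deletion fallback with ≥ 10 shared
years). Because the two cores of a tree replicate one individual, SNR
and EPS use the between-tree r̄ (cores averaged per tree first) with
N = number of trees; the core-based pair (N = cores) is also reported.
EPS = SNR/(1 + SNR) holds by construction and is asserted on every
computation.

**Cross-dating QC.** Instead of a manual skeleton-plot workflow, each
series' first-differenced indices are correlated with the leave-one-out
biweight master; series below r = 0.32 (the conventional critical level,
applied to whole series since these are only ~42 years) are flagged,
never deleted.

## BAI reconstruction

Measured core widths rarely sum exactly to the DBH-derived radius, so
radii are reconciled by a single proportional rescaling: every ring is
scaled by (DBH/2 − bark)/Σwidths, anchoring the outermost radius exactly
(an anchor-without-rescale mode is available). Bark defaults to 5% of
the DBH radius when no per-tree measurement exists; the value is logged
and configurable. Cores are averaged year-wise per tree before
reconstruction. BAI_t = π(R_t² − R_{t−1}²) telescopes, so
ΣBAI = π(R_final² − R_start²) is asserted as a property over random
series. No pith-offset estimation is attempted.

## Hegyi competition

CI_i = Σ_j (D_j/D_i)/L_ij over neighbours within 8 m with DBH ≥ 5 cm,
Euclidean distances in plot-local metres. Edge handling uses the nested
design itself: targets are restricted to the interior 30 × 30 m core
while competitors come from the full 50 × 50 m map, so the 10 m buffer
exceeds the search radius and no correction formula is needed
(`edge_mode="none"` lifts the restriction; Ripley-style weighting is
recognized but not implemented). CI is treated as time-constant: the
current index stands for a tree's relative competitive position across
all analysis windows. Coincident stems are an error, not a silent skip.

The CI–growth relation y = a·x^(−b) is fitted by nonlinear least squares
on the original scale (so large trees are not down-weighted as they are
in log space), initialized from the log–log OLS closed form, which also
serves as the fallback on non-convergence (flagged in the result). R² is
1 − SS_res/SS_tot on the original scale.

## Climate correlation functions

The predictor matrix pairs chronology year y with monthly values from
June of y − 1 ("pJun"…"pDec") through September of y (configurable to
December). For each (variable, month) cell the Pearson correlation is
computed on the overlap (pairwise deletion of missing months, logged).

Two bootstrap quantities accompany each r, both seeded: a paired
percentile interval (years resampled with replacement) reported as the
effect-size CI, and a significance call from a bootstrap test of
independence, in which the two series are resampled *independently* to
build the null distribution of r; the observed r outside the null's
2.5–97.5 range gives p < 0.05, outside 0.5–99.5 gives p < 0.01. The
null-resampling test is used for significance because the paired
percentile interval is measurably anticonservative for correlations at
~40-year sample sizes (about 7% type-I error at the nominal 5% in our
simulations, with BCa and normal-approximation variants no better),
while the independence bootstrap is calibrated (≈5.1% measured). No
multiple-testing correction is applied by default, matching standard
practice for correlation-function displays; a Benjamini–Hochberg option
exists for the full grid.

## The growth mixed model

BAI_it = a + b·CI_i + c·Age_it + d·scPDSI_t + d′·VPD_t +
e·CI_i·scPDSI_t + u_i + ε_it with u_i ~ N(0, τ₀₀) and iid ε. The
response is annual BAI in mm² (cm² × 100), which puts coefficients at
field-realistic magnitudes; the unit is configurable. Age is cambial age
(ring count from the innermost measured ring). scPDSI and VPD enter as
May–July means of the growth year. Predictors are left unstandardized.
The default fixed-effect set is configurable through a small formula
language (`y ~ a + b + a:b`).

**Estimation.** REML, implemented directly. With a single random
intercept, group g's marginal covariance is σ²(I + θ11ᵀ), θ = τ₀₀/σ²,
with closed-form inverse (Woodbury) and determinant log(1 + n_gθ). The
REML criterion is profiled to a function of θ alone,

(n − p)·log Q(θ) + Σ_g log(1 + n_gθ) + log det(XᵀW(θ)X),

evaluated in O(G·p²) from group sufficient statistics, and minimized by
bounded derivative-free search over log θ ∈ [−12, 8] followed by a local
polish on the θ scale (the log-scale search alone stops within ~1e−7
relative of the optimum; the polish reaches the closed-form ANOVA
solution on balanced layouts to 1e−6). θ = 0 is compared explicitly and
flagged as a boundary fit; at θ = 0 the GLS step is exactly OLS.

**Inference.** Wald z intervals and p-values. No
Satterthwaite/Kenward–Roger degrees-of-freedom correction: at the
n ≈ 10³ records this model targets, the normal approximation is
adequate; at small n the p-values are anticonservative and should be
read accordingly. ICC = τ₀₀/(τ₀₀ + σ²); marginal and conditional R²
follow the standard variance decomposition with Var(Xβ̂) taken over the
sample. The implementation is cross-checked against an independent mixed
model routine in the test suite and against closed-form ANOVA estimators
on balanced one-way layouts.

## Synthetic data generator

The generator reproduces the statistical structure the analysis assumes,
not forest physics. One regional climate (single-station design):
monthly temperature normals with a strong continental cycle (annual mean
≈ 0 °C), precipitation allocated by noisy summer-peaked weights and
renormalized so each annual total falls in the configured 290–390 mm
envelope, VPD from saturation vapour pressure at Tmax with multiplicative
noise, and scPDSI directly as a monthly AR(1) (φ = 0.6, unit innovation
variance) rather than through a water-balance model.

Growth acts multiplicatively: log ring-area increment = log(A·e^(−k·age)
+ c) + β_s·scPDSI_MJJ + β_v·(VPD_MJJ − V₀) + γ·(CI − C₀) + u_i + ε_it,
with AR(1) ε and per-core multiplicative measurement noise; widths are
quantized to the 0.01 mm bench precision and recovered from the running
radius. Working on log area guarantees positive widths and maps onto
both the power-law CI relation and the linear BAI model. Defaults
(β_s = 0.12, β_v = −0.75/kPa, γ = −0.22, σ_u = 0.30, σ_ε = 0.15,
ρ = 0.5, core noise 0.18) put the mean annual increment near 1000 mm²/yr
and the implied linear coefficients at the magnitudes reported for
semi-arid pine stands.

**Consistency.** A sampled tree's stem-map DBH is derived from its own
rings (outside radius plus bark), and the CI that drove growth is the
one the analysis recomputes from that map; the growth→DBH→CI circle is
resolved by fixed-point iteration with frozen noise. Competitive
suppression is self-reinforcing, so a tree crossing below the 5 cm
coring bar is frozen at that size and left unsampled — mirroring the
field protocol, which only cores trees with DBH ≥ 5 cm. A default stand
therefore carries 53 targets of which occasionally one or two end
unsampled.

**Truth mapping.** The generator stores delta-method (second-order
Taylor, raw-product parameterization) linear-scale coefficients at the
analysis period's sample means: b = Ā·γ − e·P̄, d = Ā·β_s − e·C̄,
d′ = Ā·β_v, e = Ā·γ·β_s, c = Ā·(d log agecurve/d age). Two points
matter when reading validation results. First, interval *coverage* is
checked on responses resimulated from the linear mixed model itself with
known coefficients: the exponential generator is deliberately
misspecified relative to the linear fit, so its Taylor truth is not an
unbiased coverage target, whereas sign recovery is run on the full
nonlinear generator. Second, the generator's age curve declines in area
(the spec'd negative exponential), so its truth Age coefficient is
negative; young field stands often show the opposite sign because area
increment rises with radius — a known limitation of this generator, not
of the fitted model.

**What passing tests show.** That the pipeline recovers known structure
from data with the assumed statistical shape — shared climate forcing,
multiplicative effects, a single station, exact cross-dating, complete
cores. They do not certify behaviour under dating errors, missing rings,
spatially heterogeneous climate, or non-stationary competition, none of
which the generator emulates.

## Degenerate inputs and numerical conventions

All-zero width series, coincident stems, zero-variance climate columns
and rank-deficient designs raise typed errors naming the offending
entity; zero MAD falls back to the median; r̄ = 1 yields SNR = ∞ and
EPS = 1; τ₀₀ → 0 is reported with a boundary flag rather than hidden.
RWL files use the classic Tucson decadal dialect (0.01 mm integers, 999
terminator, −9999 accepted on read); a width of exactly 9.99 mm would
collide with the terminator and is rejected on write (the generator
nudges such values down one unit). Problem sizes in the validation suite
— 100-replicate recovery studies at 53 trees × 24 years, 1000-replicate
null calibrations at 42 years, 200-tree oracle stands — were chosen to
match the study design the generator emulates while keeping each check
to seconds or a few minutes.
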
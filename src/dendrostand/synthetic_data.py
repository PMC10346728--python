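"""Synthetic stand, climate and ring-width generator.

Emulates the data-generating situation the analysis pipeline assumes: a
50 × 50 m plot of a semi-arid Scots-pine sandy-land stand whose central
30 × 30 m core is fully cored (two increment cores per target tree), a
single-station monthly climate record with strong continental seasonality
(annual precipitation ~280–400 mm concentrated in summer), and ring widths
driven by an age trend, May–July drought (scPDSI) and vapour-pressure
deficit, neighbourhood competition, a per-tree random effect and
first-order autocorrelated noise.

Growth model.  Effects act multiplicatively on the annual basal-area
increment: for tree i in year t the expected log ring-area increment is

    log A_it = log g(age_t) + β_s·scPDSI_MJJ(t) + β_v·(VPD_MJJ(t) − V₀)
               + γ·(CI_i − C₀) + u_i + ε_it,

with g the modified negative exponential age curve ``A·exp(−k·age)+c``
(cm²/yr), u_i ~ N(0, σ_u²) the tree effect and ε an AR(1) process.  Ring
widths follow from the running radius, and each of the two cores adds
independent multiplicative measurement noise.  Working on the log-area
scale keeps widths positive and maps naturally onto both the power-law
CI–growth curve and the linear BAI model; the implied linear-scale
coefficients (delta-method expansion at the sample means, raw-product
parameterization) are stored in the :class:`TruthRecord`.

Consistency.  A sampled tree's stem-map DBH is derived from its own
generated rings (outside radius plus bark), and the competition index that
drove growth is the one the analysis recomputes from that stem map; the
circular dependence (growth → DBH → CI → growth) is resolved by a short
fixed-point iteration with frozen noise draws.

scPDSI is generated directly as a monthly AR(1) process (φ = 0.6, unit
innovation variance) rather than through a water-balance model, and VPD
from saturation vapour pressure at Tmax with multiplicative noise — only
the statistical structure the analysis assumes is reproduced, not the
physics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
import numpy as np
import pandas as pd

from .competition import hegyi_ci_all
from .errors import DegenerateInputError, ValidationError
from .io_formats import ClimateTable, RingSeries, StemMap

logger = logging.getLogger(__name__)

# Hulunbuir-like (Hailar station) monthly climatology
_T_NORMALS = np.array(
    [-24.0, -19.0, -9.0, 3.0, 12.0, 18.0, 21.0, 19.0, 12.0, 2.0, -11.0, -21.0]
)
_P_WEIGHTS = np.array([2.0, 2.0, 4.0, 9.0, 18.0, 45.0, 85.0, 70.0, 35.0, 12.0, 4.0, 2.0])


def _saturation_vp(t_celsius: np.ndarray) -> np.ndarray:
    """Magnus saturation vapour pressure, kPa."""
    return 0.6108 * np.exp(17.27 * t_celsius / (t_celsius + 237.3))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults emulate the target stand."""

    seed: int = 0
    # stand
    n_trees: int = 53
    cores_per_tree: int = 2
    start_year: int = 1975
    end_year: int = 2016
    plot_size: float = 50.0
    core_region: float = 30.0
    dbh_median_cm: float = 20.0
    dbh_log_sd: float = 0.3
    spatial_pattern: str = "uniform"  # or "clustered"
    min_spacing_m: float = 0.5
    bark_fraction: float = 0.05  # bark = fraction * dbh/2
    # climate
    annual_p_range: tuple[float, float] = (290.0, 390.0)
    t_noise_sd: float = 1.5
    t_diurnal_half: float = 7.5
    pdsi_phi: float = 0.6
    pdsi_innov_sd: float = 1.0
    vpd_scale: float = 0.45
    vpd_noise_sd: float = 0.08
    p_month_noise_sd: float = 0.4
    # growth (log ring-area scale)
    age_curve_a: float = 6.0  # cm^2
    age_curve_k: float = 0.05  # 1/yr
    age_curve_c: float = 7.0  # cm^2 asymptote
    beta_scpdsi: float = 0.12  # per scPDSI unit
    beta_vpd: float = -0.75  # per kPa
    gamma_ci: float = -0.22  # per CI unit
    vpd_center: float = 1.35  # kPa, centring constant for the exponent
    ci_center: float = 3.7  # centring constant for the exponent
    tree_effect_sd: float = 0.30
    resid_sd: float = 0.15  # marginal sd of the AR(1) residual
    resid_ar1: float = 0.5
    core_noise_sd: float = 0.18  # per-core multiplicative measurement noise

    def __post_init__(self) -> None:
        if self.end_year - self.start_year + 1 < 20:
            raise ValidationError("simulated span must be at least 20 years")
        for name in ("tree_effect_sd", "resid_sd", "core_noise_sd", "dbh_log_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.resid_ar1 < 1:
            raise ValidationError("resid_ar1 must be in [0, 1)")

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    def age_curve(self, age: np.ndarray) -> np.ndarray:
        return self.age_curve_a * np.exp(-self.age_curve_k * np.asarray(age)) + self.age_curve_c

    # -- presets ------------------------------------------------------------

    def common_signal_variance(self) -> float:
        """Approximate variance of the log index shared by all cores.

        Three shared pathways: the scPDSI forcing (AR(1) May–July mean,
        closed form), the VPD forcing (delta-method through the saturation
        vapour-pressure curve at the summer Tmax normals), and the
        deterministic age-curve misfit left by spline detrending — every
        core carries the same width trend, and whatever the spline does not
        absorb is a perfectly shared signal.
        """
        var_pdsi_mjj = (
            self.pdsi_innov_sd**2 / (1 - self.pdsi_phi**2) / 9.0
            * (3 + 4 * self.pdsi_phi + 2 * self.pdsi_phi**2)
        )
        # VPD: log-scale monthly noise through es(Tmax), averaged over 3 months
        t_summer = float(np.mean(_T_NORMALS[4:7])) + self.t_diurnal_half
        k_es = 17.27 * 237.3 / (t_summer + 237.3) ** 2
        log_sd_month = np.sqrt((k_es * self.t_noise_sd) ** 2 + self.vpd_noise_sd**2)
        vpd_bar = self.vpd_scale * float(
            np.mean(_saturation_vp(_T_NORMALS[4:7] + self.t_diurnal_half))
        )
        var_vpd_mjj = (vpd_bar * log_sd_month) ** 2 / 3.0
        # deterministic age-curve misfit through the spline detrender
        from .chronology import smoothing_spline

        ages = np.arange(1, self.n_years + 1)
        areas = self.age_curve(ages)
        radii = np.sqrt(np.cumsum(areas) / np.pi)
        widths = np.diff(np.r_[0.0, radii])
        curve = smoothing_spline(widths, 0.67 * len(widths))
        var_misfit = float(np.var(np.log(widths / np.maximum(curve, 1e-9))))
        return (
            var_misfit
            + self.beta_scpdsi**2 * var_pdsi_mjj
            + self.beta_vpd**2 * var_vpd_mjj
        )

    def with_common_signal_share(self, rbar: float = 0.5) -> "SimulationConfig":
        """Retune noise so the expected between-tree rbar is ~`rbar`.

        The shared variance from :meth:`common_signal_variance` is matched
        by per-core noise (tree-temporal + measurement, split evenly) so
        that shared/(shared + noise) equals the target share.
        """
        if not 0 < rbar < 1:
            raise ValidationError("rbar target must be in (0, 1)")
        var_common = self.common_signal_variance()
        var_noise = var_common * (1 - rbar) / rbar
        return replace(
            self,
            resid_sd=float(np.sqrt(var_noise / 2.0)),
            core_noise_sd=float(np.sqrt(var_noise / 2.0)),
        )

    def low_signal(self) -> "SimulationConfig":
        """A deliberately noisy stand (weak common signal, low EPS)."""
        return replace(self, beta_scpdsi=0.02, beta_vpd=-0.1,
                       resid_sd=0.45, core_noise_sd=0.45)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# ---------------------------------------------------------------------------
# climate

def generate_climate(config: SimulationConfig) -> ClimateTable:
    """Monthly climate over [start_year − 1, end_year], seeded by config.

    Annual precipitation totals are drawn uniformly inside the configured
    envelope and allocated to months by noisy seasonal weights renormalized
    to the drawn total; Tmin ≤ T ≤ Tmax holds by construction.
    """
    rng = _rng(config, 1)
    years = np.arange(config.start_year - 1, config.end_year + 1)
    n = len(years)
    rows = []
    # scPDSI: one AR(1) chain over all months with burn-in
    burn = 120
    phi, sd = config.pdsi_phi, config.pdsi_innov_sd
    innov = rng.normal(0.0, sd, size=burn + 12 * n)
    pdsi = np.empty_like(innov)
    pdsi[0] = innov[0] / np.sqrt(1 - phi**2)
    for k in range(1, len(innov)):
        pdsi[k] = phi * pdsi[k - 1] + innov[k]
    pdsi = pdsi[burn:]

    for i, year in enumerate(years):
        t = _T_NORMALS + rng.normal(0.0, config.t_noise_sd, 12)
        hi = np.maximum(rng.normal(config.t_diurnal_half, 0.8, 12), 0.5)
        lo = np.maximum(rng.normal(config.t_diurnal_half + 0.5, 0.8, 12), 0.5)
        tmax, tmin = t + hi, t - lo
        annual_p = rng.uniform(*config.annual_p_range)
        w = _P_WEIGHTS * rng.lognormal(0.0, config.p_month_noise_sd, 12)
        p = annual_p * w / w.sum()
        vpd = (
            config.vpd_scale
            * _saturation_vp(tmax)
            * rng.lognormal(0.0, config.vpd_noise_sd, 12)
        )
        for m in range(12):
            rows.append(
                dict(year=int(year), month=m + 1, T=t[m], Tmax=tmax[m],
                     Tmin=tmin[m], P=p[m], VPD=vpd[m], scPDSI=pdsi[12 * i + m])
            )
    return ClimateTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# stand

def _place(
    rng: np.random.Generator,
    n: int,
    lo: float,
    hi: float,
    existing: np.ndarray,
    min_spacing: float,
    clustered: bool,
    max_draws: int = 100_000,
) -> np.ndarray:
    pts = list(existing)
    centers = None
    if clustered:
        n_clusters = max(3, n // 12)
        centers = rng.uniform(lo, hi, size=(n_clusters, 2))
    placed = 0
    draws = 0
    out = []
    while placed < n:
        draws += 1
        if draws > max_draws:
            raise DegenerateInputError(
                f"could not place {n} stems at spacing {min_spacing} m "
                f"after {max_draws} draws"
            )
        if clustered:
            c = centers[rng.integers(len(centers))]
            p = np.clip(c + rng.normal(0.0, 4.0, 2), lo, hi)
        else:
            p = rng.uniform(lo, hi, 2)
        if pts:
            d = np.min(np.hypot(*(np.array(pts) - p).T))
            if d < min_spacing:
                continue
        pts.append(p)
        out.append(p)
        placed += 1
    return np.array(out)


def generate_stand(config: SimulationConfig) -> StemMap:
    """Stem map: sampled targets in the core, neighbours over the full plot.

    Neighbour density outside the core matches the core's target density.
    DBH values here are provisional for neighbours and recomputed from the
    generated rings for sampled trees by :func:`generate_rings`.
    """
    rng = _rng(config, 2)
    lo = (config.plot_size - config.core_region) / 2.0
    hi = lo + config.core_region
    clustered = config.spatial_pattern == "clustered"
    core_pts = _place(rng, config.n_trees, lo, hi, np.empty((0, 2)),
                      config.min_spacing_m, clustered)
    core_area = config.core_region**2
    frame_area = config.plot_size**2 - core_area
    n_out = int(round(config.n_trees / core_area * frame_area))
    # place in the full plot, rejecting points that fall inside the core
    out_pts = []
    existing = list(core_pts)
    draws = 0
    rng_out = rng
    while len(out_pts) < n_out:
        draws += 1
        if draws > 200_000:
            raise DegenerateInputError("could not place frame neighbours")
        p = rng_out.uniform(0.0, config.plot_size, 2)
        if lo <= p[0] <= hi and lo <= p[1] <= hi:
            continue
        d = np.min(np.hypot(*(np.array(existing) - p).T))
        if d < config.min_spacing_m:
            continue
        existing.append(p)
        out_pts.append(p)
    out_pts = np.array(out_pts) if out_pts else np.empty((0, 2))

    mu = np.log(config.dbh_median_cm)
    def draw_dbh(k: int, truncate: bool) -> np.ndarray:
        d = rng.lognormal(mu, config.dbh_log_sd, k)
        if truncate:
            while np.any(d < 5.0):
                d[d < 5.0] = rng.lognormal(mu, config.dbh_log_sd, int(np.sum(d < 5.0)))
        return d

    dbh_core = draw_dbh(config.n_trees, truncate=True)
    dbh_out = draw_dbh(len(out_pts), truncate=False)
    heights = np.maximum(2.0 + 0.45 * dbh_core * rng.lognormal(0.0, 0.1, config.n_trees), 2.0)
    heights_out = np.maximum(1.0 + 0.45 * dbh_out * rng.lognormal(0.0, 0.1, len(out_pts)), 0.5)

    rows = []
    for i in range(config.n_trees):
        rows.append(dict(tree_id=f"T{i + 1:03d}", x=core_pts[i, 0], y=core_pts[i, 1],
                         dbh=dbh_core[i], height=heights[i], sampled=True))
    for i in range(len(out_pts)):
        rows.append(dict(tree_id=f"N{i + 1:03d}", x=out_pts[i, 0], y=out_pts[i, 1],
                         dbh=dbh_out[i], height=heights_out[i], sampled=False))
    return StemMap(pd.DataFrame(rows), plot_size=config.plot_size)


# ---------------------------------------------------------------------------
# rings

@dataclass
class TruthRecord:
    """Everything needed to score a pipeline run against the generator."""

    config: SimulationConfig
    tree_effects: dict[str, float]  # u_i, log scale
    true_ci: dict[str, float]
    mjj_scpdsi: pd.Series  # year -> May-July mean
    mjj_vpd: pd.Series
    #: per tree-year expected ring area (mm², conditional on u, ε averaged out)
    expected_area_mm2: pd.DataFrame  # index year, columns tree_id

    def expected_bai_mm2(self, tree_id: str, year: int) -> float:
        return float(self.expected_area_mm2.loc[year, tree_id])

    @property
    def years(self) -> np.ndarray:
        return self.expected_area_mm2.index.to_numpy()

    def linear_coefs(self, period: tuple[int, int] | None = None) -> dict[str, float]:
        """Implied linear-model coefficients over an analysis period.

        Delta-method (second-order Taylor) expansion of the multiplicative
        growth model at the period's sample means, re-expressed in the
        raw-product parameterization of the default model formula
        (``age + ci + mjj_scpdsi + mjj_vpd + ci:mjj_scpdsi``).
        """
        cfg = self.config
        if period is None:
            period = (int(self.years.min()), int(self.years.max()))
        lo, hi = period
        sub = self.expected_area_mm2.loc[lo:hi]
        a_bar = float(sub.to_numpy().mean())
        p_bar = float(self.mjj_scpdsi.loc[lo:hi].mean())
        c_bar = float(np.mean(list(self.true_ci.values())))
        ages = np.arange(lo, hi + 1) - cfg.start_year + 1
        abar_age = float(ages.mean())
        g = cfg.age_curve(np.array([abar_age]))[0]
        dlog_age = float(
            -cfg.age_curve_k * cfg.age_curve_a * np.exp(-cfg.age_curve_k * abar_age) / g
        )
        e_coef = a_bar * cfg.gamma_ci * cfg.beta_scpdsi
        return {
            "age": a_bar * dlog_age,
            "ci": a_bar * cfg.gamma_ci - e_coef * p_bar,
            "mjj_scpdsi": a_bar * cfg.beta_scpdsi - e_coef * c_bar,
            "mjj_vpd": a_bar * cfg.beta_vpd,
            "ci:mjj_scpdsi": e_coef,
            "mean_area_mm2": a_bar,
        }


def generate_rings(
    config: SimulationConfig,
    stand: StemMap,
    climate: ClimateTable,
) -> tuple[list[RingSeries], TruthRecord]:
    """Generate cores for every sampled tree plus the generator truth.

    Side effect: the sampled trees' ``dbh`` in `stand` is overwritten with
    the value implied by their generated rings (outside-bark), so the stem
    map, the rings and the competition index are mutually consistent.
    """
    rng = _rng(config, 3)
    targets = stand.sampled_ids
    if not targets:
        raise ValidationError("stand has no sampled trees")
    n_t = len(targets)
    years = np.arange(config.start_year, config.end_year + 1)
    n_y = len(years)
    ages = np.arange(1, n_y + 1)

    pdsi = np.array([
        np.mean([climate.value(int(y), m, "scPDSI") for m in (5, 6, 7)]) for y in years
    ])
    vpd = np.array([
        np.mean([climate.value(int(y), m, "VPD") for m in (5, 6, 7)]) for y in years
    ])
    if np.any(~np.isfinite(pdsi)) or np.any(~np.isfinite(vpd)):
        raise ValidationError("climate table does not cover the simulated years")

    u = rng.normal(0.0, config.tree_effect_sd, n_t)
    # AR(1) residuals, marginal sd resid_sd
    rho = config.resid_ar1
    innov_sd = config.resid_sd * np.sqrt(1.0 - rho**2)
    eps = np.empty((n_t, n_y))
    eps[:, 0] = rng.normal(0.0, config.resid_sd, n_t)
    shocks = rng.normal(0.0, innov_sd, (n_t, n_y))
    for t in range(1, n_y):
        eps[:, t] = rho * eps[:, t - 1] + shocks[:, t]

    climate_term = config.beta_scpdsi * pdsi + config.beta_vpd * (vpd - config.vpd_center)
    base_log = np.log(config.age_curve(ages))  # shared age trend, cm^2

    def areas_for_ci(ci_vec: np.ndarray) -> np.ndarray:
        """Annual ring areas (cm²), trees × years, for given CI values."""
        lin = (
            base_log[None, :]
            + climate_term[None, :]
            + (config.gamma_ci * (ci_vec - config.ci_center))[:, None]
            + u[:, None]
            + eps
        )
        return np.exp(lin)

    def dbh_from_areas(areas: np.ndarray) -> np.ndarray:
        r_out = np.sqrt(areas.sum(axis=1) / np.pi)  # cm, inside bark
        return 2.0 * r_out / (1.0 - config.bark_fraction)

    # fixed-point: growth -> DBH -> CI -> growth (noise frozen)
    df = stand.df
    tgt_mask = df["tree_id"].isin(targets)
    order = {t: i for i, t in enumerate(targets)}
    ci_vec = np.full(n_t, config.ci_center)

    def _set_dbh(new_dbh: np.ndarray) -> None:
        df.loc[tgt_mask, "dbh"] = [
            new_dbh[order[t]] for t in df.loc[tgt_mask, "tree_id"]
        ]

    # competitive suppression is self-reinforcing (smaller DBH -> higher CI
    # -> less growth); a tree crossing below the 5 cm coring bar is frozen
    # at that size (stagnant suppressed sapling) and later left unsampled,
    # which keeps the fixed point stable
    frozen = np.zeros(n_t, dtype=bool)
    dbh_cur = np.full(n_t, config.dbh_median_cm)
    for _ in range(60):
        areas = areas_for_ci(ci_vec)
        dbh_cur = np.where(frozen, dbh_cur, dbh_from_areas(areas))
        frozen |= dbh_cur < 5.0
        _set_dbh(dbh_cur)
        results = hegyi_ci_all(stand, targets=None, edge_mode="buffer",
                               core_size=config.core_region)
        new_ci = np.array([results[t].ci for t in targets])
        converged = np.max(np.abs(new_ci - ci_vec)) < 1e-12
        ci_vec = new_ci
        if converged:
            break
    areas = areas_for_ci(ci_vec)
    if np.any(areas <= 0) or np.any(~np.isfinite(areas)):
        raise DegenerateInputError("generator produced non-positive ring areas")
    final_dbh = np.where(frozen, dbh_cur, dbh_from_areas(areas))
    _set_dbh(final_dbh)
    # the field protocol only cores trees reaching 5 cm DBH: a tree whose
    # grown DBH falls below the bar is left standing but unsampled
    demoted = [t for t in targets if final_dbh[order[t]] < 5.0]
    if demoted:
        logger.warning(
            "%d suppressed tree(s) below the 5 cm coring threshold left "
            "unsampled: %s", len(demoted), demoted,
        )
        df.loc[df["tree_id"].isin(demoted), "sampled"] = False
        keep = np.array([t not in demoted for t in targets])
        targets = [t for t in targets if t not in demoted]
        n_t = len(targets)
        u, eps, areas = u[keep], eps[keep], areas[keep]
    stand.__post_init__()  # re-run the stem-map invariant checks
    # store exactly the CI the analysis will recompute from the final map
    results = hegyi_ci_all(stand, targets=None, edge_mode="buffer",
                           core_size=config.core_region)
    ci_vec = np.array([results[t].ci for t in targets])

    # radii and widths (cm -> mm), then cores with measurement noise
    radii = np.sqrt(np.cumsum(areas, axis=1) / np.pi)
    widths_mm = np.diff(np.concatenate([np.zeros((n_t, 1)), radii], axis=1), axis=1) * 10.0
    series: list[RingSeries] = []
    core_letters = "ABCDEFGH"
    for i, tid in enumerate(targets):
        for c in range(config.cores_per_tree):
            noise = rng.lognormal(0.0, config.core_noise_sd, n_y)
            # quantize to the 0.01 mm bench precision; floor at one unit
            w = np.round(np.maximum(widths_mm[i] * noise, 0.01), 2)
            # a width of exactly 9.99 mm would collide with the RWL stop value
            w[np.round(w * 100.0) == 999] -= 0.01
            series.append(
                RingSeries(f"{tid}{core_letters[c]}", tid, int(years[0]), w)
            )

    # --- truth bookkeeping -------------------------------------------------
    # expected areas conditional on u (ε integrated out: +resid_sd²/2 on log)
    lin = (
        base_log[None, :]
        + climate_term[None, :]
        + (config.gamma_ci * (ci_vec - config.ci_center))[:, None]
        + u[:, None]
        + 0.5 * config.resid_sd**2
    )
    expected = pd.DataFrame(np.exp(lin).T * 100.0, index=years, columns=targets)
    truth = TruthRecord(
        config=config,
        tree_effects=dict(zip(targets, u)),
        true_ci=dict(zip(targets, ci_vec)),
        mjj_scpdsi=pd.Series(pdsi, index=years),
        mjj_vpd=pd.Series(vpd, index=years),
        expected_area_mm2=expected,
    )
    return series, truth


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ClimateTable, StemMap, list[RingSeries], TruthRecord]:
    """Climate, stem map and cores for one stand, fully determined by seed."""
    climate = generate_climate(config)
    stand = generate_stand(config)
    rings, truth = generate_rings(config, stand, climate)
    return climate, stand, rings, truth
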
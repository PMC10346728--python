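"""Random-intercept linear mixed model of annual growth.

The model relates a tree's annual basal-area increment to its age, its
competitive status and the growing-season moisture environment:

    BAI_it = a + b·CI_i + c·Age_it + d·scPDSI_t + d'·VPD_t
             + e·CI_i·scPDSI_t + u_i + ε_it,

    u_i ~ N(0, τ₀₀),   ε_it ~ N(0, σ²),

with one random intercept u_i per tree absorbing persistent between-tree
growth differences (microsite, genotype).  scPDSI and VPD enter as
May–July means of the growth year; CI is time-constant.

Estimation is restricted maximum likelihood (REML), implemented directly:
with a single random intercept the marginal covariance of group g is
σ²(I + θ·11ᵀ) with θ = τ₀₀/σ², whose inverse and determinant are available
in closed form (Woodbury; log det = log(1 + n_g θ)).  The REML deviance is
profiled down to a one-dimensional function of θ and minimized over log θ
by bounded derivative-free search; σ², τ₀₀ and the GLS fixed effects then
follow in closed form.  Inference is Wald (normal quantiles), adequate at
the sample sizes this model is meant for (~10³ records).

Variance partitioning follows the standard mixed-model decomposition:
ICC = τ₀₀/(τ₀₀ + σ²); marginal R² = Var(Xβ)/(Var(Xβ) + τ₀₀ + σ²) and
conditional R² = (Var(Xβ) + τ₀₀)/(Var(Xβ) + τ₀₀ + σ²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .competition import CompetitionResult
from .climate_response import may_july_mean
from .errors import ValidationError
from .growth import BAISeries
from .io_formats import ClimateTable

logger = logging.getLogger(__name__)

DEFAULT_FORMULA = "bai ~ age + ci + mjj_scpdsi + mjj_vpd + ci:mjj_scpdsi"

#: annual BAI is analyzed in mm²; cm² from the growth stage are scaled by this
CM2_TO_MM2 = 100.0

_THETA_LOG_BOUNDS = (-12.0, 8.0)


# ---------------------------------------------------------------------------
# design assembly

def build_design(
    bai_by_tree: Mapping[str, BAISeries],
    ci_by_tree: Mapping[str, CompetitionResult | float],
    climate: ClimateTable,
    period: tuple[int, int],
    response_unit: str = "mm2",
) -> pd.DataFrame:
    """Assemble one growth record per (tree, year) over `period`.

    Columns: ``tree_id, year, bai, age, ci, mjj_scpdsi, mjj_vpd`` with
    ``bai`` in mm² (or cm² with ``response_unit='cm2'``), ``age`` the
    cambial age (ring count from the innermost measured ring) and the
    climate columns May–July means of the record's calendar year.  Records
    with any missing component are dropped and counted in the log; trees
    lacking a CI value are dropped entirely.
    """
    lo, hi = period
    if response_unit not in ("mm2", "cm2"):
        raise ValidationError(f"unknown response unit {response_unit!r}")
    scale = CM2_TO_MM2 if response_unit == "mm2" else 1.0
    trees = sorted(set(bai_by_tree) & set(ci_by_tree))
    if not trees:
        raise ValidationError("no tree appears in both the BAI and CI inputs")
    skipped_trees = sorted(set(bai_by_tree) - set(ci_by_tree))
    if skipped_trees:
        logger.info("trees without CI dropped from the design: %s", skipped_trees)
    clim_cache = {
        y: (may_july_mean(climate, "scPDSI", y), may_july_mean(climate, "VPD", y))
        for y in range(lo, hi + 1)
    }
    rows, dropped = [], 0
    for tid in trees:
        bai = bai_by_tree[tid]
        ci = ci_by_tree[tid]
        ci_val = float(ci.ci) if isinstance(ci, CompetitionResult) else float(ci)
        for year in range(lo, hi + 1):
            if year < bai.first_year or year > bai.last_year:
                dropped += 1
                continue
            pdsi, vpd = clim_cache[year]
            value = float(bai.bai[year - bai.first_year]) * scale
            age = year - bai.first_year + 1
            if not np.isfinite([value, pdsi, vpd, ci_val]).all():
                dropped += 1
                continue
            rows.append(
                dict(tree_id=tid, year=year, bai=value, age=age, ci=ci_val,
                     mjj_scpdsi=pdsi, mjj_vpd=vpd)
            )
    if dropped:
        logger.info("%d record(s) dropped while assembling the design", dropped)
    if not rows:
        raise ValidationError("design assembly produced no records")
    return pd.DataFrame(rows)


def _parse_formula(formula: str, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Minimal model-formula parser: ``y ~ a + b + a:b`` (``:`` = product).

    An intercept is always included first; prefix the right side with
    ``0 +`` to drop it.
    """
    try:
        lhs, rhs = (side.strip() for side in formula.split("~"))
    except ValueError:
        raise ValidationError(f"formula {formula!r} must contain one '~'") from None
    if lhs not in df.columns:
        raise ValidationError(f"response {lhs!r} not among columns {list(df.columns)}")
    terms = [t.strip() for t in rhs.split("+") if t.strip()]
    intercept = True
    if terms and terms[0] in ("0", "-1"):
        intercept = False
        terms = terms[1:]
    terms = [t for t in terms if t != "1"]  # bare 1 = explicit intercept
    cols: list[np.ndarray] = []
    names: list[str] = []
    if intercept:
        cols.append(np.ones(len(df)))
        names.append("Intercept")
    for term in terms:
        parts = [p.strip() for p in term.split(":")]
        for p in parts:
            if p not in df.columns:
                raise ValidationError(f"term {term!r}: column {p!r} not found")
        v = np.ones(len(df))
        for p in parts:
            v = v * df[p].to_numpy(dtype=float)
        cols.append(v)
        names.append(":".join(parts))
    X = np.column_stack(cols)
    y = df[lhs].to_numpy(dtype=float)
    return y, X, names


# ---------------------------------------------------------------------------
# the model / results pair

class GrowthLMM:
    """Random-intercept linear mixed model, statsmodels-style.

    Parameters
    ----------
    endog : array
        Response vector.
    exog : array
        Fixed-effect design matrix (include the intercept column).
    groups : array
        Group label per record (the tree id).
    exog_names : list of str, optional
        Column names for reporting.
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        y = np.asarray(endog, dtype=float)
        X = np.asarray(exog, dtype=float)
        groups = np.asarray(groups)
        if X.ndim != 2 or len(y) != len(X) or len(groups) != len(y):
            raise ValidationError("endog, exog and groups must align")
        if np.unique(groups).size < 2:
            raise ValidationError("need at least 2 groups for a random intercept")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            names = exog_names or [f"x{j}" for j in range(X.shape[1])]
            _, R = np.linalg.qr(X)
            bad = [names[j] for j in range(X.shape[1])
                   if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
            raise ValidationError(
                f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
                f"suspect columns: {bad}"
            )
        # sort by group once so group blocks are contiguous
        order = np.argsort(groups, kind="stable")
        self.endog = y[order]
        self.exog = X[order]
        self.groups = groups[order]
        self.exog_names = list(exog_names) if exog_names else [
            f"x{j}" for j in range(X.shape[1])
        ]
        labels, starts = np.unique(self.groups, return_index=True)
        starts = np.sort(starts)
        self.group_labels = self.groups[starts]
        self._starts = starts
        self._sizes = np.diff(np.r_[starts, len(y)])
        # group sufficient statistics
        self._Sx = np.add.reduceat(self.exog, starts, axis=0)  # G x p
        self._Sy = np.add.reduceat(self.endog, starts)  # G
        self._XtX = self.exog.T @ self.exog
        self._Xty = self.exog.T @ self.endog
        self._yty = float(self.endog @ self.endog)

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame, groups: str = "tree_id"):
        y, X, names = _parse_formula(formula, data)
        return cls(y, X, data[groups].to_numpy(), exog_names=names)

    # -- profiled REML/ML pieces -------------------------------------------

    def _gls(self, theta: float):
        """GLS quantities at a fixed variance ratio θ = τ₀₀/σ²."""
        lam = 1.0 + self._sizes * theta  # per-group log|I + theta*J| = log(lam)
        c = theta / lam  # weight of the rank-1 correction
        A = self._XtX - (self._Sx * c[:, None]).T @ self._Sx
        b = self._Xty - self._Sx.T @ (c * self._Sy)
        beta = np.linalg.solve(A, b)
        ytWy = self._yty - float(c @ self._Sy**2)
        q = ytWy - 2.0 * float(beta @ b) + float(beta @ A @ beta)
        q = max(q, 1e-300)
        return beta, A, q, lam

    def _neg2_profiled(self, theta: float, reml: bool) -> float:
        n, p = self.exog.shape
        beta, A, q, lam = self._gls(theta)
        dof = n - p if reml else n
        crit = dof * np.log(q / dof) + float(np.sum(np.log(lam)))
        if reml:
            sign, logdet = np.linalg.slogdet(A)
            crit += logdet
        return crit

    def fit(self, reml: bool = True, theta: float | None = None) -> "GrowthLMMResults":
        """Estimate the model; optionally hold θ = τ₀₀/σ² fixed.

        With ``theta=0`` the GLS step reduces exactly to ordinary least
        squares (no between-group variance).
        """
        n, p = self.exog.shape
        boundary = False
        if theta is None:
            res = scipy.optimize.minimize_scalar(
                lambda lt: self._neg2_profiled(np.exp(lt), reml),
                bounds=_THETA_LOG_BOUNDS,
                method="bounded",
                options={"xatol": 1e-10},
            )
            theta_hat = float(np.exp(res.x))
            # polish on the theta scale: the log-scale search stops within
            # ~1e-7 relative of the optimum, tighter work needs a local pass
            polish = scipy.optimize.minimize_scalar(
                lambda t: self._neg2_profiled(t, reml),
                bounds=(theta_hat * (1.0 - 1e-3), theta_hat * (1.0 + 1e-3)),
                method="bounded",
                options={"xatol": theta_hat * 1e-12},
            )
            best = res.fun
            if polish.fun <= best:
                theta_hat, best = float(polish.x), polish.fun
            # the optimizer cannot reach theta=0; compare with the boundary
            if self._neg2_profiled(0.0, reml) <= best:
                theta_hat = 0.0
            if theta_hat <= np.exp(_THETA_LOG_BOUNDS[0]) * 1.001:
                theta_hat = 0.0
            if theta_hat == 0.0 or np.log(max(theta_hat, 1e-300)) >= _THETA_LOG_BOUNDS[1] - 1e-6:
                boundary = True
        else:
            theta_hat = float(theta)
            boundary = theta_hat == 0.0
        beta, A, q, lam = self._gls(theta_hat)
        dof = n - p if reml else n
        sigma2 = q / dof
        tau00 = theta_hat * sigma2
        cov_beta = sigma2 * np.linalg.inv(A)
        deviance = self._neg2_profiled(theta_hat, reml)
        # BLUPs of the random intercepts: u_g = θ S_g(resid) / (1 + n_g θ)
        resid = self.endog - self.exog @ beta
        s_resid = np.add.reduceat(resid, self._starts)
        blups = theta_hat * s_resid / lam
        return GrowthLMMResults(
            model=self,
            params=beta,
            cov_params=cov_beta,
            sigma2=float(sigma2),
            tau00=float(tau00),
            theta=float(theta_hat),
            reml=reml,
            deviance=float(deviance),
            boundary=boundary,
            blups=dict(zip(self.group_labels, blups)),
        )


@dataclass
class GrowthLMMResults:
    """Fitted random-intercept model: estimates, uncertainty, diagnostics."""

    model: GrowthLMM
    params: np.ndarray
    cov_params: np.ndarray
    sigma2: float
    tau00: float
    theta: float
    reml: bool
    deviance: float
    boundary: bool
    blups: dict

    @property
    def exog_names(self) -> list[str]:
        return self.model.exog_names

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * scipy.stats.norm.sf(np.abs(self.zvalues))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = scipy.stats.norm.ppf(1.0 - alpha / 2.0)
        se = self.bse
        return np.column_stack([self.params - z * se, self.params + z * se])

    @property
    def icc(self) -> float:
        return self.tau00 / (self.tau00 + self.sigma2)

    @property
    def n_obs(self) -> int:
        return len(self.model.endog)

    @property
    def n_groups(self) -> int:
        return len(self.model.group_labels)

    @property
    def fixed_variance(self) -> float:
        """Population variance of the fixed-effect linear predictor."""
        eta = self.model.exog @ self.params
        return float(np.var(eta))

    @property
    def marginal_r2(self) -> float:
        vf = self.fixed_variance
        return vf / (vf + self.tau00 + self.sigma2)

    @property
    def conditional_r2(self) -> float:
        vf = self.fixed_variance
        return (vf + self.tau00) / (vf + self.tau00 + self.sigma2)

    def fe_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "term": self.exog_names,
                "estimate": self.params,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )

    def summary(self) -> str:
        """Human-readable report: fixed effects then variance components."""
        lines = [
            f"Random-intercept linear mixed model "
            f"({'REML' if self.reml else 'ML'})",
            f"{'':28s}{'estimate':>12s}  {'95% CI':>23s}  {'p':>8s}",
        ]
        ci = self.conf_int()
        for j, name in enumerate(self.exog_names):
            p = self.pvalues[j]
            ptxt = "<0.001" if p < 1e-3 else f"{p:.3f}"
            lines.append(
                f"{name:28s}{self.params[j]:12.2f}  "
                f"[{ci[j, 0]:9.2f}, {ci[j, 1]:9.2f}]  {ptxt:>8s}"
            )
        lines += [
            "",
            f"{'sigma^2 (residual)':28s}{self.sigma2:12.2f}",
            f"{'tau00 (tree intercept)':28s}{self.tau00:12.2f}",
            f"{'ICC':28s}{self.icc:12.2f}",
            f"{'N (trees)':28s}{self.n_groups:12d}",
            f"{'observations':28s}{self.n_obs:12d}",
            f"{'marginal R2':28s}{self.marginal_r2:12.3f}",
            f"{'conditional R2':28s}{self.conditional_r2:12.3f}",
        ]
        if self.boundary:
            lines.append("note: variance ratio at boundary (tau00 -> 0)")
        return "\n".join(lines)


def fit_lmm(
    records: pd.DataFrame,
    formula: str = DEFAULT_FORMULA,
    reml: bool = True,
    groups: str = "tree_id",
) -> GrowthLMMResults:
    """Fit the growth mixed model to an assembled design frame."""
    return GrowthLMM.from_formula(formula, records, groups=groups).fit(reml=reml)


# ---------------------------------------------------------------------------
# validation harness

def simulate_lmm_records(
    design: pd.DataFrame,
    coefs: Mapping[str, float],
    tau00: float,
    sigma2: float,
    rng: np.random.Generator,
    formula: str = DEFAULT_FORMULA,
    groups: str = "tree_id",
) -> pd.DataFrame:
    """Resimulate the response of a design frame from known parameters.

    Used to validate the estimator under its own assumptions (bias,
    interval coverage): the fixed-effect predictor is built from `coefs`
    (keyed by term name as in the formula), a fresh random intercept is
    drawn per group and iid residuals are added.
    """
    _, X, names = _parse_formula(formula, design)
    missing = [n for n in names if n not in coefs]
    if missing:
        raise ValidationError(f"missing coefficients for terms: {missing}")
    beta = np.array([coefs[n] for n in names])
    eta = X @ beta
    glabels = design[groups].to_numpy()
    uniq = pd.unique(glabels)
    u = dict(zip(uniq, rng.normal(0.0, np.sqrt(tau00), size=len(uniq))))
    resp = eta + np.array([u[g] for g in glabels]) + rng.normal(
        0.0, np.sqrt(sigma2), size=len(design)
    )
    out = design.copy()
    lhs = formula.split("~")[0].strip()
    out[lhs] = resp
    return out


def recover_parameters(
    truth: Mapping[str, float],
    fit: GrowthLMMResults,
) -> pd.DataFrame:
    """Per-coefficient recovery report against known generator truth.

    Returns a frame with columns ``term, truth, estimate, bias, covered,
    sign_match`` where ``covered`` marks the 95% Wald interval containing
    the truth.
    """
    ci = fit.conf_int()
    rows = []
    for j, name in enumerate(fit.exog_names):
        if name not in truth:
            continue
        t = float(truth[name])
        est = float(fit.params[j])
        rows.append(
            dict(
                term=name,
                truth=t,
                estimate=est,
                bias=est - t,
                covered=bool(ci[j, 0] <= t <= ci[j, 1]),
                sign_match=bool(np.sign(est) == np.sign(t)) or t == 0.0,
            )
        )
    return pd.DataFrame(rows)
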
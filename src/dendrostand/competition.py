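"""Distance-dependent competition: the Hegyi index and its growth relation.

The Hegyi competition index of a target tree i is

    CI_i = Σ_j (D_j / D_i) · (1 / L_ij),

summed over the competitor trees j within a fixed search radius (default
8 m) whose DBH reaches a minimum size (default 5 cm); D are DBH in cm and
L_ij the Euclidean stem-to-stem distance in metres.  Large, close
neighbours raise the index; an isolated tree scores 0.

Edge handling follows the nested sampling design the index was built for:
target trees come from an interior core region while competitors are drawn
from the full plot, so a buffer wider than the search radius removes edge
bias without correction formulas.

The relation between a tree's recent cumulative basal-area increment and
its competition index is summarized by the decreasing power law
``y = a·x^(−b)`` fitted by nonlinear least squares on the original scale
(log–log OLS provides the starting point and the fallback).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, ValidationError
from .io_formats import StemMap

DEFAULT_RADIUS_M = 8.0
DEFAULT_MIN_DBH_CM = 5.0


@dataclass(frozen=True)
class CompetitionResult:
    """Hegyi index of one target tree with its competitor breakdown."""

    tree_id: str
    ci: float
    n_competitors: int
    #: rows (competitor_id, dbh_cm, distance_m, term)
    competitors: tuple[tuple[str, float, float, float], ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.competitors, columns=["competitor_id", "dbh_cm", "distance_m", "term"]
        )


def hegyi_ci(
    stem_map: StemMap,
    target: str,
    radius: float = DEFAULT_RADIUS_M,
    min_dbh: float = DEFAULT_MIN_DBH_CM,
    _tree: cKDTree | None = None,
) -> CompetitionResult:
    """Hegyi competition index for one target tree.

    Competitors are all other stems within `radius` metres with
    DBH >= `min_dbh` cm; coincident stems are a degenerate geometry and
    raise.  A prebuilt KD-tree over the stem map may be passed to avoid
    rebuilding it per target.
    """
    df = stem_map.df
    row = stem_map.tree(target)
    xy = df[["x", "y"]].to_numpy(dtype=float)
    ids = df["tree_id"].to_numpy()
    dbh = df["dbh"].to_numpy(dtype=float)
    tree = _tree if _tree is not None else cKDTree(xy)
    p = np.array([row["x"], row["y"]], dtype=float)
    idx = np.asarray(tree.query_ball_point(p, r=radius), dtype=int)
    d_i = float(row["dbh"])
    keep = idx[(ids[idx] != row["tree_id"]) & (dbh[idx] >= min_dbh)]
    dist = np.hypot(xy[keep, 0] - p[0], xy[keep, 1] - p[1])
    if np.any(dist == 0.0):
        twin = ids[keep[dist == 0.0][0]]
        raise DegenerateInputError(
            f"trees {row['tree_id']!r} and {twin!r} share coordinates "
            f"({row['x']}, {row['y']})"
        )
    terms = (dbh[keep] / d_i) / dist
    order = np.argsort(dist)
    comps = [
        (str(ids[keep[k]]), float(dbh[keep[k]]), float(dist[k]), float(terms[k]))
        for k in order
    ]
    return CompetitionResult(
        tree_id=str(row["tree_id"]),
        ci=float(sum(c[3] for c in comps)),
        n_competitors=len(comps),
        competitors=tuple(comps),
    )


def interior_targets(
    stem_map: StemMap,
    core_size: float = 30.0,
    sampled_only: bool = True,
) -> list[str]:
    """Tree ids inside the centred core region (targets for CI).

    With a 50 m plot and a 30 m core the 10 m buffer exceeds the 8 m search
    radius, so every target's full neighbourhood lies inside the plot.
    """
    df = stem_map.df
    lo = (stem_map.plot_size - core_size) / 2.0
    hi = lo + core_size
    inside = (df["x"] >= lo) & (df["x"] <= hi) & (df["y"] >= lo) & (df["y"] <= hi)
    if sampled_only:
        inside &= df["sampled"]
    return df.loc[inside, "tree_id"].tolist()


def hegyi_ci_all(
    stem_map: StemMap,
    targets: list[str] | None = None,
    radius: float = DEFAULT_RADIUS_M,
    min_dbh: float = DEFAULT_MIN_DBH_CM,
    edge_mode: str = "buffer",
    core_size: float = 30.0,
) -> dict[str, CompetitionResult]:
    """Hegyi CI for many targets sharing one KD-tree.

    ``edge_mode='buffer'`` (default) restricts targets to the interior core;
    ``'none'`` accepts any target list; Ripley-style boundary weighting is
    recognized but not implemented.
    """
    if edge_mode == "buffer":
        if targets is None:
            # study design: cored (sampled) trees of the interior core;
            # fall back to all interior stems when nothing is flagged sampled
            targets = sorted(interior_targets(stem_map, core_size)) or sorted(
                interior_targets(stem_map, core_size, sampled_only=False)
            )
        else:
            pool = set(interior_targets(stem_map, core_size, sampled_only=False))
            out = [t for t in targets if t not in pool]
            if out:
                raise ValidationError(
                    f"targets outside the {core_size} m core region: {out}"
                )
    elif edge_mode == "none":
        if targets is None:
            targets = stem_map.df["tree_id"].tolist()
    elif edge_mode == "ripley":
        raise NotImplementedError("Ripley-style boundary weighting is not implemented")
    else:
        raise ValueError(f"unknown edge_mode {edge_mode!r}")
    kd = cKDTree(stem_map.df[["x", "y"]].to_numpy(dtype=float))
    return {
        t: hegyi_ci(stem_map, t, radius=radius, min_dbh=min_dbh, _tree=kd)
        for t in targets
    }


def ci_summary(results: dict[str, CompetitionResult] | list[CompetitionResult]) -> dict:
    """min/max/mean/sd of CI across target trees (sd with n−1 denominator)."""
    vals = [r.ci for r in (results.values() if isinstance(results, dict) else results)]
    if not vals:
        raise ValidationError("no competition results to summarize")
    arr = np.asarray(vals, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return {
        "n": int(arr.size),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
        "sd": sd,
        "sd_defined": arr.size > 1,
    }


@dataclass(frozen=True)
class PowerFitResult:
    """Fitted decreasing power law y = a·x^(−b) with original-scale R²."""

    a: float
    b: float
    r2: float
    n: int
    window: int | None = None
    converged: bool = True

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(x, dtype=float) ** (-self.b)

    def summary(self) -> str:
        tag = "" if self.converged else "  [log-log fallback]"
        win = f", window={self.window} y" if self.window else ""
        return (
            f"y = {self.a:.2f} * x^(-{self.b:.3f})   "
            f"R² = {self.r2:.4f}  (n = {self.n}{win}){tag}"
        )


def fit_power(
    ci: np.ndarray,
    y: np.ndarray,
    window: int | None = None,
    max_iter: int = 200,
) -> PowerFitResult:
    """Fit y = a·x^(−b) to cumulative BAI vs competition index.

    Nonlinear least squares on the original scale, initialized from OLS on
    log y vs log x; on non-convergence the closed-form log–log estimates are
    returned with ``converged=False``.  R² = 1 − SS_res/SS_tot is computed
    on the original scale.
    """
    x = np.asarray(ci, dtype=float)
    yy = np.asarray(y, dtype=float)
    if x.shape != yy.shape or x.ndim != 1:
        raise ValidationError("ci and y must be 1-d arrays of equal length")
    if len(x) < 5:
        raise ValidationError("power fit needs n >= 5")
    if np.any(x <= 0) or np.any(yy <= 0):
        raise ValidationError("power fit requires strictly positive ci and y")

    slope, intercept = np.polyfit(np.log(x), np.log(yy), 1)
    a0, b0 = float(np.exp(intercept)), float(-slope)

    def model(xx, a, b):
        return a * xx ** (-b)

    converged = True
    try:
        popt, _ = scipy.optimize.curve_fit(
            model, x, yy, p0=[max(a0, 1e-12), b0], maxfev=max_iter * len(x)
        )
        a, b = float(popt[0]), float(popt[1])
    except RuntimeError:
        a, b, converged = a0, b0, False

    resid = yy - model(x, a, b)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((yy - yy.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return PowerFitResult(a=a, b=b, r2=r2, n=len(x), window=window, converged=converged)
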
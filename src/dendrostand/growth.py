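"""Basal-area-increment (BAI) reconstruction from ring widths and DBH.

Annual basal area increment is the cross-sectional area a stem adds at
breast height in one year,

    BAI_t = π (R_t² − R_{t−1}²),

with R_t the inside-bark radius (cm) at the end of year t.  Because the
measured ring widths of an increment core rarely sum exactly to the
DBH-derived radius, the widths are reconciled with the stem's outside
radius minus bark by a single proportional rescaling (every ring scaled by
the same factor so the outermost radius matches DBH/2 − bark exactly); the
alternative of anchoring the outermost ring without rescaling is available.

Radii are in cm and BAI in cm² throughout; the mixed-model stage converts
annual BAI to mm² (×100).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CoverageError, DegenerateInputError, ValidationError
from .io_formats import RingSeries

#: default bark thickness as a fraction of the DBH radius, used when a
#: per-tree bark measurement is absent
DEFAULT_BARK_FRACTION = 0.05

MM_PER_CM = 10.0


@dataclass(frozen=True)
class RadiusSeries:
    """Inside-bark radius at breast height per year, cm.

    ``start_radius`` is the radius just before the first measured ring —
    zero for a pith-complete core, positive when inner rings are missing.
    """

    tree_id: str
    first_year: int
    radii: np.ndarray  # cm, non-decreasing
    start_radius: float = 0.0

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        if np.any(np.diff(r) < 0):
            raise ValidationError(f"tree {self.tree_id}: radii must be non-decreasing")
        if np.any(r < 0) or self.start_radius < 0:
            raise ValidationError(f"tree {self.tree_id}: negative radius")
        if r[0] + 1e-12 < self.start_radius:
            raise ValidationError(
                f"tree {self.tree_id}: first radius below the pre-series radius"
            )
        object.__setattr__(self, "radii", r)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.radii))


@dataclass(frozen=True)
class BAISeries:
    """Annual basal area increments, cm²/year."""

    tree_id: str
    first_year: int
    bai: np.ndarray  # cm^2
    start_radius: float  # cm, radius before the first increment
    final_radius: float  # cm

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.bai))

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.bai) - 1

    def __len__(self) -> int:
        return len(self.bai)


def bark_thickness(dbh_cm: float, bark_cm: float | None = None) -> float:
    """Per-tree bark thickness, defaulting to 5% of the DBH radius."""
    if bark_cm is not None and np.isfinite(bark_cm):
        if bark_cm < 0:
            raise ValidationError("bark thickness must be >= 0")
        return float(bark_cm)
    return DEFAULT_BARK_FRACTION * dbh_cm / 2.0


def reconstruct_radii(
    tree_rings: RingSeries,
    dbh_cm: float,
    bark_cm: float | None = None,
    rescale: bool = True,
) -> RadiusSeries:
    """Turn a tree's (core-averaged) ring widths into an annual radius series.

    Widths (mm) are converted to cm and accumulated outward; with
    ``rescale=True`` (default) all rings are scaled by one common factor so
    the outermost radius equals ``dbh/2 − bark`` exactly, otherwise the
    outermost ring is anchored at that radius and the inner rings keep their
    measured sizes.
    """
    bark = bark_thickness(dbh_cm, bark_cm)
    if dbh_cm <= 2.0 * bark:
        raise ValidationError(
            f"tree {tree_rings.tree_id}: DBH {dbh_cm} cm does not exceed twice "
            f"the bark thickness {bark} cm"
        )
    w_cm = tree_rings.widths / MM_PER_CM
    total = float(w_cm.sum())
    if total == 0.0:
        raise DegenerateInputError(
            f"tree {tree_rings.tree_id}: ring widths sum to zero"
        )
    r_out = dbh_cm / 2.0 - bark
    cum = np.cumsum(w_cm)
    if rescale:
        radii = cum * (r_out / total)
        start = 0.0
    else:
        start = r_out - total
        if start < 0:
            raise ValidationError(
                f"tree {tree_rings.tree_id}: measured widths exceed the "
                "DBH-derived radius; use rescale=True"
            )
        radii = start + cum
    return RadiusSeries(tree_rings.tree_id, tree_rings.first_year, radii, start)


def bai_series(radii: RadiusSeries) -> BAISeries:
    """Annual BAI_t = π(R_t² − R_{t−1}²) from a radius series."""
    r = radii.radii
    r_prev = np.concatenate([[radii.start_radius], r[:-1]])
    bai = np.pi * (r**2 - r_prev**2)
    return BAISeries(
        tree_id=radii.tree_id,
        first_year=radii.first_year,
        bai=bai,
        start_radius=radii.start_radius,
        final_radius=float(r[-1]),
    )


def cumulative_bai(bai: BAISeries, window: int, end_year: int | None = None) -> float:
    """Sum of annual BAI over the trailing `window` years ending at `end_year`."""
    if window < 1:
        raise ValidationError("window must be >= 1 year")
    if end_year is None:
        end_year = bai.last_year
    start_year = end_year - window + 1
    if start_year < bai.first_year or end_year > bai.last_year:
        raise CoverageError(
            f"tree {bai.tree_id}: BAI series {bai.first_year}-{bai.last_year} "
            f"does not cover the window {start_year}-{end_year}"
        )
    lo = start_year - bai.first_year
    return float(bai.bai[lo : lo + window].sum())
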
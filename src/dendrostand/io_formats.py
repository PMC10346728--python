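"""Readers and writers for the pipeline's on-disk formats.

Three domain containers are defined here and consumed by every downstream
stage:

* :class:`RingSeries` — one increment core's dated ring widths (mm, measured
  to 0.01 mm), stored on disk in the classic Tucson/RWL decadal layout with
  integer fields in units of 0.01 mm and a ``999`` terminator.
* :class:`StemMap` — mapped tree positions (plot-local metres), DBH (cm),
  height (m) and a ``sampled`` flag marking cored target trees.
* :class:`ClimateTable` — monthly climate rows keyed by (year, month) with
  columns T, Tmax, Tmin (°C), P (mm), VPD (kPa) and scPDSI (dimensionless).

Missing climate cells are carried as NaN, never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, ParseError, ValidationError

CLIMATE_VARS = ("T", "Tmax", "Tmin", "P", "VPD", "scPDSI")

_RWL_STOPPERS = (999, -9999)


@dataclass(frozen=True)
class RingSeries:
    """Dated ring widths for a single core.

    Parameters
    ----------
    series_id : str
        Core identifier, conventionally tree id plus a core letter
        (``"HDG01A"``); at most 8 characters for RWL round-tripping.
    tree_id : str
        Identifier of the tree the core was taken from.
    first_year : int
        Calendar year of the innermost measured ring.
    widths : numpy.ndarray
        Ring widths in mm, one per year, all >= 0.
    """

    series_id: str
    tree_id: str
    first_year: int
    widths: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.widths, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ValidationError(
                f"series {self.series_id!r}: widths must be a non-empty 1-d sequence"
            )
        if np.any(~np.isfinite(w)) or np.any(w < 0):
            raise ValidationError(
                f"series {self.series_id!r}: widths must be finite and >= 0"
            )
        object.__setattr__(self, "widths", w)

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def __len__(self) -> int:
        return len(self.widths)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RingSeries):
            return NotImplemented
        return (
            self.series_id == other.series_id
            and self.tree_id == other.tree_id
            and self.first_year == other.first_year
            and len(self.widths) == len(other.widths)
            and bool(np.allclose(self.widths, other.widths, atol=1e-12))
        )


def _infer_tree_id(series_id: str) -> str:
    """Tree id = series id minus a single trailing core letter, if any."""
    if len(series_id) >= 2 and series_id[-1].isalpha() and series_id[:-1][-1].isdigit():
        return series_id[:-1]
    return series_id


def read_rwl(path: str | Path) -> list[RingSeries]:
    """Read a Tucson/RWL decadal ring-width file.

    Integer width fields are in 0.01 mm and converted to mm; a ``999`` or
    ``-9999`` field terminates a series.  Decade lines of one series must be
    contiguous.
    """
    path = Path(path)
    series: list[RingSeries] = []
    cur_id: str | None = None
    cur_first: int | None = None
    cur_vals: list[float] = []
    next_year: int | None = None

    def _flush(closed: bool, lineno: int) -> None:
        nonlocal cur_id, cur_first, cur_vals, next_year
        if cur_id is None:
            return
        if not closed:
            raise ParseError(
                f"{path}: line {lineno}: series {cur_id!r} has no 999 terminator"
            )
        if not cur_vals:
            raise ParseError(f"{path}: series {cur_id!r} has no width values")
        series.append(
            RingSeries(cur_id, _infer_tree_id(cur_id), int(cur_first), np.array(cur_vals))
        )
        cur_id, cur_first, cur_vals, next_year = None, None, [], None

    with open(path) as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if not sid or not rest:
                raise ParseError(f"{path}: line {lineno}: malformed decade line")
            try:
                year = int(rest[0])
                fields = [int(tok) for tok in rest[1:]]
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer field ({exc})"
                ) from None
            if not fields:
                raise ParseError(f"{path}: line {lineno}: decade line has no values")

            if sid != cur_id:
                _flush(closed=False, lineno=lineno)  # raises if previous unterminated
                cur_id, cur_first, next_year = sid, year, year
            elif next_year is not None and year != next_year:
                raise IntegrityError(
                    f"{path}: line {lineno}: series {sid!r} expected decade year "
                    f"{next_year}, found {year}"
                )

            closed = False
            for val in fields:
                if val in _RWL_STOPPERS:
                    closed = True
                    break
                cur_vals.append(val / 100.0)
            next_year = year + len(fields) if not closed else None
            if closed:
                _flush(closed=True, lineno=lineno)
        if cur_id is not None:
            _flush(closed=False, lineno=lineno)

    seen: set[str] = set()
    for s in series:
        if s.series_id in seen:
            raise IntegrityError(f"{path}: duplicate series id {s.series_id!r}")
        seen.add(s.series_id)
    return series


def write_rwl(collection: Iterable[RingSeries], path: str | Path) -> None:
    """Write series in Tucson decadal layout (0.01 mm integers, 999 stop).

    Output is bit-stable: the same collection always yields identical bytes.
    """
    path = Path(path)
    lines: list[str] = []
    for s in collection:
        if len(s.series_id) > 8:
            raise ValidationError(
                f"series id {s.series_id!r} exceeds the 8-character RWL field"
            )
        ints = [int(round(w * 100.0)) for w in s.widths]
        if any(v in _RWL_STOPPERS for v in ints):
            raise ValidationError(
                f"series {s.series_id!r}: a width of "
                f"{_RWL_STOPPERS} * 0.01 mm collides with the terminator"
            )
        year = s.first_year
        vals = ints + [999]
        i = 0
        while i < len(vals):
            # a decade line holds the years up to the next multiple of 10
            room = 10 - (year % 10)
            chunk = vals[i : i + room]
            lines.append(
                f"{s.series_id:<8}{year:4d}" + "".join(f"{v:6d}" for v in chunk)
            )
            i += len(chunk)
            year += len(chunk)
    path.write_text("".join(line + "\n" for line in lines))


@dataclass
class StemMap:
    """Mapped stems of the plot: positions, DBH, height and sampling flags.

    The table lives in ``df`` with at least columns ``tree_id, x, y, dbh``;
    ``height``, ``sampled`` and ``bark_cm`` are optional.  Coordinates are
    plot-local metres with the origin at a plot corner, y pointing north;
    distances are Euclidean.
    """

    df: pd.DataFrame
    plot_size: float = 50.0

    def __post_init__(self) -> None:
        df = self.df.copy()
        required = {"tree_id", "x", "y", "dbh"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"stem map missing columns: {sorted(missing)}")
        if "sampled" not in df.columns:
            df["sampled"] = False
        df["sampled"] = df["sampled"].astype(bool)
        df["tree_id"] = df["tree_id"].astype(str)
        if df["tree_id"].duplicated().any():
            dups = df.loc[df["tree_id"].duplicated(), "tree_id"].tolist()
            raise ValidationError(f"duplicate tree ids: {dups}")
        bad = df[
            (df["x"] < 0)
            | (df["x"] > self.plot_size)
            | (df["y"] < 0)
            | (df["y"] > self.plot_size)
        ]
        if len(bad):
            raise ValidationError(
                f"coordinates outside the {self.plot_size} m plot for trees: "
                f"{bad['tree_id'].tolist()}"
            )
        bad = df[~(df["dbh"] > 0)]
        if len(bad):
            raise ValidationError(
                f"non-positive DBH for trees: {bad['tree_id'].tolist()}"
            )
        samp = df[df["sampled"]]
        bad_ids = samp.loc[samp["dbh"] < 5.0, "tree_id"].tolist()
        if "height" in df.columns:
            bad_ids += samp.loc[samp["height"] < 2.0, "tree_id"].tolist()
        if bad_ids:
            raise ValidationError(
                "sampled target trees must have DBH >= 5 cm and height >= 2 m; "
                f"violated by: {sorted(set(bad_ids))}"
            )
        self.df = df.reset_index(drop=True)

    @property
    def sampled_ids(self) -> list[str]:
        return self.df.loc[self.df["sampled"], "tree_id"].tolist()

    def tree(self, tree_id: str) -> pd.Series:
        rows = self.df[self.df["tree_id"] == str(tree_id)]
        if rows.empty:
            raise KeyError(f"tree {tree_id!r} not in stem map")
        return rows.iloc[0]

    def __len__(self) -> int:
        return len(self.df)


def read_stem_map(path: str | Path, plot_size: float = 50.0) -> StemMap:
    """Read a stem-map CSV (header with tree_id, x, y, dbh at minimum).

    Unknown columns are preserved untouched on the underlying frame.
    """
    df = pd.read_csv(path)
    return StemMap(df, plot_size=plot_size)


def write_stem_map(stem_map: StemMap, path: str | Path) -> None:
    stem_map.df.to_csv(path, index=False)


@dataclass
class ClimateTable:
    """Monthly climate observations keyed by (year, month).

    ``df`` is indexed by a (year, month) MultiIndex and holds the columns in
    :data:`CLIMATE_VARS`; absent observations are NaN.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        if not isinstance(df.index, pd.MultiIndex):
            df = df.set_index(["year", "month"])
        df.index = df.index.set_names(["year", "month"])
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].tolist()
            raise IntegrityError(f"duplicate (year, month) rows: {dup[:5]}")
        months = df.index.get_level_values("month")
        if ((months < 1) | (months > 12)).any():
            raise ValidationError("month must be in 1..12")
        for col in CLIMATE_VARS:
            if col not in df.columns:
                df[col] = np.nan
        both = df[["Tmin", "T", "Tmax"]].dropna()
        bad = both[(both["Tmin"] > both["T"]) | (both["T"] > both["Tmax"])]
        if len(bad):
            raise ValidationError(
                f"Tmin <= T <= Tmax violated at: {bad.index.tolist()[:5]}"
            )
        for col in ("P", "VPD"):
            vals = df[col].dropna()
            if (vals < 0).any():
                raise ValidationError(f"negative {col} values present")
        self.df = df[list(CLIMATE_VARS)].sort_index()

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.df.index.get_level_values("year"))

    def value(self, year: int, month: int, var: str) -> float:
        try:
            return float(self.df.loc[(year, month), var])
        except KeyError:
            return math.nan

    def monthly(self, var: str) -> pd.Series:
        """One variable as a Series indexed by (year, month)."""
        return self.df[var]


def read_climate(path: str | Path, layout: str = "auto") -> ClimateTable:
    """Read a monthly climate CSV in wide or long layout.

    Wide: one row per (year, month) with variable columns.  Long: rows of
    ``year, month, var, value``.  ``layout='auto'`` sniffs the header.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if layout == "auto":
        layout = "long" if {"var", "value"} <= cols else "wide"
    if layout == "long":
        if not {"year", "month", "var", "value"} <= cols:
            raise ParseError(f"{path}: long layout needs year,month,var,value columns")
        dup = df.duplicated(subset=["year", "month", "var"])
        if dup.any():
            raise IntegrityError(f"{path}: duplicate (year, month, var) rows")
        wide = df.pivot(index=["year", "month"], columns="var", values="value")
        wide.columns.name = None
        return ClimateTable(wide.reset_index())
    if not {"year", "month"} <= cols:
        raise ParseError(f"{path}: wide layout needs year and month columns")
    return ClimateTable(df)


def write_climate(climate: ClimateTable, path: str | Path, layout: str = "wide") -> None:
    if layout == "wide":
        climate.df.reset_index().to_csv(path, index=False)
    elif layout == "long":
        long = (
            climate.df.reset_index()
            .melt(id_vars=["year", "month"], var_name="var", value_name="value")
            .dropna(subset=["value"])
            .sort_values(["year", "month", "var"])
        )
        long.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def average_cores_by_tree(collection: Sequence[RingSeries]) -> list[RingSeries]:
    """Average the cores of each tree year-wise into one series per tree.

    Years covered by only one core use that core's width.  The result keeps
    the tree id as series id.
    """
    by_tree: dict[str, list[RingSeries]] = {}
    for s in collection:
        by_tree.setdefault(s.tree_id, []).append(s)
    out: list[RingSeries] = []
    for tree_id, group in sorted(by_tree.items()):
        first = min(s.first_year for s in group)
        last = max(s.last_year for s in group)
        n = last - first + 1
        total = np.zeros(n)
        count = np.zeros(n)
        for s in group:
            lo = s.first_year - first
            total[lo : lo + len(s)] += s.widths
            count[lo : lo + len(s)] += 1
        covered = count > 0
        if not covered.all():
            # keep the maximal contiguous covered block ending at `last`
            gap = np.nonzero(~covered)[0]
            start = gap[-1] + 1
            total, count = total[start:], count[start:]
            first += start
        out.append(RingSeries(tree_id, tree_id, first, total / count))
    return out
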
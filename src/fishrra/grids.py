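"""Dekadal aggregation, 0.1-degree gridding, CPUE and catch-weighted centroids.

Catch per unit effort (CPUE, tonnes per haul by default) is computed per
grid cell and ten-day period ("dekad"); cells are then binarised into
high/low relative resource abundance (RRA) by comparing CPUE with a
threshold, by default the global median over all cell-dekads.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from functools import total_ordering
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: dekad segments: F = days 1-10, S = days 11-20, L = day 21 to month end
SEGMENTS = ("F", "S", "L")


@total_ordering
@dataclass(frozen=True)
class Dekad:
    """A ten-day period: one of three segments (F/S/L) of a calendar month."""

    year: int
    month: int
    segment: str

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise ValueError(f"segment must be one of {SEGMENTS}, got {self.segment!r}")
        if not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")

    @property
    def sort_key(self) -> tuple[int, int, int]:
        return (self.year, self.month, SEGMENTS.index(self.segment))

    def __lt__(self, other: "Dekad") -> bool:
        return self.sort_key < other.sort_key

    @classmethod
    def from_date(cls, d: dt.date) -> "Dekad":
        if d.day <= 10:
            seg = "F"
        elif d.day <= 20:
            seg = "S"
        else:
            seg = "L"
        return cls(d.year, d.month, seg)

    @property
    def start(self) -> dt.date:
        day = {"F": 1, "S": 11, "L": 21}[self.segment]
        return dt.date(self.year, self.month, day)

    @property
    def label(self) -> str:
        return f"{self.year:04d}-{self.month:02d}-{self.segment}"

    @classmethod
    def from_label(cls, s: str) -> "Dekad":
        y, m, seg = s.split("-")
        return cls(int(y), int(m), seg)

    def next(self) -> "Dekad":
        i = SEGMENTS.index(self.segment)
        if i < 2:
            return Dekad(self.year, self.month, SEGMENTS[i + 1])
        if self.month == 12:
            return Dekad(self.year + 1, 1, "F")
        return Dekad(self.year, self.month + 1, "F")


def to_dekad(d: dt.date | dt.datetime | pd.Timestamp) -> Dekad:
    """Map a calendar date to its dekad; the segment depends only on the day."""
    if isinstance(d, (dt.datetime, pd.Timestamp)):
        d = d.date()
    return Dekad.from_date(d)


def dekad_range(start: dt.date, end: dt.date) -> list[Dekad]:
    """All dekads from the one containing ``start`` to the one containing ``end``."""
    if end < start:
        raise ValueError("end before start")
    out = [Dekad.from_date(start)]
    last = Dekad.from_date(end)
    while out[-1] < last:
        out.append(out[-1].next())
    return out


@dataclass(frozen=True)
class GridDefinition:
    """Regular lat/lon lattice with half-open cells [edge, edge + step)."""

    lat_min: float
    lon_min: float
    step: float
    n_lat: int
    n_lon: int

    @classmethod
    def from_bbox(
        cls, lat_min: float, lat_max: float, lon_min: float, lon_max: float, step: float = 0.1
    ) -> "GridDefinition":
        if step <= 0:
            raise ValueError("step must be positive")
        if lat_max <= lat_min or lon_max <= lon_min:
            raise ValueError("degenerate bounding box")
        n_lat = int(np.ceil(round((lat_max - lat_min) / step, 9)))
        n_lon = int(np.ceil(round((lon_max - lon_min) / step, 9)))
        return cls(lat_min, lon_min, step, n_lat, n_lon)

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_lat * self.step

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_lon * self.step

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.step

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.step

    def assign_cell(self, lat, lon):
        """Vectorised half-open binning; out-of-box positions get index -1.

        A point exactly on an interior edge belongs to the cell whose lower
        edge it is.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        i = np.floor((lat - self.lat_min) / self.step).astype(int)
        j = np.floor((lon - self.lon_min) / self.step).astype(int)
        inside = (i >= 0) & (i < self.n_lat) & (j >= 0) & (j < self.n_lon)
        i = np.where(inside, i, -1)
        j = np.where(inside, j, -1)
        return i, j

    def cell_lower_left(self, i, j) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.lat_min + np.asarray(i) * self.step,
            self.lon_min + np.asarray(j) * self.step,
        )

    def cell_center(self, i, j) -> tuple[np.ndarray, np.ndarray]:
        ll = self.cell_lower_left(i, j)
        return ll[0] + self.step / 2, ll[1] + self.step / 2


@dataclass(frozen=True)
class Centroid:
    """Catch-weighted mean haul position: X is latitude, Y is longitude."""

    X: float
    Y: float
    period: str
    total_catch: float


def assign_cell(lat: float, lon: float, grid: GridDefinition) -> tuple[int, int]:
    """Scalar convenience wrapper around :meth:`GridDefinition.assign_cell`."""
    i, j = grid.assign_cell(lat, lon)
    return int(i), int(j)


def compute_cpue(
    hauls: pd.DataFrame,
    grid: GridDefinition,
    effort_model: str = "per_haul",
    position: str = "set",
) -> pd.DataFrame:
    """Aggregate hauls into cell-dekad CPUE.

    CPUE_{i,j,t} = sum_k C_{i,j,t,k} / sum_k E_{i,j,t,k}, where k runs over
    the hauls falling in cell (i, j) during dekad t. With the default
    ``per_haul`` effort model every haul has E = 1, so CPUE is mean catch
    per haul (t/net). ``haul_hours`` uses haul duration in hours as effort.

    Hauls outside the grid are excluded; their count is logged and stored in
    ``result.attrs["n_outside"]``.
    """
    if effort_model not in ("per_haul", "haul_hours"):
        raise ValueError(f"unknown effort model {effort_model!r}")
    if position == "set":
        lat = hauls["set_lat"].to_numpy()
        lon = hauls["set_lon"].to_numpy()
    elif position == "midpoint":
        lat = (hauls["set_lat"].to_numpy() + hauls["retrieve_lat"].to_numpy()) / 2
        lon = (hauls["set_lon"].to_numpy() + hauls["retrieve_lon"].to_numpy()) / 2
    else:
        raise ValueError(f"unknown position rule {position!r}")

    i, j = grid.assign_cell(lat, lon)
    inside = i >= 0
    n_outside = int((~inside).sum())
    if n_outside:
        logger.warning("%d hauls outside the grid were excluded", n_outside)

    df = hauls.loc[inside].copy()
    df["i"] = i[inside]
    df["j"] = j[inside]
    set_times = pd.to_datetime(df["set_time"])
    df["dekad"] = [to_dekad(t).label for t in set_times]
    if effort_model == "per_haul":
        df["effort"] = 1.0
    else:
        dur = (pd.to_datetime(df["retrieve_time"]) - set_times).dt.total_seconds() / 3600.0
        if (dur <= 0).any():
            raise ValueError("non-positive haul duration under haul_hours effort")
        df["effort"] = dur

    g = df.groupby(["i", "j", "dekad"], as_index=False).agg(
        n_hauls=("catch_t", "size"),
        total_catch_t=("catch_t", "sum"),
        total_effort=("effort", "sum"),
    )
    assert (g["total_effort"] > 0).all(), "zero effort in an occupied cell"
    g["cpue"] = g["total_catch_t"] / g["total_effort"]
    lat_ll, lon_ll = grid.cell_lower_left(g["i"].to_numpy(), g["j"].to_numpy())
    g["lat_ll"] = lat_ll
    g["lon_ll"] = lon_ll
    g.attrs["n_outside"] = n_outside
    return g


def label_rra(
    cells: pd.DataFrame, threshold: float | str = "median"
) -> tuple[pd.DataFrame, float]:
    """Binarise cell-dekads into high/low RRA.

    ``threshold="median"`` uses the global median of all cell-dekad CPUE
    values. Cells with CPUE strictly greater than the threshold are "high";
    ties go to "low".
    """
    if len(cells) < 2:
        raise ValueError("need at least 2 cell-dekads to label")
    cpue = cells["cpue"].to_numpy()
    thr = float(np.median(cpue)) if threshold == "median" else float(threshold)
    out = cells.copy()
    out["rra_label"] = np.where(cpue > thr, "high", "low")
    if (out["rra_label"] == "low").all():
        logger.warning("every cell labelled low (threshold %.4g)", thr)
    return out, thr


def centroid(
    df: pd.DataFrame,
    lat_col: str = "set_lat",
    lon_col: str = "set_lon",
    weight_col: str = "catch_t",
    period: str = "season",
) -> Centroid:
    """Catch-weighted centroid: X = sum(C_i X_i)/sum(C_i), Y likewise with Y_i."""
    w = df[weight_col].to_numpy(dtype=float)
    if w.sum() <= 0:
        raise ValueError("total weight must be positive")
    x = float(np.average(df[lat_col].to_numpy(dtype=float), weights=w))
    y = float(np.average(df[lon_col].to_numpy(dtype=float), weights=w))
    return Centroid(X=x, Y=y, period=period, total_catch=float(w.sum()))


def seasonal_centroids(hauls: pd.DataFrame, by: str = "dekad") -> pd.DataFrame:
    """Centroid per dekad (or per month with ``by="month"``)."""
    t = pd.to_datetime(hauls["set_time"])
    if by == "dekad":
        keys = [to_dekad(x).label for x in t]
    elif by == "month":
        keys = t.dt.strftime("%Y-%m")
    else:
        raise ValueError(f"unknown grouping {by!r}")
    rows = []
    df = hauls.assign(_key=keys)
    for key, grp in df.groupby("_key", sort=True):
        if grp["catch_t"].sum() <= 0:
            continue
        c = centroid(grp, period=str(key))
        rows.append({"period": c.period, "X": c.X, "Y": c.Y, "total_catch": c.total_catch})
    return pd.DataFrame(rows)
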
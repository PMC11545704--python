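"""Environmental raster stacks, regridding, and per-cell feature extraction.

The analysis works on dekadal raster cubes of seven oceanographic covariates
(SST, SSS, SSH, chlorophyll-a, 50 m and 100 m water temperature, mixed layer
depth) on a regular 0.1-degree lattice. Source products on a different
lattice (e.g. 0.083 degrees) are regridded by area-weighted averaging. Each
labelled cell-dekad is then joined with the covariate values at its cell,
plus the cell-centre longitude and latitude, giving the nine candidate
predictors used by the classifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .grids import Dekad, GridDefinition

logger = logging.getLogger(__name__)

#: environmental factor ids, in canonical order
FACTORS = ("sst", "sss", "ssh", "chla", "t50", "t100", "mld")

#: the nine candidate predictors (seven covariates + cell-centre coordinates)
PREDICTORS = FACTORS + ("lon", "lat")

UNITS = {
    "sst": "degC",
    "sss": "permille",
    "ssh": "cm",
    "chla": "mg m-3",
    "t50": "degC",
    "t100": "degC",
    "mld": "m",
    "lon": "degrees_east",
    "lat": "degrees_north",
}


@dataclass
class EnvStack:
    """Dekadal raster stack of environmental covariates on one grid.

    ``data`` has dims (time, lat, lon); the time coordinate holds dekad
    labels (``"YYYY-MM-F"`` etc.), lat/lon hold cell centres. Missing values
    are NaN.
    """

    data: xr.Dataset
    grid: GridDefinition

    @property
    def factors(self) -> tuple[str, ...]:
        return tuple(self.data.data_vars)

    @property
    def dekads(self) -> list[Dekad]:
        return [Dekad.from_label(str(t)) for t in self.data["time"].values]

    def values(self, factor: str) -> np.ndarray:
        return self.data[factor].to_numpy()

    def covers(self, grid: GridDefinition, dekads: Iterable[Dekad]) -> bool:
        labels = {str(t) for t in self.data["time"].values}
        if any(d.label not in labels for d in dekads):
            return False
        eps = 1e-9
        return (
            self.grid.lat_min <= grid.lat_min + eps
            and self.grid.lat_max >= grid.lat_max - eps
            and self.grid.lon_min <= grid.lon_min + eps
            and self.grid.lon_max >= grid.lon_max - eps
            and abs(self.grid.step - grid.step) < eps
        )

    def to_netcdf(self, path) -> None:
        ds = self.data.copy()
        # time as strings is not NETCDF3-safe; store the labels as an attr
        ds = ds.assign_coords(time=np.arange(ds.sizes["time"]))
        ds.attrs["dekad_labels"] = " ".join(str(t) for t in self.data["time"].values)
        ds.attrs["grid"] = (
            f"{self.grid.lat_min} {self.grid.lon_min} {self.grid.step} "
            f"{self.grid.n_lat} {self.grid.n_lon}"
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "EnvStack":
        ds = xr.open_dataset(path, engine="scipy").load()
        labels = ds.attrs["dekad_labels"].split()
        ds = ds.assign_coords(time=labels)
        g = ds.attrs["grid"].split()
        grid = GridDefinition(float(g[0]), float(g[1]), float(g[2]), int(g[3]), int(g[4]))
        return cls(data=ds, grid=grid)


def _edges(centers: np.ndarray) -> np.ndarray:
    centers = np.asarray(centers, dtype=float)
    if centers.size < 2:
        step = 0.1
    else:
        step = centers[1] - centers[0]
    return np.concatenate([centers - step / 2, [centers[-1] + step / 2]])


def _overlap_matrix(tgt_edges: np.ndarray, src_edges: np.ndarray) -> np.ndarray:
    """W[i, s] = length of overlap between target interval i and source interval s."""
    lo = np.maximum(tgt_edges[:-1, None], src_edges[None, :-1])
    hi = np.minimum(tgt_edges[1:, None], src_edges[None, 1:])
    return np.clip(hi - lo, 0.0, None)


def regrid(source: xr.DataArray, target: GridDefinition, min_coverage: float = 0.5) -> xr.DataArray:
    """Area-weighted regridding onto the analysis lattice.

    Each target cell takes the area-weighted mean of overlapping source
    cells, ignoring missing source cells; a target cell is set missing when
    less than ``min_coverage`` of its area is backed by valid data.
    Axes are separable on regular lat/lon grids, so the weights factor into
    two 1-D overlap matrices.
    """
    src_lat = np.asarray(source["lat"].values, dtype=float)
    src_lon = np.asarray(source["lon"].values, dtype=float)
    w_lat = _overlap_matrix(_edges(target.lat_centers), _edges(src_lat))
    w_lon = _overlap_matrix(_edges(target.lon_centers), _edges(src_lon))
    if w_lat.sum() == 0 or w_lon.sum() == 0:
        raise ValueError("source and target extents are disjoint")

    vals = source.to_numpy()
    squeeze = vals.ndim == 2
    if squeeze:
        vals = vals[None, ...]
    valid = np.isfinite(vals).astype(float)
    filled = np.where(np.isfinite(vals), vals, 0.0)

    num = np.einsum("ia,tab,jb->tij", w_lat, filled * valid, w_lon)
    den = np.einsum("ia,tab,jb->tij", w_lat, valid, w_lon)
    cell_area = target.step * target.step
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    out = np.where(den / cell_area >= min_coverage, out, np.nan)
    if squeeze:
        out = out[0]
        dims = ("lat", "lon")
        coords = {"lat": target.lat_centers, "lon": target.lon_centers}
    else:
        dims = (source.dims[0], "lat", "lon")
        coords = {
            source.dims[0]: source[source.dims[0]].values,
            "lat": target.lat_centers,
            "lon": target.lon_centers,
        }
    return xr.DataArray(out, dims=dims, coords=coords, name=source.name, attrs=source.attrs)


def regrid_stack(env: EnvStack, target: GridDefinition, min_coverage: float = 0.5) -> EnvStack:
    """Regrid every factor of a stack onto a new lattice."""
    das = {f: regrid(env.data[f], target, min_coverage) for f in env.factors}
    ds = xr.Dataset(das, attrs=env.data.attrs)
    return EnvStack(data=ds, grid=target)


def build_features(
    cells: pd.DataFrame,
    env: EnvStack,
    optional_factors: Sequence[str] = (),
) -> pd.DataFrame:
    """Attach the nine candidate predictors to every labelled cell-dekad.

    Lon/Lat are cell-centre coordinates. Rows with a missing mandatory
    predictor are dropped with a logged count; factors named in
    ``optional_factors`` (typically ``("t100",)`` where bathymetry makes it
    patchy) may stay NaN without dropping the row. The dropped-row count is
    stored in ``result.attrs["n_dropped"]``.
    """
    labels = [str(t) for t in env.data["time"].values]
    t_index = {lab: k for k, lab in enumerate(labels)}
    missing_dekads = sorted(set(cells["dekad"]) - set(labels))
    if missing_dekads:
        raise KeyError(f"dekads absent from the environmental stack: {missing_dekads}")

    i = cells["i"].to_numpy(dtype=int)
    j = cells["j"].to_numpy(dtype=int)
    t = np.array([t_index[d] for d in cells["dekad"]], dtype=int)

    out = cells[["i", "j", "dekad"]].copy()
    if "rra_label" in cells:
        out["rra_label"] = cells["rra_label"].to_numpy()
    for f in env.factors:
        out[f] = env.values(f)[t, i, j]
    lat_c, lon_c = env.grid.cell_center(i, j)
    out["lon"] = lon_c
    out["lat"] = lat_c

    mandatory = [p for p in PREDICTORS if p in out.columns and p not in optional_factors]
    complete = np.isfinite(out[mandatory].to_numpy(dtype=float)).all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d cell-dekads with missing mandatory predictors", n_dropped)
    res = out.loc[complete].reset_index(drop=True)
    res.attrs["n_dropped"] = n_dropped
    return res


@dataclass
class MinMaxScaler:
    """Per-predictor min-max scaling to [0, 1], fitted on training rows only."""

    columns: tuple[str, ...]
    mins: np.ndarray = field(default=None, repr=False)
    ranges: np.ndarray = field(default=None, repr=False)

    def fit(self, df: pd.DataFrame) -> "MinMaxScaler":
        x = df[list(self.columns)].to_numpy(dtype=float)
        self.mins = np.nanmin(x, axis=0)
        rng = np.nanmax(x, axis=0) - self.mins
        self.ranges = np.where(rng > 0, rng, 1.0)
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        if self.mins is None:
            raise RuntimeError("scaler not fitted")
        x = df[list(self.columns)].to_numpy(dtype=float)
        return (x - self.mins) / self.ranges
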
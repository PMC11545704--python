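"""Synthetic fleet, logbook and environment generator with known ground truth.

Real trawler logbooks and AIS/VMS position streams are proprietary, so the
pipeline is exercised on simulated data whose statistical structure matches
what the analysis assumes: bounded random-walk vessel tracks reporting fixes
every few hours; haul records whose logged positions carry an injected error
(offset above the downstream 0.3-degree correction threshold) at a
configurable rate; smooth seasonal environmental fields; and catch per haul
drawn from a gamma distribution whose mean is proportional to a habitat
suitability computed as a product of smooth per-factor window responses over
the informative covariates. Everything is recorded in a GroundTruth object
so recovery can be tested exactly.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from .env_features import FACTORS, UNITS, EnvStack
from .grids import Dekad, GridDefinition, dekad_range, to_dekad

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for one simulated fishing season.

    The season runs December through June (southern-hemisphere squid trawl
    season). ``error_rate`` defaults to the 8.4% share of logbook positions
    that disagree with the vessel track by more than the 0.3-degree audit
    threshold; injected offsets are at least ``error_min_offset_deg`` per
    axis so every injected error is detectable.
    """

    bbox: tuple[float, float, float, float] = (-47.0, -42.0, -61.0, -57.0)
    season_start: dt.date = dt.date(2023, 12, 1)
    season_end: dt.date = dt.date(2024, 6, 30)
    n_vessels: int = 20
    fix_interval_hours: float = 2.0
    hauls_per_vessel_day: float = 3.0
    error_rate: float = 0.084
    error_min_offset_deg: float = 0.31
    grid_step: float = 0.1
    t100_missing_frac: float = 0.15
    fleet_targeting: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lat_min, lat_max, lon_min, lon_max = self.bbox
        if not (lat_min < lat_max and lon_min < lon_max):
            raise ValueError("degenerate bbox")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.season_end <= self.season_start:
            raise ValueError("season_end must follow season_start")
        if not 0.0 <= self.t100_missing_frac < 1.0:
            raise ValueError("t100_missing_frac must be in [0, 1)")

    @property
    def grid(self) -> GridDefinition:
        lat_min, lat_max, lon_min, lon_max = self.bbox
        return GridDefinition.from_bbox(lat_min, lat_max, lon_min, lon_max, self.grid_step)

    @property
    def dekads(self) -> list[Dekad]:
        return dekad_range(self.season_start, self.season_end)


@dataclass(frozen=True)
class SuitabilityParams:
    """Habitat suitability windows and catch-model parameters.

    Windows are the optimal ranges of the five informative covariates for
    Illex argentinus: SST 10.1-14.6 degC, SSS 33.8-34.1 permille, SSH -16.4
    to -3.6 cm, 50 m temperature 5.9-8.9 degC, and three MLD intervals
    (12.9-26.1, 30.8-33.4, 37.8-40.4 m). Suitability is the product of
    smooth per-factor window responses (logistic shoulders) over
    ``informative_factors``; remaining factors (plus lon/lat) are inert and
    carry no signal about catch beyond what the informative ones explain.
    """

    sst_range: tuple[float, float] = (10.1, 14.6)
    sss_range: tuple[float, float] = (33.8, 34.1)
    ssh_range: tuple[float, float] = (-16.4, -3.6)
    t50_range: tuple[float, float] = (5.9, 8.9)
    mld_ranges: tuple[tuple[float, float], ...] = (
        (12.9, 26.1),
        (30.8, 33.4),
        (37.8, 40.4),
    )
    edge_width_frac: float = 0.1
    catch_scale: float = 2.0
    catch_dispersion: float = 2.0
    informative_factors: tuple[str, ...] = ("sst", "mld", "sss", "ssh", "t50")

    def __post_init__(self) -> None:
        for lo, hi in (self.sst_range, self.sss_range, self.ssh_range, self.t50_range):
            if not lo < hi:
                raise ValueError("degenerate response window")
        for lo, hi in self.mld_ranges:
            if not lo < hi:
                raise ValueError("degenerate MLD window")
        if self.catch_scale <= 0:
            raise ValueError("catch_scale must be positive")
        unknown = set(self.informative_factors) - set(FACTORS)
        if unknown:
            raise ValueError(f"unknown informative factors: {sorted(unknown)}")

    @property
    def windows(self) -> Mapping[str, tuple[tuple[float, float], ...]]:
        return {
            "sst": (self.sst_range,),
            "sss": (self.sss_range,),
            "ssh": (self.ssh_range,),
            "t50": (self.t50_range,),
            "mld": self.mld_ranges,
        }

    @property
    def inert_factor_ids(self) -> tuple[str, ...]:
        inert = [f for f in FACTORS if f not in self.informative_factors]
        return tuple(inert) + ("lon", "lat")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    hauls: pd.DataFrame  # haul_id, true positions, error_flag, suitability
    suitability: xr.DataArray  # (time, lat, lon) in [0, 1]
    informative_factors: tuple[str, ...]


def window_response(x, lo: float, hi: float, width: float) -> np.ndarray:
    """Smooth 0-1 window: logistic shoulders at lo/hi, normalised to peak 1."""
    x = np.asarray(x, dtype=float)
    raw = 1.0 / (1.0 + np.exp(-(x - lo) / width)) / (1.0 + np.exp((x - hi) / width))
    mid = (lo + hi) / 2.0
    peak = 1.0 / (1.0 + np.exp(-(mid - lo) / width)) / (1.0 + np.exp((mid - hi) / width))
    return np.clip(raw / peak, 0.0, 1.0)


def factor_response(x, windows: Sequence[tuple[float, float]], edge_width_frac: float) -> np.ndarray:
    """Response of one factor: maximum over its (possibly several) windows."""
    resp = None
    for lo, hi in windows:
        w = max(edge_width_frac * (hi - lo), 1e-9)
        r = window_response(x, lo, hi, w)
        resp = r if resp is None else np.maximum(resp, r)
    return resp


def suitability_from_values(values: Mapping[str, np.ndarray], sp: SuitabilityParams) -> np.ndarray:
    """Product of per-factor window responses over the informative factors."""
    out = None
    for f in sp.informative_factors:
        r = factor_response(values[f], sp.windows[f], sp.edge_width_frac)
        out = r if out is None else out * r
    if out is None:
        raise ValueError("no informative factors")
    return out


# field generator coefficients per factor:
# value = mid + amp * (seasonal - 0.5) + lat_coef * (lat - lat_mid) + noise_sd * smooth_noise
# seasonal peaks ~1 in February (austral summer) and falls to -0.5 in June.
_FIELD_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "sst": (12.35, 5.6, 0.5, 0.8),
    "sss": (33.95, 0.3, 0.03, 0.10),
    "ssh": (-10.0, 12.0, 1.0, 3.5),
    "chla": (0.0, 0.0, 0.0, 0.0),  # handled separately (lognormal)
    "t50": (7.4, 3.2, 0.35, 0.6),
    "t100": (6.0, 1.8, 0.2, 0.5),
    "mld": (19.5, -28.0, 1.0, 4.5),
}


def _seasonal(dekads: Sequence[Dekad]) -> np.ndarray:
    """Seasonal index per dekad, peaking in February, in [-1, 1]."""
    m = np.array([d.month + "FSL".index(d.segment) / 3.0 for d in dekads])
    return np.cos(2 * np.pi * (m - 2.0) / 12.0)


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int, int]) -> np.ndarray:
    """Band-limited unit-variance noise over (time, lat, lon)."""
    raw = rng.standard_normal(shape)
    sig = (min(1.5, shape[0] / 3), min(4.0, shape[1] / 2), min(4.0, shape[2] / 2))
    sm = gaussian_filter(raw, sigma=sig, mode="nearest")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def simulate_environment(cfg: SimConfig, sp: SuitabilityParams | None = None) -> EnvStack:
    """Smooth seasonal environmental fields spanning the suitability windows.

    One raster per factor per dekad: a seasonal cycle (austral-summer peak)
    plus a latitudinal gradient plus band-limited spatial noise, calibrated
    so each factor's marginal distribution straddles its optimal window. A
    static fraction of 100 m-temperature cells is set missing to mimic
    bathymetric data gaps.
    """
    sp = sp or SuitabilityParams()
    grid = cfg.grid
    if grid.n_lat < 2 or grid.n_lon < 2:
        raise ValueError("bbox smaller than 2x2 cells")
    dekads = cfg.dekads
    seas = _seasonal(dekads)
    lat_c = grid.lat_centers
    lon_c = grid.lon_centers
    lat_anom = (lat_c - lat_c.mean())[None, :, None]
    shape = (len(dekads), grid.n_lat, grid.n_lon)

    ss = np.random.SeedSequence(cfg.rng_seed)
    streams = {f: np.random.default_rng(s) for f, s in zip(FACTORS, ss.spawn(len(FACTORS)))}
    rng_mask = np.random.default_rng(ss.spawn(1)[0])

    fields: dict[str, np.ndarray] = {}
    for f in FACTORS:
        informative = f in sp.informative_factors
        noise = _smooth_noise(streams[f], shape)
        if f == "chla":
            logv = np.log(0.5) + 0.5 * noise
            if informative:
                logv = logv + 0.5 * (seas - 0.5)[:, None, None]
            fields[f] = np.clip(np.exp(logv), 0.01, None)
            continue
        mid, amp, lat_coef, noise_sd = _FIELD_PARAMS[f]
        if informative:
            val = (
                mid
                + amp * (seas - 0.5)[:, None, None] / 1.5
                + lat_coef * lat_anom
                + noise_sd * noise
            )
        else:
            # inert factors carry no shared seasonal/latitudinal structure:
            # sampled independently so they are independent of catch given
            # the informative factors
            val = mid + (abs(amp) / 3.0 + noise_sd) * noise
        if f == "mld":
            val = np.clip(val, 1.0, None)
        fields[f] = val

    if cfg.t100_missing_frac > 0:
        bathy = gaussian_filter(rng_mask.standard_normal((grid.n_lat, grid.n_lon)), 2.0, mode="nearest")
        cut = np.quantile(bathy, cfg.t100_missing_frac)
        mask = bathy < cut
        fields["t100"] = fields["t100"].copy()
        fields["t100"][:, mask] = np.nan

    ds = xr.Dataset(
        {
            f: xr.DataArray(
                fields[f],
                dims=("time", "lat", "lon"),
                attrs={"units": UNITS[f]},
            )
            for f in FACTORS
        },
        coords={
            "time": [d.label for d in dekads],
            "lat": ("lat", lat_c, {"units": "degrees_north"}),
            "lon": ("lon", lon_c, {"units": "degrees_east"}),
        },
    )
    return EnvStack(data=ds, grid=grid)


def suitability_cube(env: EnvStack, sp: SuitabilityParams) -> xr.DataArray:
    """Ground-truth suitability on the stack's (time, lat, lon) lattice."""
    values = {f: np.nan_to_num(env.values(f), nan=-1e9) for f in sp.informative_factors}
    suit = suitability_from_values(values, sp)
    return xr.DataArray(
        suit, dims=("time", "lat", "lon"), coords=env.data[sp.informative_factors[0]].coords
    )


def _vessel_track(
    rng: np.random.Generator,
    cfg: SimConfig,
    times_h: np.ndarray,
    suit_at=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Bounded suitability-seeking walk: positions, speed (kn), heading per fix.

    At each step the vessel weighs a handful of candidate headings by the
    habitat suitability at the destination (``suit_at(k, lat, lon)``),
    emulating a fleet that concentrates effort on productive grounds; with
    ``suit_at=None`` the walk is an unbiased random walk.
    """
    lat_min, lat_max, lon_min, lon_max = cfg.bbox
    margin = 0.05 * min(lat_max - lat_min, lon_max - lon_min)
    n = len(times_h)
    lat = np.empty(n)
    lon = np.empty(n)
    lat[0] = rng.uniform(lat_min + margin, lat_max - margin)
    lon[0] = rng.uniform(lon_min + margin, lon_max - margin)
    heading = rng.uniform(0, 360)
    speeds = rng.uniform(3.0, 6.0, size=n)  # trawling speed range, knots
    headings = np.empty(n)
    headings[0] = heading
    dt_h = np.diff(times_h)
    for k in range(1, n):
        step_nm = speeds[k - 1] * dt_h[k - 1]
        coslat = max(np.cos(np.deg2rad(lat[k - 1])), 0.2)
        if suit_at is None:
            heading = (heading + rng.normal(0, 25)) % 360
        else:
            cands = (heading + rng.normal(0, 60, size=4)) % 360
            scores = []
            for h in cands:
                la = lat[k - 1] + step_nm / 60.0 * np.cos(np.deg2rad(h))
                lo = lon[k - 1] + step_nm / 60.0 * np.sin(np.deg2rad(h)) / coslat
                scores.append(suit_at(k, la, lo) + 0.05 * rng.random())
            heading = float(cands[int(np.argmax(scores))])
        dlat = step_nm / 60.0 * np.cos(np.deg2rad(heading))
        dlon = step_nm / 60.0 * np.sin(np.deg2rad(heading)) / coslat
        la, lo = lat[k - 1] + dlat, lon[k - 1] + dlon
        # reflect at the box walls
        if la < lat_min + margin or la > lat_max - margin:
            la = np.clip(2 * np.clip(la, lat_min + margin, lat_max - margin) - la, lat_min, lat_max)
            heading = (180 - heading) % 360
        if lo < lon_min + margin or lo > lon_max - margin:
            lo = np.clip(2 * np.clip(lo, lon_min + margin, lon_max - margin) - lo, lon_min, lon_max)
            heading = (-heading) % 360
        lat[k], lon[k] = la, lo
        headings[k] = heading
    return lat, lon, speeds, headings


def simulate_fleet(
    cfg: SimConfig, env: EnvStack, sp: SuitabilityParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate vessel tracks, haul records and injected logbook errors.

    Vessels emit fixes every ``fix_interval_hours``; hauls are anchored at
    fix times, so a haul's true set position coincides with a reported fix.
    Expected catch is ``catch_scale x suitability`` at the haul's cell-dekad,
    drawn from a gamma distribution. A Bernoulli(error_rate) subset of hauls
    has its *logged* set/retrieve positions displaced by at least
    ``error_min_offset_deg`` on both axes; true positions and flags are
    returned in the GroundTruth.
    """
    sp = sp or SuitabilityParams()
    grid = cfg.grid
    dekads = cfg.dekads
    if not env.covers(grid, dekads):
        raise ValueError("environmental stack does not cover the configured bbox/season")
    suit = suitability_cube(env, sp)
    suit_np = suit.to_numpy()
    t_index = {d.label: k for k, d in enumerate(env.dekads)}

    ss = np.random.SeedSequence((cfg.rng_seed, 7))
    rngs = ss.spawn(cfg.n_vessels + 1)
    rng_err = np.random.default_rng(rngs[-1])

    t0 = dt.datetime.combine(cfg.season_start, dt.time(0, 0))
    season_hours = (
        dt.datetime.combine(cfg.season_end, dt.time(23, 59)) - t0
    ).total_seconds() / 3600.0
    fix_times_h = np.arange(0.0, season_hours, cfg.fix_interval_hours)
    n_days = int(season_hours // 24) + 1

    dekad_per_fix = np.array(
        [t_index[to_dekad(t0 + dt.timedelta(hours=float(h))).label] for h in fix_times_h]
    )

    def suit_at(k: int, la: float, lo: float) -> float:
        i = int((la - grid.lat_min) // grid.step)
        j = int((lo - grid.lon_min) // grid.step)
        if 0 <= i < grid.n_lat and 0 <= j < grid.n_lon:
            return float(suit_np[dekad_per_fix[k], i, j])
        return -1.0

    fix_rows = []
    haul_rows = []
    truth_rows = []
    haul_id = 0
    for v in range(cfg.n_vessels):
        rng = np.random.default_rng(rngs[v])
        lat, lon, speed, heading = _vessel_track(
            rng, cfg, fix_times_h, suit_at if cfg.fleet_targeting else None
        )
        vessel = f"V{v:03d}"
        fix_rows.append(
            pd.DataFrame(
                {
                    "vessel_id": vessel,
                    "timestamp": [t0 + dt.timedelta(hours=float(h)) for h in fix_times_h],
                    "lat": lat,
                    "lon": lon,
                    "speed_kn": speed,
                    "heading_deg": heading,
                }
            )
        )
        day_of_fix = (fix_times_h // 24).astype(int)
        for day in range(n_days):
            n_hauls = rng.poisson(cfg.hauls_per_vessel_day)
            candidates = np.flatnonzero(day_of_fix == day)
            if n_hauls == 0 or candidates.size == 0:
                continue
            n_hauls = min(n_hauls, candidates.size)
            if cfg.fleet_targeting:
                # nets are set at the most promising positions visited that day
                w = np.array([max(suit_at(c, lat[c], lon[c]), 0.0) ** 2 + 1e-6 for c in candidates])
                p = w / w.sum()
                picks = np.sort(rng.choice(candidates, size=n_hauls, replace=False, p=p))
            else:
                picks = np.sort(rng.choice(candidates, size=n_hauls, replace=False))
            for p in picks:
                set_time = t0 + dt.timedelta(hours=float(fix_times_h[p]))
                dur_h = rng.uniform(2.0, 5.0)  # haul duration, hours
                ret_time = set_time + dt.timedelta(hours=dur_h)
                ret_h = fix_times_h[p] + dur_h
                r_lat = float(np.interp(ret_h, fix_times_h, lat))
                r_lon = float(np.interp(ret_h, fix_times_h, lon))
                s_lat, s_lon = float(lat[p]), float(lon[p])
                i, j = grid.assign_cell(s_lat, s_lon)
                dk = to_dekad(set_time).label
                s = float(suit_np[t_index[dk], int(i), int(j)]) if i >= 0 else 0.0
                mean_catch = sp.catch_scale * max(s, 1e-3)
                catch = float(
                    rng.gamma(sp.catch_dispersion, mean_catch / sp.catch_dispersion)
                )
                haul_rows.append(
                    (vessel, haul_id, set_time, ret_time, s_lat, s_lon, r_lat, r_lon, catch)
                )
                truth_rows.append((haul_id, s_lat, s_lon, r_lat, r_lon, s))
                haul_id += 1

    hauls = pd.DataFrame(
        haul_rows,
        columns=[
            "vessel_id",
            "haul_id",
            "set_time",
            "retrieve_time",
            "set_lat",
            "set_lon",
            "retrieve_lat",
            "retrieve_lon",
            "catch_t",
        ],
    )
    fixes = pd.concat(fix_rows, ignore_index=True)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "haul_id",
            "true_set_lat",
            "true_set_lon",
            "true_retrieve_lat",
            "true_retrieve_lon",
            "suitability",
        ],
    )

    n = len(hauls)
    flags = rng_err.random(n) < cfg.error_rate
    if flags.any():
        k = int(flags.sum())
        off_lat = (cfg.error_min_offset_deg + rng_err.exponential(0.1, k)) * rng_err.choice(
            [-1.0, 1.0], k
        )
        off_lon = (cfg.error_min_offset_deg + rng_err.exponential(0.1, k)) * rng_err.choice(
            [-1.0, 1.0], k
        )
        idx = np.flatnonzero(flags)
        for col, off in (
            ("set_lat", off_lat),
            ("retrieve_lat", off_lat),
            ("set_lon", off_lon),
            ("retrieve_lon", off_lon),
        ):
            vals = hauls[col].to_numpy(copy=True)
            vals[idx] = vals[idx] + off
            hauls[col] = vals
    truth["error_flag"] = flags

    logger.info("simulated %d hauls, %d fixes (%d injected errors)", n, len(fixes), flags.sum())
    gt = GroundTruth(hauls=truth, suitability=suit, informative_factors=sp.informative_factors)
    return hauls, fixes, gt
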
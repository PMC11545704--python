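"""Logbook position audit and correction against vessel-position fixes.

Each haul's logged set position is compared with the vessel's AIS/VMS fix
nearest in time to the set time. If the latitude or longitude difference
exceeds a threshold (0.3 degrees, roughly 15 nautical miles, chosen to
exceed the area a trawler covers during one 2-5 h haul at 3-6 knots), the
logged position is deemed a recording error and replaced with the fix
position; otherwise the record is kept as logged.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CorrectionReport:
    """Audit summary of one correction pass over a logbook."""

    n_hauls: int
    n_matched: int
    n_corrected: int
    audit: pd.DataFrame  # haul_id, matched_fix_time, delta_lat, delta_lon, action

    @property
    def corrected_fraction(self) -> float:
        """Share of matched hauls that were replaced; NaN when nothing matched."""
        return self.n_corrected / self.n_matched if self.n_matched else float("nan")

    def summary(self) -> dict:
        return {
            "n_hauls": self.n_hauls,
            "n_matched": self.n_matched,
            "n_corrected": self.n_corrected,
            "corrected_fraction": self.corrected_fraction,
        }


def match_fix(
    set_time: dt.datetime | pd.Timestamp,
    fix_times: np.ndarray,
    max_gap: dt.timedelta | pd.Timedelta = dt.timedelta(hours=4),
) -> int | None:
    """Index of the fix nearest in time to ``set_time``; earlier fix wins ties.

    ``fix_times`` must be sorted ascending (datetime64). Returns None when
    the nearest fix is farther than ``max_gap`` or the sequence is empty.
    """
    fix_times = np.asarray(fix_times, dtype="datetime64[ns]")
    if fix_times.size == 0:
        return None
    t = np.datetime64(pd.Timestamp(set_time), "ns")
    pos = int(np.searchsorted(fix_times, t))
    best = None
    for cand in (pos - 1, pos):
        if 0 <= cand < fix_times.size:
            gap = abs(fix_times[cand] - t)
            # strict < keeps the earlier candidate on an exact tie
            if best is None or gap < best[1]:
                best = (cand, gap)
    if best is None or best[1] > np.timedelta64(pd.Timedelta(max_gap)):
        return None
    return best[0]


def _discrepancy(dlat: float, dlon: float, metric: str) -> float:
    if metric == "per_axis":
        return max(abs(dlat), abs(dlon))
    if metric == "euclidean":
        return float(np.hypot(dlat, dlon))
    raise ValueError(f"unknown discrepancy metric {metric!r}")


def correct_haul(
    haul: pd.Series,
    fix: pd.Series,
    threshold_deg: float = 0.3,
    metric: str = "per_axis",
) -> tuple[pd.Series, str]:
    """Audit one haul against its matched fix.

    Kept when the set-position discrepancy is within the threshold;
    otherwise the set position is replaced by the fix position and the
    retrieve position is shifted by the same offset. Catch and times are
    never modified.
    """
    if threshold_deg <= 0:
        raise ValueError("threshold must be positive")
    dlat = haul["set_lat"] - fix["lat"]
    dlon = haul["set_lon"] - fix["lon"]
    if _discrepancy(dlat, dlon, metric) <= threshold_deg:
        return haul, "kept"
    out = haul.copy()
    out["set_lat"] = fix["lat"]
    out["set_lon"] = fix["lon"]
    out["retrieve_lat"] = haul["retrieve_lat"] - dlat
    out["retrieve_lon"] = haul["retrieve_lon"] - dlon
    return out, "replaced"


def correct_logbook(
    hauls: pd.DataFrame,
    fixes: pd.DataFrame,
    threshold_deg: float = 0.3,
    max_gap: dt.timedelta | pd.Timedelta = dt.timedelta(hours=4),
    metric: str = "per_axis",
) -> tuple[pd.DataFrame, CorrectionReport]:
    """Audit and correct every haul; unmatched hauls pass through flagged.

    Matching is per vessel against time-sorted, deduplicated fixes; the
    reference time is the haul's set time.
    """
    if threshold_deg <= 0:
        raise ValueError("threshold must be positive")
    if fixes.empty:
        logger.warning("empty fix table: all hauls unmatched")
    max_gap_ns = np.timedelta64(pd.Timedelta(max_gap))

    by_vessel: dict[str, pd.DataFrame] = {}
    if not fixes.empty:
        f = fixes.copy()
        f["timestamp"] = pd.to_datetime(f["timestamp"])
        f = f.sort_values("timestamp").drop_duplicates(["vessel_id", "timestamp"])
        by_vessel = {v: g.reset_index(drop=True) for v, g in f.groupby("vessel_id")}

    corrected = hauls.copy().reset_index(drop=True)
    set_lat = corrected["set_lat"].to_numpy(dtype=float, copy=True)
    set_lon = corrected["set_lon"].to_numpy(dtype=float, copy=True)
    ret_lat = corrected["retrieve_lat"].to_numpy(dtype=float, copy=True)
    ret_lon = corrected["retrieve_lon"].to_numpy(dtype=float, copy=True)
    set_times = pd.to_datetime(corrected["set_time"]).to_numpy(dtype="datetime64[ns]")

    audit_rows = []
    n_matched = 0
    n_corrected = 0
    for v, grp_idx in corrected.groupby("vessel_id").groups.items():
        idx = np.asarray(grp_idx)
        vf = by_vessel.get(v)
        if vf is None:
            for k in idx:
                audit_rows.append((corrected.at[k, "haul_id"], pd.NaT, np.nan, np.nan, "unmatched"))
            continue
        ft = vf["timestamp"].to_numpy(dtype="datetime64[ns]")
        flat = vf["lat"].to_numpy(dtype=float)
        flon = vf["lon"].to_numpy(dtype=float)
        t = set_times[idx]
        pos = np.searchsorted(ft, t)
        left = np.clip(pos - 1, 0, ft.size - 1)
        right = np.clip(pos, 0, ft.size - 1)
        gap_left = np.abs(ft[left] - t)
        gap_right = np.abs(ft[right] - t)
        take_left = gap_left <= gap_right  # earlier fix wins exact ties
        m = np.where(take_left, left, right)
        gap = np.where(take_left, gap_left, gap_right)
        matched = gap <= max_gap_ns
        dlat = set_lat[idx] - flat[m]
        dlon = set_lon[idx] - flon[m]
        if metric == "per_axis":
            disc = np.maximum(np.abs(dlat), np.abs(dlon))
        else:
            disc = np.hypot(dlat, dlon)
        replace = matched & (disc > threshold_deg)
        rep_idx = idx[replace]
        sel = replace.nonzero()[0]
        set_lat[rep_idx] = flat[m[sel]]
        set_lon[rep_idx] = flon[m[sel]]
        ret_lat[rep_idx] -= dlat[sel]
        ret_lon[rep_idx] -= dlon[sel]
        n_matched += int(matched.sum())
        n_corrected += int(replace.sum())
        for q, k in enumerate(idx):
            action = "unmatched" if not matched[q] else ("replaced" if replace[q] else "kept")
            audit_rows.append(
                (
                    corrected.at[k, "haul_id"],
                    pd.Timestamp(ft[m[q]]) if matched[q] else pd.NaT,
                    dlat[q] if matched[q] else np.nan,
                    dlon[q] if matched[q] else np.nan,
                    action,
                )
            )

    corrected["set_lat"] = set_lat
    corrected["set_lon"] = set_lon
    corrected["retrieve_lat"] = ret_lat
    corrected["retrieve_lon"] = ret_lon

    audit = pd.DataFrame(
        audit_rows, columns=["haul_id", "matched_fix_time", "delta_lat", "delta_lon", "action"]
    ).sort_values("haul_id", kind="stable").reset_index(drop=True)
    report = CorrectionReport(
        n_hauls=len(corrected), n_matched=n_matched, n_corrected=n_corrected, audit=audit
    )
    return corrected, report
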
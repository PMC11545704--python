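"""CSV schemas shared across the pipeline stages.

Logbook: vessel_id, haul_id, set_time, retrieve_time, set_lat, set_lon,
retrieve_lat, retrieve_lon, catch_t. Fixes: vessel_id, timestamp, lat, lon,
speed_kn, heading_deg. Timestamps are UTC, second resolution, ISO-8601.
"""

from __future__ import annotations

import pandas as pd

LOGBOOK_COLUMNS = [
    "vessel_id",
    "haul_id",
    "set_time",
    "retrieve_time",
    "set_lat",
    "set_lon",
    "retrieve_lat",
    "retrieve_lon",
    "catch_t",
]

FIX_COLUMNS = ["vessel_id", "timestamp", "lat", "lon", "speed_kn", "heading_deg"]


def write_logbook_csv(hauls: pd.DataFrame, path) -> None:
    hauls[LOGBOOK_COLUMNS].to_csv(path, index=False)


def read_logbook_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["set_time", "retrieve_time"])
    missing = set(LOGBOOK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"logbook CSV missing columns: {sorted(missing)}")
    return df


def write_fixes_csv(fixes: pd.DataFrame, path) -> None:
    fixes[FIX_COLUMNS].to_csv(path, index=False)


def read_fixes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = set(FIX_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fix CSV missing columns: {sorted(missing)}")
    return df
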
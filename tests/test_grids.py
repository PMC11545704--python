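"""Dekad binning, cell assignment, CPUE aggregation, labeling, centroids."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fishrra import (
    Dekad,
    GridDefinition,
    centroid,
    compute_cpue,
    dekad_range,
    label_rra,
    to_dekad,
)


@pytest.mark.parametrize(
    "date, expected",
    [
        (dt.date(2024, 1, 1), Dekad(2024, 1, "F")),
        (dt.date(2024, 1, 10), Dekad(2024, 1, "F")),
        (dt.date(2024, 1, 11), Dekad(2024, 1, "S")),
        (dt.date(2024, 1, 21), Dekad(2024, 1, "L")),
        (dt.date(2024, 2, 28), Dekad(2024, 2, "L")),
        (dt.date(2023, 12, 31), Dekad(2023, 12, "L")),
    ],
)
def test_to_dekad_segments(date, expected):
    assert to_dekad(date) == expected


def test_dekad_ordering_and_range():
    ds = dekad_range(dt.date(2023, 12, 25), dt.date(2024, 1, 15))
    assert [d.label for d in ds] == ["2023-12-L", "2024-01-F", "2024-01-S"]
    assert ds[0] < ds[1] < ds[2]
    assert Dekad.from_label("2024-01-S") == ds[2]


def test_assign_cell_half_open_rule():
    grid = GridDefinition.from_bbox(-45.5, -44.5, -60.5, -59.5, step=0.1)
    i, j = grid.assign_cell(-45.05, -60.05)
    lat_ll, lon_ll = grid.cell_lower_left(i, j)
    assert lat_ll == pytest.approx(-45.1) and lon_ll == pytest.approx(-60.0 - 0.1)
    # a point exactly on an interior edge belongs to the cell above it
    i_edge, _ = grid.assign_cell(-45.0, -60.05)
    assert grid.cell_lower_left(i_edge, 0)[0] == pytest.approx(-45.0)
    # outside the box is flagged
    assert grid.assign_cell(-50.0, -60.05)[0] == -1


@given(
    lat=st.floats(-45.499, -44.501),
    lon=st.floats(-60.499, -59.501),
)
def test_assign_cell_round_trip_containment(lat, lon):
    grid = GridDefinition.from_bbox(-45.5, -44.5, -60.5, -59.5, step=0.1)
    i, j = grid.assign_cell(lat, lon)
    lat_ll, lon_ll = grid.cell_lower_left(i, j)
    assert lat_ll <= lat < lat_ll + grid.step + 1e-12
    assert lon_ll <= lon < lon_ll + grid.step + 1e-12


def _haul_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["set_time", "retrieve_time", "set_lat", "set_lon",
                 "retrieve_lat", "retrieve_lon", "catch_t"],
    )


def test_compute_cpue_mean_catch_per_haul():
    t = dt.datetime(2024, 1, 5, 6)
    hauls = _haul_frame(
        [
            (t, t + dt.timedelta(hours=3), -45.05, -60.05, -45.05, -60.05, 1.0),
            (t, t + dt.timedelta(hours=3), -45.05, -60.05, -45.05, -60.05, 3.0),
        ]
    )
    grid = GridDefinition.from_bbox(-45.5, -44.5, -60.5, -59.5)
    cells = compute_cpue(hauls, grid)
    assert len(cells) == 1
    assert cells["cpue"].iloc[0] == pytest.approx(2.0)
    assert cells["n_hauls"].iloc[0] == 2


def test_compute_cpue_single_haul_identity():
    t = dt.datetime(2024, 1, 5, 6)
    hauls = _haul_frame([(t, t + dt.timedelta(hours=2), -45.05, -60.05, -45.0, -60.0, 5.0)])
    grid = GridDefinition.from_bbox(-45.5, -44.5, -60.5, -59.5)
    cells = compute_cpue(hauls, grid)
    assert cells["cpue"].iloc[0] == pytest.approx(5.0)


def test_compute_cpue_matches_brute_force(small_scenario):
    cfg, sp, env, hauls, fixes, gt = small_scenario
    grid = cfg.grid
    cells = compute_cpue(hauls, grid)
    # independent oracle: plain double loop grouping by (cell, dekad)
    acc: dict[tuple, list] = {}
    for _, h in hauls.iterrows():
        i, j = grid.assign_cell(h["set_lat"], h["set_lon"])
        if i < 0:
            continue
        key = (int(i), int(j), to_dekad(pd.Timestamp(h["set_time"])).label)
        acc.setdefault(key, []).append(h["catch_t"])
    assert len(cells) == len(acc)
    for _, row in cells.iterrows():
        catches = acc[(row["i"], row["j"], row["dekad"])]
        assert row["n_hauls"] == len(catches)
        assert row["cpue"] == pytest.approx(float(np.mean(catches)), rel=1e-12)


def test_label_rra_median_and_fixed_threshold():
    cells = pd.DataFrame({"cpue": [1.0, 2.0, 3.0, 4.0]})
    labeled, thr = label_rra(cells, "median")
    assert thr == pytest.approx(2.5)
    assert list(labeled["rra_label"]) == ["low", "low", "high", "high"]

    cells2 = pd.DataFrame({"cpue": [1.9, 2.0, 2.1]})
    labeled2, _ = label_rra(cells2, 2.0)
    # a cell exactly at the threshold goes low under strict >
    assert list(labeled2["rra_label"]) == ["low", "low", "high"]


def test_label_rra_degenerate_inputs():
    with pytest.raises(ValueError):
        label_rra(pd.DataFrame({"cpue": [1.0]}))
    labeled, _ = label_rra(pd.DataFrame({"cpue": [2.0, 2.0, 2.0]}))
    assert (labeled["rra_label"] == "low").all()


def test_cpue_scale_equivariance(small_scenario):
    cfg, sp, env, hauls, fixes, gt = small_scenario
    cells, thr = label_rra(compute_cpue(hauls, cfg.grid))
    scaled_hauls = hauls.assign(catch_t=hauls["catch_t"] * 3.0)
    cells3, thr3 = label_rra(compute_cpue(scaled_hauls, cfg.grid))
    assert thr3 == pytest.approx(3.0 * thr)
    np.testing.assert_allclose(cells3["cpue"], 3.0 * cells["cpue"])
    assert (cells3["rra_label"] == cells["rra_label"]).all()


def test_label_partition(default_labeled):
    _, _, labeled, _ = default_labeled
    counts = labeled["rra_label"].value_counts()
    assert counts.get("high", 0) + counts.get("low", 0) == len(labeled)


def test_centroid_weighted_mean_and_identity():
    df = pd.DataFrame({"set_lat": [-40.0, -42.0], "set_lon": [-60.0, -61.0],
                       "catch_t": [1.0, 3.0]})
    c = centroid(df)
    assert c.X == pytest.approx(-41.5)
    assert c.Y == pytest.approx(-60.75)

    one = pd.DataFrame({"set_lat": [-44.2], "set_lon": [-59.3], "catch_t": [0.7]})
    c1 = centroid(one)
    assert (c1.X, c1.Y) == pytest.approx((-44.2, -59.3))

    sym = pd.DataFrame({"set_lat": [-40.0, -44.0], "set_lon": [-60.0, -60.0],
                        "catch_t": [2.0, 2.0]})
    assert centroid(sym).X == pytest.approx(-42.0)


def test_centroid_rejects_zero_catch():
    df = pd.DataFrame({"set_lat": [-40.0], "set_lon": [-60.0], "catch_t": [0.0]})
    with pytest.raises(ValueError):
        centroid(df)


def test_centroid_translation_equivariance(small_scenario):
    cfg, sp, env, hauls, fixes, gt = small_scenario
    c = centroid(hauls)
    shifted = hauls.assign(set_lat=hauls["set_lat"] + 1.5, set_lon=hauls["set_lon"] - 2.0)
    cs = centroid(shifted)
    assert cs.X == pytest.approx(c.X + 1.5)
    assert cs.Y == pytest.approx(c.Y - 2.0)
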
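"""Regridding and feature-table construction."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from fishrra import GridDefinition, build_features, label_rra, regrid
from fishrra.env_features import MinMaxScaler, PREDICTORS


def _source(lat0, lon0, step, n_lat, n_lon, values):
    lat = lat0 + (np.arange(n_lat) + 0.5) * step
    lon = lon0 + (np.arange(n_lon) + 0.5) * step
    return xr.DataArray(values, dims=("lat", "lon"), coords={"lat": lat, "lon": lon})


def test_regrid_identity_on_same_grid():
    target = GridDefinition.from_bbox(-45.0, -44.0, -60.0, -59.0, step=0.1)
    rng = np.random.default_rng(0)
    src = _source(-45.0, -60.0, 0.1, 10, 10, rng.random((10, 10)))
    out = regrid(src, target)
    np.testing.assert_allclose(out.to_numpy(), src.to_numpy(), rtol=1e-12)


def test_regrid_preserves_constant():
    target = GridDefinition.from_bbox(-45.0, -44.0, -60.0, -59.0, step=0.1)
    src = _source(-45.2, -60.2, 0.083, 18, 18, np.full((18, 18), 7.25))
    out = regrid(src, target)
    covered = np.isfinite(out.to_numpy())
    assert covered.any()
    np.testing.assert_allclose(out.to_numpy()[covered], 7.25, rtol=1e-12)


def test_regrid_values_bounded_by_contributors():
    """Each target value must lie in [min, max] of overlapping source cells."""
    target = GridDefinition.from_bbox(-45.0, -44.5, -60.0, -59.5, step=0.1)
    rng = np.random.default_rng(1)
    step_s = 0.083
    src = _source(-45.1, -60.1, step_s, 10, 10, rng.random((10, 10)))
    out = regrid(src, target).to_numpy()
    src_lat = src["lat"].to_numpy()
    src_lon = src["lon"].to_numpy()
    for i in range(target.n_lat):
        for j in range(target.n_lon):
            if not np.isfinite(out[i, j]):
                continue
            t_lat0 = target.lat_min + i * target.step
            t_lon0 = target.lon_min + j * target.step
            vals = []
            for a in range(len(src_lat)):
                for b in range(len(src_lon)):
                    s_lat0, s_lon0 = src_lat[a] - step_s / 2, src_lon[b] - step_s / 2
                    olat = min(t_lat0 + target.step, s_lat0 + step_s) - max(t_lat0, s_lat0)
                    olon = min(t_lon0 + target.step, s_lon0 + step_s) - max(t_lon0, s_lon0)
                    if olat > 1e-12 and olon > 1e-12:
                        vals.append(src.to_numpy()[a, b])
            assert min(vals) - 1e-9 <= out[i, j] <= max(vals) + 1e-9


def test_regrid_disjoint_extents_rejected():
    target = GridDefinition.from_bbox(-45.0, -44.0, -60.0, -59.0, step=0.1)
    src = _source(10.0, 10.0, 0.1, 5, 5, np.ones((5, 5)))
    with pytest.raises(ValueError):
        regrid(src, target)


def test_regrid_low_coverage_is_missing():
    target = GridDefinition.from_bbox(-45.0, -44.8, -60.0, -59.8, step=0.1)
    vals = np.ones((2, 2))
    vals[0, :] = np.nan  # southern half of every target cell row is missing
    src = _source(-45.0, -60.0, 0.1, 2, 2, vals)
    out = regrid(src, target, min_coverage=0.5).to_numpy()
    assert np.isnan(out[0]).all()
    assert np.isfinite(out[1]).all()


def test_build_features_single_cell(small_scenario):
    cfg, sp, env, hauls, fixes, gt = small_scenario
    cells = pd.DataFrame({"i": [1], "j": [1], "dekad": ["2024-01-F"], "rra_label": ["high"]})
    rows = build_features(cells, env, optional_factors=("t100",))
    assert len(rows) == 1
    present = [p for p in PREDICTORS if p in rows.columns]
    assert len(present) == 9
    lat_c, lon_c = env.grid.cell_center(1, 1)
    assert rows["lat"].iloc[0] == pytest.approx(float(lat_c))
    assert rows["lon"].iloc[0] == pytest.approx(float(lon_c))


def test_build_features_lookup_oracle(small_scenario):
    cfg, sp, env, hauls, fixes, gt = small_scenario
    from fishrra import compute_cpue

    cells, _ = label_rra(compute_cpue(hauls, cfg.grid))
    rows = build_features(cells, env, optional_factors=("t100",))
    labels = [str(t) for t in env.data["time"].values]
    for _, r in rows.sample(50, random_state=0).iterrows():
        t = labels.index(r["dekad"])
        for f in env.factors:
            v = env.values(f)[t, int(r["i"]), int(r["j"])]
            if np.isfinite(v):
                assert r[f] == pytest.approx(v, rel=1e-12)


def test_build_features_drops_incomplete_and_counts(small_scenario):
    cfg, sp, env, hauls, fixes, gt = small_scenario
    # poke a hole in SST at one cell-dekad
    env2 = env.data.copy(deep=True)
    env2["sst"][0, 2, 2] = np.nan
    from fishrra.env_features import EnvStack

    stack = EnvStack(data=env2, grid=env.grid)
    cells = pd.DataFrame(
        {"i": [2, 3], "j": [2, 3], "dekad": [str(env2["time"].values[0])] * 2,
         "rra_label": ["high", "low"]}
    )
    rows = build_features(cells, stack, optional_factors=("t100",))
    assert len(rows) + rows.attrs["n_dropped"] == len(cells)
    assert rows.attrs["n_dropped"] == 1
    assert rows["i"].iloc[0] == 3


def test_build_features_unknown_dekad_named():
    import datetime as dt
    from fishrra import SimConfig, simulate_environment

    env = simulate_environment(SimConfig(bbox=(-45.0, -44.0, -60.0, -59.0),
                                         season_start=dt.date(2024, 1, 1),
                                         season_end=dt.date(2024, 1, 10), rng_seed=0))
    cells = pd.DataFrame({"i": [0], "j": [0], "dekad": ["2025-03-S"], "rra_label": ["low"]})
    with pytest.raises(KeyError, match="2025-03-S"):
        build_features(cells, env)


def test_envstack_netcdf_round_trip(tmp_path, small_scenario):
    cfg, sp, env, hauls, fixes, gt = small_scenario
    path = tmp_path / "env.nc"
    env.to_netcdf(path)
    back = __import__("fishrra").EnvStack.from_netcdf(path)
    assert back.grid == env.grid
    assert [d.label for d in back.dekads] == [d.label for d in env.dekads]
    for f in env.factors:
        np.testing.assert_allclose(back.values(f), env.values(f), rtol=1e-12)


def test_minmax_scaler_uses_training_statistics_only():
    train = pd.DataFrame({"a": [0.0, 10.0], "b": [5.0, 15.0]})
    test = pd.DataFrame({"a": [20.0], "b": [0.0]})
    sc = MinMaxScaler(columns=("a", "b")).fit(train)
    out = sc.transform(test)
    assert out[0, 0] == pytest.approx(2.0)  # beyond the training range
    assert out[0, 1] == pytest.approx(-0.5)
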
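"""Generator contracts: determinism, error injection, suitability coupling."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from fishrra import (
    FACTORS,
    SimConfig,
    SuitabilityParams,
    simulate_environment,
    simulate_fleet,
)
from fishrra.synthetic import suitability_cube, suitability_from_values, window_response


def _tiny_cfg(**kw):
    base = dict(
        bbox=(-45.0, -44.8, -60.0, -59.8),
        season_start=dt.date(2024, 1, 1),
        season_end=dt.date(2024, 1, 10),
        n_vessels=2,
        rng_seed=0,
    )
    base.update(kw)
    return SimConfig(**base)


def test_minimal_lattice_has_all_factors():
    env = simulate_environment(_tiny_cfg())
    assert set(env.factors) == set(FACTORS)
    for f in FACTORS:
        assert env.values(f).shape == (1, 2, 2)


def test_degenerate_bbox_rejected():
    with pytest.raises(ValueError):
        simulate_environment(_tiny_cfg(bbox=(-45.0, -44.95, -60.0, -59.8)))


def test_environment_deterministic_under_seed():
    cfg = _tiny_cfg(bbox=(-45.0, -44.0, -60.0, -59.0), rng_seed=42)
    a = simulate_environment(cfg)
    b = simulate_environment(cfg)
    for f in FACTORS:
        np.testing.assert_array_equal(a.values(f), b.values(f))


def test_fleet_deterministic_under_seed(small_scenario):
    cfg, sp, env, hauls, fixes, gt = small_scenario
    hauls2, fixes2, gt2 = simulate_fleet(cfg, env, sp)
    pd.testing.assert_frame_equal(hauls, hauls2)
    pd.testing.assert_frame_equal(fixes, fixes2)
    pd.testing.assert_frame_equal(gt.hauls, gt2.hauls)


def test_window_response_shape():
    # near-1 inside the window, ~0.5 at the shoulders, ->0 far outside
    assert window_response(12.3, 10.1, 14.6, 0.45) > 0.95
    assert window_response(10.1, 10.1, 14.6, 0.45) == pytest.approx(0.5, abs=0.06)
    assert window_response(20.0, 10.1, 14.6, 0.45) < 0.01


def test_suitability_fraction_strictly_interior(small_scenario):
    cfg, sp, env, hauls, fixes, gt = small_scenario
    suit = suitability_cube(env, sp).to_numpy()
    assert np.all((suit >= 0) & (suit <= 1))
    # brute-force count over the lattice
    frac = 0.0
    n = 0
    for t in range(suit.shape[0]):
        for i in range(suit.shape[1]):
            for j in range(suit.shape[2]):
                frac += suit[t, i, j] > 0.5
                n += 1
    frac /= n
    assert 0.0 < frac < 1.0


def test_no_error_limit():
    cfg = _tiny_cfg(bbox=(-45.0, -44.0, -60.0, -59.0), error_rate=0.0)
    env = simulate_environment(cfg)
    hauls, fixes, gt = simulate_fleet(cfg, env)
    np.testing.assert_array_equal(hauls["set_lat"], gt.hauls["true_set_lat"])
    np.testing.assert_array_equal(hauls["set_lon"], gt.hauls["true_set_lon"])
    assert not gt.hauls["error_flag"].any()


def test_all_error_limit():
    cfg = _tiny_cfg(bbox=(-45.0, -44.0, -60.0, -59.0), error_rate=1.0,
                    season_end=dt.date(2024, 1, 20))
    env = simulate_environment(cfg)
    hauls, fixes, gt = simulate_fleet(cfg, env)
    assert gt.hauls["error_flag"].all()
    # logged minus matched-fix (= true) position exceeds 0.3 deg on each axis
    dlat = (hauls["set_lat"] - gt.hauls["true_set_lat"]).abs()
    dlon = (hauls["set_lon"] - gt.hauls["true_set_lon"]).abs()
    assert (dlat > 0.3).all() and (dlon > 0.3).all()


def test_error_fraction_binomial(default_scenario):
    cfg, sp, env, hauls, fixes, gt = default_scenario
    n = len(gt.hauls)
    assert n >= 5000
    frac = gt.hauls["error_flag"].mean()
    sd = np.sqrt(cfg.error_rate * (1 - cfg.error_rate) / n)
    assert abs(frac - cfg.error_rate) <= 3 * sd


def test_catch_monotone_in_suitability(default_scenario):
    cfg, sp, env, hauls, fixes, gt = default_scenario
    df = gt.hauls.assign(catch=hauls["catch_t"].to_numpy())
    strata = pd.cut(df["suitability"], [0.0, 0.25, 0.5, 0.75, 1.0], include_lowest=True)
    means = df.groupby(strata, observed=True)["catch"].mean()
    assert means.is_monotonic_increasing
    # cells below the lowest stratum ceiling yield mean catch below it
    low = df[df["suitability"] < 0.25]
    assert low["catch"].mean() < sp.catch_scale * 0.25


def test_inert_factors_uninformative_given_suitability(default_scenario):
    """Catch residuals (after the suitability mean) ignore inert factors."""
    cfg, sp, env, hauls, fixes, gt = default_scenario
    grid = cfg.grid
    i, j = grid.assign_cell(gt.hauls["true_set_lat"], gt.hauls["true_set_lon"])
    labels = [str(t) for t in env.data["time"].values]
    t_index = {lab: k for k, lab in enumerate(labels)}
    from fishrra import to_dekad

    t = np.array([t_index[to_dekad(ts).label] for ts in pd.to_datetime(hauls["set_time"])])
    resid = hauls["catch_t"].to_numpy() - sp.catch_scale * gt.hauls["suitability"].to_numpy()
    for inert in ("chla", "t100"):
        vals = env.values(inert)[t, i, j]
        ok = np.isfinite(vals)
        r = np.corrcoef(resid[ok], vals[ok])[0, 1]
        assert abs(r) < 0.05, f"{inert} correlates with catch residuals (r={r:.3f})"


def test_env_season_mismatch_rejected():
    cfg = _tiny_cfg(bbox=(-45.0, -44.0, -60.0, -59.0))
    env = simulate_environment(cfg)
    late = _tiny_cfg(bbox=(-45.0, -44.0, -60.0, -59.0),
                     season_start=dt.date(2024, 2, 1), season_end=dt.date(2024, 2, 10))
    with pytest.raises(ValueError):
        simulate_fleet(late, env)


def test_t100_missing_fraction():
    cfg = _tiny_cfg(bbox=(-45.0, -43.0, -60.0, -58.0), t100_missing_frac=0.2)
    env = simulate_environment(cfg)
    frac = np.isnan(env.values("t100")).mean()
    assert 0.1 < frac < 0.3
    for f in set(FACTORS) - {"t100"}:
        assert np.isfinite(env.values(f)).all()


def test_suitability_product_form():
    sp = SuitabilityParams()
    mids = {"sst": 12.35, "mld": 19.5, "sss": 33.95, "ssh": -10.0, "t50": 7.4}
    vals = {k: np.array([v]) for k, v in mids.items()}
    near_one = suitability_from_values(vals, sp)
    assert near_one[0] > 0.95
    vals_bad = dict(vals, sst=np.array([25.0]))
    assert suitability_from_values(vals_bad, sp)[0] < 0.01
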
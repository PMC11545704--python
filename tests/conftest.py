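import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from fishrra import (
    SimConfig,
    SuitabilityParams,
    build_features,
    compute_cpue,
    correct_logbook,
    label_rra,
    simulate_environment,
    simulate_fleet,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

SELECTED_FACTORS = ["sst", "mld", "sss", "t50", "ssh"]


@pytest.fixture(scope="session")
def default_scenario():
    """Full December-June season at study conditions (8.4% error rate)."""
    cfg = SimConfig(rng_seed=1)
    sp = SuitabilityParams()
    env = simulate_environment(cfg, sp)
    hauls, fixes, gt = simulate_fleet(cfg, env, sp)
    return cfg, sp, env, hauls, fixes, gt


@pytest.fixture(scope="session")
def default_labeled(default_scenario):
    cfg, sp, env, hauls, fixes, gt = default_scenario
    corrected, report = correct_logbook(hauls, fixes)
    cells = compute_cpue(corrected, cfg.grid)
    labeled, threshold = label_rra(cells)
    return corrected, report, labeled, threshold


@pytest.fixture(scope="session")
def default_features(default_scenario, default_labeled):
    cfg, sp, env, hauls, fixes, gt = default_scenario
    _, _, labeled, _ = default_labeled
    feats = build_features(labeled, env, optional_factors=("t100",))
    return feats.dropna().reset_index(drop=True)


@pytest.fixture(scope="session")
def small_scenario():
    """Shorter December-March season on a 2x2 degree box (fast model fits)."""
    cfg = SimConfig(
        bbox=(-45.0, -43.0, -60.0, -58.0),
        season_start=dt.date(2023, 12, 1),
        season_end=dt.date(2024, 3, 31),
        n_vessels=8,
        rng_seed=5,
    )
    sp = SuitabilityParams()
    env = simulate_environment(cfg, sp)
    hauls, fixes, gt = simulate_fleet(cfg, env, sp)
    return cfg, sp, env, hauls, fixes, gt


@pytest.fixture(scope="session")
def small_features(small_scenario):
    cfg, sp, env, hauls, fixes, gt = small_scenario
    corrected, _ = correct_logbook(hauls, fixes)
    cells = compute_cpue(corrected, cfg.grid)
    labeled, _ = label_rra(cells)
    feats = build_features(labeled, env, optional_factors=("t100",))
    return feats.dropna().reset_index(drop=True)
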
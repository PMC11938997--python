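import pytest
from hypothesis import HealthCheck, settings

import quint_trees as qt

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def planted_table():
    """N=600 trial with one planted qualitative split on x1 (d = -0.8/+0.8)."""
    cfg = qt.planted_split_config(n=600, d=0.8, seed=1)
    table, tlfb, truth = qt.generate_trial(cfg)
    return table, tlfb, truth


@pytest.fixture(scope="session")
def planted_tree(planted_table):
    table, _, _ = planted_table
    cfg = qt.QuintConfig(seed=7)
    grown = qt.grow_tree(table, "prop_change", ["x1", "x2", "x3", "x4"], cfg)
    pruned = qt.prune_tree(grown, table, cfg)
    return grown, pruned


@pytest.fixture(scope="session")
def trial_like():
    """Full-battery N=338 trial with dropout and item missingness."""
    cfg = qt.default_config(seed=11)
    return qt.generate_trial(cfg)
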
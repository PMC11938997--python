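"""Criterion, assignment search, greedy growth, and bootstrap pruning."""

import math

import numpy as np
import pytest

import quint_trees as qt
from quint_trees.engine import QuintConfig, _best_criterion_nd

from _oracles import best_assignment, make_table, random_instance, stepwise_grow


def _eff(n_per_arm, d):
    """EffectSummary with the requested total n and Cohen's d."""
    return qt.effect_from_summary(n_per_arm, 0.0, 1.0, n_per_arm, d, 1.0)


class TestPartitionCriterion:
    def test_hand_computed_example(self):
        # two equal leaves with d = +0.5 / -0.5 and unit weights
        effects = [_eff(25, 0.5), _eff(25, -0.5)]
        c = qt.partition_criterion(effects, ["P1", "P2"], QuintConfig())
        assert c == pytest.approx(2 * math.log(1.5) + 2 * math.log(0.5))

    def test_zero_weights_give_zero(self):
        effects = [_eff(25, 0.5), _eff(25, -0.5)]
        cfg = QuintConfig(a1=0.0, a2=0.0)
        assert qt.partition_criterion(effects, ["P1", "P2"], cfg) == 0.0

    def test_monotone_in_responder_effect(self):
        cfg = QuintConfig()
        weak = [_eff(25, 0.5), _eff(25, -0.5)]
        strong = [_eff(25, 1.0), _eff(25, -0.5)]
        assert qt.partition_criterion(
            strong, ["P1", "P2"], cfg
        ) > qt.partition_criterion(weak, ["P1", "P2"], cfg)

    def test_ineligible_assignment_is_undefined(self):
        cfg = QuintConfig(dmin=0.3)
        effects = [_eff(25, 0.2), _eff(25, -0.5)]  # first below dmin
        assert qt.partition_criterion(effects, ["P1", "P2"], cfg) is None
        # all-P3 is inadmissible (no qualitative interaction)
        assert qt.partition_criterion(effects, ["P3", "P3"], cfg) is None


class TestOptimalAssignment:
    def test_two_opposed_leaves(self):
        res = qt.optimal_assignment([_eff(25, 0.8), _eff(25, -0.8)], QuintConfig())
        assert res is not None
        assert res[0] == ("P1", "P2")

    def test_no_iatrogenic_leaf_means_none(self):
        res = qt.optimal_assignment([_eff(25, 0.8), _eff(25, 0.4)], QuintConfig())
        assert res is None

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_oracle_on_random_leaves(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        ns = rng.integers(10, 60, size=k)
        ds = rng.normal(0, 0.7, size=k)
        effects = [_eff(int(n) // 2 + 5, d) for n, d in zip(ns, ds)]
        cfg = QuintConfig()
        res = qt.optimal_assignment(effects, cfg)
        oracle = best_assignment(
            [e.n for e in effects], [e.d for e in effects], dmin=cfg.dmin
        )
        if oracle is None:
            assert res is None
        else:
            assert res is not None
            assert res[1] == pytest.approx(oracle[1], abs=1e-12)

    @pytest.mark.parametrize("seed", range(15))
    def test_fast_closed_form_equals_exhaustive(self, seed):
        rng = np.random.default_rng(100 + seed)
        k = int(rng.integers(2, 7))
        ns = rng.integers(20, 80, size=k).astype(float)
        ds = rng.normal(0, 0.6, size=k)
        cfg = QuintConfig()
        fast = _best_criterion_nd(ns, ds, cfg)
        slow = best_assignment(list(ns), list(ds), dmin=cfg.dmin)
        if slow is None:
            assert fast is None
        else:
            assert fast == pytest.approx(slow[1], abs=1e-12)


class TestGrowth:
    def test_recovers_planted_split(self, planted_table, planted_tree):
        table, _, _ = planted_table
        grown, _ = planted_tree
        first = grown.trace[0]
        assert first.feature == "x1"
        # threshold lands near the planted boundary at 0
        assert abs(first.threshold) < 0.25

    def test_null_data_yields_flagged_root(self):
        cfg = qt.null_config(n=600, seed=1001)
        table, _, _ = qt.generate_trial(cfg)
        tree = qt.grow_tree(table, "prop_change", ["x1", "x2", "x3", "x4"])
        assert tree.n_leaves == 1
        assert tree.no_interaction
        assert tree.leaves()[0].klass == "P3"

    def test_min_per_arm_respected(self, planted_tree):
        grown, _ = planted_tree
        for leaf in grown.leaves():
            assert leaf.effect.n_p >= 10 and leaf.effect.n_t >= 10

    def test_monotone_transform_changes_thresholds_not_membership(
        self, planted_table
    ):
        table, _, _ = planted_table
        cfg = QuintConfig()
        preds = ["x1", "x2", "x3", "x4"]
        base = qt.grow_tree(table, "prop_change", preds, cfg)
        warped = table.copy()
        warped.df["x1"] = np.exp(warped.df["x1"])

        t2 = qt.grow_tree(warped, "prop_change", preds, cfg)
        ids1 = base.route_frame(table.df)
        ids2 = t2.route_frame(warped.df)
        # same partition up to leaf relabeling
        _, inv1 = np.unique(ids1, return_inverse=True)
        _, inv2 = np.unique(ids2, return_inverse=True)
        assert (inv1 == inv2).all()

    def test_growth_deterministic(self, planted_table):
        table, _, _ = planted_table
        cfg = QuintConfig(seed=9)
        preds = ["x1", "x2", "x3", "x4"]
        j1 = qt.tree_to_json(qt.grow_tree(table, "prop_change", preds, cfg))
        j2 = qt.tree_to_json(qt.grow_tree(table, "prop_change", preds, cfg))
        assert j1 == j2

    def test_rejects_missing_outcome_or_predictors(self, trial_like):
        table, _, _ = trial_like  # has dropout missingness
        with pytest.raises(ValueError, match="missing"):
            qt.grow_tree(table, "prop_change", ["drinks_per_week"])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_stepwise_bruteforce_on_tiny_instances(self, seed):
        """Growth equals an independent pure-Python exhaustive step search."""
        rng = np.random.default_rng(seed)
        X, y, t = random_instance(rng, planted=seed % 2 == 0)
        cfg = QuintConfig(max_leaves=3, min_per_arm=3, b_prune=1)
        tree = qt.grow_tree(
            make_table(X, y, t),
            "prop_change",
            [f"x{j + 1}" for j in range(X.shape[1])],
            cfg,
        )
        oracle = stepwise_grow(X, y, t, max_leaves=3, min_per_arm=3)
        assert len(tree.trace) == len(oracle)
        for step, (li, j, thr, c) in zip(tree.trace, oracle):
            assert step.feature == f"x{j + 1}"
            assert step.threshold == pytest.approx(thr, abs=1e-12)
            assert step.criterion == pytest.approx(c, abs=1e-9)


class TestPruning:
    def test_identity_resample_reduces_to_apparent_maximum(self, planted_table):
        table, _, _ = planted_table
        cfg = QuintConfig(b_prune=1, seed=0)
        grown = qt.grow_tree(table, "prop_change", ["x1", "x2", "x3", "x4"], cfg)
        identity = lambda rng, t: np.arange(len(t))
        pruned = qt.prune_tree(grown, table, cfg, resampler=identity)
        rows = pruned.meta["prune"]["table"]
        assert all(r["optimism"] == 0.0 for r in rows)
        # zero optimism: selection degenerates to the apparent-criterion max
        best = max(rows, key=lambda r: r["corrected"])
        assert pruned.n_leaves == best["k"]

    def test_planted_interaction_prunes_to_two_classified_leaves(
        self, planted_table, planted_tree
    ):
        table, _, truth = planted_table
        _, pruned = planted_tree
        assert pruned.n_leaves == 2
        assert pruned.trace[0].feature == "x1"
        assert [l.klass for l in pruned.leaves()] == ["P2", "P1"]
        # leaf classes match the planted effect signs
        ids = pruned.route_frame(table.df)
        for leaf in pruned.leaves():
            frac_high = (truth.labels[ids == leaf.node_id] == "high").mean()
            assert leaf.klass == ("P1" if frac_high > 0.5 else "P2")

    def test_prune_deterministic_under_seed(self, planted_table):
        table, _, _ = planted_table
        cfg = QuintConfig(b_prune=25, seed=123)
        preds = ["x1", "x2", "x3", "x4"]
        grown = qt.grow_tree(table, "prop_change", preds, cfg)
        j1 = qt.tree_to_json(qt.prune_tree(grown, table, cfg))
        j2 = qt.tree_to_json(qt.prune_tree(grown, table, cfg))
        assert j1 == j2

    def test_root_only_tree_passes_through(self):
        cfg = qt.null_config(n=600, seed=1001)
        table, _, _ = qt.generate_trial(cfg)
        qcfg = QuintConfig(seed=1)
        tree = qt.grow_tree(table, "prop_change", ["x1", "x2", "x3", "x4"], qcfg)
        assert tree.n_leaves == 1
        pruned = qt.prune_tree(tree, table, qcfg)
        assert pruned.n_leaves == 1


def test_truncated_subtrees_are_nested(planted_tree):
    grown, _ = planted_tree
    sizes = range(1, grown.n_leaves + 1)
    prev_splits: set = set()
    for k in sizes:
        sub = grown.truncated(k)
        assert sub.n_leaves == k
        cur = {(s.node_id, s.feature, s.threshold) for s in sub.trace}
        assert prev_splits <= cur
        prev_splits = cur
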
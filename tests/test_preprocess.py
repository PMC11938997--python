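"""Outcome derivation, scale scoring, imputation, missing-outcome handling."""

import numpy as np
import pandas as pd
import pytest

import quint_trees as qt
from quint_trees.preprocess import ImputationError, ScoringError
from quint_trees.trial_data import TLFBSeries


def _series(base_heavy, maint_heavy, maint_observed=168, sex="F"):
    """Diary with the given number of heavy days in each window."""
    days = np.concatenate([np.arange(-28, 0), np.arange(8, 176)])
    drinks = np.zeros(len(days))
    drinks[:base_heavy] = 6.0
    drinks[28 : 28 + maint_heavy] = 6.0
    observed = np.ones(len(days), dtype=bool)
    observed[28 + maint_observed :] = False
    return TLFBSeries("p1", sex, days, drinks, observed)


class TestDeriveOutcomes:
    def test_full_reduction(self):
        out = qt.derive_outcomes(_series(14, 0))
        assert out.phdd_base == 0.5
        assert out.raw_change == pytest.approx(14.0)
        assert out.prop_change == pytest.approx(1.0)

    def test_half_reduction_uses_observed_days_only(self):
        out = qt.derive_outcomes(_series(14, 21, maint_observed=84))
        assert out.phdd_maint == pytest.approx(0.25)
        assert out.prop_change == pytest.approx(0.5)
        assert out.observed_maint_days == 84

    def test_no_observed_maintenance_is_missing(self):
        out = qt.derive_outcomes(_series(14, 0, maint_observed=0))
        assert out.missing
        assert np.isnan(out.prop_change) and np.isnan(out.raw_change)

    def test_zero_baseline_heavy_leaves_prop_undefined(self):
        out = qt.derive_outcomes(_series(0, 10))
        assert np.isnan(out.prop_change)
        assert out.raw_change == pytest.approx((0 - 10 / 168) * 28)

    def test_invariant_to_day_permutation(self):
        s = _series(9, 30, maint_observed=120)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(s.days))
        shuffled = TLFBSeries(
            "p1", s.sex, s.days[perm], s.drinks[perm], s.observed[perm]
        )
        assert qt.derive_outcomes(shuffled) == qt.derive_outcomes(s)

    def test_prop_change_is_one_iff_no_maintenance_heavy(self):
        assert qt.derive_outcomes(_series(5, 0)).prop_change == 1.0
        assert qt.derive_outcomes(_series(5, 1)).prop_change < 1.0

    def test_windows_validated(self):
        with pytest.raises(ValueError, match="28 days"):
            qt.derive_outcomes(_series(5, 0), baseline=(-10, -1))
        with pytest.raises(ValueError, match="disjoint"):
            qt.derive_outcomes(_series(5, 0), baseline=(-10, 17))

    def test_frame_derivation_matches_per_participant(self, trial_like):
        _, tlfb, _ = trial_like
        frame = qt.derive_outcomes_frame(tlfb)
        series = qt.trial_data.tlfb_series(tlfb)
        for pid in list(series)[:10]:
            single = qt.derive_outcomes(series[pid])
            row = frame.loc[pid]
            for field, value in single.as_row().items():
                if isinstance(value, float) and np.isnan(value):
                    assert np.isnan(row[field])
                else:
                    assert row[field] == pytest.approx(value)


# ---------------------------------------------------------------------------
# scale scoring


def _item_table(values: dict[str, list[float]]):
    n = len(next(iter(values.values())))
    schema = qt.FeatureSchema(
        tuple(
            qt.FeatureSpec(name, "ordinal", scale="total") for name in values
        )
    )
    df = pd.DataFrame(values)
    df.insert(0, "arm", ["placebo", "active"] * (n // 2) + ["placebo"] * (n % 2))
    df.insert(0, "participant_id", [f"p{i}" for i in range(n)])
    return qt.TrialTable(df, schema, validate=False)


def test_scale_score_is_item_sum():
    table = _item_table({"i1": [1.0] * 4, "i2": [2.0] * 4, "i3": [3.0] * 4})
    scored, log = qt.score_scales(table)
    assert (scored.df["total"] == 6.0).all()
    assert log["excluded_items"]["total"] == []


def test_high_missing_item_excluded_trial_wide():
    i3 = [1.0, np.nan, 1.0, np.nan]  # 50% not-applicable
    table = _item_table({"i1": [1.0] * 4, "i2": [2.0] * 4, "i3": i3})
    scored, log = qt.score_scales(table, max_item_missing=0.10)
    assert log["excluded_items"]["total"] == ["i3"]
    assert (scored.df["total"] == 3.0).all()


def test_exclusion_threshold_one_keeps_everything():
    i3 = [1.0, np.nan, 1.0, np.nan]
    table = _item_table({"i1": [1.0] * 4, "i2": [2.0] * 4, "i3": i3})
    scored, log = qt.score_scales(table, max_item_missing=1.0)
    assert log["excluded_items"]["total"] == []
    assert np.isnan(scored.df["total"].iloc[1])  # unimputed item propagates


def test_all_items_excluded_raises():
    table = _item_table({"i1": [np.nan] * 4, "i2": [np.nan] * 4})
    with pytest.raises(ScoringError):
        qt.score_scales(table, max_item_missing=0.10)


# ---------------------------------------------------------------------------
# imputation


def _numeric_table(df):
    schema = qt.FeatureSchema(
        tuple(
            qt.FeatureSpec(c, "numeric")
            for c in df.columns
            if c not in ("participant_id", "arm")
        )
    )
    return qt.TrialTable(df, schema, validate=False)


def _with_ids(df):
    df = df.copy()
    n = len(df)
    df.insert(0, "arm", ["placebo", "active"] * (n // 2) + ["placebo"] * (n % 2))
    df.insert(0, "participant_id", [f"p{i}" for i in range(n)])
    return df


def test_impute_identity_when_complete():
    df = _with_ids(pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 1, 4, 3]}))
    table = _numeric_table(df)
    out = qt.impute_predictors(table, seed=0)
    pd.testing.assert_frame_equal(out.df, table.df)


def test_impute_recovers_collinear_column():
    rng = np.random.default_rng(1)
    x = rng.normal(size=40)
    y = 2.0 * x
    y_miss = y.copy()
    y_miss[5] = np.nan
    z = rng.normal(size=40)
    df = _with_ids(pd.DataFrame({"x": x, "y": y_miss, "z": z}))
    out = qt.impute_predictors(_numeric_table(df), seed=0)
    assert out.df["y"].iloc[5] == pytest.approx(2.0 * x[5], abs=1e-6)
    # observed cells untouched
    assert np.allclose(out.df["y"].drop(index=5), np.delete(y, 5))


def test_impute_deterministic_under_seed():
    rng = np.random.default_rng(2)
    df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
    df = df.mask(rng.random((30, 4)) < 0.2)
    table = _numeric_table(_with_ids(df))
    out1 = qt.impute_predictors(table, seed=5)
    out2 = qt.impute_predictors(table, seed=5)
    pd.testing.assert_frame_equal(out1.df, out2.df)


def test_impute_rejects_fully_missing_predictor():
    df = _with_ids(pd.DataFrame({"a": [np.nan] * 4, "b": [1.0, 2, 3, 4]}))
    with pytest.raises(ImputationError, match="a"):
        qt.impute_predictors(_numeric_table(df), seed=0)


def test_imputation_better_with_correlated_predictors():
    """MCAR RMSE shrinks as inter-predictor correlation rises (rho 0 vs 0.8)."""
    rmse = {}
    for rho in (0.0, 0.8):
        rng = np.random.default_rng(17)
        n = 400
        cov = np.array([[1, rho, rho], [rho, 1, rho], [rho, rho, 1]])
        X = rng.multivariate_normal(np.zeros(3), cov, size=n)
        truth = X[:, 0].copy()
        mask = rng.random(n) < 0.2
        X[mask, 0] = np.nan
        df = _with_ids(pd.DataFrame(X, columns=["a", "b", "c"]))
        out = qt.impute_predictors(_numeric_table(df), seed=0)
        rmse[rho] = float(
            np.sqrt(np.mean((out.df["a"].to_numpy()[mask] - truth[mask]) ** 2))
        )
    assert rmse[0.8] < rmse[0.0]


def test_imputed_ordinals_snap_to_legal_values():
    vals = [1.0, 2, 3, 1, 2, 3, 1, 2, np.nan, 3]
    df = _with_ids(
        pd.DataFrame({"o": vals, "b": np.arange(10.0), "c": np.arange(10.0)[::-1]})
    )
    schema = qt.FeatureSchema(
        (
            qt.FeatureSpec("o", "ordinal"),
            qt.FeatureSpec("b", "numeric"),
            qt.FeatureSpec("c", "numeric"),
        )
    )
    out = qt.impute_predictors(qt.TrialTable(df, schema, validate=False), seed=0)
    assert out.df["o"].iloc[8] in {1.0, 2.0, 3.0}


# ---------------------------------------------------------------------------
# compliance and missing outcomes


def test_compliance_zero_fill():
    df = _with_ids(pd.DataFrame({"a": [1.0, 2, 3, 4]}))
    for w in range(1, 27):
        df[f"compliance_w{w}"] = 10.0
    df.loc[0, "compliance_w3"] = np.nan
    df.loc[0, "compliance_w20"] = np.nan
    df.loc[1, [f"compliance_w{w}" for w in range(1, 27)]] = np.nan
    table = _numeric_table(df)
    out = qt.handle_compliance(table)
    assert out.df.loc[0, "compliance_w3"] == 0.0
    assert out.df.loc[0, "compliance_total"] == 240.0  # 24 weeks observed
    assert out.df.loc[1, "compliance_total"] == 0.0  # fully missing
    assert out.df.loc[2, "compliance_total"] == 260.0  # untouched


class TestResolveMissingOutcomes:
    def _table(self, n=338, missing_rate=0.1775, seed=21):
        cfg = qt.planted_split_config(n=n, d=0.5, seed=seed)
        table, _, _ = qt.generate_trial(cfg)
        return qt.apply_missingness(table, {"outcome": missing_rate}, seed=seed)

    def test_exclude_drops_missing_records(self):
        table = self._table()
        n_missing = int(table.outcome_missing_mask().sum())
        out, log = qt.resolve_missing_outcomes(table, "exclude")
        assert out.n == table.n - n_missing
        assert log["n_dropped"] == n_missing
        assert not out.outcome_missing_mask().any()

    def test_both_strategies_identity_when_complete(self):
        table = self._table(missing_rate=0.0)
        for strategy in ("exclude", "impute"):
            out, _ = qt.resolve_missing_outcomes(table, strategy)
            pd.testing.assert_frame_equal(out.df, table.df)

    def test_impute_is_deterministic_and_fills_everything(self):
        table = self._table()
        out1, log = qt.resolve_missing_outcomes(table, "impute", seed=3)
        out2, _ = qt.resolve_missing_outcomes(table, "impute", seed=3)
        pd.testing.assert_frame_equal(out1.df, out2.df)
        assert not out1.df["prop_change"].isna().any()
        assert log["n_imputed"] > 0

    def test_all_missing_raises(self):
        table = self._table(missing_rate=1.0)
        with pytest.raises(ValueError, match="all outcomes"):
            qt.resolve_missing_outcomes(table, "exclude")


def test_full_pipeline_provenance(trial_like):
    table, tlfb, _ = trial_like
    out, prov = qt.preprocess_trial(
        table, tlfb, missing_outcomes="exclude", seed=2
    )
    assert "imbibe_parenting" in prov["excluded_items"]
    assert "imbibe_total" in out.df.columns
    assert "compliance_total" in out.df.columns
    assert not out.outcome_missing_mask().any()
    assert out.n == table.n - prov["n_dropped"]
    # retained items imputed, so scored scales are complete
    assert not out.df["imbibe_total"].isna().any()
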
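"""Outcome derivation and missing-data handling for drinking-diary trials.

The analysis outcomes are changes in the proportion of heavy drinking days
(%HDD) between a 28-day pre-randomization baseline window and the
maintenance phase (Weeks 2-25, days 8-175 after randomization):

* ``raw_change``  = (pHDD_base - pHDD_maint) * 28, i.e. heavy drinking days
  saved per 28-day period (range -28..28);
* ``prop_change`` = (pHDD_base - pHDD_maint) / pHDD_base, unitless, at most
  1 (1 = complete abstinence from heavy drinking during maintenance),
  undefined when the baseline window has no heavy days.

Maintenance %HDD is computed over *observed* diary days only — zero-filling
unobserved days would fabricate abstinence for dropouts — and a participant
with no observed maintenance days has a missing outcome.

Predictor missingness is handled by deterministic chained-regression
imputation; weekly compliance gaps are zero-filled (no study visit means no
medication dispensed); missing outcomes are either excluded or imputed from
the predictor battery, mirroring the two strategies a sensitivity analysis
compares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial_data import (
    COMPLIANCE_PREFIX,
    OUTCOME_COLS,
    FeatureSchema,
    TLFBSeries,
    TrialTable,
    heavy_flags,
)

__all__ = [
    "BASELINE_WINDOW",
    "MAINTENANCE_WINDOW",
    "OutcomeSet",
    "ScoringError",
    "ImputationError",
    "derive_outcomes",
    "derive_outcomes_frame",
    "item_missing_fractions",
    "score_scales",
    "impute_predictors",
    "handle_compliance",
    "resolve_missing_outcomes",
    "preprocess_trial",
]

# Day 0 = randomization. Baseline: the 28 days before; maintenance:
# Weeks 2-25 post-randomization (titration week excluded), 168 days.
BASELINE_WINDOW = (-28, -1)
MAINTENANCE_WINDOW = (8, 175)


class ScoringError(ValueError):
    """Scale scoring impossible (e.g. every item excluded)."""


class ImputationError(ValueError):
    """Chained imputation cannot run (e.g. a fully missing predictor)."""


@dataclass(frozen=True)
class OutcomeSet:
    """Derived drinking outcomes for one participant.

    All fields are NaN (and ``missing`` is True) when no maintenance-phase
    day was observed.  ``prop_change`` alone is NaN when the baseline window
    has no heavy days (division by zero); the record is retained and
    ``raw_change`` is still defined.
    """

    phdd_base: float
    phdd_maint: float
    raw_change: float
    prop_change: float
    observed_maint_days: int

    @property
    def missing(self) -> bool:
        return self.observed_maint_days == 0

    def as_row(self) -> dict:
        return {
            "phdd_base": self.phdd_base,
            "phdd_maint": self.phdd_maint,
            "raw_change": self.raw_change,
            "prop_change": self.prop_change,
            "observed_maint_days": self.observed_maint_days,
        }


def _window_len(window: tuple[int, int]) -> int:
    return window[1] - window[0] + 1


def _check_windows(baseline: tuple[int, int], maintenance: tuple[int, int]) -> None:
    if _window_len(baseline) != 28:
        raise ValueError(f"baseline window must span 28 days, got {baseline}")
    if baseline[1] >= maintenance[0]:
        raise ValueError("baseline and maintenance windows must be disjoint")


def derive_outcomes(
    series: TLFBSeries,
    baseline: tuple[int, int] = BASELINE_WINDOW,
    maintenance: tuple[int, int] = MAINTENANCE_WINDOW,
) -> OutcomeSet:
    """Derive %HDD outcomes for one participant's diary."""
    _check_windows(baseline, maintenance)
    heavy = heavy_flags(series.drinks, np.repeat(series.sex, len(series.days)))
    in_base = (series.days >= baseline[0]) & (series.days <= baseline[1])
    in_maint = (series.days >= maintenance[0]) & (series.days <= maintenance[1])
    obs = series.observed

    n_base = int((in_base & obs).sum())
    n_maint = int((in_maint & obs).sum())
    if n_base == 0 or n_maint == 0:
        return OutcomeSet(np.nan, np.nan, np.nan, np.nan, 0)

    pb = float((heavy & in_base & obs).sum()) / n_base
    pm = float((heavy & in_maint & obs).sum()) / n_maint
    raw = (pb - pm) * 28.0
    prop = (pb - pm) / pb if pb > 0 else np.nan
    return OutcomeSet(pb, pm, raw, prop, n_maint)


def derive_outcomes_frame(
    tlfb: pd.DataFrame,
    baseline: tuple[int, int] = BASELINE_WINDOW,
    maintenance: tuple[int, int] = MAINTENANCE_WINDOW,
) -> pd.DataFrame:
    """Vectorized :func:`derive_outcomes` over a long-format TLFB frame.

    Returns one row per participant, indexed by ``participant_id``.
    """
    _check_windows(baseline, maintenance)
    heavy = heavy_flags(tlfb["drinks"].to_numpy(), tlfb["sex"].to_numpy())
    days = tlfb["day"].to_numpy()
    obs = tlfb["observed"].to_numpy(dtype=bool)
    in_base = (days >= baseline[0]) & (days <= baseline[1]) & obs
    in_maint = (days >= maintenance[0]) & (days <= maintenance[1]) & obs

    agg = pd.DataFrame(
        {
            "participant_id": tlfb["participant_id"],
            "n_base": in_base,
            "h_base": in_base & heavy,
            "n_maint": in_maint,
            "h_maint": in_maint & heavy,
        }
    ).groupby("participant_id", sort=False).sum()

    n_base = agg["n_base"].to_numpy(dtype=float)
    n_maint = agg["n_maint"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pb = np.where(n_base > 0, agg["h_base"] / n_base, np.nan)
        pm = np.where(n_maint > 0, agg["h_maint"] / n_maint, np.nan)
        raw = (pb - pm) * 28.0
        prop = np.where(pb > 0, (pb - pm) / pb, np.nan)
    out = pd.DataFrame(
        {
            "phdd_base": pb,
            "phdd_maint": pm,
            "raw_change": raw,
            "prop_change": prop,
            "observed_maint_days": n_maint.astype(int),
        },
        index=agg.index,
    )
    missing = (n_maint == 0) | (n_base == 0)
    out.loc[missing, ["phdd_base", "phdd_maint", "raw_change", "prop_change"]] = np.nan
    out.loc[missing, "observed_maint_days"] = 0
    return out


# ---------------------------------------------------------------------------
# scale scoring


def item_missing_fractions(table: TrialTable, schema: FeatureSchema) -> dict[str, float]:
    """Fraction of missing or not-applicable responses per scale item."""
    fracs: dict[str, float] = {}
    for scale, items in schema.scales.items():
        for item in items:
            if item in table.df.columns:
                fracs[item] = float(table.df[item].isna().mean())
    return fracs


def score_scales(
    table: TrialTable,
    schema: FeatureSchema | None = None,
    max_item_missing: float = 0.10,
    exclude: list[str] | None = None,
) -> tuple[TrialTable, dict]:
    """Add scale-score columns (sum of retained items) to the table.

    Items whose missing/not-applicable fraction reaches ``max_item_missing``
    are dropped from their scale trial-wide (pass ``exclude`` to reuse
    fractions computed before imputation).  Returns the augmented table and
    a provenance dict listing excluded items per scale.
    """
    schema = schema or table.schema
    df = table.df.copy()
    if exclude is None:
        fracs = item_missing_fractions(table, schema)
        exclude = [item for item, f in fracs.items() if f >= max_item_missing]
    log: dict = {"excluded_items": {}, "max_item_missing": max_item_missing}
    for scale, items in schema.scales.items():
        present = [i for i in items if i in df.columns]
        if not present:
            continue
        dropped = [i for i in present if i in exclude]
        retained = [i for i in present if i not in exclude]
        if not retained:
            raise ScoringError(f"scale {scale!r}: all items excluded")
        df[scale] = df[retained].sum(axis=1, skipna=False)
        log["excluded_items"][scale] = dropped
    return TrialTable(df, schema, validate=False), log


# ---------------------------------------------------------------------------
# chained-regression imputation


def _snap_to_legal(values: np.ndarray, legal: np.ndarray) -> np.ndarray:
    """Nearest legal value; distance ties resolve to the smaller value."""
    diffs = np.abs(values[:, None] - legal[None, :])
    return legal[np.argmin(diffs, axis=1)]


def _lstsq_fill(X: np.ndarray, target_obs: np.ndarray, j: int) -> np.ndarray:
    """Predict column ``j`` for its missing rows from all other columns."""
    others = [k for k in range(X.shape[1]) if k != j]
    A = np.column_stack([np.ones(X.shape[0]), X[:, others]])
    beta, *_ = np.linalg.lstsq(A[target_obs], X[target_obs, j], rcond=None)
    return A[~target_obs] @ beta


def impute_predictors(
    table: TrialTable,
    seed: int = 0,
    sweeps: int = 10,
    columns: list[str] | None = None,
) -> TrialTable:
    """Fill missing predictor cells by chained least-squares regression.

    Each incomplete column is regressed on all other predictor columns
    (current working values), sweeping round-robin ``sweeps`` times from a
    column-median start.  Ordinal and binary predictors are snapped to the
    nearest legally observed value.  Observed cells are never altered; the
    seed fixes the column visitation order, making the fill deterministic.
    """
    cols = columns if columns is not None else table.feature_names
    if len(cols) < 2:
        raise ImputationError("need at least two predictors to impute")
    df = table.df.copy()
    X = df[cols].to_numpy(dtype=float)
    obs = ~np.isnan(X)
    empty = [c for c, k in zip(cols, range(len(cols))) if not obs[:, k].any()]
    if empty:
        raise ImputationError(f"predictors with no observed values: {empty}")

    missing_cols = [k for k in range(len(cols)) if not obs[:, k].all()]
    if not missing_cols:
        return table.copy()

    legal: dict[int, np.ndarray] = {}
    for k in missing_cols:
        if table.schema is not None and cols[k] in table.schema:
            if table.schema[cols[k]].kind in ("ordinal", "binary"):
                legal[k] = np.unique(X[obs[:, k], k])

    # median start
    for k in missing_cols:
        X[~obs[:, k], k] = np.median(X[obs[:, k], k])

    rng = np.random.default_rng(seed)
    order = [missing_cols[i] for i in rng.permutation(len(missing_cols))]
    for _ in range(sweeps):
        for k in order:
            pred = _lstsq_fill(X, obs[:, k], k)
            if k in legal:
                pred = _snap_to_legal(pred, legal[k])
            X[~obs[:, k], k] = pred

    df[cols] = X
    return TrialTable(df, table.schema, validate=False)


# ---------------------------------------------------------------------------
# compliance and missing outcomes


def handle_compliance(table: TrialTable) -> TrialTable:
    """Zero-fill missing weekly compliance entries and recompute the total.

    Medication is dispensed at weekly visits, so a missed visit means no
    dispensation: missing weeks count as zero doses.
    """
    df = table.df.copy()
    cols = table.compliance_cols
    if cols:
        df[cols] = df[cols].fillna(0.0)
        df["compliance_total"] = df[cols].sum(axis=1)
    return TrialTable(df, table.schema, validate=False)


def resolve_missing_outcomes(
    table: TrialTable,
    strategy: str,
    seed: int = 0,
    predictors: list[str] | None = None,
) -> tuple[TrialTable, dict]:
    """Apply one of the two missing-outcome strategies.

    ``"exclude"`` drops participants whose maintenance outcome is missing;
    ``"impute"`` fills ``raw_change`` and ``prop_change`` by least-squares
    regression on the (already imputed) predictor battery, the same
    mechanism chained imputation uses.  Returns the resolved table and a
    provenance dict with the affected count.
    """
    if strategy not in ("exclude", "impute"):
        raise ValueError(f"strategy must be 'exclude' or 'impute', got {strategy!r}")
    missing = table.outcome_missing_mask()
    n_missing = int(missing.sum())
    if n_missing == len(table.df):
        raise ValueError("all outcomes missing; nothing to analyse")
    log = {"strategy": strategy, "n_missing_outcome": n_missing}
    if n_missing == 0:
        return table.copy(), log

    if strategy == "exclude":
        out = table.subset(~missing)
        log["n_dropped"] = n_missing
        return out, log

    df = table.df.copy()
    cols = predictors if predictors is not None else table.feature_names
    P = df[cols].to_numpy(dtype=float)
    complete = [k for k in range(P.shape[1]) if not np.isnan(P[:, k]).any()]
    if not complete:
        raise ImputationError("no complete predictor columns for outcome imputation")
    A = np.column_stack([np.ones(len(df)), P[:, complete]])
    for col in ("raw_change", "prop_change"):
        y = df[col].to_numpy(dtype=float)
        fit_rows = ~missing & ~np.isnan(y)
        beta, *_ = np.linalg.lstsq(A[fit_rows], y[fit_rows], rcond=None)
        y[missing] = A[missing] @ beta
        df[col] = y
    # keep the %HDD columns consistent with the imputed raw change
    pb = df["phdd_base"].to_numpy(dtype=float)
    raw = df["raw_change"].to_numpy(dtype=float)
    pm = df["phdd_maint"].to_numpy(dtype=float)
    pm[missing] = np.clip(pb[missing] - raw[missing] / 28.0, 0.0, 1.0)
    df["phdd_maint"] = pm
    log["n_imputed"] = n_missing
    return TrialTable(df, table.schema, validate=False), log


# ---------------------------------------------------------------------------
# end-to-end preprocessing


def preprocess_trial(
    table: TrialTable,
    tlfb: pd.DataFrame | None,
    schema: FeatureSchema | None = None,
    missing_outcomes: str = "exclude",
    seed: int = 0,
    max_item_missing: float = 0.10,
    sweeps: int = 10,
    baseline: tuple[int, int] = BASELINE_WINDOW,
    maintenance: tuple[int, int] = MAINTENANCE_WINDOW,
) -> tuple[TrialTable, dict]:
    """Run the full preprocessing pipeline, returning table + provenance.

    Steps: derive outcomes from the diary (if one is given), decide item
    exclusions on pre-imputation missingness, impute predictor items,
    score scales, zero-fill compliance, then resolve missing outcomes.
    """
    schema = schema or table.schema
    df = table.df.copy()
    if tlfb is not None:
        outcomes = derive_outcomes_frame(tlfb, baseline, maintenance)
        outcomes = outcomes.reindex(df["participant_id"].astype(str))
        for col in OUTCOME_COLS:
            df[col] = outcomes[col].to_numpy()
    work = TrialTable(df, schema, validate=False)

    fracs = item_missing_fractions(work, schema)
    exclude = [item for item, f in fracs.items() if f >= max_item_missing]
    impute_cols = [c for c in work.feature_names if c not in exclude]
    work = impute_predictors(work, seed=seed, sweeps=sweeps, columns=impute_cols)
    work, score_log = score_scales(
        work, schema, max_item_missing=max_item_missing, exclude=exclude
    )
    work = handle_compliance(work)
    work, outcome_log = resolve_missing_outcomes(work, missing_outcomes, seed=seed)
    provenance = {
        "item_missing_fractions": fracs,
        "excluded_items": exclude,
        "imputation_sweeps": sweeps,
        "scored_scales": score_log["excluded_items"],
        **outcome_log,
    }
    return work, provenance
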
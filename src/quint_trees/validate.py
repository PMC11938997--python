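"""Bootstrap optimism validation and cross-outcome model comparison.

A qualitative interaction tree hunts for subgroups with extreme positive
and negative treatment effects, so the spread between its largest and
smallest leaf effects is optimistically biased.  The validation procedure
refits a same-sized tree on bootstrap resamples and compares the effect
range on each resample with the range the same tree attains on the
original data; the mean difference (O_range) estimates the optimism, and
100 * O_range / observed range expresses it as an inflation percentage.

The cross-outcome comparison routes participants through a fitted tree and
recomputes each leaf's Cohen's d on *other* outcome definitions, showing
how robust the partition is to the outcome choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .effects import DegenerateLeafError, effect_range, leaf_effect
from .engine import QuintConfig, _stratified_resample, grow_tree
from .preprocess import resolve_missing_outcomes
from .trial_data import QuintTree, TrialTable

__all__ = [
    "OptimismReport",
    "optimism_range",
    "inflation_percent",
    "cross_outcome_table",
    "compare_missing_strategies",
]


@dataclass
class OptimismReport:
    """Bootstrap optimism of the leaf-effect range."""

    b_requested: int
    b_kept: int
    dropped: int
    scale: str  # "d" or "delta"
    range_boot: list[float]
    range_orig: list[float]
    differences: list[float]
    o_range: float
    observed_range: float
    inflation_pct: float
    leaf_count: int
    seed: int | None

    def to_json(self) -> str:
        doc = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "OptimismReport":
        return cls(**json.loads(text))


def inflation_percent(o_range: float, observed_range: float) -> float:
    """Optimism as a percentage of the observed effect-size range."""
    if observed_range <= 0:
        raise ValueError("observed_range must be positive")
    return 100.0 * o_range / observed_range


def _resample_table(table: TrialTable, idx: np.ndarray) -> TrialTable:
    return TrialTable(table.df.iloc[idx].copy(), table.schema, validate=False)


def _leaf_effects_on(
    tree: QuintTree, table: TrialTable, outcome: str
) -> list | None:
    """Per-leaf effect summaries of ``tree`` evaluated on ``table``.

    Returns None when any leaf is degenerate (an arm with < 2 records).
    """
    y = table.df[outcome].to_numpy(dtype=float)
    t = table.arm_indicator()
    leaf_ids = tree.route_frame(table.df)
    out = []
    for leaf in tree.leaves():
        rows = leaf_ids == leaf.node_id
        try:
            out.append(leaf_effect(y[rows & (t == 0)], y[rows & (t == 1)]))
        except DegenerateLeafError:
            return None
    return out


def optimism_range(
    table: TrialTable,
    outcome: str,
    predictors: Sequence[str],
    leaf_count: int,
    config: QuintConfig | None = None,
    B: int = 1000,
    seed: int | None = None,
    scale: str = "d",
    resampler: Callable[[np.random.Generator, np.ndarray], np.ndarray] | None = None,
) -> OptimismReport:
    """Estimate the optimism of the leaf-effect range at a fixed tree size.

    ``leaf_count`` should be the pruned size of the primary fit.  Each
    replicate grows a ``leaf_count``-leaf tree on an arm-stratified
    resample; replicates where no such tree is admissible, or where a leaf
    is degenerate when mapped back to the original table, are dropped and
    counted.  Positive ``o_range`` means the fitted model overestimates the
    spread of subgroup treatment effects.
    """
    config = replace(config or QuintConfig(), max_leaves=max(leaf_count, 2))
    original = grow_tree(table, outcome, predictors, config)
    if original.n_leaves >= 2:
        observed = effect_range(
            [leaf.effect for leaf in original.leaves()], scale=scale
        )
    else:
        # no admissible fit on the original data (e.g. null data probed at a
        # forced size); optimism is still estimable from the resamples
        observed = float("nan")

    rng = np.random.default_rng(seed)
    draw = resampler or _stratified_resample
    t = table.arm_indicator()
    r_boot: list[float] = []
    r_orig: list[float] = []
    diffs: list[float] = []
    dropped = 0
    for _ in range(B):
        idx = draw(rng, t)
        boot_table = _resample_table(table, idx)
        boot_tree = grow_tree(boot_table, outcome, predictors, config)
        if boot_tree.n_leaves < leaf_count:
            dropped += 1
            continue
        eff_orig = _leaf_effects_on(boot_tree, table, outcome)
        if eff_orig is None:
            dropped += 1
            continue
        rb = effect_range([leaf.effect for leaf in boot_tree.leaves()], scale=scale)
        ro = effect_range(eff_orig, scale=scale)
        r_boot.append(rb)
        r_orig.append(ro)
        diffs.append(rb - ro)
    if not diffs:
        raise ValueError("every bootstrap replicate was dropped; cannot estimate")
    o_range = float(np.mean(diffs))
    inflation = (
        inflation_percent(o_range, observed)
        if np.isfinite(observed) and observed > 0
        else float("nan")
    )
    return OptimismReport(
        b_requested=B,
        b_kept=len(diffs),
        dropped=dropped,
        scale=scale,
        range_boot=r_boot,
        range_orig=r_orig,
        differences=diffs,
        o_range=o_range,
        observed_range=float(observed),
        inflation_pct=inflation,
        leaf_count=leaf_count,
        seed=seed,
    )


def cross_outcome_table(
    trees: Mapping[str, QuintTree],
    table: TrialTable,
    outcomes: Sequence[str],
) -> pd.DataFrame:
    """Per-leaf Cohen's d (with 95% CI) of each model on each outcome.

    Rows are ordered (model, leaf, outcome).  Complete cases of each
    outcome are used; a leaf where an arm has < 2 complete cases is
    flagged and its d omitted.
    """
    t = table.arm_indicator()
    rows = []
    for model, tree in trees.items():
        leaf_ids = tree.route_frame(table.df)
        leaf_order = {leaf.node_id: i + 1 for i, leaf in enumerate(tree.leaves())}
        for leaf in tree.leaves():
            in_leaf = leaf_ids == leaf.node_id
            for outcome in outcomes:
                y = table.df[outcome].to_numpy(dtype=float)
                ok = in_leaf & ~np.isnan(y)
                try:
                    eff = leaf_effect(y[ok & (t == 0)], y[ok & (t == 1)])
                    rows.append(
                        {
                            "model": model,
                            "leaf": leaf_order[leaf.node_id],
                            "outcome": outcome,
                            "n_placebo": eff.n_p,
                            "n_active": eff.n_t,
                            "d": eff.d,
                            "ci_lo": eff.ci_lo,
                            "ci_hi": eff.ci_hi,
                            "flagged": False,
                        }
                    )
                except DegenerateLeafError:
                    rows.append(
                        {
                            "model": model,
                            "leaf": leaf_order[leaf.node_id],
                            "outcome": outcome,
                            "n_placebo": int((ok & (t == 0)).sum()),
                            "n_active": int((ok & (t == 1)).sum()),
                            "d": np.nan,
                            "ci_lo": np.nan,
                            "ci_hi": np.nan,
                            "flagged": True,
                        }
                    )
    return pd.DataFrame(rows).sort_values(
        ["model", "leaf", "outcome"], ignore_index=True
    )


def compare_missing_strategies(
    table: TrialTable,
    outcome: str,
    predictors: Sequence[str],
    leaf_count: int,
    config: QuintConfig | None = None,
    B: int = 200,
    seed: int | None = None,
    scale: str = "d",
) -> dict[str, OptimismReport]:
    """Optimism reports under the two missing-outcome strategies.

    The input table should have predictors already imputed but outcomes
    unresolved; each strategy (exclude / impute) is applied and validated
    with the same settings, so the two reports are directly comparable.
    The direction of the difference is data-dependent and left to the
    caller to interpret.
    """
    reports: dict[str, OptimismReport] = {}
    for strategy in ("exclude", "impute"):
        resolved, _ = resolve_missing_outcomes(table, strategy, seed=seed or 0)
        reports[strategy] = optimism_range(
            resolved,
            outcome,
            predictors,
            leaf_count,
            config=config,
            B=B,
            seed=seed,
            scale=scale,
        )
    return reports
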
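"""Qualitative interaction tree fitting.

Unlike an ordinary regression tree, which groups participants with similar
*outcomes*, a qualitative interaction tree groups participants with similar
*treatment effects*, and only accepts partitions exhibiting a qualitative
interaction: at least one subgroup where the active arm beats placebo
(class P1, treatment responders) and at least one where placebo beats the
active arm (class P2, iatrogenic responders); remaining subgroups are
nonresponders (P3).

The partitioning criterion balances effect size against subgroup size:

    C = a1 * [log(1 + D1) + log(1 + D2)] + a2 * [log(N1/N) + log(N2/N)]

where D1 is the size-weighted mean Cohen's d over P1 leaves, D2 the
size-weighted mean of -d over P2 leaves, and N1, N2 the participant counts
in P1 and P2 leaves.  A leaf is eligible for P1 (P2) only when its d is at
least dmin (at most -dmin).  Growth is greedy over all (leaf, predictor,
threshold) candidates; tree size is then selected by a bias-corrected
bootstrap: the optimism of the criterion is estimated by refitting on
resamples, and the smallest size whose corrected criterion comes within
``c_se`` standard errors of the best is kept.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
from dataclasses import asdict, dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .effects import EffectSummary, leaf_effect
from .trial_data import GrowthStep, LeafNode, QuintTree, SplitNode, TrialTable

__all__ = [
    "QuintConfig",
    "partition_criterion",
    "optimal_assignment",
    "grow_tree",
    "prune_tree",
    "fit_tree",
]

_NEG_INF = -math.inf


@dataclass(frozen=True)
class QuintConfig:
    """Tuning parameters of the tree algorithm.

    ``a1``/``a2`` weight the effect-size and subgroup-size criterion
    components; ``dmin`` is the minimum |d| for a leaf to qualify as
    P1/P2; ``min_per_arm`` the minimum records per arm in any leaf;
    ``b_prune`` the bootstrap count for pruning and ``c_se`` the
    standard-error multiplier of the size-selection rule.
    """

    a1: float = 1.0
    a2: float = 1.0
    dmin: float = 0.30
    max_leaves: int = 8
    min_per_arm: int = 10
    b_prune: int = 200
    c_se: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.max_leaves < 2:
            raise ValueError("max_leaves must be >= 2")
        if self.min_per_arm < 2:
            raise ValueError("min_per_arm must be >= 2")
        if self.b_prune < 1:
            raise ValueError("b_prune must be >= 1")
        if self.a1 < 0 or self.a2 < 0 or self.dmin < 0:
            raise ValueError("a1, a2 and dmin must be non-negative")

    @property
    def fast_assignment(self) -> bool:
        # With equal positive weights and dmin > 0 the optimal assignment
        # provably includes every eligible leaf (each eligible leaf scales
        # (N1 + sum n*d)/N by a factor > 1), enabling closed-form search.
        return self.a1 == self.a2 and self.a1 > 0 and self.dmin > 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# criterion and assignment


def _criterion_for_classes(
    ns: Sequence[float], ds: Sequence[float], classes: Sequence[str], config: QuintConfig
) -> float | None:
    """Criterion value of one class assignment, or None if inadmissible."""
    n_tot = float(sum(ns))
    n1 = n2 = s1 = s2 = 0.0
    for n, d, c in zip(ns, ds, classes):
        if c == "P1":
            if not (np.isfinite(d) and d >= config.dmin):
                return None
            n1 += n
            s1 += n * d
        elif c == "P2":
            if not (np.isfinite(d) and -d >= config.dmin):
                return None
            n2 += n
            s2 += -n * d
        elif c != "P3":
            raise ValueError(f"invalid class {c!r}")
    if n1 == 0 or n2 == 0:
        return None
    return config.a1 * (math.log1p(s1 / n1) + math.log1p(s2 / n2)) + config.a2 * (
        math.log(n1 / n_tot) + math.log(n2 / n_tot)
    )


def partition_criterion(
    effects: Sequence[EffectSummary],
    assignment: Sequence[str],
    config: QuintConfig,
) -> float | None:
    """Criterion of an explicit leaf-class assignment (None = inadmissible)."""
    ns = [e.n for e in effects]
    ds = [e.d for e in effects]
    return _criterion_for_classes(ns, ds, assignment, config)


_CLASS_ORDER = {"P1": 0, "P2": 1, "P3": 2}


def _optimal_assignment_nd(
    ns: Sequence[float], ds: Sequence[float], config: QuintConfig
) -> tuple[tuple[str, ...], float] | None:
    choices = []
    for d in ds:
        opts = ["P3"]
        if np.isfinite(d):
            if d >= config.dmin:
                opts.insert(0, "P1")
            if -d >= config.dmin:
                opts.insert(0, "P2")
        choices.append(opts)
    best: tuple[tuple[str, ...], float] | None = None
    best_key = None
    for classes in itertools.product(*choices):
        c = _criterion_for_classes(ns, ds, classes, config)
        if c is None:
            continue
        # ties favor more P3 leaves, then lexicographically smaller classes
        key = (
            -c,
            -classes.count("P3"),
            tuple(_CLASS_ORDER[x] for x in classes),
        )
        if best_key is None or key < best_key:
            best_key = key
            best = (classes, c)
    return best


def optimal_assignment(
    effects: Sequence[EffectSummary], config: QuintConfig
) -> tuple[tuple[str, ...], float] | None:
    """Exhaustive search for the criterion-maximizing admissible assignment.

    Returns (classes per leaf, criterion) or None when no admissible
    qualitative assignment exists.
    """
    return _optimal_assignment_nd([e.n for e in effects], [e.d for e in effects], config)


def _best_criterion_nd(
    ns: np.ndarray, ds: np.ndarray, config: QuintConfig
) -> float | None:
    """Max criterion over assignments (fast closed form when available)."""
    if config.fast_assignment:
        finite = np.isfinite(ds)
        p1 = finite & (ds >= config.dmin)
        p2 = finite & (-ds >= config.dmin)
        a = float(np.sum(ns[p1] * (1.0 + ds[p1])))
        b = float(np.sum(ns[p2] * (1.0 - ds[p2])))
        if a <= 0 or b <= 0:
            return None
        n_tot = float(ns.sum())
        return config.a1 * (math.log(a / n_tot) + math.log(b / n_tot))
    res = _optimal_assignment_nd(list(ns), list(ds), config)
    return None if res is None else res[1]


# ---------------------------------------------------------------------------
# greedy growth


@dataclass
class _LeafState:
    node_id: int
    rows: np.ndarray
    n: int
    d: float  # NaN when undefined (degenerate arm or zero pooled variance)


def _leaf_nd(y: np.ndarray, t: np.ndarray, rows: np.ndarray) -> tuple[int, float]:
    yl = y[rows]
    tl = t[rows]
    n1 = int(tl.sum())
    n0 = len(rows) - n1
    if n0 < 2 or n1 < 2:
        return len(rows), float("nan")
    y1 = yl[tl == 1]
    y0 = yl[tl == 0]
    v = ((n0 - 1) * y0.var(ddof=1) + (n1 - 1) * y1.var(ddof=1)) / (n0 + n1 - 2)
    if v <= 0:
        return len(rows), float("nan")
    return len(rows), float((y1.mean() - y0.mean()) / math.sqrt(v))


def _scan_candidates(
    x: np.ndarray, y: np.ndarray, t: np.ndarray, min_per_arm: int
) -> tuple[np.ndarray, ...] | None:
    """All admissible threshold candidates within one leaf for one predictor.

    Returns (thresholds, n_l, d_l, n_r, d_r, valid) vectors over candidate
    cut positions, or None when the predictor is constant in the leaf.
    """
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    cut = np.flatnonzero(xs[:-1] < xs[1:])
    if cut.size == 0:
        return None
    ys = y[order]
    ts = t[order].astype(float)

    c1 = np.cumsum(ts)
    c0 = np.cumsum(1.0 - ts)
    s1 = np.cumsum(ys * ts)
    s0 = np.cumsum(ys * (1.0 - ts))
    q1 = np.cumsum(ys * ys * ts)
    q0 = np.cumsum(ys * ys * (1.0 - ts))

    n1l, n0l = c1[cut], c0[cut]
    n1r, n0r = c1[-1] - n1l, c0[-1] - n0l
    valid = (
        (n1l >= min_per_arm)
        & (n0l >= min_per_arm)
        & (n1r >= min_per_arm)
        & (n0r >= min_per_arm)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        m1l = s1[cut] / n1l
        m0l = s0[cut] / n0l
        m1r = (s1[-1] - s1[cut]) / n1r
        m0r = (s0[-1] - s0[cut]) / n0r
        ss1l = np.maximum(q1[cut] - n1l * m1l**2, 0.0)
        ss0l = np.maximum(q0[cut] - n0l * m0l**2, 0.0)
        ss1r = np.maximum(q1[-1] - q1[cut] - n1r * m1r**2, 0.0)
        ss0r = np.maximum(q0[-1] - q0[cut] - n0r * m0r**2, 0.0)
        v_l = (ss1l + ss0l) / (n1l + n0l - 2)
        v_r = (ss1r + ss0r) / (n1r + n0r - 2)
        d_l = (m1l - m0l) / np.sqrt(v_l)
        d_r = (m1r - m0r) / np.sqrt(v_r)
    valid &= (v_l > 0) & (v_r > 0)
    thresholds = 0.5 * (xs[cut] + xs[cut + 1])
    return thresholds, (n1l + n0l), d_l, (n1r + n0r), d_r, valid


def _eligible_terms(n, d, dmin):
    """Contributions n(1+d) / n(1-d) of a leaf to the P1 / P2 pools."""
    if isinstance(n, np.ndarray):
        finite = np.isfinite(d)
        a = np.where(finite & (d >= dmin), n * (1.0 + d), 0.0)
        b = np.where(finite & (-d >= dmin), n * (1.0 - d), 0.0)
        return a, b
    if not np.isfinite(d):
        return 0.0, 0.0
    return (
        n * (1.0 + d) if d >= dmin else 0.0,
        n * (1.0 - d) if -d >= dmin else 0.0,
    )


def _grow_arrays(
    X: np.ndarray, y: np.ndarray, t: np.ndarray, config: QuintConfig
) -> tuple[list[_LeafState], list[tuple]]:
    """Greedy growth on raw arrays.

    Returns the final leaves (left-to-right) and the split list
    [(node_id, left_id, right_id, feature_idx, threshold, criterion), ...].
    """
    n, p = X.shape
    n_tot = float(n)
    root_n, root_d = _leaf_nd(y, t, np.arange(n))
    leaves = [_LeafState(0, np.arange(n), root_n, root_d)]
    splits: list[tuple] = []
    next_id = 1
    current_c = _NEG_INF
    fast = config.fast_assignment

    while len(leaves) < config.max_leaves:
        if fast:
            terms = [_eligible_terms(lf.n, lf.d, config.dmin) for lf in leaves]
            a_all = sum(a for a, _ in terms)
            b_all = sum(b for _, b in terms)
        best = None  # (C, leaf_pos, feature_idx, threshold, rows_left, rows_right)
        for li, leaf in enumerate(leaves):
            if len(leaf.rows) < 4 * config.min_per_arm:
                continue
            yl = y[leaf.rows]
            tl = t[leaf.rows]
            for j in range(p):
                scan = _scan_candidates(X[leaf.rows, j], yl, tl, config.min_per_arm)
                if scan is None:
                    continue
                thr, n_l, d_l, n_r, d_r, valid = scan
                if not valid.any():
                    continue
                if fast:
                    a_oth = a_all - terms[li][0]
                    b_oth = b_all - terms[li][1]
                    al, bl = _eligible_terms(n_l, d_l, config.dmin)
                    ar, br = _eligible_terms(n_r, d_r, config.dmin)
                    a_new = a_oth + al + ar
                    b_new = b_oth + bl + br
                    ok = valid & (a_new > 0) & (b_new > 0)
                    if not ok.any():
                        continue
                    with np.errstate(divide="ignore"):
                        c_vec = np.where(
                            ok,
                            config.a1
                            * (np.log(a_new / n_tot) + np.log(b_new / n_tot)),
                            _NEG_INF,
                        )
                    pos = int(np.argmax(c_vec))
                    c_best = float(c_vec[pos])
                    if c_best == _NEG_INF:
                        continue
                else:
                    other_ns = [lf.n for k, lf in enumerate(leaves) if k != li]
                    other_ds = [lf.d for k, lf in enumerate(leaves) if k != li]
                    c_best, pos = _NEG_INF, -1
                    for q in np.flatnonzero(valid):
                        res = _optimal_assignment_nd(
                            other_ns + [float(n_l[q]), float(n_r[q])],
                            other_ds + [float(d_l[q]), float(d_r[q])],
                            config,
                        )
                        if res is not None and res[1] > c_best:
                            c_best, pos = res[1], int(q)
                    if pos < 0:
                        continue
                if best is None or c_best > best[0]:
                    xcol = X[leaf.rows, j]
                    go_left = xcol <= thr[pos]
                    best = (
                        c_best,
                        li,
                        j,
                        float(thr[pos]),
                        leaf.rows[go_left],
                        leaf.rows[~go_left],
                    )
        if best is None or best[0] <= current_c:
            break
        c_new, li, j, threshold, rows_l, rows_r = best
        parent = leaves[li]
        left = _LeafState(next_id, rows_l, *_leaf_nd(y, t, rows_l))
        right = _LeafState(next_id + 1, rows_r, *_leaf_nd(y, t, rows_r))
        next_id += 2
        leaves[li : li + 1] = [left, right]
        splits.append((parent.node_id, left.node_id, right.node_id, j, threshold, c_new))
        current_c = c_new
    return leaves, splits


def _build_tree(
    splits: list[tuple],
    predictors: Sequence[str],
    outcome: str,
    config: QuintConfig,
) -> QuintTree:
    root: SplitNode | LeafNode = LeafNode(node_id=0)
    nodes: dict[int, LeafNode | SplitNode] = {0: root}
    parents: dict[int, tuple[SplitNode, str]] = {}
    trace = []
    for step, (node_id, left_id, right_id, j, threshold, criterion) in enumerate(
        splits, start=1
    ):
        split = SplitNode(
            node_id=node_id,
            feature=predictors[j],
            threshold=threshold,
            left=LeafNode(left_id),
            right=LeafNode(right_id),
        )
        nodes[left_id] = split.left
        nodes[right_id] = split.right
        if node_id in parents:
            parent, side = parents[node_id]
            setattr(parent, side, split)
        else:
            root = split
        parents[left_id] = (split, "left")
        parents[right_id] = (split, "right")
        nodes.pop(node_id, None)
        trace.append(
            GrowthStep(
                step=step,
                node_id=node_id,
                left_id=left_id,
                right_id=right_id,
                feature=predictors[j],
                threshold=threshold,
                criterion=criterion,
            )
        )
    return QuintTree(
        root=root,
        outcome=outcome,
        predictors=tuple(predictors),
        config_hash=config.config_hash(),
        seed=config.seed,
        trace=tuple(trace),
    )


def _extract_arrays(
    table: TrialTable, outcome: str, predictors: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    y = table.df[outcome].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(
            f"outcome {outcome!r} has missing values; resolve them first"
        )
    X = table.df[list(predictors)].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [p for p in predictors if table.df[p].isna().any()]
        raise ValueError(f"predictors with missing values: {bad}; impute first")
    t = table.arm_indicator().astype(float)
    return X, y, t


def _classify_leaves(
    tree: QuintTree, y: np.ndarray, t: np.ndarray, df: pd.DataFrame
) -> tuple[QuintTree, float | None]:
    """Attach effect summaries and optimal classes computed on (df, y, t)."""
    from .effects import DegenerateLeafError

    leaf_ids = tree.route_frame(df)
    leaves = tree.leaves()
    effects = []
    for leaf in leaves:
        rows = leaf_ids == leaf.node_id
        try:
            effects.append(leaf_effect(y[rows & (t == 0)], y[rows & (t == 1)]))
        except DegenerateLeafError:
            effects.append(None)
    config = tree.meta.get("_config")
    res = (
        optimal_assignment(effects, config)
        if config is not None and all(e is not None for e in effects)
        else None
    )
    if res is None:
        classes = tuple("P3" for _ in leaves)
        crit = None
    else:
        classes, crit = res
    for leaf, eff, klass in zip(leaves, effects, classes):
        leaf.effect = eff
        leaf.klass = klass
    return tree, crit


def grow_tree(
    table: TrialTable,
    outcome: str,
    predictors: Sequence[str],
    config: QuintConfig | None = None,
) -> QuintTree:
    """Grow an unpruned qualitative interaction tree (greedy, with trace).

    A root-only tree flagged ``no_interaction`` is returned when no
    admissible first split exists (no qualitative interaction detected).
    """
    config = config or QuintConfig()
    X, y, t = _extract_arrays(table, outcome, predictors)
    _, splits = _grow_arrays(X, y, t, config)
    tree = _build_tree(splits, predictors, outcome, config)
    tree.meta["_config"] = config
    tree, _ = _classify_leaves(tree, y, t, table.df)
    if not splits:
        tree.no_interaction = True
        for leaf in tree.leaves():
            leaf.klass = "P3"
    tree.meta.pop("_config", None)
    tree.meta["config"] = asdict(config)
    return tree


def _stratified_resample(rng: np.random.Generator, t: np.ndarray) -> np.ndarray:
    idx0 = np.flatnonzero(t == 0)
    idx1 = np.flatnonzero(t == 1)
    return np.concatenate(
        [rng.choice(idx0, size=idx0.size), rng.choice(idx1, size=idx1.size)]
    )


def _subtree_criterion_on(
    splits: list[tuple],
    k: int,
    leaf_of_row: np.ndarray,
    leaf_sets: list[set[int]],
    parent_of: dict[int, int],
    y: np.ndarray,
    t: np.ndarray,
    config: QuintConfig,
) -> float | None:
    """Criterion of the size-k nested subtree, evaluated on (y, t) whose
    rows were routed to the *final* leaves (leaf_of_row)."""
    target = leaf_sets[k - 1]
    # map each final leaf up to its ancestor in the size-k leaf set
    remap: dict[int, int] = {}
    for fid in leaf_sets[-1]:
        node = fid
        while node not in target:
            node = parent_of[node]
        remap[fid] = node
    ids = sorted(target)
    pos = {nid: i for i, nid in enumerate(ids)}
    lab = np.array([pos[remap[f]] for f in leaf_sets[-1]])
    final_ids = sorted(leaf_sets[-1])
    fpos = {nid: i for i, nid in enumerate(final_ids)}
    row_lab = lab[np.array([fpos[f] for f in leaf_of_row])]

    kcount = len(ids)
    ns = np.zeros(kcount)
    ds = np.full(kcount, np.nan)
    for i in range(kcount):
        rows = np.flatnonzero(row_lab == i)
        if rows.size == 0:
            return None
        n_i, d_i = _leaf_nd(y, t, rows)
        if not np.isfinite(d_i):
            return None
        ns[i], ds[i] = n_i, d_i
    return _best_criterion_nd(ns, ds, config)


def prune_tree(
    tree: QuintTree,
    table: TrialTable,
    config: QuintConfig | None = None,
    resampler: Callable[[np.random.Generator, np.ndarray], np.ndarray] | None = None,
) -> QuintTree:
    """Select tree size by bias-corrected bootstrap and re-classify leaves.

    For each nested size k the apparent criterion is corrected by the
    bootstrap optimism o_k = mean(c_boot - c_orig) over ``config.b_prune``
    refits on resamples (stratified by arm); the smallest size whose
    corrected criterion is within ``c_se`` standard errors of the maximum
    is kept.  Bootstrap refits with no admissible size-k subtree (or a
    degenerate evaluation on the original data) are dropped and counted.
    """
    config = config or QuintConfig()
    if tree.n_leaves == 1:
        return tree
    X, y, t = _extract_arrays(table, tree.outcome, tree.predictors)
    big_l = tree.n_leaves
    sizes = list(range(2, big_l + 1))
    apparent = {s.step + 1: s.criterion for s in tree.trace}

    rng = np.random.default_rng(config.seed)
    draw = resampler or _stratified_resample
    diffs: dict[int, list[float]] = {k: [] for k in sizes}
    dropped = {k: 0 for k in sizes}
    for _ in range(config.b_prune):
        idx = draw(rng, t)
        _, bsplits = _grow_arrays(X[idx], y[idx], t[idx], config)
        if not bsplits:
            for k in sizes:
                dropped[k] += 1
            continue
        # route original rows through the bootstrap tree
        leaf_sets: list[set[int]] = [{0}]
        parent_of: dict[int, int] = {}
        for node_id, left_id, right_id, *_ in bsplits:
            nxt = set(leaf_sets[-1])
            nxt.discard(node_id)
            nxt |= {left_id, right_id}
            leaf_sets.append(nxt)
            parent_of[left_id] = node_id
            parent_of[right_id] = node_id
        leaf_of_row = _route_splits(bsplits, X)
        leaf_of_boot_row = _route_splits(bsplits, X[idx])
        for k in sizes:
            if len(bsplits) < k - 1:
                dropped[k] += 1
                continue
            # evaluate both sides with the same evaluator so that a
            # degenerate resample (identity) yields exactly zero optimism
            c_boot = _subtree_criterion_on(
                bsplits, k, leaf_of_boot_row, leaf_sets, parent_of,
                y[idx], t[idx], config,
            )
            c_orig = _subtree_criterion_on(
                bsplits, k, leaf_of_row, leaf_sets, parent_of, y, t, config
            )
            if c_boot is None or c_orig is None:
                dropped[k] += 1
                continue
            diffs[k].append(c_boot - c_orig)

    table_rows = []
    corrected: dict[int, tuple[float, float]] = {}
    for k in sizes:
        kept = diffs[k]
        if kept:
            o_k = float(np.mean(kept))
            se_k = float(np.std(kept, ddof=1)) if len(kept) > 1 else 0.0
            corrected[k] = (apparent[k] - o_k, se_k)
        else:
            o_k, se_k = float("nan"), float("nan")
        table_rows.append(
            {
                "k": k,
                "criterion": apparent[k],
                "optimism": o_k,
                "se": se_k,
                "corrected": apparent[k] - o_k,
                "kept_replicates": len(kept),
                "dropped_replicates": dropped[k],
            }
        )

    if corrected:
        k_max = max(corrected, key=lambda k: (corrected[k][0], -k))
        cut = corrected[k_max][0] - config.c_se * corrected[k_max][1]
        k_sel = min(k for k in corrected if corrected[k][0] >= cut)
    else:  # every bootstrap replicate dropped at every size
        k_sel = max(sizes)

    pruned = tree.truncated(k_sel)
    pruned.meta["_config"] = config
    pruned, _ = _classify_leaves(pruned, y, t, table.df)
    pruned.meta.pop("_config", None)
    pruned.meta["config"] = asdict(config)
    pruned.meta["prune"] = {"selected_size": k_sel, "table": table_rows}
    return pruned


def _route_splits(splits: list[tuple], X: np.ndarray) -> np.ndarray:
    """Leaf node id per row of X for an internal split list."""
    n = X.shape[0]
    out = np.zeros(n, dtype=int)
    children: dict[int, tuple] = {
        node_id: (left, right, j, thr) for node_id, left, right, j, thr, _ in splits
    }
    active = {0: np.arange(n)}
    for node_id, left, right, j, thr, _ in splits:
        rows = active.pop(node_id)
        go_left = X[rows, j] <= thr
        active[left] = rows[go_left]
        active[right] = rows[~go_left]
    for node_id, rows in active.items():
        out[rows] = node_id
    return out


def fit_tree(
    table: TrialTable,
    outcome: str,
    predictors: Sequence[str],
    config: QuintConfig | None = None,
) -> QuintTree:
    """Grow then prune: the full fitting procedure."""
    config = config or QuintConfig()
    grown = grow_tree(table, outcome, predictors, config)
    return prune_tree(grown, table, config)
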
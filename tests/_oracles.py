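"""Independent brute-force oracles for the tree engine tests.

Everything here is deliberately written from the definitions (plain Python
loops, itertools enumeration) rather than calling the engine's vectorized
code paths, so it can serve as an independent check.
"""

import itertools
import math

import numpy as np
import pandas as pd

import quint_trees as qt


def make_table(X, y, t, outcome: str = "prop_change") -> "qt.TrialTable":
    """Minimal trial table from raw arrays (t: 1 = active arm)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n, p = X.shape
    df = pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(n)],
            "arm": np.where(np.asarray(t) == 1, "active", "placebo"),
            outcome: np.asarray(y, dtype=float),
        }
    )
    names = [f"x{j + 1}" for j in range(p)]
    for j, name in enumerate(names):
        df[name] = X[:, j]
    schema = qt.FeatureSchema(
        tuple(qt.FeatureSpec(name, "numeric") for name in names)
    )
    return qt.TrialTable(df, schema, validate=False)


def cohens_d(y, t, rows):
    """Pooled-SD standardized mean difference (active minus placebo)."""
    y0 = [y[i] for i in rows if t[i] == 0]
    y1 = [y[i] for i in rows if t[i] == 1]
    if len(y0) < 2 or len(y1) < 2:
        return None
    m0 = sum(y0) / len(y0)
    m1 = sum(y1) / len(y1)
    ss0 = sum((v - m0) ** 2 for v in y0)
    ss1 = sum((v - m1) ** 2 for v in y1)
    v = (ss0 + ss1) / (len(y0) + len(y1) - 2)
    if v <= 0:
        return None
    return (m1 - m0) / math.sqrt(v)


def criterion(ns, ds, classes, a1, a2, dmin):
    """The partitioning criterion for an explicit assignment, or None."""
    n_tot = sum(ns)
    n1 = n2 = s1 = s2 = 0.0
    for n, d, c in zip(ns, ds, classes):
        if c == "P1":
            if d is None or d < dmin:
                return None
            n1 += n
            s1 += n * d
        elif c == "P2":
            if d is None or -d < dmin:
                return None
            n2 += n
            s2 += -n * d
    if n1 == 0 or n2 == 0:
        return None
    return a1 * (math.log(1 + s1 / n1) + math.log(1 + s2 / n2)) + a2 * (
        math.log(n1 / n_tot) + math.log(n2 / n_tot)
    )


def best_assignment(ns, ds, a1=1.0, a2=1.0, dmin=0.3):
    """Exhaustive search over all 3^k class assignments."""
    best = None
    for classes in itertools.product("123", repeat=len(ns)):
        classes = tuple("P" + c for c in classes)
        c = criterion(ns, ds, classes, a1, a2, dmin)
        if c is not None and (best is None or c > best[1]):
            best = (classes, c)
    return best


def _candidates(x, rows):
    xs = sorted({x[i] for i in rows})
    return [(a + b) / 2 for a, b in zip(xs[:-1], xs[1:])]


def _leaf_sizes_ok(t, rows, m):
    return (
        sum(1 for i in rows if t[i] == 0) >= m
        and sum(1 for i in rows if t[i] == 1) >= m
    )


def stepwise_grow(X, y, t, max_leaves=3, min_per_arm=3, a1=1.0, a2=1.0, dmin=0.3):
    """Brute-force reimplementation of greedy growth.

    Each step enumerates every (leaf, predictor, threshold) candidate,
    scores the resulting leaf set with the exhaustive assignment search,
    and takes the first-encountered maximum (leaf order, predictor order,
    ascending threshold).  Growth stops when no candidate strictly improves
    the criterion.  Returns the list of splits
    (leaf_position, predictor, threshold, criterion).
    """
    n, p = X.shape
    leaves = [list(range(n))]
    splits = []
    current = -math.inf
    while len(leaves) < max_leaves:
        best = None
        for li, rows in enumerate(leaves):
            for j in range(p):
                for thr in _candidates(X[:, j], rows):
                    left = [i for i in rows if X[i, j] <= thr]
                    right = [i for i in rows if X[i, j] > thr]
                    if not (
                        _leaf_sizes_ok(t, left, min_per_arm)
                        and _leaf_sizes_ok(t, right, min_per_arm)
                    ):
                        continue
                    new_leaves = leaves[:li] + [left, right] + leaves[li + 1 :]
                    ns = [len(r) for r in new_leaves]
                    ds = [cohens_d(y, t, r) for r in new_leaves]
                    if any(d is None for d in ds[li : li + 2]):
                        continue
                    res = best_assignment(ns, ds, a1, a2, dmin)
                    if res is None:
                        continue
                    if best is None or res[1] > best[0]:
                        best = (res[1], li, j, thr, left, right)
        if best is None or best[0] <= current:
            break
        c, li, j, thr, left, right = best
        leaves[li : li + 1] = [left, right]
        splits.append((li, j, thr, c))
        current = c
    return splits


def all_two_leaf_trees(X, y, t, min_per_arm=3, a1=1.0, a2=1.0, dmin=0.3):
    """Global enumeration of every admissible single-split tree."""
    n, p = X.shape
    rows = list(range(n))
    out = []
    for j in range(p):
        for thr in _candidates(X[:, j], rows):
            left = [i for i in rows if X[i, j] <= thr]
            right = [i for i in rows if X[i, j] > thr]
            if not (
                _leaf_sizes_ok(t, left, min_per_arm)
                and _leaf_sizes_ok(t, right, min_per_arm)
            ):
                continue
            ds = [cohens_d(y, t, left), cohens_d(y, t, right)]
            if any(d is None for d in ds):
                continue
            res = best_assignment([len(left), len(right)], ds, a1, a2, dmin)
            if res is not None:
                out.append((j, thr, res[1]))
    return out


def random_instance(rng, planted: bool):
    """A tiny random two-arm dataset, optionally with a planted interaction."""
    n = int(rng.integers(20, 31))
    p = int(rng.integers(1, 3))
    X = rng.random((n, p))
    y = rng.standard_normal(n)
    t = np.tile([0, 1], n // 2 + 1)[:n]
    if planted:
        y = y + np.where(X[:, 0] > 0.5, 1.0, -1.0) * np.where(t == 1, 0.6, 0.0)
    return X, y, t
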
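"""Domain types and I/O for two-arm trial tables, drinking diaries, and trees.

The central containers are:

* :class:`FeatureSchema` — declares the baseline covariate battery (kinds,
  missing-value codes, item-to-scale membership, not-applicable flags).
* :class:`TrialTable` — participant-level records (site, arm, features,
  weekly compliance, derived outcomes) backed by a pandas DataFrame with a
  single missing sentinel (NaN).
* :class:`TLFBSeries` — one participant's timeline-followback daily drinking
  record relative to randomization (day 0); negative days are the baseline
  window, positive days the post-randomization phases.
* :class:`QuintTree` — a binary partitioning tree whose leaves carry
  :class:`~quint_trees.effects.EffectSummary` statistics and a responder
  class (P1 treatment responder / P2 iatrogenic responder / P3 nonresponder).

Tables travel as delimited text, trees as JSON (thresholds at full
precision), schemas as YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .effects import EffectSummary

__all__ = [
    "ARM_ACTIVE",
    "ARM_PLACEBO",
    "ID_COL",
    "SITE_COL",
    "ARM_COL",
    "COMPLIANCE_PREFIX",
    "OUTCOME_COLS",
    "LEAF_CLASSES",
    "SchemaError",
    "LoadError",
    "TreeParseError",
    "RoutingError",
    "FeatureSpec",
    "FeatureSchema",
    "TrialTable",
    "TLFBSeries",
    "LeafNode",
    "SplitNode",
    "GrowthStep",
    "QuintTree",
    "is_heavy_day",
    "heavy_flags",
    "load_trial_table",
    "save_trial_table",
    "load_tlfb",
    "save_tlfb",
    "tlfb_series",
    "tree_to_json",
    "tree_from_json",
]

ARM_PLACEBO = "placebo"
ARM_ACTIVE = "active"

ID_COL = "participant_id"
SITE_COL = "site"
ARM_COL = "arm"
COMPLIANCE_PREFIX = "compliance_w"
OUTCOME_COLS = (
    "phdd_base",
    "phdd_maint",
    "raw_change",
    "prop_change",
    "observed_maint_days",
)
LEAF_CLASSES = ("P1", "P2", "P3")

# Heavy drinking day thresholds in standard drinks, by sex.
HEAVY_THRESHOLD = {"F": 4.0, "M": 5.0}


class SchemaError(ValueError):
    """A value or column conflicts with the feature schema."""


class LoadError(ValueError):
    """A delimited-text file could not be interpreted as a trial table."""


class TreeParseError(ValueError):
    """A tree JSON document is malformed; carries the offending JSON path."""

    def __init__(self, message: str, path: str):
        super().__init__(f"{message} (at {path})")
        self.path = path


class RoutingError(KeyError):
    """A record lacks a feature needed to route it through a tree."""


# ---------------------------------------------------------------------------
# heavy-drinking-day semantics


def is_heavy_day(drinks: float, sex: str) -> bool:
    """Whether a day with ``drinks`` standard drinks is a heavy drinking day.

    Thresholds are >= 4 standard drinks for females and >= 5 for males.
    """
    if sex not in HEAVY_THRESHOLD:
        raise SchemaError(f"unknown sex code {sex!r}; expected 'M' or 'F'")
    drinks = float(drinks)
    if not np.isfinite(drinks) or drinks < 0:
        raise ValueError(f"drinks must be finite and >= 0, got {drinks}")
    return drinks >= HEAVY_THRESHOLD[sex]


def heavy_flags(drinks: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Vectorized :func:`is_heavy_day` over per-day arrays."""
    sex = np.asarray(sex)
    bad = ~np.isin(sex, list(HEAVY_THRESHOLD))
    if bad.any():
        raise SchemaError(f"unknown sex code {sex[bad][0]!r}; expected 'M' or 'F'")
    thr = np.where(sex == "F", HEAVY_THRESHOLD["F"], HEAVY_THRESHOLD["M"])
    return np.asarray(drinks, dtype=float) >= thr


# ---------------------------------------------------------------------------
# schema


@dataclass(frozen=True)
class FeatureSpec:
    """One baseline feature: its kind and (optional) scale membership."""

    name: str
    kind: str  # "numeric" | "ordinal" | "binary"
    scale: str | None = None  # scale this item belongs to, if any
    not_applicable: bool = False  # item may carry "Not Applicable" responses

    def __post_init__(self):
        if self.kind not in ("numeric", "ordinal", "binary"):
            raise SchemaError(
                f"feature {self.name!r}: kind must be numeric/ordinal/binary,"
                f" got {self.kind!r}"
            )


DEFAULT_MISSING_CODES = ("", "NA", "Refuse to Respond", "Not Applicable")
DEFAULT_ARM_SYNONYMS = {
    ARM_PLACEBO: ("placebo", "pbo", "control", "0"),
    ARM_ACTIVE: ("active", "treatment", "drug", "1"),
}


@dataclass(frozen=True)
class FeatureSchema:
    """Feature battery declaration used by loaders and preprocessing."""

    features: tuple[FeatureSpec, ...]
    missing_codes: tuple[str, ...] = DEFAULT_MISSING_CODES
    arm_synonyms: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_ARM_SYNONYMS)
    )

    def __post_init__(self):
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate feature names: {dupes}")
        for scale, items in self.scales.items():
            if not items:
                raise SchemaError(f"scale {scale!r} references no items")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    @property
    def scales(self) -> dict[str, list[str]]:
        """Mapping scale name -> ordered list of member item names."""
        out: dict[str, list[str]] = {}
        for f in self.features:
            if f.scale is not None:
                out.setdefault(f.scale, []).append(f.name)
        return out

    def __getitem__(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise SchemaError(f"unknown feature {name!r}")

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def normalize_arm(self, label: str) -> str:
        low = str(label).strip().lower()
        for canonical, synonyms in self.arm_synonyms.items():
            if low == canonical or low in (s.lower() for s in synonyms):
                return canonical
        raise LoadError(f"unrecognized arm label {label!r}")

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self) -> str:
        doc = {
            "features": {
                f.name: {
                    "kind": f.kind,
                    **({"scale": f.scale} if f.scale else {}),
                    **({"not_applicable": True} if f.not_applicable else {}),
                }
                for f in self.features
            },
            "missing_codes": list(self.missing_codes),
            "arm_synonyms": {k: list(v) for k, v in self.arm_synonyms.items()},
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "FeatureSchema":
        doc = yaml.safe_load(text)
        feats = tuple(
            FeatureSpec(
                name=name,
                kind=spec.get("kind", "numeric"),
                scale=spec.get("scale"),
                not_applicable=bool(spec.get("not_applicable", False)),
            )
            for name, spec in doc["features"].items()
        )
        return cls(
            features=feats,
            missing_codes=tuple(doc.get("missing_codes", DEFAULT_MISSING_CODES)),
            arm_synonyms={
                k: tuple(v)
                for k, v in doc.get("arm_synonyms", DEFAULT_ARM_SYNONYMS).items()
            },
        )


# ---------------------------------------------------------------------------
# trial table


class TrialTable:
    """Participant-level trial records backed by a typed DataFrame.

    Structural columns are ``participant_id``, ``site``, ``arm``, weekly
    compliance columns (``compliance_w1`` ...), and the derived outcome
    columns; every remaining column must be declared in the schema.  Missing
    values are NaN throughout.
    """

    def __init__(self, df: pd.DataFrame, schema: FeatureSchema, validate: bool = True):
        self.df = df.reset_index(drop=True)
        self.schema = schema
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.df
        for col in (ID_COL, ARM_COL):
            if col not in df.columns:
                raise LoadError(f"missing required column {col!r}")
        if df[ID_COL].duplicated().any():
            dup = df[ID_COL][df[ID_COL].duplicated()].iloc[0]
            raise LoadError(f"duplicate participant id {dup!r}")
        arms = set(df[ARM_COL].unique())
        if not arms <= {ARM_PLACEBO, ARM_ACTIVE}:
            raise LoadError(
                f"arm column has labels {sorted(map(str, arms))}; expected"
                f" exactly {{{ARM_PLACEBO!r}, {ARM_ACTIVE!r}}}"
            )
        if arms != {ARM_PLACEBO, ARM_ACTIVE}:
            raise LoadError("arm column must contain both arms")
        derived = set(self.schema.scales) | {"compliance_total"}
        for col in self.feature_names:
            if col not in self.schema and col not in derived:
                raise LoadError(f"unknown column {col!r} not in schema")

    # -- column groups ------------------------------------------------------

    @property
    def compliance_cols(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith(COMPLIANCE_PREFIX)]

    @property
    def feature_names(self) -> list[str]:
        reserved = {ID_COL, SITE_COL, ARM_COL, *OUTCOME_COLS}
        return [
            c
            for c in self.df.columns
            if c not in reserved and not c.startswith(COMPLIANCE_PREFIX)
        ]

    @property
    def has_outcomes(self) -> bool:
        return all(c in self.df.columns for c in OUTCOME_COLS)

    def outcome_missing_mask(self) -> np.ndarray:
        """True where the participant's maintenance outcome is missing."""
        if not self.has_outcomes:
            return np.ones(len(self.df), dtype=bool)
        return self.df["phdd_maint"].isna().to_numpy()

    @property
    def n(self) -> int:
        return len(self.df)

    def arm_indicator(self) -> np.ndarray:
        """1 for the active arm, 0 for placebo."""
        return (self.df[ARM_COL] == ARM_ACTIVE).to_numpy().astype(np.int8)

    def features_frame(self) -> pd.DataFrame:
        return self.df[self.feature_names]

    def copy(self) -> "TrialTable":
        return TrialTable(self.df.copy(), self.schema, validate=False)

    def subset(self, mask_or_idx) -> "TrialTable":
        return TrialTable(self.df.loc[mask_or_idx].copy(), self.schema, validate=False)


def _parse_numeric(raw: pd.Series, missing_codes: tuple[str, ...], col: str) -> pd.Series:
    cleaned = raw.astype("string").str.strip()
    cleaned = cleaned.where(~cleaned.isin(list(missing_codes)), other=pd.NA)
    # cell-wise float() keeps the parse exactly round-trippable, which the
    # fast vectorized parsers are not
    values = np.empty(len(cleaned), dtype=float)
    for row, cell in enumerate(cleaned):
        if cell is pd.NA:
            values[row] = np.nan
        else:
            try:
                values[row] = float(cell)
            except ValueError:
                raise LoadError(
                    f"unparseable value {cell!r} in column {col!r}, row {row}"
                ) from None
    return pd.Series(values, index=raw.index)


def load_trial_table(path, schema: FeatureSchema, sep: str = ",") -> TrialTable:
    """Read a delimited trial table, mapping schema missing codes to NaN."""
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if ID_COL not in raw.columns or ARM_COL not in raw.columns:
        raise LoadError(f"file must contain {ID_COL!r} and {ARM_COL!r} columns")
    df = pd.DataFrame()
    df[ID_COL] = raw[ID_COL].astype(str)
    if SITE_COL in raw.columns:
        df[SITE_COL] = raw[SITE_COL].astype(str)
    df[ARM_COL] = raw[ARM_COL].map(schema.normalize_arm)
    numeric_cols = [c for c in raw.columns if c not in (ID_COL, SITE_COL, ARM_COL)]
    derived = set(schema.scales) | {"compliance_total"}
    for col in numeric_cols:
        if (
            col.startswith(COMPLIANCE_PREFIX)
            or col in OUTCOME_COLS
            or col in schema
            or col in derived
        ):
            df[col] = _parse_numeric(raw[col], schema.missing_codes, col)
        else:
            raise LoadError(f"unknown column {col!r} not in schema")
    if "observed_maint_days" in df.columns:
        df["observed_maint_days"] = df["observed_maint_days"].astype("Int64")
    return TrialTable(df, schema)


def save_trial_table(table: TrialTable, path, sep: str = ",") -> None:
    """Write the table as delimited text (missing cells left empty)."""
    table.df.to_csv(path, sep=sep, index=False, na_rep="")


# ---------------------------------------------------------------------------
# timeline followback


@dataclass
class TLFBSeries:
    """One participant's daily drinking record (day 0 = randomization)."""

    participant_id: str
    sex: str
    days: np.ndarray  # integer day indices, unique
    drinks: np.ndarray  # standard drinks, >= 0 where observed
    observed: np.ndarray  # bool

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=int)
        self.drinks = np.asarray(self.drinks, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if len(np.unique(self.days)) != len(self.days):
            raise ValueError(
                f"duplicate day indices for participant {self.participant_id}"
            )
        if self.sex not in HEAVY_THRESHOLD:
            raise SchemaError(f"unknown sex code {self.sex!r}; expected 'M' or 'F'")
        obs_drinks = self.drinks[self.observed]
        if obs_drinks.size and (np.isnan(obs_drinks).any() or (obs_drinks < 0).any()):
            raise ValueError(
                f"observed drinks must be >= 0 for participant {self.participant_id}"
            )


TLFB_COLS = ("participant_id", "sex", "day", "drinks", "observed")


def load_tlfb(path, sep: str = ",") -> pd.DataFrame:
    """Read a long-format TLFB file (one row per participant-day)."""
    df = pd.read_csv(path, sep=sep, dtype={"participant_id": str, "sex": str})
    missing = set(TLFB_COLS) - set(df.columns)
    if missing:
        raise LoadError(f"TLFB file missing columns {sorted(missing)}")
    df["day"] = df["day"].astype(int)
    df["drinks"] = df["drinks"].astype(float)
    df["observed"] = df["observed"].astype(bool)
    return df[list(TLFB_COLS)]


def save_tlfb(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def tlfb_series(df: pd.DataFrame) -> dict[str, TLFBSeries]:
    """Split a long-format TLFB frame into per-participant series."""
    out: dict[str, TLFBSeries] = {}
    for pid, grp in df.groupby("participant_id", sort=False):
        out[str(pid)] = TLFBSeries(
            participant_id=str(pid),
            sex=str(grp["sex"].iloc[0]),
            days=grp["day"].to_numpy(),
            drinks=grp["drinks"].to_numpy(),
            observed=grp["observed"].to_numpy(),
        )
    return out


# ---------------------------------------------------------------------------
# qualitative interaction tree structure


@dataclass
class LeafNode:
    node_id: int
    klass: str | None = None  # "P1" | "P2" | "P3"
    effect: EffectSummary | None = None

    @property
    def is_leaf(self) -> bool:
        return True


@dataclass
class SplitNode:
    node_id: int
    feature: str
    threshold: float
    left: "SplitNode | LeafNode"
    right: "SplitNode | LeafNode"

    @property
    def is_leaf(self) -> bool:
        return False

    @property
    def rule(self) -> str:
        return f"{self.feature} <= {self.threshold!r}"


@dataclass(frozen=True)
class GrowthStep:
    """One greedy split: which node was split, on what, and the criterion."""

    step: int
    node_id: int
    left_id: int
    right_id: int
    feature: str
    threshold: float
    criterion: float


@dataclass
class QuintTree:
    """Binary qualitative-interaction partitioning tree.

    ``trace`` records the greedy growth sequence; replaying its first
    ``k - 1`` entries reconstructs the nested subtree with ``k`` leaves.
    """

    root: SplitNode | LeafNode
    outcome: str
    predictors: tuple[str, ...]
    config_hash: str
    seed: int | None = None
    trace: tuple[GrowthStep, ...] = ()
    no_interaction: bool = False
    meta: dict = field(default_factory=dict)

    # -- structure ----------------------------------------------------------

    def leaves(self) -> list[LeafNode]:
        out: list[LeafNode] = []

        def walk(node):
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def truncated(self, n_leaves: int) -> "QuintTree":
        """Nested subtree after the first ``n_leaves - 1`` splits.

        Leaf classes and effect summaries are dropped (they must be
        recomputed on whatever data the subtree is evaluated against).
        """
        if n_leaves < 1 or n_leaves > len(self.trace) + 1:
            raise ValueError(f"no nested subtree with {n_leaves} leaves")
        root: SplitNode | LeafNode = LeafNode(node_id=self.root.node_id)
        nodes: dict[int, LeafNode | SplitNode] = {root.node_id: root}
        parents: dict[int, tuple[SplitNode, str]] = {}
        for step in self.trace[: n_leaves - 1]:
            old = nodes.pop(step.node_id)
            split = SplitNode(
                node_id=step.node_id,
                feature=step.feature,
                threshold=step.threshold,
                left=LeafNode(step.left_id),
                right=LeafNode(step.right_id),
            )
            nodes[step.left_id] = split.left
            nodes[step.right_id] = split.right
            if old.node_id in parents:
                parent, side = parents[old.node_id]
                setattr(parent, side, split)
            else:
                root = split
            parents[step.left_id] = (split, "left")
            parents[step.right_id] = (split, "right")
        return QuintTree(
            root=root,
            outcome=self.outcome,
            predictors=self.predictors,
            config_hash=self.config_hash,
            seed=self.seed,
            trace=self.trace[: n_leaves - 1],
            no_interaction=False,
            meta={},
        )

    # -- routing ------------------------------------------------------------

    def route_record(self, record: Mapping[str, float]) -> int:
        """Leaf node id for one record; ties (value == threshold) go left."""
        node = self.root
        while not node.is_leaf:
            if node.feature not in record:
                raise RoutingError(
                    f"record lacks split feature {node.feature!r}"
                )
            value = record[node.feature]
            if value is None or (isinstance(value, float) and np.isnan(value)):
                raise RoutingError(
                    f"record has missing value for split feature {node.feature!r}"
                )
            node = node.left if value <= node.threshold else node.right
        return node.node_id

    def route_frame(self, df: pd.DataFrame) -> np.ndarray:
        """Vectorized routing; returns the leaf node id per row."""
        n = len(df)
        ids = np.empty(n, dtype=int)
        idx = np.arange(n)

        def walk(node, rows):
            if node.is_leaf:
                ids[rows] = node.node_id
                return
            if node.feature not in df.columns:
                raise RoutingError(f"table lacks split feature {node.feature!r}")
            values = df[node.feature].to_numpy(dtype=float)[rows]
            if np.isnan(values).any():
                raise RoutingError(
                    f"missing values in split feature {node.feature!r}"
                )
            go_left = values <= node.threshold
            walk(node.left, rows[go_left])
            walk(node.right, rows[~go_left])

        walk(self.root, idx)
        return ids

    def assignment(self) -> dict[int, str]:
        return {leaf.node_id: leaf.klass for leaf in self.leaves()}


def assign_leaf(tree: QuintTree, record: Mapping[str, float]) -> int:
    """Route one participant's features to a leaf id (ties go left)."""
    return tree.route_record(record)


# -- JSON serialization -----------------------------------------------------

TREE_FORMAT = "quint-tree/1"


def _node_to_doc(node) -> dict:
    if node.is_leaf:
        return {
            "id": node.node_id,
            "kind": "leaf",
            "class": node.klass,
            "effect": node.effect.to_dict() if node.effect is not None else None,
        }
    return {
        "id": node.node_id,
        "kind": "split",
        "feature": node.feature,
        "threshold": node.threshold,
        "rule": node.rule,
        "left": _node_to_doc(node.left),
        "right": _node_to_doc(node.right),
    }


def tree_to_json(tree: QuintTree) -> str:
    doc = {
        "format": TREE_FORMAT,
        "outcome": tree.outcome,
        "predictors": list(tree.predictors),
        "config_hash": tree.config_hash,
        "seed": tree.seed,
        "no_interaction": tree.no_interaction,
        "trace": [
            {
                "step": s.step,
                "node": s.node_id,
                "left": s.left_id,
                "right": s.right_id,
                "feature": s.feature,
                "threshold": s.threshold,
                "criterion": s.criterion,
            }
            for s in tree.trace
        ],
        "meta": tree.meta,
        "root": _node_to_doc(tree.root),
    }
    return json.dumps(doc, sort_keys=True, separators=(",", ":"))


def _node_from_doc(doc, path: str):
    if not isinstance(doc, dict):
        raise TreeParseError("node must be an object", path)
    kind = doc.get("kind")
    if kind == "leaf":
        if "class" not in doc:
            raise TreeParseError("leaf missing 'class'", path)
        klass = doc["class"]
        if klass is not None and klass not in LEAF_CLASSES:
            raise TreeParseError(f"invalid leaf class {klass!r}", path + ".class")
        effect = doc.get("effect")
        return LeafNode(
            node_id=int(doc["id"]),
            klass=klass,
            effect=EffectSummary.from_dict(effect) if effect is not None else None,
        )
    if kind == "split":
        for key in ("feature", "threshold", "left", "right"):
            if key not in doc:
                raise TreeParseError(f"split missing {key!r}", path)
        return SplitNode(
            node_id=int(doc["id"]),
            feature=doc["feature"],
            threshold=float(doc["threshold"]),
            left=_node_from_doc(doc["left"], path + ".left"),
            right=_node_from_doc(doc["right"], path + ".right"),
        )
    raise TreeParseError(f"unknown node kind {kind!r}", path + ".kind")


def tree_from_json(text: str) -> QuintTree:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise TreeParseError(f"invalid JSON: {exc}", "$") from exc
    if doc.get("format") != TREE_FORMAT:
        raise TreeParseError(
            f"unsupported format {doc.get('format')!r}", "$.format"
        )
    trace = tuple(
        GrowthStep(
            step=int(s["step"]),
            node_id=int(s["node"]),
            left_id=int(s["left"]),
            right_id=int(s["right"]),
            feature=s["feature"],
            threshold=float(s["threshold"]),
            criterion=float(s["criterion"]),
        )
        for s in doc.get("trace", [])
    )
    return QuintTree(
        root=_node_from_doc(doc["root"], "$.root"),
        outcome=doc["outcome"],
        predictors=tuple(doc["predictors"]),
        config_hash=doc["config_hash"],
        seed=doc.get("seed"),
        trace=trace,
        no_interaction=bool(doc.get("no_interaction", False)),
        meta=doc.get("meta", {}),
    )
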
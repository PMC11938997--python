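"""Synthetic two-arm drinking trials with known subgroup ground truth.

The generator emulates the structure of a multisite placebo-controlled
alcohol pharmacotherapy trial: 1:1 permuted-block randomization stratified
by site, a correlated mixed-type baseline covariate battery (Gaussian
copula), planted covariate-defined subgroups whose treatment effects differ
qualitatively (sign reversal), daily drinking diaries realizing the target
heavy-drinking-day proportions, maintenance-phase outcome dropout (default
17.75%, optionally missing-at-random in baseline drinking), and item-level
predictor missingness.

Treatment effects are planted on the proportion-change scale: a subgroup
with standardized effect *d* has its active-arm latent proportion change
shifted by ``d * outcome_noise_sd``, with the sign convention that positive
*d* favors the active arm (more reduction in heavy drinking).  Latent
proportions are then realized as daily heavy/non-heavy drinking records so
that downstream outcome derivation exercises the real diary code path.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtr

from .preprocess import BASELINE_WINDOW, MAINTENANCE_WINDOW, derive_outcomes_frame
from .trial_data import (
    ARM_ACTIVE,
    ARM_PLACEBO,
    HEAVY_THRESHOLD,
    OUTCOME_COLS,
    FeatureSchema,
    FeatureSpec,
    TrialTable,
)

__all__ = [
    "ConfigError",
    "CovariateSpec",
    "Subgroup",
    "SimConfig",
    "GroundTruth",
    "default_config",
    "planted_split_config",
    "null_config",
    "schema_for",
    "generate_trial",
    "apply_missingness",
]

MIN_PHDD_BASE = 4.0 / 28.0  # inclusion criterion: >=1 heavy day/week at baseline


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution of one baseline covariate.

    ``dist`` is one of ``normal``, ``lognormal``, ``int_normal``,
    ``int_lognormal``, ``binary``; parameters live in ``params``
    (``mu``/``sd`` on the underlying normal scale, optional ``lo``/``hi``
    clipping bounds, ``p`` for binary).
    """

    name: str
    kind: str  # schema kind: numeric | ordinal | binary
    dist: str
    params: tuple[tuple[str, float], ...]
    scale: str | None = None
    not_applicable: bool = False

    def transform(self, z: np.ndarray) -> np.ndarray:
        p = dict(self.params)
        if self.dist == "normal":
            x = p["mu"] + p["sd"] * z
        elif self.dist == "lognormal":
            x = np.exp(p["mu"] + p["sd"] * z)
        elif self.dist == "int_normal":
            x = np.round(p["mu"] + p["sd"] * z)
        elif self.dist == "int_lognormal":
            x = np.round(np.exp(p["mu"] + p["sd"] * z))
        elif self.dist == "binary":
            return (ndtr(z) < p["p"]).astype(float)
        else:
            raise ConfigError(f"unknown marginal dist {self.dist!r}")
        if "lo" in p or "hi" in p:
            x = np.clip(x, p.get("lo", -np.inf), p.get("hi", np.inf))
        return x.astype(float)


def _cv(name, kind, dist, scale=None, not_applicable=False, **params) -> CovariateSpec:
    return CovariateSpec(
        name=name,
        kind=kind,
        dist=dist,
        params=tuple(params.items()),
        scale=scale,
        not_applicable=not_applicable,
    )


@dataclass(frozen=True)
class Subgroup:
    """A planted subgroup: a conjunction of threshold rules plus its true d."""

    name: str
    rules: tuple[tuple[str, str, float], ...]  # (feature, "<=" or ">", threshold)
    d: float

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(df), dtype=bool)
        for feature, op, thr in self.rules:
            if feature not in df.columns:
                raise ConfigError(f"subgroup {self.name!r}: unknown feature {feature!r}")
            x = df[feature].to_numpy(dtype=float)
            m &= (x <= thr) if op == "<=" else (x > thr)
        return m


_DEFAULT_BATTERY: tuple[CovariateSpec, ...] = (
    _cv("drinks_per_week", "numeric", "lognormal", mu=math.log(45.0), sd=0.40),
    _cv("drinks_per_day", "numeric", "lognormal", mu=math.log(8.0), sd=0.35),
    _cv("pct_days_abstinent", "numeric", "normal", mu=20.0, sd=12.0, lo=0.0, hi=85.0),
    _cv("years_drinking", "numeric", "normal", mu=18.0, sd=8.0, lo=1.0, hi=50.0),
    _cv("aud_symptoms", "ordinal", "int_normal", mu=7.0, sd=2.0, lo=4.0, hi=11.0),
    _cv("craving", "numeric", "normal", mu=35.0, sd=12.0, lo=0.0, hi=70.0),
    _cv("motivation", "ordinal", "int_normal", mu=6.5, sd=2.2, lo=1.0, hi=10.0),
    _cv("confidence", "ordinal", "int_normal", mu=6.0, sd=2.3, lo=1.0, hi=10.0),
    _cv("anxiety", "ordinal", "int_lognormal", mu=math.log(9.0), sd=0.8, lo=0.0, hi=63.0),
    _cv("depression", "ordinal", "int_lognormal", mu=math.log(8.0), sd=0.8, lo=0.0, hi=63.0),
    _cv("impulsivity_attention", "ordinal", "int_normal", mu=16.0, sd=4.0, lo=8.0, hi=32.0),
    _cv("sleep_quality", "ordinal", "int_normal", mu=7.0, sd=3.0, lo=0.0, hi=21.0),
    _cv("education_years", "ordinal", "int_normal", mu=14.0, sd=2.5, lo=8.0, hi=20.0),
    _cv("income", "numeric", "lognormal", mu=math.log(55000.0), sd=0.7),
    _cv("smoker", "binary", "binary", p=0.35),
    _cv("imbibe_social", "ordinal", "int_normal", mu=1.5, sd=1.0, lo=0.0, hi=3.0,
        scale="imbibe_total"),
    _cv("imbibe_health", "ordinal", "int_normal", mu=1.5, sd=1.0, lo=0.0, hi=3.0,
        scale="imbibe_total"),
    _cv("imbibe_work", "ordinal", "int_normal", mu=1.2, sd=1.0, lo=0.0, hi=3.0,
        scale="imbibe_total"),
    _cv("imbibe_parenting", "ordinal", "int_normal", mu=1.0, sd=1.0, lo=0.0, hi=3.0,
        scale="imbibe_total", not_applicable=True),
    _cv("imbibe_marriage", "ordinal", "int_normal", mu=1.2, sd=1.0, lo=0.0, hi=3.0,
        scale="imbibe_total", not_applicable=True),
)

_DEFAULT_ITEM_MISSING: tuple[tuple[str, float], ...] = (
    ("imbibe_parenting", 0.25),
    ("imbibe_marriage", 0.10),
    ("motivation", 0.02),
    ("confidence", 0.02),
    ("anxiety", 0.02),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic trial."""

    n: int = 338
    n_sites: int = 10
    block_size: int = 4
    covariates: tuple[CovariateSpec, ...] = _DEFAULT_BATTERY
    rho: float = 0.3  # exchangeable copula correlation
    subgroups: tuple[Subgroup, ...] = (Subgroup("all", (), 0.0),)
    female_frac: float = 0.34
    phdd_base_mean: float = 0.55
    phdd_base_sd: float = 0.12
    phdd_base_feature: str | None = "drinks_per_week"
    outcome_base_mean: float = 0.35
    outcome_noise_sd: float = 0.30
    outcome_dropout: float = 0.1775
    mar_dropout: bool = False
    mar_slope: float = 1.0
    compliance_weeks: int = 26
    compliance_missing_rate: float = 0.05
    item_missing_rates: tuple[tuple[str, float], ...] = _DEFAULT_ITEM_MISSING
    seed: int = 0

    def __post_init__(self):
        if self.block_size % 2 != 0 or self.block_size < 2:
            raise ConfigError("block_size must be a positive even number")
        for _, rate in self.item_missing_rates:
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("missingness rates must lie in [0, 1]")
        if not 0.0 <= self.outcome_dropout <= 1.0:
            raise ConfigError("outcome_dropout must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Per-participant planted subgroup labels and true effect sizes."""

    labels: np.ndarray  # subgroup name per participant
    d: dict[str, float]  # subgroup name -> planted standardized effect
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {"labels": self.labels.tolist(), "d": self.d, "seed": self.seed},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        doc = json.loads(text)
        return cls(np.asarray(doc["labels"]), dict(doc["d"]), int(doc["seed"]))


def default_config(**overrides) -> SimConfig:
    """Trial-like study conditions: N=338, full battery, null overall effect."""
    return replace(SimConfig(), **overrides)


def _simple_battery(n_noise: int) -> tuple[CovariateSpec, ...]:
    return tuple(
        _cv(f"x{i + 1}", "numeric", "normal", mu=0.0, sd=1.0)
        for i in range(n_noise + 1)
    )


def planted_split_config(
    n: int = 600,
    d: float = 0.8,
    n_noise: int = 3,
    noise_sd: float = 0.30,
    dropout: float = 0.0,
    seed: int = 0,
    **overrides,
) -> SimConfig:
    """One planted threshold split: x1 <= 0 has effect -d, x1 > 0 has +d."""
    fields = dict(
        n=n,
        n_sites=4,
        covariates=_simple_battery(n_noise),
        rho=0.0,
        subgroups=(
            Subgroup("low", (("x1", "<=", 0.0),), -d),
            Subgroup("high", (("x1", ">", 0.0),), +d),
        ),
        phdd_base_feature=None,
        outcome_noise_sd=noise_sd,
        outcome_dropout=dropout,
        item_missing_rates=(),
        compliance_missing_rate=0.0,
        seed=seed,
    )
    fields.update(overrides)
    return replace(SimConfig(), **fields)


def null_config(n: int = 600, n_noise: int = 3, seed: int = 0, **overrides) -> SimConfig:
    """No treatment-by-subgroup interaction anywhere (d = 0)."""
    fields = dict(
        n=n,
        n_sites=4,
        covariates=_simple_battery(n_noise),
        rho=0.0,
        subgroups=(Subgroup("all", (), 0.0),),
        phdd_base_feature=None,
        outcome_dropout=0.0,
        item_missing_rates=(),
        compliance_missing_rate=0.0,
        seed=seed,
    )
    fields.update(overrides)
    return replace(SimConfig(), **fields)


def schema_for(config: SimConfig) -> FeatureSchema:
    """Feature schema matching the generator's covariate battery."""
    feats = [
        FeatureSpec(c.name, c.kind, scale=c.scale, not_applicable=c.not_applicable)
        for c in config.covariates
    ]
    feats.append(FeatureSpec("sex_female", "binary"))
    return FeatureSchema(features=tuple(feats))


# ---------------------------------------------------------------------------
# generation internals


def _permuted_block_arms(
    site: np.ndarray, n_sites_labels: list, block_size: int, rng: np.random.Generator
) -> np.ndarray:
    arm = np.empty(len(site), dtype=object)
    half = block_size // 2
    base_block = np.array([0] * half + [1] * half)
    for s in n_sites_labels:
        idx = np.flatnonzero(site == s)
        blocks_needed = -(-len(idx) // block_size)
        seq = np.concatenate([rng.permutation(base_block) for _ in range(blocks_needed)])
        arm[idx] = np.where(seq[: len(idx)] == 1, ARM_ACTIVE, ARM_PLACEBO)
    return arm


def _copula_draw(n: int, p: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal((n, p))
    if rho == 0.0 or p == 1:
        return z
    cov = np.full((p, p), rho)
    np.fill_diagonal(cov, 1.0)
    return z @ np.linalg.cholesky(cov).T


def _heavy_day_layout(
    k: np.ndarray, width: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (n, width) matrix with exactly k[i] heavy days in row i."""
    u = rng.random((len(k), width))
    ranks = np.argsort(np.argsort(u, axis=1), axis=1)
    return ranks < k[:, None]


def _drinks_for(
    heavy: np.ndarray, thr: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Daily standard drinks consistent with the heavy/non-heavy layout."""
    n, width = heavy.shape
    over = np.round(rng.exponential(scale=2.0, size=(n, width)), 1)
    light = np.round(rng.uniform(0.5, thr[:, None] - 0.5), 1)
    zero = rng.random((n, width)) < 0.35
    light = np.where(zero, 0.0, light)
    return np.where(heavy, thr[:, None] + over, light)


def _subgroup_labels(config: SimConfig, features: pd.DataFrame) -> np.ndarray:
    masks = [sg.mask(features) for sg in config.subgroups]
    counts = np.sum(masks, axis=0)
    if (counts != 1).any():
        bad = int(np.flatnonzero(counts != 1)[0])
        raise ConfigError(
            f"subgroup predicates do not partition the data: participant {bad}"
            f" matches {int(counts[bad])} subgroups"
        )
    labels = np.empty(len(features), dtype=object)
    for sg, m in zip(config.subgroups, masks):
        labels[m] = sg.name
    return labels


def generate_trial(
    config: SimConfig,
) -> tuple[TrialTable, pd.DataFrame, GroundTruth]:
    """Generate one synthetic trial; fully reproducible from ``config.seed``.

    Returns the participant table (features, compliance, derived outcomes —
    NaN for maintenance dropouts), the long-format daily diary, and the
    planted ground truth.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    pids = np.array([f"P{i + 1:05d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.female_frac, "F", "M")
    site_labels = [f"S{i + 1:02d}" for i in range(config.n_sites)]
    site = np.asarray(site_labels)[rng.integers(0, config.n_sites, size=n)]
    arm = _permuted_block_arms(site, site_labels, config.block_size, rng)
    active = (arm == ARM_ACTIVE).astype(float)

    # correlated covariate battery
    specs = config.covariates
    Z = _copula_draw(n, len(specs), config.rho, rng)
    features = pd.DataFrame(
        {spec.name: spec.transform(Z[:, j]) for j, spec in enumerate(specs)}
    )
    features["sex_female"] = (sex == "F").astype(float)

    labels = _subgroup_labels(config, features)
    d_map = {sg.name: sg.d for sg in config.subgroups}
    d_vec = np.array([d_map[lab] for lab in labels])

    # baseline %HDD, optionally linked to a drinking covariate
    if config.phdd_base_feature is not None:
        j = [s.name for s in specs].index(config.phdd_base_feature)
        z_link = Z[:, j]
    else:
        z_link = rng.standard_normal(n)
    pb = np.clip(
        config.phdd_base_mean + config.phdd_base_sd * z_link, MIN_PHDD_BASE, 0.95
    )

    # latent proportion change: arm-by-subgroup shift of d * sigma
    sigma = config.outcome_noise_sd
    pc = (
        config.outcome_base_mean
        + active * d_vec * sigma
        + sigma * rng.standard_normal(n)
    )
    pm = np.clip(pb * (1.0 - pc), 0.0, 1.0)

    # realize the daily diary
    thr = np.where(sex == "F", HEAVY_THRESHOLD["F"], HEAVY_THRESHOLD["M"])
    base_days = np.arange(BASELINE_WINDOW[0], BASELINE_WINDOW[1] + 1)
    maint_days = np.arange(MAINTENANCE_WINDOW[0], MAINTENANCE_WINDOW[1] + 1)
    k_base = np.round(pb * len(base_days)).astype(int)
    k_maint = np.round(pm * len(maint_days)).astype(int)
    heavy_base = _heavy_day_layout(k_base, len(base_days), rng)
    heavy_maint = _heavy_day_layout(k_maint, len(maint_days), rng)
    drinks_base = _drinks_for(heavy_base, thr, rng)
    drinks_maint = _drinks_for(heavy_maint, thr, rng)

    # maintenance-phase dropout (all diary days unobserved)
    if config.outcome_dropout > 0:
        if config.mar_dropout:
            zb = (pb - pb.mean()) / max(pb.std(), 1e-12)
            eta = config.mar_slope * zb
            alpha = brentq(
                lambda a: expit(a + eta).mean() - config.outcome_dropout, -30, 30
            )
            p_drop = expit(alpha + eta)
        else:
            p_drop = np.full(n, config.outcome_dropout)
        dropped = rng.random(n) < p_drop
    else:
        dropped = np.zeros(n, dtype=bool)

    def _long(days, drinks, observed_row):
        width = len(days)
        return pd.DataFrame(
            {
                "participant_id": np.repeat(pids, width),
                "sex": np.repeat(sex, width),
                "day": np.tile(days, n),
                "drinks": drinks.ravel(),
                "observed": np.repeat(observed_row, width)
                if observed_row is not None
                else np.ones(n * width, dtype=bool),
            }
        )

    tlfb = pd.concat(
        [
            _long(base_days, drinks_base, None),
            _long(maint_days, drinks_maint, ~dropped),
        ],
        ignore_index=True,
    ).sort_values(["participant_id", "day"], kind="mergesort", ignore_index=True)

    # participant table with derived outcomes
    df = pd.DataFrame({"participant_id": pids, "site": site, "arm": arm})
    for col in features.columns:
        df[col] = features[col]
    doses = rng.binomial(14, 0.9, size=(n, config.compliance_weeks)).astype(float)
    if config.compliance_missing_rate > 0:
        doses[rng.random(doses.shape) < config.compliance_missing_rate] = np.nan
    for w in range(config.compliance_weeks):
        df[f"compliance_w{w + 1}"] = doses[:, w]

    outcomes = derive_outcomes_frame(tlfb).reindex(pids)
    for col in OUTCOME_COLS:
        df[col] = outcomes[col].to_numpy()

    schema = schema_for(config)
    table = TrialTable(df, schema, validate=False)
    if config.item_missing_rates:
        table = apply_missingness(
            table, dict(config.item_missing_rates), seed=int(rng.integers(2**31))
        )
    truth = GroundTruth(labels=labels, d=d_map, seed=config.seed)
    return table, tlfb, truth


def apply_missingness(
    table: TrialTable, rates: dict[str, float], seed: int = 0
) -> TrialTable:
    """Mask cells missing-completely-at-random at the given per-key rates.

    Keys are feature names, or ``"outcome"`` to blank the derived outcome
    set.  The input table is left untouched.
    """
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    for key, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ConfigError(f"rate for {key!r} must lie in [0, 1], got {rate}")
        mask = rng.random(len(df)) < rate
        if key == "outcome":
            df.loc[mask, ["phdd_maint", "raw_change", "prop_change"]] = np.nan
            df.loc[mask, "observed_maint_days"] = 0
        elif key in df.columns and key in table.schema:
            df.loc[mask, key] = np.nan
        else:
            raise ConfigError(f"unknown missingness key {key!r}")
    return TrialTable(df, table.schema, validate=False)
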
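"""Per-leaf two-arm effect statistics.

Every subgroup (tree leaf) is summarized by the placebo-minus-active mean
difference ``delta``, its pooled-variance standard error, and the
standardized mean difference (Cohen's *d*).  Sign conventions follow the
reporting style of two-arm alcohol trials where the outcome is a *reduction*
in drinking: ``delta = mean_placebo - mean_active`` while
``d = (mean_active - mean_placebo) / s_pool``, so a positive *d* means the
active arm reduced drinking more than placebo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DegenerateLeafError",
    "EffectSummary",
    "leaf_effect",
    "effect_from_summary",
    "effect_range",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class DegenerateLeafError(ValueError):
    """Raised when an arm has fewer than two values or zero pooled variance."""


@dataclass(frozen=True)
class EffectSummary:
    """Two-arm summary statistics for one subgroup.

    ``sd_p``/``sd_t`` are sample standard deviations (denominator ``n - 1``);
    ``se`` is the pooled-variance standard error of ``delta``; ``ci_lo`` /
    ``ci_hi`` bound Cohen's *d* at the 95% level (normal theory,
    ``d ± 1.96 * se / s_pool``).
    """

    n_p: int
    n_t: int
    mean_p: float
    mean_t: float
    sd_p: float
    sd_t: float
    delta: float
    s_pool: float
    se: float
    d: float
    ci_lo: float
    ci_hi: float

    @property
    def n(self) -> int:
        return self.n_p + self.n_t

    def to_dict(self) -> dict:
        return {
            "n_p": self.n_p,
            "n_t": self.n_t,
            "mean_p": self.mean_p,
            "mean_t": self.mean_t,
            "sd_p": self.sd_p,
            "sd_t": self.sd_t,
            "delta": self.delta,
            "s_pool": self.s_pool,
            "se": self.se,
            "d": self.d,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "EffectSummary":
        return cls(**{k: data[k] for k in cls.__dataclass_fields__})


def effect_from_summary(
    n_p: int,
    mean_p: float,
    sd_p: float,
    n_t: int,
    mean_t: float,
    sd_t: float,
    hedges: bool = False,
) -> EffectSummary:
    """Build an :class:`EffectSummary` from per-arm n / mean / SD.

    The pooled SD weights each arm's variance by its degrees of freedom:
    ``s_pool^2 = ((n_p-1) sd_p^2 + (n_t-1) sd_t^2) / (n_p + n_t - 2)`` and
    ``se = s_pool * sqrt(1/n_p + 1/n_t)``.  With ``hedges=True`` the
    small-sample correction ``1 - 3/(4(n_p+n_t)-9)`` is applied to *d* and
    its CI (off by default: plain Cohen's d).
    """
    if n_p < 2 or n_t < 2:
        raise DegenerateLeafError(
            f"each arm needs >= 2 values (got n_p={n_p}, n_t={n_t})"
        )
    df = n_p + n_t - 2
    s2 = ((n_p - 1) * sd_p**2 + (n_t - 1) * sd_t**2) / df
    if s2 <= 0.0:
        raise DegenerateLeafError("pooled variance is zero; d undefined")
    s_pool = math.sqrt(s2)
    delta = mean_p - mean_t
    se = s_pool * math.sqrt(1.0 / n_p + 1.0 / n_t)
    d = (mean_t - mean_p) / s_pool
    half = Z95 * se / s_pool  # = Z95 * sqrt(1/n_p + 1/n_t)
    if hedges:
        j = 1.0 - 3.0 / (4.0 * (n_p + n_t) - 9.0)
        d *= j
        half *= j
    return EffectSummary(
        n_p=int(n_p),
        n_t=int(n_t),
        mean_p=float(mean_p),
        mean_t=float(mean_t),
        sd_p=float(sd_p),
        sd_t=float(sd_t),
        delta=float(delta),
        s_pool=float(s_pool),
        se=float(se),
        d=float(d),
        ci_lo=float(d - half),
        ci_hi=float(d + half),
    )


def leaf_effect(
    placebo: Sequence[float] | np.ndarray,
    treatment: Sequence[float] | np.ndarray,
    hedges: bool = False,
) -> EffectSummary:
    """Two-arm effect summary from raw outcome values."""
    p = np.asarray(placebo, dtype=float)
    t = np.asarray(treatment, dtype=float)
    if p.size < 2 or t.size < 2:
        raise DegenerateLeafError(
            f"each arm needs >= 2 values (got n_p={p.size}, n_t={t.size})"
        )
    return effect_from_summary(
        n_p=p.size,
        mean_p=float(p.mean()),
        sd_p=float(p.std(ddof=1)),
        n_t=t.size,
        mean_t=float(t.mean()),
        sd_t=float(t.std(ddof=1)),
        hedges=hedges,
    )


def effect_range(effects: Iterable[EffectSummary], scale: str = "d") -> float:
    """Spread between the largest and smallest leaf effect.

    ``scale`` selects the effect measure: ``"d"`` (Cohen's d) or ``"delta"``
    (raw mean difference).
    """
    if scale not in ("d", "delta"):
        raise ValueError(f"scale must be 'd' or 'delta', got {scale!r}")
    values = [getattr(e, scale) for e in effects]
    if not values:
        raise ValueError("effect_range needs at least one effect")
    return float(max(values) - min(values))
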
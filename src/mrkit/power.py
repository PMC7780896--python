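"""Statistical power for two-sample MR designs.

Power of the asymptotic Wald test of the causal effect, given the total
outcome sample size, the proportion of exposure variance explained by the
instruments (R²), and the true effect.  For a continuous outcome the
noncentrality is |b|·sqrt(n·R²); for a binary outcome the outcome
variance factor cf·(1-cf) (case fraction cf) enters under the square
root.  Both rejection tails are retained, so power(effect=0) equals the
significance level exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

__all__ = ["PowerQuery", "mr_power", "power_grid"]


@dataclass(frozen=True)
class PowerQuery:
    """One power calculation.

    ``effect`` is the log odds ratio per SD of exposure for binary
    outcomes, or the SD change per SD of exposure for continuous ones.
    """

    n_total: int
    r2: float
    effect: float
    alpha: float = 0.007
    outcome_kind: str = "binary"
    case_fraction: float | None = None

    def __post_init__(self):
        if not (0.0 < self.r2 < 1.0):
            raise ValueError("r2 must lie in (0,1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0,1)")
        if self.outcome_kind not in ("binary", "continuous"):
            raise ValueError("outcome_kind must be 'binary' or 'continuous'")
        if self.outcome_kind == "binary":
            if self.case_fraction is None:
                raise ValueError("binary outcome requires case_fraction")
            if not (0.0 < self.case_fraction < 1.0):
                raise ValueError("case_fraction must lie in (0,1)")


def mr_power(q: PowerQuery, adjust_case_fraction: bool = True) -> float:
    """Two-sided asymptotic power of the MR Wald test.

    ``adjust_case_fraction=False`` drops the binary-outcome variance
    factor, matching calculators that assume an equal standardized effect
    regardless of case balance.
    """
    z = stats.norm.ppf(1.0 - q.alpha / 2.0)
    scale = q.n_total * q.r2
    if q.outcome_kind == "binary" and adjust_case_fraction:
        scale *= q.case_fraction * (1.0 - q.case_fraction)
    ncp = abs(q.effect) * math.sqrt(scale)
    return float(stats.norm.cdf(ncp - z) + stats.norm.cdf(-ncp - z))


def power_grid(
    r2_values: Sequence[float],
    designs: Iterable[PowerQuery],
    adjust_case_fraction: bool = True,
) -> pd.DataFrame:
    """Cross-product power table: one row per (r2, design)."""
    r2_values = list(r2_values)
    designs = list(designs)
    if not r2_values or not designs:
        raise ValueError("r2_values and designs must be nonempty")
    rows = []
    for d in designs:
        for r2 in r2_values:
            q = replace(d, r2=r2)
            rows.append({
                "r2": r2,
                "n_total": q.n_total,
                "effect": q.effect,
                "alpha": q.alpha,
                "outcome_kind": q.outcome_kind,
                "case_fraction": q.case_fraction,
                "power": mr_power(q, adjust_case_fraction=adjust_case_fraction),
            })
    return pd.DataFrame(rows)
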
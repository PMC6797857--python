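"""Exact power and minimal sample size for Fisher's exact test on two
independent proportions, by full enumeration of binomial outcome pairs.

For equal group sizes n, the power at true incidences (p_low, p_high) is

    sum over k1, k2 in [0, n] of  Binom(n, p_low)(k1) * Binom(n, p_high)(k2)
    restricted to pairs whose two-sided Fisher exact p-value <= alpha.

The two-sided rule is the point-probability definition (sum of conditional
table probabilities not exceeding that of the observed table); a doubled
one-sided ("central") variant is available for diagnosis of calculations
done under other conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

__all__ = ["PowerSpec", "fisher_p_grid", "fisher_exact_power",
           "required_n_per_group"]


@dataclass(frozen=True)
class PowerSpec:
    """Design assumptions for the two-group incidence comparison.

    Defaults are the published low/high-dose impairment rates (11.1% vs
    66.7%) at two-sided alpha 0.05 and 80% target power.
    """

    p_low: float = 0.111
    p_high: float = 0.667
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self) -> None:
        for name in ("p_low", "p_high"):
            p = getattr(self, name)
            if not (0.0 < p < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {p}")
        if self.p_low == self.p_high:
            raise ValueError("p_low and p_high must differ")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0.0 <= self.target_power <= 1.0):
            raise ValueError(f"target_power must be in [0, 1], got {self.target_power}")


@lru_cache(maxsize=128)
def fisher_p_grid(n: int, rule: str = "point") -> np.ndarray:
    """(n+1, n+1) matrix of two-sided Fisher p-values for tables
    [[k1, n-k1], [k2, n-k2]] over all event-count pairs.

    rule="point": conventional two-sided (scipy's definition).
    rule="doubled": twice the smaller one-sided p, capped at 1.
    """
    grid = np.empty((n + 1, n + 1))
    for k1 in range(n + 1):
        for k2 in range(n + 1):
            table = [[k1, n - k1], [k2, n - k2]]
            if rule == "point":
                grid[k1, k2] = stats.fisher_exact(table)[1]
            elif rule == "doubled":
                p_less = stats.fisher_exact(table, alternative="less")[1]
                p_greater = stats.fisher_exact(table, alternative="greater")[1]
                grid[k1, k2] = min(1.0, 2.0 * min(p_less, p_greater))
            else:
                raise ValueError(f"unknown rule {rule!r}")
    return grid


def fisher_exact_power(n_per_group: int, spec: PowerSpec = PowerSpec(),
                       rule: str = "point") -> float:
    """Exact power of the two-sided Fisher test at equal group size n."""
    if n_per_group < 2:
        raise ValueError(f"n_per_group must be >= 2, got {n_per_group}")
    n = n_per_group
    ks = np.arange(n + 1)
    weights = np.outer(stats.binom.pmf(ks, n, spec.p_low),
                       stats.binom.pmf(ks, n, spec.p_high))
    reject = fisher_p_grid(n, rule) <= spec.alpha
    return float(weights[reject].sum())


def required_n_per_group(spec: PowerSpec = PowerSpec(), rule: str = "point",
                         n_max: int = 10_000) -> int:
    """Smallest per-group n whose exact power reaches the target, scanning
    upward from n = 2."""
    for n in range(2, n_max + 1):
        if fisher_exact_power(n, spec, rule) >= spec.target_power:
            return n
    raise RuntimeError(f"target power {spec.target_power} not reached by n = {n_max}")
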
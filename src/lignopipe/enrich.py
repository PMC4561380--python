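"""Two-sample enrichment statistics for family read proportions.

Each family is compared between a consortium sample and the inoculum as a
2x2 table (family reads vs other matched reads) using the exact two-sided
Fisher test, with a Newcombe-Wilson 95% interval on the difference of
proportions, and both Benjamini-Hochberg and Storey q-values for multiple
testing. Families at p < 0.005 are flagged as significantly enriched or
depleted, matching the significance convention of the profiling analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "TwoSampleCount",
    "EnrichmentResult",
    "fisher_two_sided",
    "wilson_interval",
    "newcombe_diff_ci",
    "bh_fdr",
    "storey_q",
    "enrichment_table",
]

SIGNIFICANCE_P = 0.005


@dataclass(frozen=True)
class TwoSampleCount:
    family: str
    x1: int
    n1: int
    x2: int
    n2: int

    def __post_init__(self) -> None:
        for x, n in ((self.x1, self.n1), (self.x2, self.n2)):
            if not 0 <= x <= n:
                raise ValueError(f"invalid counts x={x}, n={n}")


@dataclass(frozen=True)
class EnrichmentResult:
    family: str
    p_value: float
    diff: float
    ci_low: float
    ci_high: float
    q_bh: float
    q_storey: float

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_P


def fisher_two_sided(x1: int, n1: int, x2: int, n2: int) -> float:
    """Exact two-sided Fisher p for the table [[x1, n1-x1], [x2, n2-x2]].

    Two-sidedness by the point-probability method: the sum over all tables
    with the observed margins whose hypergeometric probability does not
    exceed the observed table's.
    """
    if n1 == 0 or n2 == 0:
        raise ValueError("both sample sizes must be positive")
    table = [[x1, n1 - x1], [x2, n2 - x2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def wilson_interval(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if not 0 <= x <= n or n < 1:
        raise ValueError("require 0 <= x <= n and n >= 1")
    lo, hi = proportion_confint(x, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def newcombe_diff_ci(
    x1: int, n1: int, x2: int, n2: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Newcombe-Wilson interval for the difference of two proportions.

    Combines the per-arm Wilson limits (l_i, u_i) around p1 - p2:
    lower = d - sqrt((p1-l1)^2 + (u2-p2)^2), upper = d + sqrt((u1-p1)^2 + (p2-l2)^2).
    """
    p1, p2 = x1 / n1, x2 / n2
    l1, u1 = wilson_interval(x1, n1, alpha)
    l2, u2 = wilson_interval(x2, n2, alpha)
    d = p1 - p2
    lo = d - np.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2)
    hi = d + np.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2)
    return float(lo), float(hi)


def _step_up(p: np.ndarray) -> np.ndarray:
    """BH step-up values: q_(i) = min_{j>=i} (m/j) p_(j), in input order."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return _step_up(p)


def storey_q(p_values, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with the single-lambda pi0 estimator.

    pi0 = #{p > lambda} / (m (1 - lambda)), clipped to (0, 1]; q-values are
    pi0 times the BH step-up values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if not 0 < lam < 1:
        raise ValueError("lambda must be in (0, 1)")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = np.sum(p > lam) / (m * (1 - lam))
    if pi0 <= 0:
        warnings.warn(
            "all p-values below lambda; pi0 clipped to 1/m", stacklevel=2
        )
        pi0 = 1.0 / m
    pi0 = min(pi0, 1.0)
    return np.minimum(pi0 * _step_up(p), 1.0)


def enrichment_table(counts: list[TwoSampleCount], alpha: float = 0.05) -> list[EnrichmentResult]:
    """Full per-family enrichment analysis with both FDR corrections."""
    ps = np.array([fisher_two_sided(c.x1, c.n1, c.x2, c.n2) for c in counts])
    if ps.size == 0:
        return []
    qb = bh_fdr(ps)
    qs = storey_q(ps)
    out = []
    for c, p, q1, q2 in zip(counts, ps, qb, qs):
        lo, hi = newcombe_diff_ci(c.x1, c.n1, c.x2, c.n2, alpha)
        out.append(
            EnrichmentResult(
                family=c.family,
                p_value=float(p),
                diff=c.x1 / c.n1 - c.x2 / c.n2,
                ci_low=lo,
                ci_high=hi,
                q_bh=float(q1),
                q_storey=float(q2),
            )
        )
    return out
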
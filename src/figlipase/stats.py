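"""Group comparisons of gene counts: Kruskal-Wallis with tie correction.

The pollinating (PFW) vs non-pollinating (NPFW) comparisons are two-group
Kruskal-Wallis tests (equivalent to Mann-Whitney up to the chi-square
approximation), computed with midranks and the standard tie-correction
denominator::

    H = [ 12 / (N (N+1)) * sum R_i^2 / n_i  -  3 (N+1) ] / [ 1 - sum(t^3 - t) / (N^3 - N) ]

with the p-value from the upper tail of chi-square with k - 1 degrees of
freedom.  When every pooled observation is tied the statistic is defined as
0 (p = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .formats import CountTable

__all__ = ["KWResult", "ShareSummary", "kruskal_wallis", "chisq_upper_tail", "share_summary"]


@dataclass(frozen=True)
class KWResult:
    statistic: float  # tie-corrected H
    df: int
    pvalue: float
    n: int
    rank_sums: tuple[float, ...]

    @property
    def statistic_3dp(self) -> float:
        return round(self.statistic, 3)


@dataclass(frozen=True)
class ShareSummary:
    shares: dict[str, float]  # species -> (neutral + acid) / total * 100, 1 dp
    min_species: str
    min_share: float
    max_species: str
    max_share: float


def kruskal_wallis(groups: list[list[float]]) -> KWResult:
    """Tie-corrected Kruskal-Wallis H over two or more groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    sizes = [len(g) for g in groups]
    n = sum(sizes)
    if n < 3:
        raise ValueError("need at least three observations in total")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = sps.rankdata(pooled)  # midranks for ties
    rank_sums = []
    offset = 0
    for size in sizes:
        rank_sums.append(float(ranks[offset : offset + size].sum()))
        offset += size

    h = 12.0 / (n * (n + 1)) * sum(r * r / s for r, s in zip(rank_sums, sizes)) - 3.0 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(((tie_counts**3 - tie_counts).sum()) / (n**3 - n))
    df = len(groups) - 1
    if correction == 0.0:  # every observation tied
        return KWResult(0.0, df, 1.0, n, tuple(rank_sums))
    h /= correction
    h = max(h, 0.0)  # guard against -0.0 from floating cancellation
    return KWResult(h, df, chisq_upper_tail(h, df), n, tuple(rank_sums))


def chisq_upper_tail(x: float, df: int) -> float:
    """P(X >= x) for chi-square with ``df`` degrees of freedom."""
    if x < 0:
        raise ValueError("statistic must be non-negative")
    if df < 1:
        raise ValueError("df must be at least 1")
    return float(sps.chi2.sf(x, df))


def share_summary(table: CountTable, families: tuple[str, str] = ("neutral", "acid")) -> ShareSummary:
    """Per-species share of the two dominant families in the total, in %."""
    totals = table.totals
    if (totals <= 0).any():
        bad = list(totals[totals <= 0].index)
        raise ValueError(f"species with zero total count: {bad}")
    shares = {}
    for sp in table.species:
        part = sum(int(table.counts.loc[sp, f]) for f in families)
        shares[sp] = round(100.0 * part / int(totals[sp]), 1)
    min_sp = min(shares, key=lambda s: (shares[s], s))
    max_sp = max(shares, key=lambda s: (shares[s], s))
    return ShareSummary(shares, min_sp, shares[min_sp], max_sp, shares[max_sp])
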
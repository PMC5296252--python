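"""Rank statistics shared by the enrichment and contingency analyses.

The Wilcoxon-Mann-Whitney test used for annotation enrichment is computed
exactly (by enumerating rank assignments, which handles ties naturally) when
the number of subsets is small, and by the normal approximation with tie
correction otherwise.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

# Exhaustive enumeration is used while C(N, min(n, m)) stays below this cap;
# beyond it the normal approximation with tie correction takes over.
EXACT_ENUMERATION_CAP = 200_000


def midrank(values) -> np.ndarray:
    """Ranks in [1, N] with ties sharing the mean of their rank span."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty vector")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    return sps.rankdata(values, method="average")


def _exact_two_sided_p(ranks: np.ndarray, n_in: int, observed_sum: float) -> float:
    """P(|rank-sum - E| >= |observed - E|) over all C(N, n_in) assignments."""
    n = ranks.size
    expected = n_in * (n + 1) / 2.0
    observed_dev = abs(observed_sum - expected)
    hits = 0
    total = comb(n, n_in)
    # enumerate the smaller side for speed; deviation is symmetric in group swap
    if n_in <= n - n_in:
        k, target_dev = n_in, observed_dev
    else:
        k = n - n_in
        # complement group rank-sum deviates by the same absolute amount
        target_dev = observed_dev
    for subset in combinations(ranks, k):
        dev = abs(sum(subset) - k * (n + 1) / 2.0)
        if dev >= target_dev - 1e-9:
            hits += 1
    return hits / total


def mann_whitney_p(in_values, out_values) -> float:
    """Two-sided Mann-Whitney p for one group against its complement.

    Exact by enumeration of rank assignments (valid under ties) when
    feasible; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(in_values, dtype=float)
    y = np.asarray(out_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = midrank(pooled)
    n, m = x.size, y.size
    big_n = n + m
    rank_sum_in = float(ranks[:n].sum())

    if comb(big_n, min(n, m)) <= EXACT_ENUMERATION_CAP:
        return _exact_two_sided_p(ranks, n, rank_sum_in)

    expected = n * (big_n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    variance = n * m / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    if variance <= 0:  # all values tied: no evidence either way
        return 1.0
    deviation = abs(rank_sum_in - expected)
    z = max(deviation - 0.5, 0.0) / sqrt(variance)  # continuity correction
    return min(1.0, 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0)))))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def pearson_chi2_2x2(a: float, b: float, c: float, d: float, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square and p for the 2x2 table [[a, b], [c, d]], df = 1.

    Uses the closed form n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); optional
    Yates continuity correction.
    """
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ValueError("chi-square undefined: a marginal total is zero")
    delta = abs(a * d - b * c)
    if yates:
        delta = max(delta - n / 2.0, 0.0)
    chi2 = n * delta**2 / denom
    return float(chi2), float(sps.chi2.sf(chi2, df=1))
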
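"""Rank-based 1D and 2D annotation enrichment of motif categories.

Each motif category is scored against the complement of all other quantified
sites on one or two quantitative dimensions (typically the oriented log2
fold changes of the forward and reverse SILAC repeats). The score

    s = 2 * (mean rank in - mean rank out) / N

lies in [-1, 1], reaches +1 exactly when the category occupies the largest
values, -1 when it occupies the smallest, and has expectation 0 under random
assignment. Category membership is tested with a two-sided
Wilcoxon-Mann-Whitney test; p-values are Benjamini-Hochberg adjusted across
categories per dimension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .stats import benjamini_hochberg, mann_whitney_p, midrank

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.02


class UndefinedScoreError(ValueError):
    """The score is undefined for empty or all-covering categories."""


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-category enrichment score(s), test p-values and significance."""

    category: str
    n_in: int
    score_x: float
    p_x: float
    q_x: float
    score_y: float | None = None
    p_y: float | None = None
    q_y: float | None = None
    significant: bool = False


def category_score(ranks, in_mask) -> float:
    """Rank-based enrichment score in [-1, 1] for a category vs its complement."""
    ranks = np.asarray(ranks, dtype=float)
    in_mask = np.asarray(in_mask, dtype=bool)
    if ranks.shape != in_mask.shape:
        raise ValueError("ranks and in_mask must have matching shapes")
    n = ranks.size
    n_in = int(in_mask.sum())
    if n_in == 0 or n_in == n:
        raise UndefinedScoreError(
            f"category must contain between 1 and N-1 members, got {n_in} of {n}"
        )
    return float(2.0 * (ranks[in_mask].mean() - ranks[~in_mask].mean()) / n)


def _as_mask(index: pd.Index, members) -> np.ndarray:
    if isinstance(members, pd.Series):
        return members.reindex(index, fill_value=False).to_numpy(dtype=bool)
    member_set = set(members)
    return np.fromiter((sid in member_set for sid in index), dtype=bool, count=len(index))


def _score_and_test(values: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    ranks = midrank(values)
    return category_score(ranks, mask), mann_whitney_p(values[mask], values[~mask])


def enrich_1d(
    values: pd.Series,
    categories: Mapping[str, object],
    alpha: float = DEFAULT_ALPHA,
    use_adjusted: bool = True,
) -> list[EnrichmentResult]:
    """Enrichment of each category along a single quantitative dimension.

    ``values`` is indexed by site id; ``categories`` maps category name to a
    site-id collection or boolean Series. Sites without a finite value are
    excluded; degenerate categories (empty or covering everything) are
    skipped with a warning.
    """
    values = values.dropna()
    if values.empty:
        raise ValueError("no finite values to rank")
    x = values.to_numpy(dtype=float)
    names, scores, pvals, sizes = [], [], [], []
    for name, members in categories.items():
        mask = _as_mask(values.index, members)
        n_in = int(mask.sum())
        if n_in == 0 or n_in == len(values):
            logger.warning("skipping degenerate category %r (n_in=%d of %d)",
                           name, n_in, len(values))
            continue
        score, p = _score_and_test(x, mask)
        names.append(name)
        scores.append(score)
        pvals.append(p)
        sizes.append(n_in)
    qvals = benjamini_hochberg(pvals)
    results = []
    for name, n_in, score, p, q in zip(names, sizes, scores, pvals, qvals):
        criterion = q if use_adjusted else p
        results.append(
            EnrichmentResult(
                category=name, n_in=n_in,
                score_x=score, p_x=float(p), q_x=float(q),
                significant=bool(criterion < alpha),
            )
        )
    return results


def enrich_2d(
    values_x: pd.Series,
    values_y: pd.Series,
    categories: Mapping[str, object],
    alpha: float = DEFAULT_ALPHA,
    require_both: bool = True,
    use_adjusted: bool = True,
) -> list[EnrichmentResult]:
    """Enrichment along two dimensions on their shared quantified sites.

    Scores and tests are computed independently per dimension on the
    intersection of sites with finite values in both. With ``require_both``
    (the default, conservative) a category is significant only when its
    adjusted p-value clears ``alpha`` in both dimensions; otherwise either
    dimension suffices.
    """
    shared = values_x.dropna().index.intersection(values_y.dropna().index)
    if shared.empty:
        raise ValueError("no sites quantified in both dimensions")
    x = values_x.loc[shared].to_numpy(dtype=float)
    y = values_y.loc[shared].to_numpy(dtype=float)

    names, rows, sizes = [], [], []
    for name, members in categories.items():
        mask = _as_mask(shared, members)
        n_in = int(mask.sum())
        if n_in == 0 or n_in == len(shared):
            logger.warning("skipping degenerate category %r (n_in=%d of %d)",
                           name, n_in, len(shared))
            continue
        sx, px = _score_and_test(x, mask)
        sy, py = _score_and_test(y, mask)
        names.append(name)
        sizes.append(n_in)
        rows.append((sx, px, sy, py))
    qx = benjamini_hochberg([r[1] for r in rows])
    qy = benjamini_hochberg([r[3] for r in rows])
    results = []
    for name, n_in, (sx, px, sy, py), qxi, qyi in zip(names, sizes, rows, qx, qy):
        cx = qxi if use_adjusted else px
        cy = qyi if use_adjusted else py
        hit = (cx < alpha and cy < alpha) if require_both else (cx < alpha or cy < alpha)
        results.append(
            EnrichmentResult(
                category=name, n_in=n_in,
                score_x=sx, p_x=float(px), q_x=float(qxi),
                score_y=sy, p_y=float(py), q_y=float(qyi),
                significant=bool(hit),
            )
        )
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of enrichment results (one row per category)."""
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "n_in": r.n_in,
                "score_x": r.score_x,
                "score_y": r.score_y,
                "p_x": r.p_x,
                "p_y": r.p_y,
                "q_x": r.q_x,
                "q_y": r.q_y,
                "significant": r.significant,
            }
            for r in results
        ]
    )
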
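"""SILAC ratio normalization, orientation, selection and control calibration.

Heavy/light ratios from inverse-label repeats are median-centred per mixture,
oriented onto a common mutant-over-wildtype log2 scale (forward mixtures keep
their sign, reverse mixtures flip it), and sites are called
phosphatase-regulated when both repeats independently exceed the fold
threshold (the upper-left-quadrant rule of an inverse-labeling scatter).
Same-strain control mixtures, whose expected ratio is 1 for every site,
calibrate the measurement variability and imply a false-discovery rate for
the one-sided enrichment selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import SilacMixture
from .stats import mann_whitney_p


def normalize_ratios(ratios) -> pd.Series:
    """Median log2-centre a ratio vector (missing entries pass through).

    After centring, the median of log2 of the present ratios is 0, i.e. the
    median ratio is 1 — emulating the normalized heavy/light ratios produced
    by standard SILAC processing.
    """
    s = pd.Series(np.asarray(ratios, dtype=float)) if not isinstance(ratios, pd.Series) else ratios.astype(float)
    present = s.dropna()
    if present.empty:
        raise ValueError("cannot normalize: all ratios missing")
    if (present <= 0).any():
        raise ValueError("ratios must be > 0")
    log2_median = np.median(np.log2(present.to_numpy()))
    return s / 2.0**log2_median


def orient_log2_fc(ratio_hl, direction: str):
    """Oriented log2 mutant-over-wildtype fold change of one measurement.

    In forward mixtures the phosphatase-null strain is the heavy channel, so
    the oriented value is log2(ratio); in reverse mixtures the labels are
    swapped and the sign flips. Control mixtures carry no orientation.
    """
    if direction == "control":
        raise ValueError("control mixtures are not oriented; use calibrate_control")
    if direction not in ("forward", "reverse"):
        raise ValueError(f"unknown direction {direction!r}")
    ratio = np.asarray(ratio_hl, dtype=float)
    if np.any(ratio[~np.isnan(ratio)] <= 0):
        raise ValueError("ratios must be > 0")
    value = np.log2(ratio)
    value = value if direction == "forward" else -value
    return value if value.ndim else float(value)


def build_oriented_pairs(
    forward: SilacMixture,
    reverse: SilacMixture,
    fold_threshold: float = 2.0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Pair oriented log2 fold changes from a forward and a reverse mixture.

    Returns a frame indexed by site id with columns ``log2_fc_forward``,
    ``log2_fc_reverse``, ``phase`` and ``enriched`` (both values present and
    above log2 of the fold threshold).
    """
    if forward.direction != "forward":
        raise ValueError(f"mixture {forward.mixture_id!r} is not a forward mixture")
    if reverse.direction != "reverse":
        raise ValueError(f"mixture {reverse.mixture_id!r} is not a reverse mixture")
    f = normalize_ratios(forward.ratios) if normalize else forward.ratios
    r = normalize_ratios(reverse.ratios) if normalize else reverse.ratios
    pairs = pd.DataFrame(
        {
            "log2_fc_forward": orient_log2_fc(f.to_numpy(), "forward"),
            "log2_fc_reverse": orient_log2_fc(r.reindex(f.index).to_numpy(), "reverse"),
        },
        index=f.index,
    )
    pairs["phase"] = forward.phase
    cut = _log2_threshold(fold_threshold)
    pairs["enriched"] = (pairs["log2_fc_forward"] > cut) & (pairs["log2_fc_reverse"] > cut)
    return pairs


def _log2_threshold(fold_threshold: float) -> float:
    if not fold_threshold > 1.0:
        raise ValueError(f"fold threshold must exceed 1, got {fold_threshold}")
    return float(np.log2(fold_threshold))


def select_enriched(pairs: pd.DataFrame, fold_threshold: float = 2.0) -> pd.Index:
    """Site ids whose oriented fold change exceeds the threshold in BOTH repeats.

    Sites missing either repeat are never selected. Raising the threshold can
    only shrink the selection.
    """
    cut = _log2_threshold(fold_threshold)
    keep = (pairs["log2_fc_forward"] > cut) & (pairs["log2_fc_reverse"] > cut)
    return pairs.index[keep.fillna(False)]


def select_enriched_single(
    pairs: pd.DataFrame, fold_threshold: float = 2.0, column: str = "log2_fc_forward"
) -> pd.Index:
    """Single-repeat variant of the selection (one oriented dimension only)."""
    cut = _log2_threshold(fold_threshold)
    keep = pairs[column] > cut
    return pairs.index[keep.fillna(False)]


def calibrate_control(control_ratio_vectors, fold: float = 2.0) -> dict:
    """Reproducibility statistics from same-strain control mixtures.

    Each control vector is normalized, then pooled. Returns the fraction of
    sites within ``fold``-fold of unity, the one-sided implied FDR (the share
    of control sites that would pass the enrichment cut, matching the
    one-directional selection), the pooled median normalized ratio and n.
    """
    vectors = list(control_ratio_vectors)
    if not vectors:
        raise ValueError("at least one control mixture is required")
    pooled = []
    for vec in vectors:
        ratios = vec.ratios if isinstance(vec, SilacMixture) else vec
        normalized = normalize_ratios(ratios).dropna()
        pooled.append(np.log2(normalized.to_numpy()))
    log2_pooled = np.concatenate(pooled)
    if log2_pooled.size == 0:
        raise ValueError("control mixtures contain no present measurements")
    cut = _log2_threshold(fold)
    return {
        "n": int(log2_pooled.size),
        "median_ratio": float(2.0 ** np.median(log2_pooled)),
        "fraction_within_fold": float(np.mean(np.abs(log2_pooled) < cut)),
        "implied_fdr": float(np.mean(log2_pooled > cut)),
    }


def cumulative_frequency_test(oriented_values, category_mask) -> dict:
    """Compare a category's cumulative fold-change distribution to the rest.

    Orders all sites by their oriented change and returns the empirical CDFs
    of the category and its complement on the pooled value grid together with
    the two-sided Mann-Whitney p-value for a rank shift.
    """
    values = np.asarray(oriented_values, dtype=float)
    mask = np.asarray(category_mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("values and mask must have matching shapes")
    keep = np.isfinite(values)
    values, mask = values[keep], mask[keep]
    inside, outside = values[mask], values[~mask]
    if inside.size == 0 or outside.size == 0:
        raise ValueError("both the category and its complement must be non-empty")
    grid = np.sort(values)
    ecdf_in = np.searchsorted(np.sort(inside), grid, side="right") / inside.size
    ecdf_out = np.searchsorted(np.sort(outside), grid, side="right") / outside.size
    return {
        "grid": grid,
        "ecdf_in": ecdf_in,
        "ecdf_out": ecdf_out,
        "mwu_p": mann_whitney_p(inside, outside),
    }
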
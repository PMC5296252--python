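"""Time-course trajectory filtering, normalization and peak-time classification.

Per-site intensity trajectories over a synchronized cell cycle (sampled at
10-min intervals against a common metaphase reference) are kept when covered
in at least 8 of the 10 timepoints, normalized to the value at the 90-min
reference, and classified by the time of their maximal phosphorylation:
sites failing a 2-fold rise between the first covered timepoint and their
maximum are *stable*; rising sites peaking at 10-30, 40-60 or 70-90 min are
*early*, *intermediate* or *late* respectively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

TIMING_BINS = {"early": (10.0, 30.0), "intermediate": (40.0, 60.0), "late": (70.0, 90.0)}
TIMING_CATEGORIES = ("early", "intermediate", "late", "stable")

DEFAULT_MIN_PRESENT = 8
DEFAULT_N_TIMEPOINTS = 10
DEFAULT_REF_TIME = 90
DEFAULT_FOLD = 2.0


class ReferenceMissingError(ValueError):
    """The reference-timepoint value is absent or zero; the site is dropped."""


@dataclass(frozen=True)
class TimecourseProfile:
    """One site's classified trajectory."""

    site_id: str
    acceptor: str
    motif_labels: frozenset[str]
    raw: pd.Series
    normalized: pd.Series
    increasing: bool
    peak_time: float | None
    timing_category: str


def filter_coverage(
    values: pd.Series,
    min_present: int = DEFAULT_MIN_PRESENT,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
) -> bool:
    """Keep a profile iff it is measured in at least ``min_present`` of the
    design's ``n_timepoints`` timepoints."""
    present = int(values.notna().sum())
    if len(values) != n_timepoints:
        logger.debug("profile covers %d of the designed %d timepoints", len(values), n_timepoints)
    return present >= min_present


def normalize_to_reference(values: pd.Series, ref_time: float = DEFAULT_REF_TIME) -> pd.Series:
    """Divide a trajectory by its value at the reference timepoint."""
    if ref_time not in values.index:
        raise ReferenceMissingError(f"reference timepoint {ref_time} not in profile")
    ref = values.loc[ref_time]
    if pd.isna(ref) or ref == 0:
        raise ReferenceMissingError(
            f"reference value at t={ref_time} is missing or zero"
        )
    return values / ref


def classify_increase(values: pd.Series, fold: float = DEFAULT_FOLD) -> bool:
    """True iff the profile rises more than ``fold``-fold from its first
    covered timepoint to its maximum."""
    present = values.dropna()
    if present.empty:
        raise ValueError("profile has no present values")
    first = present.iloc[0]
    if first <= 0:
        return True  # any positive maximum is an infinite-fold rise
    return bool(present.max() / first > fold)


def peak_time_of(values: pd.Series, rel_tol: float = 0.0) -> float:
    """Earliest timepoint attaining the maximum (within ``rel_tol`` of it).

    ``rel_tol = 0`` is the exact earliest-tie-break rule used for per-site
    classification; a small positive tolerance extends the same rule to
    averaged profiles, whose maxima sit on a near-flat plateau.
    """
    present = values.dropna()
    if present.empty:
        raise ValueError("profile has no present values")
    peak = present.max()
    cutoff = peak - rel_tol * abs(peak)
    return float(present.index[present.to_numpy() >= cutoff - 1e-12][0])


def classify_timing(normalized: pd.Series, increasing: bool) -> tuple[str, float | None]:
    """Timing category and peak time of a normalized, coverage-filtered profile.

    Non-increasing profiles are *stable* (no peak time). Increasing profiles
    peaking outside the 10-90 min bins (i.e. at t = 0) are classed stable and
    logged; ties in the maximum break to the earliest timepoint, which biases
    against calling a site late.
    """
    if not increasing:
        return "stable", None
    peak = peak_time_of(normalized)
    for category, (lo, hi) in TIMING_BINS.items():
        if lo <= peak <= hi:
            return category, peak
    logger.debug("increasing profile peaks at t=%g outside the timing bins; classed stable", peak)
    return "stable", peak


def analyze_profile(
    site_id: str,
    values: pd.Series,
    acceptor: str = "?",
    motif_labels: frozenset[str] = frozenset(),
    min_present: int = DEFAULT_MIN_PRESENT,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    ref_time: float = DEFAULT_REF_TIME,
    fold: float = DEFAULT_FOLD,
) -> TimecourseProfile | None:
    """Run one site through the coverage filter, normalization and timing
    classification; returns None when the site is dropped."""
    if not filter_coverage(values, min_present, n_timepoints):
        logger.debug("site %s dropped: %d/%d timepoints present",
                     site_id, int(values.notna().sum()), n_timepoints)
        return None
    try:
        normalized = normalize_to_reference(values, ref_time)
    except ReferenceMissingError as exc:
        logger.debug("site %s dropped: %s", site_id, exc)
        return None
    increasing = classify_increase(normalized, fold)
    category, peak = classify_timing(normalized, increasing)
    return TimecourseProfile(
        site_id=site_id,
        acceptor=acceptor,
        motif_labels=motif_labels,
        raw=values,
        normalized=normalized,
        increasing=increasing,
        peak_time=peak,
        timing_category=category,
    )


def analyze_timecourse_table(
    intensities: pd.DataFrame,
    annotations: dict[str, frozenset[str]] | None = None,
    acceptors: dict[str, str] | None = None,
    **kwargs,
) -> list[TimecourseProfile]:
    """Classify every row of a sites x timepoints intensity table."""
    annotations = annotations or {}
    acceptors = acceptors or {}
    profiles = []
    for site_id, row in intensities.iterrows():
        profile = analyze_profile(
            str(site_id),
            row,
            acceptor=acceptors.get(site_id, "?"),
            motif_labels=annotations.get(site_id, frozenset()),
            **kwargs,
        )
        if profile is not None:
            profiles.append(profile)
    return profiles


def profiles_to_frame(profiles: list[TimecourseProfile]) -> pd.DataFrame:
    """One row per kept site: category, peak time and normalized values."""
    rows = []
    for p in profiles:
        row = {
            "site_id": p.site_id,
            "acceptor": p.acceptor,
            "motif_labels": ";".join(sorted(p.motif_labels)),
            "increasing": p.increasing,
            "peak_time": p.peak_time,
            "timing_category": p.timing_category,
        }
        for t, v in p.normalized.items():
            row[f"norm.t{int(t)}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def average_category_profile(
    profiles: list[TimecourseProfile], category_filter
) -> tuple[pd.Series, pd.Series]:
    """Mean normalized trajectory (and per-timepoint n) over a site subset.

    ``category_filter`` is a predicate over TimecourseProfile.
    """
    selected = [p for p in profiles if category_filter(p)]
    if not selected:
        raise ValueError("no profiles match the category filter")
    table = pd.DataFrame({p.site_id: p.normalized for p in selected}).T
    return table.mean(axis=0), table.notna().sum(axis=0)


def peak_lag(profile_a: pd.Series, profile_b: pd.Series, rel_tol: float = 0.2) -> float:
    """Peak-time difference (minutes) of trajectory b after trajectory a.

    Both profiles must share the timepoint grid. Averaged trajectories of a
    monotone rise approach their maximum along a near-flat plateau, so the
    peak time of an average profile is taken as the earliest timepoint within
    ``rel_tol`` of the maximum (the per-site earliest-tie-break rule with a
    plateau tolerance); the default 20% places the crossing on the steep part
    of the mean curve where it is insensitive to residual averaging noise.
    """
    if not profile_a.index.equals(profile_b.index):
        raise ValueError("profiles must share the same timepoint grid")
    return peak_time_of(profile_b, rel_tol) - peak_time_of(profile_a, rel_tol)
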
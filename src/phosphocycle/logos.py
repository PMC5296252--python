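"""Sequence-logo matrices and acceptor-by-timing contingency statistics.

Logos are built from the ±6 windows of a site set: a position probability
matrix (padding excluded from each position's denominator), Shannon
information content per position (log2(20) − H, in bits) and letter heights
(probability × information). Differential logos test each residue's
foreground frequency per position against a background residue distribution
(by default proteome-wide frequencies), following the species-aware z-score
formulation used for background-corrected logos.

The contingency side cross-tabulates timing categories against the pSP/pTP
motif of minimal-Cdk sites and asks, with a Pearson chi-square on the focal
category versus the pooled rest, whether late sites are enriched for pTP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .site_tables import PAD_CHAR, WINDOW_FLANK, WINDOW_LENGTH
from .stats import pearson_chi2_2x2
from .timecourse import TIMING_CATEGORIES, TimecourseProfile

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
POSITIONS = tuple(range(-WINDOW_FLANK, WINDOW_FLANK + 1))
MAX_IC_BITS = float(np.log2(len(AMINO_ACIDS)))


@dataclass(frozen=True)
class LogoMatrix:
    """Per-position residue probabilities, information content and heights."""

    probabilities: pd.DataFrame  # positions x residues, rows sum to 1
    information: pd.Series  # bits per position
    letter_heights: pd.DataFrame  # probabilities * information
    n_windows: int


def position_probability_matrix(windows: Sequence[str]) -> pd.DataFrame:
    """Column-wise residue frequencies of a window set.

    Padding characters are excluded from each position's normalizing
    denominator, so probabilities at a position sum to 1 over the 20 amino
    acids whenever any real residue is observed there.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("at least one window is required")
    lengths = {len(w) for w in windows}
    if lengths != {WINDOW_LENGTH}:
        raise ValueError(f"all windows must have length {WINDOW_LENGTH}, got {sorted(lengths)}")
    counts = pd.DataFrame(0.0, index=list(POSITIONS), columns=list(AMINO_ACIDS))
    for window in windows:
        for pos, residue in zip(POSITIONS, window):
            if residue != PAD_CHAR:
                counts.loc[pos, residue] += 1
    totals = counts.sum(axis=1)
    ppm = counts.div(totals.where(totals > 0, 1.0), axis=0)
    return ppm


def information_logo(ppm: pd.DataFrame, small_sample_n: int | None = None) -> LogoMatrix:
    """Shannon information logo from a position probability matrix.

    IC(pos) = log2(20) − H(pos) with H = −Σ p·log2 p; letter heights are
    probability × IC. ``small_sample_n`` optionally applies the standard
    small-sample correction e = (20−1)/(2·ln2·n) (off by default).
    """
    p = ppm.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    entropy = -plogp.sum(axis=1)
    correction = 0.0
    if small_sample_n:
        correction = (len(AMINO_ACIDS) - 1) / (2.0 * np.log(2.0) * small_sample_n)
    ic = np.clip(MAX_IC_BITS - entropy - correction, 0.0, MAX_IC_BITS)
    # positions with no observed residues carry no information
    ic = np.where(p.sum(axis=1) > 0, ic, 0.0)
    information = pd.Series(ic, index=ppm.index)
    return LogoMatrix(
        probabilities=ppm,
        information=information,
        letter_heights=ppm.mul(information, axis=0),
        n_windows=0,
    )


def build_logo(windows: Sequence[str], small_sample_correction: bool = False) -> LogoMatrix:
    windows = list(windows)
    ppm = position_probability_matrix(windows)
    logo = information_logo(ppm, small_sample_n=len(windows) if small_sample_correction else None)
    return LogoMatrix(
        probabilities=logo.probabilities,
        information=logo.information,
        letter_heights=logo.letter_heights,
        n_windows=len(windows),
    )


def differential_logo(
    foreground_windows: Sequence[str],
    background_frequencies: Mapping[str, float],
) -> pd.DataFrame:
    """Background-corrected per-position residue enrichment.

    For each (position, residue) the foreground frequency p_fg over n
    windows is compared to the background frequency p_bg with
    z = (p_fg − p_bg) / sqrt(p_bg·(1−p_bg)/n) and a two-sided normal p.
    A residue absent from the background but present in the foreground gets
    an infinite-z sentinel and is flagged.
    """
    bg = pd.Series(background_frequencies, dtype=float).reindex(list(AMINO_ACIDS))
    if bg.isna().any():
        raise ValueError("background must cover all 20 amino acids")
    if abs(bg.sum() - 1.0) > 1e-6:
        raise ValueError(f"background frequencies must sum to 1, got {bg.sum():.6f}")
    windows = list(foreground_windows)
    if not windows:
        raise ValueError("at least one foreground window is required")
    ppm = position_probability_matrix(windows)
    n = len(windows)
    rows = []
    for pos in POSITIONS:
        for residue in AMINO_ACIDS:
            p_fg = float(ppm.loc[pos, residue])
            p_bg = float(bg[residue])
            flagged = False
            if p_bg in (0.0, 1.0):
                if p_fg == p_bg:
                    z = 0.0
                else:
                    z = np.inf if p_fg > p_bg else -np.inf
                    flagged = True
                p = 0.0 if flagged else 1.0
            else:
                z = (p_fg - p_bg) / np.sqrt(p_bg * (1.0 - p_bg) / n)
                p = float(2.0 * sps.norm.sf(abs(z)))
            rows.append(
                {"position": pos, "residue": residue, "p_fg": p_fg, "p_bg": p_bg,
                 "z": float(z), "p": p, "infinite_z": flagged}
            )
    return pd.DataFrame(rows)


def background_from_sequences(sequences: Iterable[str]) -> dict[str, float]:
    """Residue frequencies of a proteome, for differential-logo backgrounds."""
    counts = {aa: 0 for aa in AMINO_ACIDS}
    for seq in sequences:
        for residue in seq:
            if residue in counts:
                counts[residue] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequences contain no standard residues")
    return {aa: c / total for aa, c in counts.items()}


def acceptor_category_counts(profiles: Sequence[TimecourseProfile]) -> pd.DataFrame:
    """Timing-category × pSP/pTP contingency table of minimal-Cdk sites."""
    table = pd.DataFrame(0, index=list(TIMING_CATEGORIES), columns=["pTP", "pSP"])
    for p in profiles:
        for motif in ("pTP", "pSP"):
            if motif in p.motif_labels:
                table.loc[p.timing_category, motif] += 1
    return table


def ptp_fold_change(table: pd.DataFrame, cat_a: str = "early", cat_b: str = "late") -> float:
    """Fold change of the pTP proportion between two timing categories."""
    total_a = table.loc[cat_a].sum()
    total_b = table.loc[cat_b].sum()
    if total_a == 0 or total_b == 0:
        raise ValueError(f"both category rows must be non-empty (got {total_a}, {total_b})")
    ptp_a = table.loc[cat_a, "pTP"]
    if ptp_a == 0:
        raise ValueError(
            f"pTP proportion in {cat_a!r} is zero (counts: {table.loc[cat_a].to_dict()}); fold undefined"
        )
    return float((table.loc[cat_b, "pTP"] / total_b) / (ptp_a / total_a))


def chi2_late_vs_rest(
    table: pd.DataFrame,
    focal: str = "late",
    correction_factor: int = 4,
    yates: bool = False,
    categories: Sequence[str] | None = None,
) -> dict:
    """Pearson chi-square of the focal timing category against the pooled rest.

    Collapses the table to 2×2 (focal vs pooled others × pTP/pSP), computes
    the Pearson statistic (df = 1, no continuity correction by default) and
    Bonferroni-adjusts the p-value by ``correction_factor`` — one test per
    possible focal category. Falls back to Fisher's exact test when an
    expected count is zero.
    """
    rows = list(categories) if categories is not None else list(table.index)
    if focal not in rows:
        raise ValueError(f"focal category {focal!r} not among {rows}")
    rest = [r for r in rows if r != focal]
    a = int(table.loc[focal, "pTP"])
    b = int(table.loc[focal, "pSP"])
    c = int(table.loc[rest, "pTP"].sum())
    d = int(table.loc[rest, "pSP"].sum())
    try:
        chi2, p_raw = pearson_chi2_2x2(a, b, c, d, yates=yates)
        method = "pearson"
    except ValueError:
        _, p_raw = sps.fisher_exact([[a, b], [c, d]])
        chi2 = float("nan")
        method = "fisher_exact"
    return {
        "chi2": chi2,
        "df": 1,
        "p_raw": float(p_raw),
        "p_adjusted": float(min(1.0, correction_factor * p_raw)),
        "method": method,
        "table": {"focal_pTP": a, "focal_pSP": b, "rest_pTP": c, "rest_pSP": d},
    }


def logo_to_frame(logo: LogoMatrix) -> pd.DataFrame:
    """TSV-ready long view of a logo (position × residue heights)."""
    height = logo.letter_heights.stack()
    prob = logo.probabilities.stack()
    out = pd.DataFrame({"probability": prob, "height_bits": height})
    out.index.names = ["position", "residue"]
    return out.reset_index()


def render_logo(logo: LogoMatrix, path, title: str | None = None) -> None:
    """Minimal information-content logo rendering (stacked letters per position)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    for pos in logo.probabilities.index:
        heights = logo.letter_heights.loc[pos]
        bottom = 0.0
        for residue, h in heights.sort_values().items():
            if h <= 0:
                continue
            ax.text(pos, bottom + h / 2, residue, ha="center", va="center",
                    fontsize=6 + 16 * min(h / MAX_IC_BITS, 1.0), family="monospace")
            bottom += h
    ax.set_xlim(min(logo.probabilities.index) - 0.5, max(logo.probabilities.index) + 0.5)
    ax.set_ylim(0, MAX_IC_BITS)
    ax.set_xlabel("position relative to phosphoacceptor")
    ax.set_ylabel("bits")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
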
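"""Generative model of cell-cycle phosphosite data.

The model is a kinase-phosphatase steady-state equilibrium: each phosphosite
has a kinase efficiency ``k_kin`` and an effective dephosphorylation rate
``d_phos * P``; under Cdk activity ``C`` its phosphorylation occupancy is

    occupancy = k_kin * C / (k_kin * C + d_phos * P)

Cdk activity rises along the cell cycle as a logistic curve, so each site
crosses half-occupancy at a characteristic activity threshold
``C* = d_phos * P / k_kin``: the stronger the opposing phosphatase, the later
in the cycle the site becomes phosphorylated. The PP2A-Cdc55-like phosphatase
is modelled as a multiplicative ``cdc55_sensitivity`` factor on the basal
phosphatase rate that is biased toward threonine-acceptor Cdk sites; deleting
the phosphatase removes the multiplier (a basal rate always remains).

From the per-site occupancies the module produces the two study designs the
downstream analyses consume: heavy/light SILAC mixtures (forward, reverse and
same-strain control pairings across cell-cycle phases) and a 10-timepoint
course in which every sample is referenced against a metaphase spike-in.
Measurement noise is multiplicative log-normal on ratios; missingness is
uniform at random; all randomness derives from the config seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .motifs import annotate_motifs
from .site_tables import (
    INTENSITY_PREFIX,
    RATIO_PREFIX,
    extract_window,
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Budding-yeast proteome amino-acid frequencies (SwissProt composition,
# rounded); used both to draw synthetic protein sequences and as the default
# background for differential logos.
YEAST_AA_FREQS = {
    "A": 0.0551, "C": 0.0131, "D": 0.0582, "E": 0.0656, "F": 0.0441,
    "G": 0.0497, "H": 0.0217, "I": 0.0657, "K": 0.0734, "L": 0.0957,
    "M": 0.0207, "N": 0.0613, "P": 0.0438, "Q": 0.0393, "R": 0.0444,
    "S": 0.0900, "T": 0.0588, "V": 0.0556, "W": 0.0104, "Y": 0.0337,
}

GENOTYPES = ("wildtype", "phosphatase_null")

# Fixed minute mapping of the sampling phases onto the activity curve; the
# metaphase reference sits past the half-activation time.
PHASE_MINUTES = {"G1": 0.0, "S": 25.0, "G2": 50.0, "metaphase_reference": 90.0}


class UndefinedStateError(ValueError):
    """Occupancy is undefined when kinase and phosphatase flux are both zero."""


@dataclass(frozen=True)
class CdkCurve:
    """Logistic rise of Cdk activity with time (minutes)."""

    c0: float = 0.0
    cmax: float = 1.0
    t_half: float = 90.0
    tau: float = 12.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not self.cmax > self.c0 >= 0:
            raise ValueError("require cmax > c0 >= 0")


def cdk_activity(t, curve: CdkCurve):
    """Cdk activity C(t): logistic from ``c0`` to ``cmax``, midpoint ``t_half``."""
    t = np.asarray(t, dtype=float)
    value = curve.c0 + (curve.cmax - curve.c0) * expit((t - curve.t_half) / curve.tau)
    return value if value.ndim else float(value)


def steady_state_occupancy(k_kin, activity, d_phos, phosphatase=1.0):
    """Equilibrium phosphorylation occupancy k*C / (k*C + d*P)."""
    k = np.asarray(k_kin, dtype=float)
    c = np.asarray(activity, dtype=float)
    d = np.asarray(d_phos, dtype=float)
    p = np.asarray(phosphatase, dtype=float)
    if np.any(k <= 0) or np.any(d <= 0):
        raise ValueError("k_kin and d_phos must be > 0")
    if np.any(c < 0) or np.any(p < 0):
        raise ValueError("activity and phosphatase level must be >= 0")
    kin = k * c
    dep = d * p
    if np.any((kin == 0) & (dep == 0)):
        raise UndefinedStateError("no kinase activity and no phosphatase flux")
    value = kin / (kin + dep)
    return value if value.ndim else float(value)


def half_activation_threshold(k_kin, d_phos, phosphatase=1.0):
    """Cdk activity C* at which occupancy crosses one half: d*P/k."""
    k = np.asarray(k_kin, dtype=float)
    if np.any(k <= 0):
        raise ValueError("k_kin must be > 0")
    value = np.asarray(d_phos, dtype=float) * np.asarray(phosphatase, dtype=float) / k
    return value if value.ndim else float(value)


@dataclass(frozen=True)
class SiteKineticSpec:
    """Simulator ground truth for one phosphosite."""

    site_id: str
    protein_id: str
    position: int
    acceptor: str
    window: str
    motif_labels: frozenset[str]
    k_kin: float
    d_phos: float
    cdc55_sensitivity: float
    abundance: float

    def __post_init__(self) -> None:
        if self.acceptor not in ("S", "T"):
            raise ValueError("simulated acceptor must be S or T")
        if len(self.window) != 13 or self.window[6] != self.acceptor:
            raise ValueError("window must be a 13-mer centred on the acceptor")
        if not (self.k_kin > 0 and self.d_phos > 0 and self.abundance > 0):
            raise ValueError("k_kin, d_phos and abundance must be > 0")
        if not self.cdc55_sensitivity >= 1:
            raise ValueError("cdc55_sensitivity must be >= 1")

    def effective_d(self, genotype: str) -> float:
        """Dephosphorylation rate under a genotype.

        The wild type carries the acceptor-biased phosphatase, so its basal
        rate is multiplied by ``cdc55_sensitivity``; the phosphatase-null
        strain retains only the basal rate.
        """
        if genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {genotype!r}")
        return self.d_phos * (self.cdc55_sensitivity if genotype == "wildtype" else 1.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and model parameters of one simulated dataset.

    The kinetic priors place median half-activation thresholds low on the
    activity curve for serine Cdk sites and ``t_sensitivity_factor``-fold
    higher for threonine Cdk sites, so threonine-directed phosphorylation
    crosses its threshold later along the logistic activity rise.
    """

    n_sites: int = 2000
    fraction_threonine: float = 0.3
    fraction_cdk_motif: float = 0.2
    fraction_full_motif: float = 0.4
    t_sensitivity_factor: float = 4.0
    timepoints: tuple[float, ...] = (0, 10, 20, 30, 40, 50, 60, 70, 80, 90)
    cdk_curve: CdkCurve = field(default_factory=CdkCurve)
    noise_sd_log2: float = 0.525
    missing_rate: float = 0.05
    seed: int = 0
    # Kinetic priors (log-normal medians / log-sds). The defaults place the
    # median serine Cdk site's half-activation threshold low on the activity
    # curve (early crossing) and spread site thresholds ~e^2-fold around it,
    # so that threonine sites (thresholds raised t_sensitivity_factor-fold)
    # cross 10-20 min later and a tail of them is still rising at the end of
    # the sampled course.
    k_kin_median: float = 4000.0
    k_kin_log_sd: float = 1.0
    d_phos_median: float = 1.0
    d_phos_log_sd: float = 0.25
    sensitivity_log_sd: float = 0.25
    abundance_median: float = 1e6
    abundance_log_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("fraction_threonine", "fraction_cdk_motif", "fraction_full_motif", "missing_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        if self.t_sensitivity_factor < 1:
            raise ValueError("t_sensitivity_factor must be >= 1")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if len(self.timepoints) and list(self.timepoints) != sorted(set(self.timepoints)):
            raise ValueError("timepoints must be strictly increasing")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def phase_to_minutes(phase: str) -> float:
    if phase in PHASE_MINUTES:
        return PHASE_MINUTES[phase]
    if phase.startswith("timepoint:"):
        return float(phase.split(":", 1)[1])
    raise ValueError(f"unknown phase {phase!r}")


@dataclass(frozen=True)
class SilacMixture:
    """One heavy/light pairing and its measured per-site ratio vector."""

    mixture_id: str
    heavy_genotype: str
    light_genotype: str
    phase: str
    ratios: pd.Series  # index: site_id; NaN = missing

    @property
    def direction(self) -> str:
        if self.heavy_genotype == self.light_genotype:
            return "control"
        return "forward" if self.heavy_genotype == "phosphatase_null" else "reverse"


def _mixture_rng(config: SimulationConfig, label: str) -> np.random.Generator:
    # Stable per-output stream: same seed+config+label -> identical draws,
    # independent streams across outputs.
    return np.random.default_rng([config.seed, zlib.crc32(label.encode())])


def _draw_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    letters = np.array(list(YEAST_AA_FREQS))
    probs = np.array(list(YEAST_AA_FREQS.values()))
    probs = probs / probs.sum()
    return rng.choice(letters, size=length, p=probs)


def generate_site_panel(
    config: SimulationConfig, with_proteins: bool = False
) -> list[SiteKineticSpec] | tuple[list[SiteKineticSpec], dict[str, str]]:
    """Draw a panel of sites (and optionally their host protein sequences).

    Each site lives on its own synthetic protein so that windows, positions
    and the emitted FASTA stay mutually consistent, including end-of-sequence
    padding. Motif structure is engineered in: a ``fraction_cdk_motif`` share
    of sites receives a +1 proline, of which ``fraction_full_motif`` also get
    a basic +3 residue. Threonine Cdk sites draw their phosphatase
    sensitivity around ``t_sensitivity_factor``; all other sites keep a
    sensitivity of 1.
    """
    rng = _mixture_rng(config, "panel")
    panel: list[SiteKineticSpec] = []
    proteins: dict[str, str] = {}
    for i in range(config.n_sites):
        length = int(rng.integers(25, 81))
        seq = _draw_sequence(rng, length)
        acceptor = "T" if rng.random() < config.fraction_threonine else "S"
        is_cdk = rng.random() < config.fraction_cdk_motif
        is_full = is_cdk and rng.random() < config.fraction_full_motif
        position = int(rng.integers(1, length + 1))
        if is_full:
            position = min(position, length - 3)
        elif is_cdk:
            position = min(position, length - 1)
        position = max(position, 1)
        seq[position - 1] = acceptor
        if is_cdk:
            seq[position] = "P"
        if is_full:
            seq[position + 2] = "K" if rng.random() < 0.5 else "R"
        sequence = "".join(seq)
        protein_id = f"prot{i:05d}"
        window = extract_window(sequence, position)
        labels = annotate_motifs(window).labels

        k_kin = config.k_kin_median * np.exp(rng.normal(0.0, config.k_kin_log_sd))
        d_phos = config.d_phos_median * np.exp(rng.normal(0.0, config.d_phos_log_sd))
        if acceptor == "T" and "minimal_cdk" in labels and config.t_sensitivity_factor > 1:
            # log-normal with mean exactly t_sensitivity_factor
            s = config.sensitivity_log_sd
            sensitivity = float(
                np.exp(rng.normal(np.log(config.t_sensitivity_factor) - s * s / 2.0, s))
            )
            sensitivity = max(sensitivity, 1.0)
        else:
            sensitivity = 1.0
        abundance = config.abundance_median * np.exp(rng.normal(0.0, config.abundance_log_sd))

        proteins[protein_id] = sequence
        panel.append(
            SiteKineticSpec(
                site_id=f"site{i:05d}",
                protein_id=protein_id,
                position=position,
                acceptor=acceptor,
                window=window,
                motif_labels=labels,
                k_kin=float(k_kin),
                d_phos=float(d_phos),
                cdc55_sensitivity=sensitivity,
                abundance=float(abundance),
            )
        )
    return (panel, proteins) if with_proteins else panel


def _apply_noise_and_missingness(
    true_values: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    noise = rng.normal(0.0, config.noise_sd_log2, size=true_values.shape)
    measured = true_values * np.exp2(noise)
    if config.missing_rate > 0:
        measured = np.where(
            rng.random(true_values.shape) < config.missing_rate, np.nan, measured
        )
    return measured


def simulate_silac_mixture(
    panel: Sequence[SiteKineticSpec],
    heavy_genotype: str,
    light_genotype: str,
    phase: str,
    config: SimulationConfig,
    mixture_id: str | None = None,
) -> SilacMixture:
    """Simulate one SILAC mixture's measured heavy/light ratio vector.

    The true ratio is occupancy(heavy)/occupancy(light) at the phase's Cdk
    activity; control mixtures (same genotype in both channels) have a true
    ratio of exactly 1 for every site. Measurement noise multiplies the true
    ratio by 2^eps with eps ~ N(0, noise_sd_log2^2); measurements drop out
    independently at ``missing_rate``.
    """
    for g in (heavy_genotype, light_genotype):
        if g not in GENOTYPES:
            raise ValueError(f"unknown genotype {g!r}")
    minutes = phase_to_minutes(phase)
    activity = cdk_activity(minutes, config.cdk_curve)
    if mixture_id is None:
        mixture_id = f"{phase}_{heavy_genotype[:2]}H_{light_genotype[:2]}L"
    rng = _mixture_rng(config, f"silac:{mixture_id}")

    site_ids = [s.site_id for s in panel]
    if heavy_genotype == light_genotype:
        true_ratio = np.ones(len(panel))
    else:
        k = np.array([s.k_kin for s in panel])
        d_heavy = np.array([s.effective_d(heavy_genotype) for s in panel])
        d_light = np.array([s.effective_d(light_genotype) for s in panel])
        occ_heavy = steady_state_occupancy(k, activity, d_heavy)
        occ_light = steady_state_occupancy(k, activity, d_light)
        true_ratio = occ_heavy / occ_light
    measured = _apply_noise_and_missingness(true_ratio, config, rng)
    return SilacMixture(
        mixture_id=mixture_id,
        heavy_genotype=heavy_genotype,
        light_genotype=light_genotype,
        phase=phase,
        ratios=pd.Series(measured, index=pd.Index(site_ids, name="site_id")),
    )


def default_silac_design(phases: Sequence[str] = ("G1", "S", "G2")) -> list[dict]:
    """Forward, reverse and two same-strain control mixtures per phase.

    Mirrors a full-factorial SILAC design table: experimental mixtures pair
    the phosphatase-null strain against the wild type in both label
    orientations; the control mixtures on the table diagonal pair a strain
    against itself.
    """
    design = []
    for phase in phases:
        design.append(dict(heavy_genotype="phosphatase_null", light_genotype="wildtype",
                           phase=phase, mixture_id=f"{phase}_F"))
        design.append(dict(heavy_genotype="wildtype", light_genotype="phosphatase_null",
                           phase=phase, mixture_id=f"{phase}_R"))
        design.append(dict(heavy_genotype="wildtype", light_genotype="wildtype",
                           phase=phase, mixture_id=f"{phase}_Cwt"))
        design.append(dict(heavy_genotype="phosphatase_null", light_genotype="phosphatase_null",
                           phase=phase, mixture_id=f"{phase}_Cnull"))
    return design


def simulate_silac_study(
    panel: Sequence[SiteKineticSpec],
    config: SimulationConfig,
    design: Iterable[dict] | None = None,
) -> list[SilacMixture]:
    design = default_silac_design() if design is None else design
    return [simulate_silac_mixture(panel, config=config, **spec) for spec in design]


def simulate_timecourse(
    panel: Sequence[SiteKineticSpec], config: SimulationConfig
) -> pd.DataFrame:
    """Simulate the wild-type time course against a heavy metaphase reference.

    Every sample taken at time t is mixed with the same metaphase spike-in,
    so the stored value per site and timepoint is the light/heavy ratio
    occupancy(t)/occupancy(metaphase) times measurement noise. Higher
    half-activation thresholds translate into later half-maximum crossing
    along the rising activity curve.
    """
    if not len(config.timepoints):
        raise ValueError("timepoints must be non-empty")
    rng = _mixture_rng(config, "timecourse")
    times = np.asarray(config.timepoints, dtype=float)
    activity = cdk_activity(times, config.cdk_curve)
    ref_activity = cdk_activity(phase_to_minutes("metaphase_reference"), config.cdk_curve)

    k = np.array([s.k_kin for s in panel])[:, None]
    d = np.array([s.effective_d("wildtype") for s in panel])[:, None]
    occ = steady_state_occupancy(k, activity[None, :], d)
    occ_ref = steady_state_occupancy(k, ref_activity, d)
    true_traj = occ / occ_ref
    measured = _apply_noise_and_missingness(true_traj, config, rng)
    return pd.DataFrame(
        measured,
        index=pd.Index([s.site_id for s in panel], name="site_id"),
        columns=pd.Index([int(t) for t in times], name="timepoint"),
    )


def panel_truth_table(panel: Sequence[SiteKineticSpec]) -> pd.DataFrame:
    """Ground-truth table (kinetics + motif labels) for recovery tests."""
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in panel],
            "protein_id": [s.protein_id for s in panel],
            "acceptor": [s.acceptor for s in panel],
            "k_kin": [s.k_kin for s in panel],
            "d_phos": [s.d_phos for s in panel],
            "cdc55_sensitivity": [s.cdc55_sensitivity for s in panel],
            "abundance": [s.abundance for s in panel],
            "motif_labels": [";".join(sorted(s.motif_labels)) for s in panel],
        }
    ).set_index("site_id", drop=False)


def study_site_table(
    panel: Sequence[SiteKineticSpec],
    mixtures: Sequence[SilacMixture] = (),
    timecourse: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the wide phosphosite TSV table for a simulated study."""
    df = pd.DataFrame(
        {
            "site_id": [s.site_id for s in panel],
            "protein_id": [s.protein_id for s in panel],
            "position": [s.position for s in panel],
            "amino_acid": [s.acceptor for s in panel],
            "sequence_window": [s.window for s in panel],
            "localization_prob": 1.0,
        }
    ).set_index("site_id", drop=False)
    for mixture in mixtures:
        df[RATIO_PREFIX + mixture.mixture_id] = mixture.ratios
    if timecourse is not None:
        for t in timecourse.columns:
            df[f"{INTENSITY_PREFIX}{int(t)}"] = timecourse[t]
    return df
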
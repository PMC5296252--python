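"""End-to-end study orchestration: simulate → analyze → report.

Two composite runs mirror the study's two experimental arms:

* ``run_silac_study`` — forward/reverse/control SILAC mixtures across the
  G1/S/G2 phases, ratio normalization and orientation, 2-fold selection,
  control calibration, per-phase 2D annotation enrichment and logos of
  enriched vs unchanged Cdk sites.
* ``run_timecourse_study`` — the 10-timepoint course against a metaphase
  reference, coverage filtering, 90-min normalization, timing
  classification, category-average profiles, the pSP/pTP peak lag and the
  late-versus-rest contingency test.

All randomness flows from the config seed; identical configs give
byte-identical output tables.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment, logos, motifs, silac, simulate, timecourse

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    fold_threshold: float = 2.0
    alpha: float = 0.02
    ref_time: float = 90.0
    min_present: int = 8
    chi2_correction_factor: int = 4
    peak_lag_rel_tol: float = 0.2
    motif_registry: dict | None = None


@dataclass(frozen=True)
class RunConfig:
    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulation.seed != self.seed:
            object.__setattr__(self, "simulation", self.simulation.with_seed(self.seed))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_kwargs = dict(raw.get("simulation", {}))
        if "cdk_curve" in sim_kwargs:
            sim_kwargs["cdk_curve"] = simulate.CdkCurve(**sim_kwargs["cdk_curve"])
        if "timepoints" in sim_kwargs:
            sim_kwargs["timepoints"] = tuple(sim_kwargs["timepoints"])
        return cls(
            simulation=simulate.SimulationConfig(**sim_kwargs),
            analysis=AnalysisConfig(**raw.get("analysis", {})),
            output_dir=raw.get("output_dir"),
            seed=int(raw.get("seed", sim_kwargs.get("seed", 0))),
        )

    def config_hash(self) -> str:
        payload = repr((asdict_safe(self.simulation), asdict(self.analysis), self.seed))
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def asdict_safe(obj):
    d = asdict(obj)
    return {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# phosphocycle seed={config.seed} config_hash={config.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=index)
    logger.info("wrote %s (%d rows)", path, len(df))


def motif_categories(
    windows: dict[str, str], registry: dict | None = None
) -> dict[str, set[str]]:
    """Site-id membership of every registry motif, from sequence windows."""
    registry = registry or motifs.DEFAULT_MOTIF_REGISTRY
    categories: dict[str, set[str]] = {name: set() for name in registry}
    for site_id, window in windows.items():
        for label in motifs.annotate_motifs(window, registry).labels:
            categories[label].add(site_id)
    return categories


def run_silac_study(config: RunConfig) -> dict:
    """Simulate and analyze the phosphatase-null vs wild-type SILAC arm."""
    sim = config.simulation
    panel, proteins = simulate.generate_site_panel(sim, with_proteins=True)
    mixtures = simulate.simulate_silac_study(panel, sim)
    by_id = {m.mixture_id: m for m in mixtures}
    windows = {s.site_id: s.window for s in panel}
    categories = motif_categories(windows, config.analysis.motif_registry)

    controls = [m for m in mixtures if m.direction == "control"]
    control_calibration = silac.calibrate_control(controls, fold=config.analysis.fold_threshold)
    logger.info(
        "control calibration: %.1f%% within %.0f-fold (n=%d), implied FDR %.3f",
        100 * control_calibration["fraction_within_fold"],
        config.analysis.fold_threshold,
        control_calibration["n"],
        control_calibration["implied_fdr"],
    )

    phases = sorted({m.phase for m in mixtures}, key=simulate.phase_to_minutes)
    pairs_by_phase: dict[str, pd.DataFrame] = {}
    enriched_by_phase: dict[str, pd.Index] = {}
    enrichment_by_phase: dict[str, pd.DataFrame] = {}
    for phase in phases:
        pairs = silac.build_oriented_pairs(
            by_id[f"{phase}_F"], by_id[f"{phase}_R"], config.analysis.fold_threshold
        )
        pairs_by_phase[phase] = pairs
        enriched_by_phase[phase] = silac.select_enriched(pairs, config.analysis.fold_threshold)
        results = enrichment.enrich_2d(
            pairs["log2_fc_forward"],
            pairs["log2_fc_reverse"],
            categories,
            alpha=config.analysis.alpha,
        )
        enrichment_by_phase[phase] = enrichment.results_to_frame(results)
        logger.info(
            "phase %s: %d sites paired, %d enriched >%.0f-fold in both repeats",
            phase, int(pairs[["log2_fc_forward", "log2_fc_reverse"]].dropna().shape[0]),
            len(enriched_by_phase[phase]), config.analysis.fold_threshold,
        )

    # Logos: minimal-Cdk sites enriched in any phase vs those never enriched.
    cdk_ids = categories["minimal_cdk"]
    enriched_ids = set().union(*(set(ix) for ix in enriched_by_phase.values()))
    enriched_cdk = sorted(cdk_ids & enriched_ids)
    unchanged_cdk = sorted(cdk_ids - enriched_ids)
    logo_enriched = logos.build_logo([windows[s] for s in enriched_cdk]) if enriched_cdk else None
    logo_unchanged = logos.build_logo([windows[s] for s in unchanged_cdk]) if unchanged_cdk else None
    background = logos.background_from_sequences(proteins.values())

    site_table = simulate.study_site_table(panel, mixtures)
    results = {
        "panel": panel,
        "proteins": proteins,
        "mixtures": mixtures,
        "site_table": site_table,
        "categories": categories,
        "control_calibration": control_calibration,
        "pairs_by_phase": pairs_by_phase,
        "enriched_by_phase": enriched_by_phase,
        "enrichment_by_phase": enrichment_by_phase,
        "logo_enriched": logo_enriched,
        "logo_unchanged": logo_unchanged,
        "background_frequencies": background,
    }
    if config.output_dir:
        out = Path(config.output_dir)
        _write_table(site_table, out / "silac_site_table.tsv", config)
        _write_table(simulate.panel_truth_table(panel), out / "silac_ground_truth.tsv", config)
        _write_table(
            pd.DataFrame([control_calibration]), out / "control_calibration.tsv", config
        )
        for phase, pairs in pairs_by_phase.items():
            _write_table(pairs, out / f"pairs_{phase}.tsv", config, index=True)
            _write_table(enrichment_by_phase[phase], out / f"enrichment_2d_{phase}.tsv", config)
        if logo_enriched:
            _write_table(logos.logo_to_frame(logo_enriched), out / "logo_enriched.tsv", config)
        if logo_unchanged:
            _write_table(logos.logo_to_frame(logo_unchanged), out / "logo_unchanged.tsv", config)
    return results


def run_timecourse_study(config: RunConfig) -> dict:
    """Simulate and analyze the 10-timepoint cell-cycle arm."""
    sim = config.simulation
    panel, proteins = simulate.generate_site_panel(sim, with_proteins=True)
    intensities = simulate.simulate_timecourse(panel, sim)
    annotations = {s.site_id: s.motif_labels for s in panel}
    acceptors = {s.site_id: s.acceptor for s in panel}

    profiles = timecourse.analyze_timecourse_table(
        intensities,
        annotations=annotations,
        acceptors=acceptors,
        min_present=config.analysis.min_present,
        n_timepoints=len(sim.timepoints),
        ref_time=config.analysis.ref_time,
    )
    logger.info("timecourse: %d of %d sites pass the coverage filter",
                len(profiles), len(panel))

    increasing = [p for p in profiles if p.increasing]

    def is_increasing_motif(motif):
        return lambda p: p.increasing and motif in p.motif_labels

    avg_psp, n_psp = timecourse.average_category_profile(profiles, is_increasing_motif("pSP"))
    avg_ptp, n_ptp = timecourse.average_category_profile(profiles, is_increasing_motif("pTP"))
    lag = timecourse.peak_lag(avg_psp, avg_ptp, rel_tol=config.analysis.peak_lag_rel_tol)
    logger.info("average pTP profile peaks %.0f min after the average pSP profile", lag)

    category_averages = {}
    for category in timecourse.TIMING_CATEGORIES:
        members = [p for p in profiles if p.timing_category == category
                   and "minimal_cdk" in p.motif_labels]
        if members:
            category_averages[category] = timecourse.average_category_profile(
                profiles,
                lambda p, c=category: p.timing_category == c and "minimal_cdk" in p.motif_labels,
            )[0]

    table = logos.acceptor_category_counts(profiles)
    chi2 = logos.chi2_late_vs_rest(
        table, correction_factor=config.analysis.chi2_correction_factor
    )
    try:
        fold = logos.ptp_fold_change(table)
    except ValueError:
        fold = float("nan")
    logger.info("late-vs-rest chi2=%.2f, adjusted p=%.2g; early-to-late pTP fold %.2f",
                chi2["chi2"], chi2["p_adjusted"], fold)

    windows = {s.site_id: s.window for s in panel}
    category_logos = {}
    for category in timecourse.TIMING_CATEGORIES:
        member_windows = [
            windows[p.site_id]
            for p in profiles
            if p.timing_category == category and "minimal_cdk" in p.motif_labels
        ]
        if member_windows:
            category_logos[category] = logos.build_logo(member_windows)

    profile_frame = timecourse.profiles_to_frame(profiles)
    results = {
        "panel": panel,
        "proteins": proteins,
        "intensities": intensities,
        "profiles": profiles,
        "profile_frame": profile_frame,
        "n_increasing": len(increasing),
        "average_pSP": avg_psp,
        "average_pTP": avg_ptp,
        "peak_lag": lag,
        "category_averages": category_averages,
        "acceptor_category_table": table,
        "chi2_late_vs_rest": chi2,
        "ptp_fold_change": fold,
        "category_logos": category_logos,
    }
    if config.output_dir:
        out = Path(config.output_dir)
        _write_table(simulate.study_site_table(panel, timecourse=intensities),
                     out / "timecourse_site_table.tsv", config)
        _write_table(profile_frame, out / "timecourse_profiles.tsv", config)
        _write_table(table.rename_axis("timing_category").reset_index(),
                     out / "acceptor_category_counts.tsv", config)
        summary = pd.DataFrame([{**chi2["table"], "chi2": chi2["chi2"],
                                 "p_raw": chi2["p_raw"], "p_adjusted": chi2["p_adjusted"],
                                 "peak_lag_min": lag, "ptp_fold_change": fold}])
        _write_table(summary, out / "timecourse_summary.tsv", config)
        averages = pd.DataFrame({"pSP": avg_psp, "pTP": avg_ptp})
        for category, avg in category_averages.items():
            averages[category] = avg
        _write_table(averages.rename_axis("timepoint").reset_index(),
                     out / "category_average_profiles.tsv", config)
    return results
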
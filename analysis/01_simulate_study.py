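#!/usr/bin/env python
"""Generate the seeded synthetic study both analysis arms consume.

Draws a 2000-site phosphoproteome panel from the kinase-phosphatase
equilibrium model, simulates the 12-mixture SILAC design (forward/reverse/
two controls in G1, S and G2) and the 10-timepoint course against a
metaphase reference, and writes the site table, the ground-truth kinetics
and the synthetic proteome FASTA under results/simulated/.
"""

from pathlib import Path

from phosphocycle import simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = simulate.SimulationConfig(seed=SEED)
    panel, proteins = simulate.generate_site_panel(config, with_proteins=True)
    mixtures = simulate.simulate_silac_study(panel, config)
    intensities = simulate.simulate_timecourse(panel, config)

    table = simulate.study_site_table(panel, mixtures, intensities)
    table.to_csv(OUT / "site_table.tsv", sep="\t", index=False)
    simulate.panel_truth_table(panel).to_csv(OUT / "ground_truth.tsv", sep="\t", index=False)

    from phosphocycle.site_tables import write_fasta

    write_fasta(proteins, OUT / "proteome.fasta")

    n_cdk = sum("minimal_cdk" in s.motif_labels for s in panel)
    n_ptp = sum("pTP" in s.motif_labels for s in panel)
    print(f"simulated {len(panel)} phosphosites on {len(proteins)} proteins (seed {SEED})")
    print(f"  {n_cdk} minimal-Cdk sites, of which {n_ptp} pTP")
    print(f"  {len(mixtures)} SILAC mixtures, {intensities.shape[1]} timepoints")
    print(f"  wrote {OUT}/site_table.tsv, ground_truth.tsv, proteome.fasta")


if __name__ == "__main__":
    main()
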
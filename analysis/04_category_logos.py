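#!/usr/bin/env python
"""Sequence logos of phosphatase-regulated vs unchanged Cdk sites.

Builds information-content logos of the minimal-Cdk sites enriched >2-fold
in the absence of the phosphatase versus those unchanged, plus a
background-corrected differential logo against the synthetic proteome's
residue frequencies. The enriched logo is expected to be threonine-biased at
the acceptor with the +1 proline fixed by the consensus. Outputs under
results/logos/.
"""

from pathlib import Path

from phosphocycle import logos
from phosphocycle.pipeline import RunConfig, run_silac_study

OUT = Path(__file__).resolve().parent.parent / "results" / "logos"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    results = run_silac_study(RunConfig(seed=SEED))

    windows = {s.site_id: s.window for s in results["panel"]}
    cdk_ids = results["categories"]["minimal_cdk"]
    enriched_ids = set().union(*(set(ix) for ix in results["enriched_by_phase"].values()))

    for name, ids in (("enriched", cdk_ids & enriched_ids),
                      ("unchanged", cdk_ids - enriched_ids)):
        logo = logos.build_logo([windows[s] for s in sorted(ids)])
        logos.logo_to_frame(logo).to_csv(OUT / f"logo_{name}.tsv", sep="\t", index=False)
        logos.render_logo(logo, OUT / f"logo_{name}.svg", title=f"{name} Cdk sites (n={logo.n_windows})")
        t_prob = logo.probabilities.loc[0, "T"]
        print(f"{name} Cdk sites: n={logo.n_windows}, acceptor pT share {t_prob:.2f}, "
              f"+1 P information {logo.information.loc[1]:.2f} bits")

    diff = logos.differential_logo(
        [windows[s] for s in sorted(cdk_ids & enriched_ids)],
        results["background_frequencies"],
    )
    diff.to_csv(OUT / "differential_logo.tsv", sep="\t", index=False)
    top = diff[(diff["p"] < 0.01) & (diff["z"] > 0)].nlargest(5, "z")
    print("top background-corrected enrichments (position, residue, z):")
    for r in top.itertuples():
        print(f"  {r.position:+d} {r.residue} z={r.z:.1f}")
    print(f"wrote logo matrices and SVGs to {OUT}")


if __name__ == "__main__":
    main()
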
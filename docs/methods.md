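# Methods

## The equilibrium model

Every phosphosite is described by a kinase efficiency `k > 0`, a basal
phosphatase rate `d > 0`, and a phosphatase-sensitivity multiplier `f ≥ 1`
applied to `d` when the threonine-directed PP2A^Cdc55^-like phosphatase is
present. Under Cdk activity `C ≥ 0` the site's phosphorylation occupancy is
the steady state of a two-state phosphorylation/dephosphorylation cycle
with linear (non-saturating) rates:

    occ(C) = k·C / (k·C + d·P),    C* = d·P / k

`C*` is the half-activation threshold: occupancy crosses 1/2 exactly when
`C = C*`, rises monotonically in `C` and falls monotonically in the
phosphatase level `P`. The linear-rate form is the simplest equilibrium
consistent with the threshold picture; saturable (Michaelis-type) kinetics
would change the shape but not the ordering by `C*`, and are deliberately
out of scope.

Cdk activity follows a four-parameter logistic in time,
`C(t) = c0 + (cmax − c0)·σ((t − t_half)/τ)`, chosen because it is smooth,
strictly monotone and analytically invertible, which gives closed-form
half-maximum crossing times for oracle tests. Phosphatase deletion is
modelled by *removing the multiplier f* (not by setting `P = 0`), so a
residual basal phosphatase always remains and occupancies stay well
defined.

Genotype–phase designs map onto this model as:

* SILAC mixture at phase p: true heavy/light ratio per site =
  `occ_heavy(C(t_p)) / occ_light(C(t_p))`, with the wild type using `d·f`
  and the phosphatase-null strain `d`. Same-strain controls therefore have
  a true ratio of exactly 1 everywhere.
* Time course: wild-type samples at t = 0, 10, …, 90 min, each referenced
  against one metaphase sample, giving `occ(t)/occ(t_meta)` per site and
  timepoint.

Phases are fixed minutes on the activity curve: G1 = 0, S = 25, G2 = 50,
metaphase reference = 90.

## Measurement model

Measured ratios are `true × 2^ε` with `ε ~ N(0, σ²)`, independent per
measurement, and each measurement is missing independently with probability
`missing_rate` (default 0.05). The default `σ = 0.525` is calibrated so
that a same-strain control mixture shows ~94.3% of sites within 2-fold of
unity (`2·Φ(1/0.525) − 1 = 0.943`), the reproducibility level the analysis
assumes when using a 2-fold change as selection criterion. Ratios are
median-log2-centred per mixture before analysis, emulating normalized
heavy/light ratios; missing values are excluded from every statistic, never
imputed.

## Generator defaults and calibration

| parameter | default | rationale |
|---|---|---|
| `n_sites` | 2000 | ~400 pSP/pTP sites enter the time-course tables, the scale of a deep phosphoproteome run |
| `fraction_threonine` | 0.30 | pTP share among classified Cdk sites in deep yeast data is ~1/4–1/3 |
| `fraction_cdk_motif` | 0.20 | ~900 of 4600 quantified sites carry the minimal consensus |
| `fraction_full_motif` | 0.40 | share of Cdk sites with the +3 K/R of the full consensus |
| `t_sensitivity_factor` | 4 | mean phosphatase-sensitivity multiplier of pT Cdk sites (log-normal, mean exactly 4); pS sites keep f = 1 |
| `cdk_curve` | c0=0, cmax=1, t_half=90, tau=12 | activity still rising through the sampled 0–90 min window, midpoint at the metaphase reference — Cdk activity is maximal at metaphase, so the sampled course covers the rising flank |
| `k_kin_median`, `k_kin_log_sd` | 4000, 1.0 | places the median pS threshold low on the curve (early crossing) with an e²-fold site-to-site spread — kinase efficiencies for Cdk substrates vary over orders of magnitude |
| `d_phos_median`, `d_phos_log_sd` | 1.0, 0.25 | basal phosphatase rate; mild spread |
| `noise_sd_log2` | 0.525 | control calibration above |

With these values the thresholds of pT full-Cdk sites cross the activity
curve `τ·ln f ≈ 17` minutes after matched pS sites (the logistic inverse is
linear in `ln C*` on its rising flank), which is what produces the 10–20
min lag between the average pTP and pSP trajectories and the
threonine-biased enrichment in the phosphatase-null comparison. This is a
calibration of the generator to the study conditions it emulates, stated
openly as such, not a discovered result.

One consequence of the calibrated kinetics: by G2 (t = 50) most Cdk sites
are saturated under both genotypes, so the phosphatase contrast in the
SILAC arm is largest in G1 and weakens through S and G2 — in the model the
phosphatase sets *when* a site switches, and once Cdk activity is far above
`C*` removing the phosphatase changes little.

## Analysis rules

* **Selection** — a site is phosphatase-regulated when its oriented log2
  fold change (forward: `log2 ratio`; reverse: `−log2 ratio`) exceeds
  `log2(2)` in *both* inverse-label repeats (the upper-left-quadrant rule of
  an inverse-labeling scatter). A single-repeat variant exists behind
  `select_enriched_single`. The implied FDR reported from controls is
  one-sided, matching the one-directional selection.
* **Enrichment** — categories are scored as
  `s = 2·(mean rank in − mean rank out)/N`, which is +1/−1 exactly when the
  category occupies the largest/smallest values and has null expectation 0.
  The Mann–Whitney test is exact by enumeration of rank assignments
  (valid under ties) while `C(N, min(n, m)) ≤ 2·10⁵`, and otherwise uses the
  normal approximation with tie and continuity corrections. The full
  exhaustive enumeration becomes combinatorially infeasible long before
  N = 200 when both groups are large, hence the subset-count gate.
  Benjamini–Hochberg runs across categories per dimension; 2D significance
  requires both adjusted p-values below α = 0.02 (an OR variant is a flag).
* **Time course** — profiles are kept with ≥ 8 of 10 timepoints, normalized
  to the 90-min value (sites with a missing or zero reference are dropped
  and logged), called increasing when max/first-covered > 2, and classified
  by the timepoint of their maximum: early 10–30, intermediate 40–60, late
  70–90 min; non-increasing sites and increasing sites peaking at t = 0 are
  stable. Ties in the maximum break to the *earliest* timepoint, which
  biases against "late" and is therefore conservative for the
  threonine-late conclusion. Classification is invariant under global
  rescaling of a profile.
* **Peak lag of averaged profiles** — a strictly monotone mean trajectory
  attains its maximum at the last timepoint by construction, so the peak
  time of an *average* profile extends the earliest-tie-break rule with a
  relative plateau tolerance: the earliest timepoint within 20% of the
  maximum. The 20% default places the crossing on the steep flank of the
  mean curve, where it is insensitive to the ~3–5% residual noise of a
  ~100-site average; per-site classification keeps the exact-argmax rule.
* **Contingency** — timing categories are cross-tabulated against pTP/pSP
  for minimal-Cdk sites; the focal category (late) is tested against the
  pooled rest with a Pearson chi-square (df = 1, no Yates correction, which
  matches the closed 2×2 form `n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`) and
  Bonferroni-corrected by factor 4 for the four possible focal categories.
  A Fisher-exact fallback handles zero expected counts.
* **Logos** — position probability matrices exclude the `_` padding from
  each position's denominator; information content is `log2 20 − H` bits
  with letter heights `p·IC`; the small-sample correction is off by default.
  Differential logos test per-(position, residue) foreground frequencies
  against background frequencies (by default computed from the supplied
  proteome, a species-aware background) with
  `z = (p_fg − p_bg)/√(p_bg(1−p_bg)/n)`; a residue absent from the
  background but present in the foreground yields an infinite-z sentinel
  and a flag rather than an error.
* **Motifs** — the registry is data-driven (name → acceptors + per-offset
  allowed residues). The Aurora consensus is operationalized as basic
  residues at −2 and −3 ([R/K]-[R/K]-x-S/T), a widely used definition kept
  behind the registry so an alternative is one config edit. The full-Cdk
  rule reads the +3 position literally (K or R at +3 exactly). Motifs see
  only the unmodified window; padding never matches.

## What the simulator does and does not emulate

It reproduces: the heavy/light ratio structure of forward/reverse/control
mixtures with a true-ratio of 1 in controls; calibrated multiplicative
noise and missingness; threshold-ordered, monotone phosphorylation
trajectories referenced to metaphase; motif-structured sequence windows on
synthetic proteins consistent with the emitted FASTA; and a
threonine-biased phosphatase effect of known ground truth, enabling
recovery tests.

It does not emulate: trajectories that *decline* after their peak
(dephosphorylation or degradation after mitotic commitment) — model
occupancancies only rise, so a site's observed peak time sits on a
noise-dominated plateau rather than at a true interior maximum;
protein-abundance changes under the phosphosites; correlated (peptide- or
run-level) measurement error; localization ambiguity between neighbouring
acceptors. Passing recovery tests therefore demonstrates that the inference
stack detects threshold-ordered, threonine-biased regulation under
realistic noise — not that it would resolve every timing structure present
in real data. The most visible consequence: per-site timing categories are
substantially noisier than in real data whose profiles rise *and fall*, so
the late-versus-rest chi-square at 2000 simulated sites recovers the
correct direction in essentially every run but reaches Bonferroni-adjusted
significance in only ~3/4 of seeds. The peak-lag of averaged profiles,
which pools sites before estimating timing, is robust (10–20 min in ~95% of
seeds).

## Degenerate inputs and numerical conventions

Empty ratio vectors, all-missing profiles, categories covering none or all
sites, zero chi-square margins and non-positive ratios raise typed errors
(or, for categories, are skipped with a logged warning). Determinism: every
random draw derives from the config seed plus a stable per-output label, so
identical configs give byte-identical tables regardless of the order in
which outputs are generated; output TSVs carry a `# phosphocycle seed=…
config_hash=…` header line.
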
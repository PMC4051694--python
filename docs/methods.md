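# Methods

## Scope and model

`dielprot` implements the quantitative core of a diel-cycle (12 h light /
12 h dark) shotgun-proteomics study in a cyanobacterium: acceptance
filtering of peptide-spectrum matches (PSMs), target-decoy FDR estimation,
protein inference and emPAI ranking, multi-fraction coverage accounting,
ICPL light/heavy differential quantification with a one-sample
significance test on log ratios, and spectrophotometric pigment
quantitation. Search engines, raw-spectrum processing and wet-lab
protocols are out of scope: PSM tables and XIC traces are inputs, either
supplied by the user or produced by the synthetic generator.

## Identification

**Digestion.** Trypsin cleaves C-terminal to K/R except before proline.
Products with 0..`max_missed` (default 1) internal missed cleavages are
enumerated; monoisotopic masses come from `pyteomics.mass.fast_mass`.
Repeated identical products of one protein are collapsed to one peptide
species.

**PSM acceptance.** Accept if score > 50; accept if 25 < score ≤ 50 and
the spectrum shows ≥ 4 consecutive y- or b-type ions; reject otherwise.
Both score boundaries are strict. The consecutive-ion rule is the
machine-checkable encoding of manual spectrum inspection; genuinely manual
curation is represented only as an input flag, never performed.

**Decoy FDR.** Default formula is 100·D/T among accepted PSMs (the decoy
report convention of the search engine this models); the alternative
100·2D/(T+D) is available as `formula="doubled"`. Zero accepted targets is
an error, not 0%.

**Protein inference.** Shared peptides count toward every matching
protein; proteins with identical accepted-peptide sets are merged into one
group (reported once, ids sorted). How shared peptides should be
apportioned between homologs is genuinely underdetermined; this
indistinguishability-merge is a declared design choice. Single-peptide
proteins are kept but flagged.

**emPAI.** 10^(N_observed/N_observable) − 1, with observable peptides
defined as distinct tryptic peptides (≤ max_missed) whose doubly-protonated
m/z lies in the configured scan window (default 300–1500 m/z). For a merged
group the representative (lexicographically first) sequence defines
N_observable.

**Coverage.** `aggregate_methods` enumerates all 2^k − 1 disjoint Venn
regions from per-protein membership, so regions are non-negative and sum
to the union by construction; coverage = union / theoretical proteome
size.

## ICPL quantification

**Orientation.** The heavy (13C-nicotinoyl) label marks the light-phase
culture and the light label the dark-phase culture, so every reported
ratio is light-phase/dark-phase. Label sites per peptide = lysine count +
1 (N-terminus), the post-digest ICPL chemistry; the per-site mass delta is
fixed at 6.0201 Da (six 13C–12C substitutions).

**Pairing and integration.** A light/heavy pair is accepted when the
Pearson correlation of the two traces on their overlapping grid is ≥ 0.8
(fewer than 3 overlapping points, or a zero-variance trace, is a coded
rejection). The integration window is at most 7 scans centered on the
joint apex — "max XIC width: 7" read as a scan count — with flanking
points below 0.2 × the apex intensity trimmed ("XIC threshold" read as an
apex fraction); if trimming leaves fewer than 3 points the untrimmed
window is integrated. A Distiller "quality: fraction" parameter exists in
the modeled software but is not interpretable from available descriptions
and is not implemented. Areas use composite Simpson's rule
(`scipy.integrate.simpson`); an even point count is closed with a
trapezoid on the final interval. Peptides need ion score strictly above 30
and two nonzero areas.

**Normalization and rollup.** Raw ratios are divided by the run
(replicate) median. Per protein and replicate, x̄ and s are the mean and
SD (N−1 denominator, matching the N−1 df of the test) of the natural-log
normalized ratios; ratio = exp(x̄), geometric SD = exp(s). Significance vs
unity: N ≥ 2 and |x̄| > t·s/√N with t the two-sided 95% Student critical
value at N−1 df. The test is base-invariant: log10 and ln give identical
decisions (property-tested).

**Replicates and retention.** Replicates combine in log space: combined
ratio = exp(mean of per-replicate x̄), combined geometric SD = exp(SD of
those x̄). A protein is retained as differentially abundant when it is
quantified with ≥ 2 peptides in every replicate and, in at least one
replicate, is simultaneously significant and beyond a threshold
(ratio ≥ 1.25 or ≤ 0.8, inclusive). A stricter variant that applies the
thresholds to the combined ratio is available
(`rule="strict_average"`); the default any-replicate rule is the one that
reproduces every row of the published 30-protein reference table, whereas
the strict-average reading would not (several rows sit inside the band in
one replicate). Threshold inclusivity is not exercised by that table —
boundary rows qualify via their other replicate — so it is a documented
convention, not an empirically pinned one. Direction is up when the
combined ratio exceeds 1.

**Reference table.** The package ships the published per-replicate ratio
table (30 proteins × 2 replicates: ratio, geometric SD, peptide count,
printed significance marking) as plain TSV. `summaries_from_table` takes
the printed significance flags as given; `significant_from_stats`
re-evaluates the inequality from the printed (ratio, SDgeo, N) so
disagreements between printed marking and recomputation are reported, not
overwritten — one CP43 replicate is known to be internally inconsistent
with its printed values, and two geometric-SD cells were not printed (NA).

## Pigments

Phycocyanin from phosphate-buffer extracts: PC = (A615 − 0.474·A652)/5.34
mg/mL per cm path (Bennett–Bogorad constants; overridable arguments, since
fidelity of the constants to any individual lab's usage cannot be
confirmed). Chlorophyll a in 100% methanol: A665/74.5 mg/mL per cm. Both
are linear in absorbance; negative computed concentrations are flagged,
never clipped, to preserve auditability.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
exercised. One `numpy` Generator seeded from `SimConfig.seed` drives
everything, so a fixed seed gives bit-identical datasets.

- **Proteome**: `n_proteins` (default 200 — desk scale; a real
  cyanobacterial theoretical proteome is ~6000) random sequences over the
  20 standard residues, lengths ~ Normal(300, 90) truncated at 30. Copy
  numbers are lognormal(μ=8, σ=1.5).
- **Fold changes**: `fold_change_spec` assigns true light/dark ratios by
  largest-remainder apportionment then random permutation; default 80%
  unchanged, 10% at 2.0, 10% at 0.5 — a null-dominated design comparable
  in spirit to a study where 30 of 185 quantified proteins changed.
- **Detection**: a protein's detectability score s is a logistic function
  of its abundance quantile; method m with nominal probability p detects
  each peptide with p^(1/s). This preserves certainty (p = 1 stays 1 for
  every protein) while making abundant proteins visible to more methods,
  reproducing the qualitative dominance of abundant proteins in real
  inventories and the Venn structure between workflows. Defaults:
  IEF 0.30, SDS-PAGE 0.30, 2D-LC 0.60, 3D-LC 0.50; ICPL quantification
  runs use 0.60.
- **Scores**: correct matches ~ Normal(85, 20) (match score) and
  Normal(45, 12) (ion score), clipped positive; decoys draw from the null
  component only, Normal(20, 8) / Normal(10, 5), with Poisson(1)
  consecutive ions against Poisson(8) for targets. After T target PSMs,
  D ~ Binomial(T, r/(1−r)) decoys are injected so the decoy fraction
  converges to the configured rate r (default 0.01).
- **XIC pairs**: each quantifiable peptide gets two Gaussian peaks with
  shared center and width (2 scans) on a uniform grid (default 1
  unit/scan, 21 points); the heavy:light area ratio is the protein's true
  ratio × exp(Normal(0, σ)) with σ = `peptide_ratio_noise_sigma`
  (default 0.25 — chosen so the induced per-protein geometric SDs fall in
  the 1.05–1.8 range typical of printed ICPL tables; no published noise
  magnitude exists to adopt). Heavy mass = light mass + 6.0201 × label
  sites (metadata). Peptide sequences shared between proteins are
  ambiguous for quantification and are emitted once.

What the generator does **not** emulate: fragment spectra, isotope
envelopes, charge states, retention-time drift between replicates,
chimeric/co-eluting interference, missing-not-at-random dropout, or
correlated peptide noise within a protein. Passing tests therefore
demonstrate the correctness of the arithmetic and the calibration of the
significance test under idealized lognormal noise, not robustness to the
full pathology of real LC-MS data.

## Numerical choices and problem sizes

- Student critical values from `scipy.stats.t.ppf`; N = 1 records carry
  s = 0 (geometric SD 1) and are never significant.
- emPAI ranking ties break by protein id, lexicographically.
- Median normalization leaves the run median exactly 1 for odd run sizes
  and 1 by midpoint construction for even ones.
- Fold-change histograms use octave (powers-of-2) bins, lower-edge
  inclusive, extended one bin past the maximum.
- Statistical property checks run at the sizes where their guarantees are
  sharp and cheap: 10^4 proteins for the 5% ± 1% type-I calibration, 500
  proteins × 8 peptides for twofold-ratio recovery, ≥ 10^4 PSMs for decoy
  rate recovery (binomial 95% CI). These sizes are the package's test
  design, chosen to keep the full suite in tens of seconds on one core.

## Known limitations

- Protein grouping ignores subset relationships (a protein whose peptides
  are a strict subset of another's stays a separate group).
- `n_observable` of a merged group uses the representative sequence only.
- The XIC windowing is defined on scan indices, so very asymmetric peaks
  can lose tail area; real Distiller peak detection is not reproduced.
- The pipeline assumes one PSM per detected peptide per method; spectral
  counting beyond distinct-peptide counts is not modeled.
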
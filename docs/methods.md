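# Methods

This note documents the models, conventions and numerical choices behind
`chromtx`, and what the synthetic benchmark does and does not establish.

## Coordinate frame and track processing

All internal coordinates are 0-based, half-open (the native bedGraph/BED
convention); GFF3 is converted on read/write. Coverage is carried as per-bp
depth per chromosome. CPM normalization multiplies every value by
`1e6 / total_mapped_reads`, where the mapped-read total is metadata supplied
with the track (manifest sidecar or CLI flag), never inferred from the
coverage integral — the two differ by the read length and by clipping.

Smoothing and binning are one pass: bin *i* holds the mean of per-bp values
over the window `[i·step, i·step + window)`, left-anchored at the bin origin
(default window 100 bp, step 10 bp). Whether the original procedure anchored
or centered its windows is not documented; left-anchoring keeps bin origin =
genomic coordinate and is what "slid by 10 bp" reads as. Windows running
past the chromosome end are truncated and averaged over covered bases only,
so subtelomeric signal — where H3K9me3 matters — is not diluted by zero
padding. The implementation uses cumulative sums; it agrees with an explicit
per-window loop to 1e-9. A consequence worth knowing: mirroring a chromosome
and re-binning accumulates floating-point error in the opposite direction,
so mirror-symmetry holds to ~1e-9 relative, not bitwise.

## Metagene windows and per-gene mark levels

Windows are expressed in gene orientation: position 0 is the anchor (ATG or
stop codon), negative positions run upstream. For a minus-strand gene with
half-open anchor coordinate *a*, gene position *p* maps to genomic base
`a − p − 1`, which makes a minus-strand gene over mirror-image signal
produce the identical row. Off-chromosome positions are NaN-masked and
excluded from averages; genes with more than 50 % of the window masked are
flagged unusable and excluded from tier classification rather than silently
zeroed.

Two per-gene mark quantities are provided because both are in common use
for thresholding: the **window-mean CPM** over −500…+1500 around the ATG (the
operational definition used for thresholding here, default) and an
**ORF RPKM** (`reads overlapping ORF × 1e9 / (total mapped reads × ORF
length)`), exact when per-gene read counts are supplied and otherwise
estimated from raw coverage as coverage mass / read length (default 50 bp,
fractional overlap allowed). log2 values add a pseudocount of 0.01 × the
genome-wide nonzero median (configurable): it keeps zeros finite without
perturbing the ranking of expressed genes.

## Differential expression

The statistical stack is a self-contained, documented equivalent of the
voom+limma/edgeR workflow a practitioner would otherwise reach for:

1. **TMM factors.** Reference = sample whose upper quartile of nonzero-gene
   CPM is closest to the mean upper quartile. Per sample, M and A values are
   computed over genes expressed in both sample and reference; the top and
   bottom 30 % by M and 5 % by A are trimmed; the factor is 2^(weighted mean
   of surviving M values) with binomial delta-method inverse-variance
   weights; factors are rescaled to geometric mean 1. On a 20-gene fixture
   with 4 genes planted 8× up, the factors agree with the Bioconductor TMM
   implementation to <1e-9 (frozen reference values in the test suite).
2. **log2-CPM** with a 0.5-count offset against effective library sizes
   (library size × TMM factor).
3. **Moderated t.** Per-gene pooled two-group variance (df = n1+n2−2) is
   shrunk toward a lowess trend of log variance vs mean log2-CPM
   (frac = 0.5). The prior df d0 solves
   `trigamma(d0/2) = var(log s² − trend) − trigamma(df/2)` by Newton
   inversion (moments estimator); the posterior variance is the df-weighted
   blend, and the t statistic uses df + d0 degrees of freedom (normal when
   the excess variance is non-positive, i.e. complete shrinkage). Genes
   all-zero in both groups report log2FC 0, p 1, call `ns`.
4. **BH step-up FDR**, then calls at named threshold profiles: `methods`
   (FDR < 0.01), `fig5` (FDR < 0.005), `fig6` (FDR < 0.05), all with
   |log2FC| ≥ 2 (4-fold). The three stringencies correspond to the
   different analyses this pipeline reproduces; all are exposed as named
   profiles rather than hard-coded.

Calibration, measured by the suite on 20 null simulations of 2000 NB genes
(4 replicates per group, dispersion 0.05): mean type-I rate at p < 0.05 is
≈ 0.049, pooled null p-values are uniform to KS < 0.05, and FDR < 0.01
flags < 2 % of null genes. With planted 4-fold effects the median recovered
log2FC is within ±0.25 of 2. Note a sampling limit, not an estimator flaw:
at 2 vs 2 replicates, dispersion 0.05 and mean 500, the sd of the estimated
log2FC is √(2(φ + 1/μ)/n)/ln 2 ≈ 0.33, so no unbiased estimator lands in
[1.5, 2.5] more than ~87 % of the time; the recovery test therefore uses the
emulated design's 2 biological × 2 technical = 4 replicates per group.

## Integration

Mark tiers split at log2 level 5 (H3K4me3) and 2 (H3K36me3), boundary to
"low" (the published rule is ≤). Groups G1–G4 (primary metabolism; G5–G8
under the secondary-metabolism condition) are tier × DE-direction cells;
`ns` genes get no group, so group counts partition the DE-called, tiered
genes. Category enrichment is the exact upper-tail hypergeometric
(equivalently one-sided Fisher), computed with `scipy.stats.hypergeom` and
verified against exhaustive combinatorial enumeration for all small
universes; the universe defaults to the categorized genes but is
overridable, and one-sided testing is the convention for directional
category overlap. CSF vs SM mark comparisons report medians/quartiles plus
a two-sided Mann–Whitney p.

H3K9me3 domains are called as maximal runs of bins at or above a threshold
(default 4× the genome-wide median of nonzero bin CPM), merged across gaps
≤ 500 bp and filtered to ≥ 2 kb. Cluster flanking measures the distance
from each cluster's outermost gene coordinates to the nearest domain on each
side (0 when a domain overlaps the boundary) and flags sides within 5 kb;
classification is both/one/none. Flanking has conventionally been assessed
by visual inspection of genome-browser tracks; the threshold rule here is an
explicit, deterministic criterion, and all four parameters are configurable.

## Peptide stoichiometry

Input is form-level relative abundance per proteolytic peptide ("site"),
not spectra. Composite peptides (K9…K14, K27…K36) keep joint form labels:
per-residue marginals are not identifiable from form-level ratios and are
deliberately not deconvolved. Abundances are renormalized to sum to 1 per
site and strain (inputs that look like fractions but miss 1 by >1 % warn).
Total methylation is the me1+me2+me3 sum, so total + me0 = 100 % exactly.
Strain comparisons report mutant − WT in percentage points and
(mut − wt)/wt × 100 in percent. The wild-type H3K4 numbers
(me3/me2/me1 = 47.5/13.5/10.3 %) and the H3K9/K14 peptide's unmodified
fraction (22 %) belong to different peptides and are kept as distinct
sites, never reconciled.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the
conditions of the emulated experiments wherever those are known, and single
documented choices elsewhere.

* **Genome.** 2 chromosomes × 300 kb, 220 genes of 900–2400 bp on a 10-bp
  grid (so ATGs align with bin origins), non-overlapping, placed between
  5-kb heterochromatin-sized terminal margins; 4 SM clusters of 6 contiguous
  genes; all other genes are CSF. This is a desk-scale genome — the real
  one has ~10 000 genes on 8 chromosomes — sized so the whole suite runs in
  seconds; all rates below are per-gene, so conclusions scale.
* **Mark kernels.** H3K4me3: Gaussian at +250 bp from ATG, σ 150 (≈ 90 % of
  mass within the first 500 bp, matching the "first three nucleosomes"
  shape); H3Ac: Gaussian at +75, σ 75; H3K36me3: linear ramp rising to the
  stop codon; H3K9me3: 5-kb rectangles at chromosome termini and, for a
  configurable fraction of clusters (default 0.5), abutting both cluster
  boundaries. Amplitudes scale with expression tier (0.25/1/2 for
  low/mid/high) and SM genes are attenuated (×1/8 for H3K4me3, ×1/4 for
  H3Ac/H3K36me3 — SM clusters carry low activating marks). Per-bp counts
  are Poisson around kernel + uniform background (λ = 1).
* **Counts.** NB with dispersion 0.05, per-sample depth 2×10⁶ expected
  reads with ~10 % lognormal library jitter, 4 replicates per strain
  (2 biological × 2 technical in the emulated design). Planted |log2FC| = 2
  (the 4-fold criterion); per-direction DE rates default to the
  48-h rates observed in the emulated dataset: CSF 401/5676 down and 547/5676 up in the mutant, SM 97/149
  down and 22/149 up. The mutant also doubles/halves the H3K4me3 amplitude
  of up/down-planted genes, mirroring the observed mark–transcription
  coupling.
* **Peptides.** Observed per-site fractions are Dirichlet(c × truth) with
  concentration c = 200 by default; zero-truth forms stay exactly zero.
  The sd of an observed fraction is √(f(1−f)/(c+1)) — about 3.5 pp for a
  47.5 % form at c = 200 — which bounds single-draw recovery accuracy;
  estimates are unbiased (verified at c = 50 over 1000 draws).
* **Seeding.** One seed feeds every stream through `SeedSequence` spawn
  keys — (0,) genome, (1, mark, strain) coverage, (2,) counts,
  (3,) peptides — so any stage can be regenerated independently and
  identical configs give byte-identical fixture files (sha256-checked).

What the generator does **not** emulate: read-level artifacts (mappability,
GC bias, duplicates), fragment-length effects, ChIP efficiency differences
between antibodies, biological replicate structure beyond exchangeable
library jitter, isoforms/exon structure (ORF = one interval), or genuine
inter-gene correlation. Passing tests therefore demonstrate the correctness
and calibration of the computations under the assumed noise models, not
robustness to real-data artifacts.

## Problem sizes used by the checks

Null DE calibration: 20 simulations × 2000 genes, 4 vs 4. Planted-recovery
and integration checks: the default 220-gene genome. Oracle comparisons:
random tracks ≤ 10 kb against explicit-loop means (1e-9), exhaustive
hypergeometric enumeration for universes ≤ 25, BH against an independent
step-up on vectors ≤ 1000. The full suite runs in ~half a minute on one
core.

## Known limitations

* The moderated t on log2-CPM ignores the mean–variance relationship within
  a gene across samples (voom's precision weights); at the tested depths the
  trend-based shrinkage alone calibrates well, but very shallow libraries
  would benefit from observation-level weights.
* ORF RPKM from coverage assumes uniform read length and full-length reads.
* Domain calling has no local background model; a uniform threshold is
  appropriate for the rectangular planted domains but real pericentromeric
  signal may need per-chromosome thresholds.
* The enrichment universe choice (all genes vs categorized genes) changes p
  slightly; both are exposed, categorized-genes is the default.
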
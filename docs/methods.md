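# Methods

This note documents the models, parameter choices and numerical decisions
behind `meiotrace`, and what the synthetic-data studies do and do not show
about real data.

## Genome model

No alignment is performed anywhere in the package, so the genome is purely
a coordinate system: 22 autosomes plus X and Y with hg19-like length
proportions, 0-based half-open coordinates, and a configurable centromere
position (default mid-chromosome). `Genome.hg19_like(scale)` shrinks every
chromosome linearly; simulations and tests run at `scale = 0.01`, which
keeps a whole genome at ~31 Mb (≈ 3 100 ten-kb bins, ≈ 1 550 twenty-kb
bins) while every chromosome retains enough bins for median-based calling.
Length thresholds (e.g. the 10 Mb minimum segmental-event span) are scaled
with the genome when it is scaled.

GC content is a deterministic smooth track (a fixed per-chromosome
sinusoid within [0.38, 0.52]) standing in for the real GC landscape: it
produces a realistic confounded depth bias for the LOESS step without
pretending to model actual sequence.

## Meiosis simulator

Each meiosis produces a full tetrad. Per chromosome the parent contributes
four chromatids (two sisters per homolog); a fixed number of crossovers
(default 1) at uniform positions exchanges distal segments between
non-sister chromatids before segregation. Segregation outcomes:

* **normal** — one recombinant chromatid per product;
* **MI nondisjunction** — two products receive one chromatid of *each*
  homolog (centromere-proximal heterozygosity preserved), two receive none;
* **MII nondisjunction** — one product receives both sisters of one
  homolog (centromere-proximal homozygosity), one receives none, the other
  two are normal;
* **whole-genome diploidy** — the meiosis-I division is skipped genome-wide:
  two unreduced products each carry one chromatid of each homolog for
  every chromosome, two are empty.

The whole-genome-diploid gamete is deliberately modeled as *unreduced*
(both homologs retained) rather than as a duplicated chromatid set: a
duplicated set would be homozygous genome-wide (HI ≈ −1), whereas diploid
sperm are recognized precisely by balanced heterozygosity (HI ≈ 0). The
unreduced model is the configuration consistent with that signature.

Sex chromosomes: a male parent is hemizygous; X and Y form one bivalent
that segregates jointly (no X–Y recombination is modeled), so an
error-free gamete carries 22 autosomes plus X *or* Y — 23 chromosomes. A
female parent has a normal X pair and no Y. Tetrad conservation therefore
holds per chromosome *pair*: each autosome sums to 4 copies over the four
products, and the X+Y bivalent jointly sums to 4. This invariant holds
exactly under every error annotation and is verified over 10 000 random
meioses in the test suite.

## Observation model

`NoiseModel` captures the artefacts that matter to the inference:

| parameter | default | meaning |
|---|---|---|
| `reads_per_bin` | 32 | expected bin count at baseline copy number; matches ~10 M reads over ~310 k 10-kb bins (embryos) and ~5 M over ~155 k 20-kb bins (sperm) |
| `inverse_dispersion` | 44.4 | negative-binomial r (var = m + m²/r); sets the extra-Poisson CV to 0.15 for a copy-2 bin in the deep-coverage limit (at 32 reads/bin the Poisson floor dominates and total CV ≈ 0.23) |
| `gc_slope` | 1.5 | log-linear GC efficiency exp(slope·(gc − 0.45)), monotone by construction |
| `ado_rate` | 0.1 | per-locus, per-haplotype allele dropout (MDA-like); 0 for bulk parental DNA |
| `seq_error` | 0.005 | per-read allele flip probability |

Bin counts are negative binomial with mean proportional to the *absolute*
local copy number times GC efficiency (library yield scales with input
DNA). This choice is what lets a uniformly diploid sperm show ratio ≈ 2
against a haploid reference profile; with a self-median reference a
uniform ploidy shift cancels and only the heterozygosity index can detect
it — both behaviors are intentional and documented on
`copy_ratio_profile`. Mosaic events contribute mean ∝ (baseline + f·Δ)
over their span. Allele counts draw a Poisson(depth) read total per locus
from the cell's allele pool (copies weighted by clone fraction, after
independent per-copy dropout), with per-read error mixing the allele
identity. Every simulation entry point is byte-deterministic given its
seed.

## Copy-number inference

1. **GC normalization**: LOESS (span 0.3) of count on GC over bins with
   GC ∈ [0.3, 0.6] and count > 0; all bins are normalized through the
   interpolated fit; output rescaled to preserve the genome-wide median.
   A constant-GC profile degenerates to a pure rescaling.
2. **Copy ratio**: `baseline_copies · count / reference level`, baseline 2
   for embryos and 1 for sperm; the reference is a matched-bin control
   profile or, by default, the cell's own median.
3. **Whole-chromosome calls**: f̂ = |median ratio − baseline| clipped to
   [0, 1] (single-copy-delta assumption), direction from the sign, status
   euploid / mosaic / aneuploid by the 0.30 / 0.70 thresholds (boundary
   semantics exact: f̂ = 0.30 and 0.70 are mosaic). A whole-chromosome
   call additionally requires ≥ 80 % of bins deviating in the call
   direction, else the chromosome is left to segmental calling.
   Chromosomes with a median ratio ≥ 3.5 on a diploid baseline (deviation
   ≥ 1.5 on haploid) are reported with a rounded integer copy estimate and
   f̂ = 1: the single-clone fraction model is meaningless for multi-copy
   gains. Chromosomes with < 10 usable bins are skipped with a warning.
4. **Segmental calls**: per-bin ratios are smoothed with a 9-bin centered
   rolling median (raw low-coverage bins break run-length logic), then
   maximal runs deviating beyond the euploid threshold and spanning the
   minimum length (10 Mb full-genome scale) are reported. Chromosome-level
   calls take precedence: chromosomes already called are not re-reported
   as segments.
5. **Embryo class**: SA = 1–2 whole-chromosome *aneuploid-status* events,
   CA = ≥ 3, "other" = only mosaic or segmental findings, E otherwise.
   Whole-chromosome mosaic events do not count toward SA/CA. Sex
   chromosomes are excluded from the count by default (a male embryo is
   legitimately X-hemizygous). Segmental-only embryos are classed "other"
   regardless of segment size — the category definition groups mosaic and
   segmental findings together, and we follow it literally.

## Sperm ploidy

The heterozygosity rate R is the fraction of loci with depth ≥ 10 whose
minor-allele read fraction lies within [0.2, 0.8]; HI = log₂(R_sample /
R_diploid) with R_sample floored at 1e-4 (flagged) so an error-free
haploid, whose het rate is exactly 0, yields a finite, strongly negative
HI rather than −∞. In real MDA data residual artefactual het calls keep
haploid HI near −1; the floor is our explicit stand-in for that behavior
and the decision thresholds (haploid HI ≤ −0.7, diploid |HI| ≤ 0.3) are
configuration.

Decision integration: flat haploid CNV + haploid-like HI → haploid;
uniformly doubled autosomes + diploid-like HI → diploid; isolated events →
aneuploid-simple (1–2) / aneuploid-complex (≥ 3); on conflict the CNV
reading wins when ≥ 80 % of autosomes support it (depth evidence is the
first-listed parameter), otherwise the call is ambiguous with both
evidence lines reported. FISH tables are consumed as tabulated counts and
converted to percentages of analyzable nuclei.

## Parental origin

Informative loci are those with opposite-homozygous parents (AABB / BBAA).
Embryo genotypes are called from BAF (AA < 0.1, BB > 0.9, AB within
[0.2, 0.8], depth ≥ 10 — the thresholds are configuration; the decision
rules are stated in genotype space but no caller is canonical).
Duplications use a Z-statistic per pattern comparing regional AB-locus BAF
with the empirical non-CNV background, Z = (m_region − m_background) /
(SD_background / √n_region), with both patterns required to pass |Z| > 3
in opposite directions — a conservative reading of the "concurrent shift"
requirement. Using the empirical background rather than the theoretical
0.5 makes the test robust to a global BAF offset (e.g. from asymmetric
dropout). Losses use genotype ratios over AABB loci (> 0.8), with BBAA
loci evaluated symmetrically as an advisory, never blocking, confirmation.
Regions need ≥ 20 informative loci (≥ 20 AB calls for the Z path, at
least 3 per pattern) and the background ≥ 50; anything less is flagged
unanalyzable rather than guessed. Multi-copy gains keep the same sign
rules; the expected BAF (1+k)/(2+k) is reported, not thresholded.

Exact label symmetry holds by construction: swapping the parental labels
turns every AABB locus into BBAA and vice versa while all read data are
unchanged, so Z_AABB and Z_BBAA exchange exactly and every maternal call
becomes paternal. This is the precise form of the symmetry the test suite
asserts.

## Cohort statistics

Percentages are rounded half-up to one decimal (`decimal`-based, so 0.15 %
→ 0.2 %). The group comparison is the classical pooled-variance unpaired
two-tailed t-test (Welch correction available but off by default);
identical constant groups return p = 1 by convention, constant groups with
unequal means raise. The bundled example tallies reproduce the printed
cohort fractions exactly; where a split is not determined by the tallies
(the E/SA/other decomposition of the non-CA remainder of the
recurrent-failure cohort) the records are synthetic filler chosen to be
consistent with every asserted fraction, and nothing asserts the filler.

## Study conditions and problem sizes

The simulation studies in `meiotrace.studies` run at: 1/100-scale genome;
SNP panels of 200 loci/chromosome (general use) or 800 loci/chromosome
(origin analyses — opposite-homozygote loci are 1/8 of a B-frequency-0.5
panel, and regions need tens of them; the real deep-sequencing platform
genotypes far more loci genome-wide than either figure); allele depth 30×;
default noise. Under these conditions the suite verifies: 100 %
parental-origin recovery at zero noise and ≥ 95 % over 200 default-noise
replicates (3 events per embryo); zero tetrad-conservation violations over
10 000 random meioses; 100 % haploid-vs-diploid sperm classification at
zero noise and ≥ 95 % over 100 cells per class; ≥ 95 % sensitivity for
constitutive whole-chromosome events over 200 embryos with zero direction
errors.

## Limitations

* The generator emulates the *statistical structure* the inference relies
  on (copy-ratio shifts, BAF displacement, dropout, overdispersion), not
  real amplification chemistry: no chimeric reads, no locus-specific
  amplification bias beyond the GC curve, no correlated dropout. Passing
  tests show the inference is correct under its stated model, not that the
  model captures every failure mode of MDA/PicoPLEX data.
* Segmentation is transparent run-length thresholding, adequate for a
  whole-chromosome-dominated phenotype; it is not a substitute for HMM or
  CBS segmentation on focal-CNV problems.
* The f̂ cell-fraction estimate presumes a single abnormal clone with a
  single-copy delta.
* No haplotype phasing or linkage analysis: origin calls are marginal,
  per-region, and do not stage MI vs MII origin in embryos.
* With a self-median reference, genome-wide ploidy changes are invisible
  to depth; the HI covers this for sperm, and embryos are assumed diploid
  at baseline.
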
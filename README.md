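# meiotrace

Simulation and inference toolkit for tracing **meiotic-origin chromosome
abnormalities** in preimplantation embryos and single sperm from
low-coverage sequencing data.

## The problem

Some couples repeatedly produce morphologically good cleavage-stage embryos
that never form blastocysts. A major cause is *complex aneuploidy* of
gametic origin: meiosis I (homolog) or meiosis II (sister-chromatid)
nondisjunction in a parent carrying damaging variants in meiotic genes
produces eggs or sperm with multiple whole-chromosome gains and losses.
Detecting this phenotype requires a chain of bespoke computations on
low-coverage single-cell sequencing data:

* **CNV calling from binned read depth** — reads binned in 10-kb (embryo)
  or 20-kb (sperm) windows, GC-normalized by LOESS, converted to copy
  ratios against a diploid or haploid baseline. Per event, the abnormal
  cell fraction f̂ = |median ratio − baseline| classifies the call:
  euploid (f̂ < 0.30), mosaic (0.30 ≤ f̂ ≤ 0.70), aneuploid (f̂ > 0.70).
  Embryos are then classed **E** (euploid), **SA** (simple aneuploidy, 1–2
  whole-chromosome abnormalities), **CA** (complex aneuploidy, ≥ 3) or
  **other** (only mosaic or segmental findings).
* **Single-sperm ploidy** — the CNV profile on a haploid baseline is
  integrated with the *heterozygosity index*
  **HI = log₂(R_sample / R_diploid)**, the log-ratio of the cell's
  heterozygous-call rate to a diploid reference's. HI ≈ 0 indicates
  balanced heterozygosity (diploid), HI ≈ −1 genome-wide homozygosity
  (haploid).
* **Parental origin of embryonic CNVs** — at *informative SNPs* (father
  AA / mother BB, "AABB", or the reciprocal "BBAA") every read allele is
  attributable to a parent. A duplication is maternal when the AABB
  B-allele frequency rises above 0.5 while the BBAA BAF falls below it
  (|Z| > 3 against non-CNV regions on both patterns), paternal on the
  reversed pattern. A loss is paternal when > 80 % of AABB loci call BB
  (only the maternal allele remains), maternal when > 80 % call AA.
* **Variant screening** — a three-gate filter on annotated exome tables
  (population frequency < 1 % in gnomAD/ExAC, damaging functional class,
  membership in a gamete-expression/infertility gene panel) followed by
  carrier-genotype detection (homozygous, or ≥ 2 distinct heterozygous
  variants in one gene).
* **Cohort statistics** — per-class embryo proportions, couples producing
  exclusively CA embryos, abnormality-count bands, FISH-style aneuploidy
  frequencies, and unpaired two-tailed t-tests.

All of it is exercised end-to-end on synthetic data with known ground
truth: the `simkit` module simulates parents (Hardy–Weinberg), complete
meioses (recombination, MI/MII nondisjunction, unreduced gametes),
fertilization, mosaic events, and the sequencing observables (negative-
binomial bin counts with GC bias; allele counts with MDA-style allele
dropout and read error).

## Worked example

```python
from meiotrace import pipeline, simkit
from meiotrace.genome import Genome
from meiotrace.simkit.scenarios import gamete_with_copy_number

genome = Genome.hg19_like(scale=0.01)          # 1/100-scale hg19-like genome
panel = simkit.SnpPanel.random(genome, loci_per_chrom=800, seed=1)
parents = simkit.simulate_parents(panel, seed=2)
noise = simkit.NoiseModel()                    # MDA-like single-cell noise

# an embryo from an egg disomic for chromosome 16 (MI error) + normal sperm
egg = gamete_with_copy_number(parents.mother, "16", 2, error="MI", seed=3)
sperm = simkit.simulate_gamete(parents.father, seed=4)
embryo = simkit.form_embryo(sperm, egg, seed=5)

bins = simkit.simulate_bin_depth(embryo, bin_size=10_000, noise=noise, seed=6)
alleles = simkit.simulate_allele_counts(embryo, parents, depth=30,
                                        noise=noise, seed=7)
result = pipeline.analyze_embryo(bins, alleles=alleles,
                                 min_segment_bp=100_000)

print("embryo class:", result.embryo_class.label,
      f"({result.embryo_class.whole_chrom_abnormalities} whole-chromosome events)")
for call in result.cn.aneuploid_chromosomes():
    print(f"  chr{call.chrom}: {call.event}, median ratio "
          f"{call.median_ratio:.2f}, f = {call.fraction:.2f}")
for oc in result.origin_calls:
    print(f"  chr{oc.chrom} {oc.event}: {oc.origin} "
          f"(Z_AABB = {oc.z_aabb:.1f}, Z_BBAA = {oc.z_bbaa:.1f})")
```

prints

```
embryo class: SA (1 whole-chromosome events)
  chr16: gain, median ratio 3.06, f = 1.00
  chr16 duplication: maternal (Z_AABB = 8.2, Z_BBAA = -7.5)
```

The maternal trisomy injected at simulation time is recovered as a
whole-chromosome gain (ratio ≈ 3 on the diploid baseline, f̂ = 1 →
aneuploid), the embryo is classed SA, and the origin call names the
mother: at AABB loci the extra maternal copy pushes the B-allele frequency
toward 2/3 (Z ≫ +3) while BBAA loci mirror it below 0.5 (Z ≪ −3).

A command-line interface mirrors the library
(`meiotrace simulate / call-cnv / ploidy / origin / screen / summarize`);
see `meiotrace --help`.

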
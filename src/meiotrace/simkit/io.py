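"""On-disk formats for simulated data.

Parental genotypes go out as a minimal GT-only VCF (readable back with
cyvcf2 or any standard tool); karyotype truth, bin depth and allele counts
are plain TSV so that real data prepared by other tools can use the same
entry points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..genome import Genome
from .embryo import EmbryoTruth
from .panel import Haplotypes, ParentalGenotypes, SnpPanel

_GT_CODE = {"AA": "0/0", "AB": "0/1", "BB": "1/1"}
_HAP_GT = {(0, 0): "0|0", (0, 1): "0|1", (1, 0): "1|0", (1, 1): "1|1"}


def write_parental_vcf(parents: ParentalGenotypes, path) -> None:
    """Write both parents' phased genotypes as a minimal VCF 4.2.

    REF/ALT are placeholder bases (A/C): only the GT matrix carries
    information in this pipeline.
    """
    panel = parents.panel
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=meiotrace-simkit\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in panel.genome.lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
                 "\tFATHER\tMOTHER\n")
        for i in range(panel.n_loci):
            fgt = _HAP_GT[(int(parents.father.h1[i]), int(parents.father.h2[i]))]
            mgt = _HAP_GT[(int(parents.mother.h1[i]), int(parents.mother.h2[i]))]
            fh.write(f"{panel.chrom[i]}\t{panel.pos[i] + 1}\t.\tA\tC\t.\tPASS"
                     f"\tAF={panel.b_freq[i]:.4g}\tGT\t{fgt}\t{mgt}\n")


def read_parental_vcf(path) -> pd.DataFrame:
    """Read a two-sample (FATHER, MOTHER) VCF into a genotype table.

    Returns columns chrom, pos (0-based), father_gt, mother_gt with
    genotypes in {AA, AB, BB}.  Loci with missing genotypes are dropped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(samples) != 2:
        raise ValueError("parental VCF must contain exactly two samples")
    try:
        i_f = samples.index("FATHER")
        i_m = samples.index("MOTHER")
    except ValueError:
        i_f, i_m = 0, 1  # fall back to sample order father, mother
    rows = []
    for var in vcf:
        gts = var.genotypes
        gt = []
        for idx in (i_f, i_m):
            alleles = [a for a in gts[idx][:-1] if a is not None and a >= 0]
            if len(alleles) < 2:
                gt = None
                break
            gt.append("AA" if sum(alleles[:2]) == 0
                      else "BB" if sum(alleles[:2]) == 2 else "AB")
        if gt is not None:
            rows.append((var.CHROM, var.POS - 1, gt[0], gt[1]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "father_gt", "mother_gt"])


def parents_from_frame(df: pd.DataFrame, genome: Genome) -> ParentalGenotypes:
    """Rebuild a ParentalGenotypes object from a genotype table.

    Phasing of heterozygotes is arbitrary (0|1): downstream inference only
    uses unphased genotypes.
    """
    df = df.sort_values(["chrom", "pos"],
                        key=lambda s: (s.map({c: i for i, c in
                                              enumerate(genome.chromosomes)})
                                       if s.name == "chrom" else s))
    panel = SnpPanel(genome=genome, chrom=df["chrom"].to_numpy(dtype=object),
                     pos=df["pos"].to_numpy(),
                     b_freq=np.full(len(df), 0.5))
    hap = {}
    for side in ("father", "mother"):
        dosage = df[f"{side}_gt"].map({"AA": 0, "AB": 1, "BB": 2}).to_numpy()
        h1 = (dosage == 2).astype(np.uint8)
        h2 = (dosage >= 1).astype(np.uint8)
        hap[side] = Haplotypes(panel=panel, h1=h1, h2=h2)
    return ParentalGenotypes(panel=panel, father=hap["father"],
                             mother=hap["mother"])


def write_truth_tsv(truth: EmbryoTruth, path) -> None:
    """Karyotype truth as TSV: per-chromosome parental copies + events."""
    kf = truth.karyotype_frame()
    ev = truth.events_frame()
    with open(path, "w") as fh:
        kf.to_csv(fh, sep="\t", index=False)
        fh.write("#events\n")
        ev.to_csv(fh, sep="\t", index=False)
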
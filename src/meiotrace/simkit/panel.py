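"""SNP panels and parental genotypes.

A :class:`SnpPanel` is the fixed set of loci at which allele-level evidence
is observed; :func:`simulate_parents` draws phased parental haplotypes at
those loci under Hardy-Weinberg equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..genome import Genome

GENOTYPES = ("AA", "AB", "BB")


@dataclass
class SnpPanel:
    """Genotyping panel: loci with population B-allele frequencies.

    Loci are stored sorted by genome chromosome order, positions strictly
    increasing within each chromosome.
    """

    genome: Genome
    chrom: np.ndarray
    pos: np.ndarray
    b_freq: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.b_freq = np.asarray(self.b_freq, dtype=float)
        n = len(self.chrom)
        if n == 0:
            raise ValueError("panel must contain at least one locus")
        if not (len(self.pos) == len(self.b_freq) == n):
            raise ValueError("panel arrays must have equal length")
        if ((self.b_freq < 0) | (self.b_freq > 1)).any():
            raise ValueError("B-allele frequencies must lie in [0, 1]")
        known = set(self.genome.chromosomes)
        slices: dict[str, slice] = {}
        i = 0
        while i < n:
            c = self.chrom[i]
            if c not in known:
                raise ValueError(f"unknown chromosome id: {c!r}")
            j = i
            while j < n and self.chrom[j] == c:
                j += 1
            if c in slices:
                raise ValueError("panel loci must be grouped by chromosome")
            p = self.pos[i:j]
            if (np.diff(p) <= 0).any():
                raise ValueError(
                    f"positions must be strictly increasing on chrom {c}")
            if p[0] < 0 or p[-1] >= self.genome.lengths[c]:
                raise ValueError(f"locus outside chromosome {c} bounds")
            slices[c] = slice(i, j)
            i = j
        self._slices = slices

    @property
    def n_loci(self) -> int:
        return len(self.pos)

    def chromosomes(self) -> list[str]:
        return list(self._slices)

    def chrom_slice(self, chrom: str) -> slice:
        """Index slice of this chromosome's loci in panel order."""
        return self._slices[chrom]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "b_freq": self.b_freq})

    @classmethod
    def random(cls, genome: Genome, loci_per_chrom: int = 200,
               b_freq: float | str = 0.5, seed=0) -> "SnpPanel":
        """Uniformly placed loci on every chromosome.

        ``b_freq`` may be a constant, or ``"beta"`` for a U-shaped
        Beta(0.8, 0.8) frequency spectrum typical of common-SNP panels.
        """
        rng = np.random.default_rng(seed)
        chroms, poss, freqs = [], [], []
        for c in genome.chromosomes:
            length = genome.lengths[c]
            k = min(loci_per_chrom, length)
            pos = np.sort(rng.choice(length, size=k, replace=False))
            chroms.append(np.full(k, c, dtype=object))
            poss.append(pos)
            if b_freq == "beta":
                freqs.append(rng.beta(0.8, 0.8, size=k))
            else:
                freqs.append(np.full(k, float(b_freq)))
        return cls(genome=genome,
                   chrom=np.concatenate(chroms),
                   pos=np.concatenate(poss),
                   b_freq=np.concatenate(freqs))


@dataclass
class Haplotypes:
    """One parent's two phased haplotypes over a panel (0 = A/ref, 1 = B/alt).

    ``sex`` controls the sex-chromosome model: a male parent is hemizygous —
    ``h1`` carries the single X haplotype at X loci and the single Y
    haplotype at Y loci (``h2`` is ignored there); a female parent has a
    normal X pair and no Y.
    """

    panel: SnpPanel
    h1: np.ndarray
    h2: np.ndarray
    sex: str = "female"

    def __post_init__(self) -> None:
        self.h1 = np.asarray(self.h1, dtype=np.uint8)
        self.h2 = np.asarray(self.h2, dtype=np.uint8)
        if len(self.h1) != self.panel.n_loci or len(self.h2) != self.panel.n_loci:
            raise ValueError("haplotype length must match panel")
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")

    def genotypes(self) -> np.ndarray:
        """Unphased genotype strings per locus.

        Hemizygous male X/Y loci report the single allele doubled (AA/BB);
        female Y loci report "NN" (no genotype), which keeps them out of
        informative-marker selection.
        """
        dosage = self.h1.astype(int) + self.h2.astype(int)
        gt = np.array(GENOTYPES, dtype=object)[dosage]
        chrom = self.panel.chrom
        if self.sex == "male":
            hemi = (chrom == "X") | (chrom == "Y")
            gt[hemi] = np.where(self.h1[hemi] > 0, "BB", "AA")
        else:
            gt[chrom == "Y"] = "NN"
        return gt


@dataclass
class ParentalGenotypes:
    """Phased genotypes of the two parents over a shared panel."""

    panel: SnpPanel
    father: Haplotypes
    mother: Haplotypes = field(repr=False)

    def __post_init__(self) -> None:
        if self.father.panel is not self.panel or self.mother.panel is not self.panel:
            # allow equal-but-distinct panels as long as loci agree
            for hap in (self.father, self.mother):
                if hap.panel.n_loci != self.panel.n_loci:
                    raise ValueError("parent haplotypes on a different panel")

    def swapped(self) -> "ParentalGenotypes":
        """Same data with the parental labels exchanged.

        Sex attributes travel with the haplotypes, so sex-linked loci are
        only meaningful for autosomal analyses after a swap (which is what
        the label-symmetry property is about).
        """
        return ParentalGenotypes(panel=self.panel, father=self.mother,
                                 mother=self.father)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.panel.chrom,
            "pos": self.panel.pos,
            "father_gt": self.father.genotypes(),
            "mother_gt": self.mother.genotypes(),
        })


def simulate_parents(panel: SnpPanel, seed=0) -> ParentalGenotypes:
    """Draw both parents' phased genotypes under Hardy-Weinberg equilibrium.

    Each haplotype allele is an independent Bernoulli(b_freq) draw, which
    yields genotype frequencies p^2 / 2pq / q^2 at every locus.
    """
    rng = np.random.default_rng(seed)
    draws = rng.random((4, panel.n_loci)) < panel.b_freq
    draws = draws.astype(np.uint8)
    father = Haplotypes(panel=panel, h1=draws[0], h2=draws[1], sex="male")
    mother = Haplotypes(panel=panel, h1=draws[2], h2=draws[3], sex="female")
    return ParentalGenotypes(panel=panel, father=father, mother=mother)
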
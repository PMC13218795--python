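"""Meiosis simulation: recombination, MI/MII nondisjunction, unreduced gametes.

One meiosis produces a tetrad of four products.  Per chromosome the parent
contributes four chromatids (two sister copies of each homolog); crossovers
exchange distal segments between non-sister chromatids before segregation.

Segregation outcomes per chromosome:

* ``none`` — each product receives one recombinant chromatid.
* MI nondisjunction — both homologs co-segregate: two products receive one
  chromatid of *each* homolog (heterozygosity preserved near the
  centromere), two receive none.
* MII nondisjunction — sister chromatids co-segregate: one product receives
  both sisters of one homolog (centromere-proximal homozygosity), one
  receives none, the other two are normal.
* whole-genome diploidy — the meiosis-I division is skipped genome-wide:
  two unreduced products each carry one chromatid of each homolog for every
  chromosome (balanced heterozygosity, as seen in diploid sperm), two
  products are empty.

In every case the four products jointly carry exactly four copies of each
chromosome (tetrad conservation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..genome import Genome
from .panel import Haplotypes, SnpPanel

ERROR_NONE = "none"
ERROR_MI = "MI-nondisjunction"
ERROR_MII = "MII-nondisjunction"
ERROR_WGD = "whole-genome-diploidy"

_ERROR_ALIASES = {
    "none": ERROR_NONE,
    "mi": ERROR_MI, "mi-nondisjunction": ERROR_MI,
    "mii": ERROR_MII, "mii-nondisjunction": ERROR_MII,
}


def _canonical_error(name: str) -> str:
    try:
        return _ERROR_ALIASES[name.lower()]
    except KeyError:
        raise ValueError(f"unknown meiotic error type: {name!r}") from None


@dataclass
class GameteKaryotype:
    """One gamete: per-chromosome copies with their allele sequences.

    ``copies[chrom]`` is a list (possibly empty) of uint8 allele arrays over
    that chromosome's panel loci; ``errors[chrom]`` annotates the meiotic
    error that produced the configuration.
    """

    panel: SnpPanel
    copies: dict[str, list[np.ndarray]]
    errors: dict[str, str] = field(default_factory=dict)
    whole_genome_diploid: bool = False

    @property
    def genome(self) -> Genome:
        return self.panel.genome

    def copy_number(self, chrom: str) -> int:
        return len(self.copies[chrom])

    def is_euploid_haploid(self) -> bool:
        """One copy of every autosome and exactly one sex chromosome."""
        for c, v in self.copies.items():
            if c not in ("X", "Y") and len(v) != 1:
                return False
        sex = [c for c in ("X", "Y") if c in self.copies]
        if not sex:
            return True
        return sum(len(self.copies[c]) for c in sex) == 1

    def karyotype_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": list(self.copies),
            "copies": [len(v) for v in self.copies.values()],
            "error": [self.errors.get(c, ERROR_NONE) for c in self.copies],
        })


def _recombine(h1: np.ndarray, h2: np.ndarray, pos: np.ndarray, length: int,
               n_crossovers: int, rng: np.random.Generator):
    """Four chromatids after ``n_crossovers`` uniform non-sister exchanges."""
    chromatids = [h1.copy(), h1.copy(), h2.copy(), h2.copy()]
    for _ in range(n_crossovers):
        x = rng.uniform(0, length)
        i = rng.integers(2)          # chromatid of homolog 1
        j = 2 + rng.integers(2)      # chromatid of homolog 2
        mask = pos >= x
        tmp = chromatids[i][mask].copy()
        chromatids[i][mask] = chromatids[j][mask]
        chromatids[j][mask] = tmp
    return chromatids


def _segregate(chromatids, error: str, rng: np.random.Generator):
    """Distribute four chromatids into the four tetrad slots."""
    c11, c12, c21, c22 = chromatids
    if error == ERROR_NONE:
        products = [[c11], [c12], [c21], [c22]]
    elif error in (ERROR_MI, ERROR_WGD):
        # both homologs to one pole; MII then splits into two bivalent-derived
        # disomic products, each with one chromatid per homolog
        if rng.integers(2):
            c21, c22 = c22, c21
        products = [[c11, c21], [c12, c22], [], []]
    elif error == ERROR_MII:
        if rng.integers(2):  # which homolog's MII division fails
            products = [[c11, c12], [], [c21], [c22]]
        else:
            products = [[c11], [c12], [c21, c22], []]
    else:  # pragma: no cover - guarded by _canonical_error
        raise ValueError(error)
    order = rng.permutation(4)
    return [products[k] for k in order]


def simulate_tetrad(parent: Haplotypes, error_spec: dict[str, str] | None = None,
                    recomb_rate: int = 1, seed=0,
                    whole_genome_diploid: bool = False) -> list[GameteKaryotype]:
    """Simulate one complete meiosis, returning all four products.

    ``error_spec`` maps chromosome id -> error type ("MI", "MII"); any
    chromosome not listed segregates normally.  ``recomb_rate`` is the fixed
    crossover count per chromosome.  With ``whole_genome_diploid`` the
    meiosis-I division is skipped for every chromosome (two unreduced
    products, two empty); a per-chromosome error_spec cannot be combined
    with it.
    """
    rng = np.random.default_rng(seed)
    panel = parent.panel
    spec = {c: _canonical_error(e) for c, e in (error_spec or {}).items()}
    for c in spec:
        if c not in panel.genome.lengths:
            raise ValueError(f"unknown chromosome id: {c!r}")
        if c == "Y" and parent.sex == "female":
            raise ValueError("a female parent carries no Y chromosome")
    if whole_genome_diploid and spec:
        raise ValueError(
            "whole-genome diploidy cannot be combined with per-chromosome errors")

    male_pair = parent.sex == "male" and (
        "X" in panel.chromosomes() or "Y" in panel.chromosomes())
    slot_copies: list[dict[str, list[np.ndarray]]] = [{}, {}, {}, {}]
    errors: dict[str, str] = {}
    for chrom in panel.chromosomes():
        if male_pair and chrom in ("X", "Y"):
            continue  # the X-Y bivalent is handled jointly below
        sl = panel.chrom_slice(chrom)
        pos = panel.pos[sl]
        length = panel.genome.lengths[chrom]
        error = ERROR_WGD if whole_genome_diploid else spec.get(chrom, ERROR_NONE)
        if chrom == "Y":  # female parent: no Y material
            products = [[], [], [], []]
            error = ERROR_NONE
        else:
            chromatids = _recombine(parent.h1[sl], parent.h2[sl], pos, length,
                                    int(recomb_rate), rng)
            if whole_genome_diploid:
                # the two unreduced products must occupy the same slots for
                # every chromosome: fixed slots 0/1
                if rng.integers(2):
                    chromatids = chromatids[2:] + chromatids[:2]
                c11, c12, c21, c22 = chromatids
                products = [[c11, c21], [c12, c22], [], []]
            else:
                products = _segregate(chromatids, error, rng)
        errors[chrom] = error
        for k in range(4):
            slot_copies[k][chrom] = products[k]

    if male_pair:
        error = (ERROR_WGD if whole_genome_diploid
                 else spec.get("X", spec.get("Y", ERROR_NONE)))
        _segregate_male_sex_pair(parent, error, whole_genome_diploid,
                                 slot_copies, rng)
        for chrom in ("X", "Y"):
            if chrom in panel.genome.lengths:
                errors[chrom] = error

    return [GameteKaryotype(panel=panel, copies=slot_copies[k],
                            errors=dict(errors),
                            whole_genome_diploid=whole_genome_diploid)
            for k in range(4)]


def _segregate_male_sex_pair(parent, error: str, wgd: bool, slot_copies,
                             rng: np.random.Generator) -> None:
    """Segregate the X-Y bivalent of a male parent (no X-Y recombination).

    The pair jointly obeys tetrad conservation: the four products together
    carry two X chromatids and two Y chromatids.
    """
    panel = parent.panel
    chroms = panel.chromosomes()
    x = parent.h1[panel.chrom_slice("X")].copy() if "X" in chroms else None
    y = parent.h1[panel.chrom_slice("Y")].copy() if "Y" in chroms else None
    # product -> (n_x, n_y) copies
    if wgd or error == ERROR_MI:
        layout = [(1, 1), (1, 1), (0, 0), (0, 0)]
    elif error == ERROR_MII:
        layout = [(2, 0), (0, 0), (0, 1), (0, 1)] if rng.integers(2) \
            else [(1, 0), (1, 0), (0, 2), (0, 0)]
    else:
        layout = [(1, 0), (1, 0), (0, 1), (0, 1)]
    order = np.arange(4) if wgd else rng.permutation(4)
    for slot, k in enumerate(order):
        n_x, n_y = layout[k]
        if x is not None:
            slot_copies[slot]["X"] = [x.copy() for _ in range(n_x)]
        if y is not None:
            slot_copies[slot]["Y"] = [y.copy() for _ in range(n_y)]


def simulate_gamete(parent: Haplotypes, error_spec: dict[str, str] | None = None,
                    recomb_rate: int = 1, seed=0,
                    whole_genome_diploid: bool = False,
                    product_index: int | None = None) -> GameteKaryotype:
    """Simulate meiosis and transmit one product.

    The transmitted product is chosen uniformly among the four (among the
    two unreduced products for whole-genome diploidy, which is by definition
    the transmission of a diploid gamete).  ``product_index`` forces a slot,
    e.g. to obtain the disomic product of a nondisjunction deterministically.
    """
    rng = np.random.default_rng(seed)
    tetrad = simulate_tetrad(parent, error_spec=error_spec,
                             recomb_rate=recomb_rate, seed=rng,
                             whole_genome_diploid=whole_genome_diploid)
    if product_index is None:
        if whole_genome_diploid:
            candidates = [g for g in tetrad
                          if all(len(v) == 2 for c, v in g.copies.items()
                                 if c not in ("X", "Y"))]
            return candidates[rng.integers(len(candidates))]
        return tetrad[rng.integers(4)]
    return tetrad[product_index]
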
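"""Shared fixtures: a scaled genome and reusable synthetic families.

All simulations run on a 1/100-scale hg19-like genome: chromosome
proportions and bin sizes are realistic, while whole-genome objects stay
small enough for many replicates per test.
"""

import numpy as np
import pytest

from meiotrace.genome import Genome
from meiotrace.simkit import (Haplotypes, NoiseModel, ParentalGenotypes,
                              SnpPanel, simulate_parents)

SCALE = 0.01


@pytest.fixture(scope="session")
def genome():
    return Genome.hg19_like(SCALE)


@pytest.fixture(scope="session")
def panel(genome):
    """Moderate-density panel: 200 loci per chromosome, common SNPs."""
    return SnpPanel.random(genome, loci_per_chrom=200, b_freq=0.5, seed=11)


@pytest.fixture(scope="session")
def dense_panel(genome):
    """Dense panel (800 loci/chromosome) for origin analyses, which need
    tens of informative (opposite-homozygote) loci per chromosome."""
    return SnpPanel.random(genome, loci_per_chrom=800, b_freq=0.5, seed=13)


@pytest.fixture(scope="session")
def parents(panel):
    return simulate_parents(panel, seed=17)


@pytest.fixture(scope="session")
def dense_parents(dense_panel):
    return simulate_parents(dense_panel, seed=19)


@pytest.fixture(scope="session")
def noise():
    return NoiseModel()


@pytest.fixture(scope="session")
def informative_parents(panel):
    """Fully informative parents: father AA and mother BB at every locus
    on odd chromosomes, the reciprocal pattern on even ones."""
    n = panel.n_loci
    odd = np.array([c in {"1", "3", "5", "7", "9", "11", "13", "15", "17",
                          "19", "21", "X"} for c in panel.chrom])
    father = Haplotypes(panel=panel, h1=np.where(odd, 0, 1).astype(np.uint8),
                        h2=np.where(odd, 0, 1).astype(np.uint8), sex="male")
    mother = Haplotypes(panel=panel, h1=np.where(odd, 1, 0).astype(np.uint8),
                        h2=np.where(odd, 1, 0).astype(np.uint8), sex="female")
    return ParentalGenotypes(panel=panel, father=father, mother=mother)
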
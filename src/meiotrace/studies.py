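"""Reproducible simulation studies exercising the full pipelines.

Each study generates its own synthetic data at the package's standard study
conditions (1/100-scale hg19-like genome, default noise model, dense SNP
panel for origin analyses) and measures a recovery or classification rate
against the known ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import origin, pipeline, variantscreen
from .genome import Genome
from .simkit import (NoiseModel, SnpPanel, form_embryo,
                     simulate_allele_counts, simulate_bin_depth,
                     simulate_gamete, simulate_parents, simulate_tetrad)
from .simkit.scenarios import (SPERM_BIN_SIZE, diploid_reference_alleles,
                               reference_depth_profile, sperm_gamete)
from .spermploidy import het_rate

GENOME_SCALE = 0.01
ORIGIN_LOCI_PER_CHROM = 800
ALLELE_DEPTH = 30.0


def _setup(seed, loci_per_chrom=ORIGIN_LOCI_PER_CHROM):
    rng = np.random.default_rng(seed)
    genome = Genome.hg19_like(GENOME_SCALE)
    panel = SnpPanel.random(genome, loci_per_chrom=loci_per_chrom,
                            b_freq=0.5, seed=rng.integers(2**31))
    parents = simulate_parents(panel, seed=rng.integers(2**31))
    return rng, genome, panel, parents


def origin_recovery_study(n_replicates: int, noise: NoiseModel | None = None,
                          seed: int = 0, events_per_embryo: int = 3) -> dict:
    """Parental-origin recovery rate on embryos with known meiotic events.

    Each replicate embryo carries ``events_per_embryo`` single-copy
    whole-chromosome events (random gain/loss, random parent of origin);
    an event counts as recovered only if its origin call names the true
    parent (undetermined counts as a miss).
    """
    noise = noise or NoiseModel()
    rng, genome, panel, parents = _setup(seed)
    hit = total = 0
    for _ in range(n_replicates):
        chroms = rng.choice(genome.autosomes, size=events_per_embryo,
                            replace=False)
        egg_spec, sperm_spec, truth = [], [], {}
        for c in chroms:
            is_gain = bool(rng.integers(2))
            is_maternal = bool(rng.integers(2))
            (egg_spec if is_maternal else sperm_spec).append(
                (c, 2 if is_gain else 0))
            truth[c] = ("duplication" if is_gain else "loss",
                        "maternal" if is_maternal else "paternal")
        egg = _gamete_with_events(parents.mother, egg_spec, rng)
        sperm = _gamete_with_events(parents.father, sperm_spec, rng)
        embryo = form_embryo(sperm, egg, seed=rng)
        alleles = simulate_allele_counts(embryo, parents, ALLELE_DEPTH,
                                         noise, seed=rng)
        calls = origin.call_origins(
            [(c, ev) for c, (ev, _) in truth.items()], alleles)
        for call in calls:
            total += 1
            hit += call.origin == truth[call.chrom][1]
    return {"accuracy": hit / total, "n_events": total,
            "n_replicates": n_replicates}


def _gamete_with_events(parent, spec, rng):
    """Gamete disomic/nullisomic for the requested chromosomes."""
    if not spec:
        return simulate_gamete(parent, seed=rng)
    error_spec = {c: str(rng.choice(["MI", "MII"])) for c, _ in spec}
    want = dict(spec)
    # redraw until each errored chromosome transmits the requested outcome
    for _ in range(200):
        tetrad = simulate_tetrad(parent, error_spec, seed=rng)
        for g in tetrad:
            if all(g.copy_number(c) == k for c, k in want.items()):
                return g
    raise RuntimeError("failed to draw requested gamete configuration")


def tetrad_conservation_study(n_meioses: int, seed: int = 0,
                              loci_per_chrom: int = 10) -> dict:
    """Count violations of tetrad copy conservation under random errors.

    Every chromosome pair (the X-Y bivalent counted jointly) must sum to
    exactly 4 copies across the four meiotic products.
    """
    rng, genome, panel, parents = _setup(seed, loci_per_chrom=loci_per_chrom)
    violations = 0
    sides = (parents.father, parents.mother)
    for i in range(n_meioses):
        parent = sides[i % 2]
        allowed = [c for c in genome.chromosomes
                   if not (c == "Y" and parent.sex == "female")]
        n_err = int(rng.integers(0, 5))
        spec = {c: str(rng.choice(["MI", "MII"]))
                for c in rng.choice(allowed, size=n_err, replace=False)}
        wgd = n_err == 0 and rng.random() < 0.1
        tetrad = simulate_tetrad(parent, None if wgd else spec,
                                 seed=rng, whole_genome_diploid=wgd)
        for c in genome.autosomes:
            if sum(t.copy_number(c) for t in tetrad) != 4:
                violations += 1
        if sum(t.copy_number("X") + t.copy_number("Y") for t in tetrad) != 4:
            violations += 1
    return {"n_meioses": n_meioses, "violations": violations}


def sperm_classification_study(n_per_class: int,
                               noise: NoiseModel | None = None,
                               seed: int = 0) -> dict:
    """Haploid-vs-diploid sperm classification accuracy.

    Simulates ``n_per_class`` haploid and whole-genome-diploid sperm,
    runs the full GC-normalize -> copy-ratio -> HI -> ploidy pipeline with
    a simulated haploid reference profile and diploid reference rate, and
    scores the two-way classification.
    """
    noise = noise or NoiseModel()
    rng, genome, panel, parents = _setup(seed, loci_per_chrom=200)
    reference = reference_depth_profile(parents.father, noise,
                                        SPERM_BIN_SIZE,
                                        seed=rng.integers(2**31))
    r_diploid = het_rate(diploid_reference_alleles(
        parents, ALLELE_DEPTH, noise, seed=rng.integers(2**31)))
    correct = total = 0
    for kind in ("haploid", "diploid"):
        for _ in range(n_per_class):
            gamete = sperm_gamete(parents.father, kind, seed=rng)
            prof = simulate_bin_depth(gamete, SPERM_BIN_SIZE, noise,
                                      seed=rng)
            alleles = simulate_allele_counts(gamete, parents, ALLELE_DEPTH,
                                             noise, seed=rng)
            result = pipeline.analyze_sperm(prof, alleles, r_diploid,
                                            reference=reference)
            total += 1
            correct += result.ploidy.label == kind
    return {"accuracy": correct / total, "n_cells": total}


def carrier_screen_study(n_carriers: int = 20, n_samples: int = 109,
                         seed: int = 0) -> dict:
    """Run the variant filter chain on a synthetic annotated cohort table.

    The cohort holds ``n_carriers`` true carriers (13 homozygous, the rest
    with two rare heterozygous variants in one panel gene) among samples
    whose remaining variants all fail at least one gate; returns the
    carrier rate recomputed by the screening pipeline.
    """
    import itertools

    rng = np.random.default_rng(seed)
    positions = itertools.count(1_000_000, 17)  # unique variant positions
    panel_genes = frozenset({"SPO11", "MEI1", "REC114", "ANKRD31", "DMC1",
                             "CNTD1", "MLH3", "SYCE1", "SYCP2", "MEIKIN"})
    genes = sorted(panel_genes)
    rows = []
    n_hom = min(13, n_carriers)
    for i in range(n_samples):
        sample = f"S{i:03d}"
        if i < n_hom:  # homozygous carriers
            rows.append(_variant_row(sample, genes[i % len(genes)],
                                     "nonsynonymous-SNV", "hom", positions))
        elif i < n_carriers:  # potential compound-het carriers
            gene = genes[i % len(genes)]
            rows.append(_variant_row(sample, gene, "stopgain", "het",
                                     positions))
            rows.append(_variant_row(sample, gene, "frameshift-indel",
                                     "het", positions))
        # everyone also carries variants that must be filtered out
        rows.append(_variant_row(sample, "TTN", "nonsynonymous-SNV",
                                 "hom", positions))            # off panel
        rows.append(_variant_row(sample, genes[0], "synonymous",
                                 "hom", positions))            # silent
        rows.append(_variant_row(sample, genes[1], "nonsynonymous-SNV",
                                 "het", positions, freq=0.05))  # common
    table = pd.DataFrame(rows)
    surviving = variantscreen.filter_variants(table, panel_genes)
    carriers = variantscreen.detect_carriers(surviving)
    return {"carrier_rate_percent":
            variantscreen.carrier_rate(carriers, n_samples),
            "n_samples": n_samples,
            "n_carrier_samples": int(carriers["sample"].nunique())
            if len(carriers) else 0}


def _variant_row(sample, gene, effect, zygosity, positions, freq=0.0):
    pos = next(positions)
    return {"sample": sample, "gene": gene, "effect": effect,
            "zygosity": zygosity, "gnomad": freq, "exac": freq,
            "chrom": "22", "pos": pos, "ref": "C", "alt": "T"}
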
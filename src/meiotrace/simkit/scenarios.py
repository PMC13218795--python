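"""Scenario presets and the YAML-driven simulation entry point.

The presets encode the cell populations this pipeline is built to
recognize: normal haploid sperm, whole-genome diploid sperm (as seen in
macrocephalic heads), simple and complex aneuploid sperm (microcephalic
heads), and embryos carrying meiotic-origin whole-chromosome abnormalities
plus optional mitotic mosaic or segmental events.  The two sperm presets
are phenomenological — the pipeline makes no mechanistic claim about why a
given head morphology carries a given karyotype.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ..containers import BinnedDepthProfile
from ..genome import Genome
from .embryo import EmbryoTruth, MosaicEvent, form_embryo
from .meiosis import GameteKaryotype, simulate_gamete
from .noise import NoiseModel
from .observe import simulate_allele_counts, simulate_bin_depth
from .panel import Haplotypes, ParentalGenotypes, SnpPanel, simulate_parents
from . import io as sim_io

# Simulation defaults: a 1/100-scale hg19-like genome keeps whole-genome
# runs cheap while leaving every chromosome with enough 10/20-kb bins for
# median-based calling.
DEFAULT_GENOME_SCALE = 0.01
EMBRYO_BIN_SIZE = 10_000
SPERM_BIN_SIZE = 20_000
DEFAULT_ALLELE_DEPTH = 30.0

SPERM_CLASSES = ("haploid", "diploid", "aneuploid-simple", "aneuploid-complex")


def sperm_gamete(parent: Haplotypes, kind: str, seed=0) -> GameteKaryotype:
    """Draw a single sperm of a given ploidy class.

    Aneuploid classes place MI/MII errors on 1-2 (simple) or 3-8 (complex)
    random autosomes; each errored chromosome ends up disomic or nullisomic
    with equal probability.
    """
    rng = np.random.default_rng(seed)
    autosomes = [c for c in parent.panel.chromosomes() if c not in ("X", "Y")]
    if kind == "haploid":
        return simulate_gamete(parent, seed=rng)
    if kind == "diploid":
        return simulate_gamete(parent, whole_genome_diploid=True, seed=rng)
    if kind == "aneuploid-simple":
        n_err = int(rng.integers(1, 3))
    elif kind == "aneuploid-complex":
        n_err = int(rng.integers(3, 9))
    else:
        raise ValueError(f"unknown sperm class {kind!r}; "
                         f"expected one of {SPERM_CLASSES}")
    chroms = rng.choice(autosomes, size=n_err, replace=False)
    errors = {c: str(rng.choice(["MI", "MII"])) for c in chroms}
    return simulate_gamete(parent, error_spec=errors, seed=rng)


def gamete_with_copy_number(parent: Haplotypes, chrom: str, copies: int,
                            error: str = "MI", seed=0,
                            recomb_rate: int = 1) -> GameteKaryotype:
    """A gamete guaranteed disomic (copies=2) or nullisomic (0) for one chromosome.

    Retries the meiosis with fresh product draws until the requested product
    is transmitted (each tetrad always contains both outcomes).
    """
    from .meiosis import simulate_tetrad

    rng = np.random.default_rng(seed)
    tetrad = simulate_tetrad(parent, error_spec={chrom: error},
                             recomb_rate=recomb_rate, seed=rng)
    candidates = [g for g in tetrad if g.copy_number(chrom) == copies]
    if not candidates:
        raise ValueError(f"no tetrad product with {copies} copies of {chrom}")
    return candidates[rng.integers(len(candidates))]


def reference_depth_profile(parent: Haplotypes, noise: NoiseModel,
                            bin_size: int, baseline: str = "haploid",
                            n_cells: int = 8, seed=0) -> BinnedDepthProfile:
    """Average depth profile of unremarkable cells, for ratio calibration.

    Haploid baseline averages error-free gametes; diploid baseline averages
    embryos formed from two error-free gametes of the same parent (only bin
    geometry and GC structure matter for the reference).
    """
    rng = np.random.default_rng(seed)
    acc = None
    for _ in range(n_cells):
        g = simulate_gamete(parent, seed=rng)
        if baseline == "diploid":
            g2 = simulate_gamete(parent, seed=rng)
            cell = form_embryo(g, g2, seed=rng)
        else:
            cell = g
        prof = simulate_bin_depth(cell, bin_size, noise, seed=rng)
        acc = prof.bins["count"].to_numpy(dtype=float) if acc is None \
            else acc + prof.bins["count"].to_numpy(dtype=float)
        bins = prof.bins
    bins = bins.assign(count=acc / n_cells)
    return BinnedDepthProfile(bins=bins, baseline=baseline)


def diploid_reference_alleles(parents: ParentalGenotypes, depth: float,
                              noise: NoiseModel, seed=0):
    """Allele counts of a diploid reference cell (two error-free gametes)."""
    rng = np.random.default_rng(seed)
    egg = simulate_gamete(parents.mother, seed=rng)
    sperm = simulate_gamete(parents.father, seed=rng)
    embryo = form_embryo(sperm, egg, seed=rng)
    return simulate_allele_counts(embryo, parents, depth, noise, seed=rng)


def _mosaic_from_cfg(items, genome: Genome) -> list[MosaicEvent]:
    events = []
    for it in items or []:
        chrom = str(it["chrom"])
        start = int(it.get("start", 0))
        end = int(it.get("end", genome.lengths[chrom]))
        events.append(MosaicEvent(chrom=chrom, start=start, end=end,
                                  delta=int(it["delta"]),
                                  parent=it["parent"],
                                  fraction=float(it.get("fraction", 1.0))))
    return events


def run_scenario(config: dict, seed: int, outdir) -> dict:
    """Generate a full synthetic dataset from a scenario mapping.

    Writes parents.vcf plus per-cell bins/alleles/truth TSVs under
    ``outdir`` and returns a manifest of what was written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    genome = Genome.hg19_like(
        scale=float(config.get("genome_scale", DEFAULT_GENOME_SCALE)))
    pcfg = config.get("panel", {})
    panel = SnpPanel.random(genome,
                            loci_per_chrom=int(pcfg.get("loci_per_chrom", 200)),
                            b_freq=pcfg.get("b_freq", 0.5),
                            seed=rng.integers(2**31))
    noise = NoiseModel(**(config.get("noise") or {}))
    depth = float(config.get("allele_depth", DEFAULT_ALLELE_DEPTH))
    parents = simulate_parents(panel, seed=rng.integers(2**31))
    sim_io.write_parental_vcf(parents, outdir / "parents.vcf")
    manifest = {"parents": "parents.vcf", "cells": []}

    for cfg in config.get("embryos", []) or []:
        cid = str(cfg["id"])
        egg = simulate_gamete(parents.mother,
                              error_spec=cfg.get("egg_errors"),
                              seed=rng.integers(2**31))
        sperm = simulate_gamete(parents.father,
                                error_spec=cfg.get("sperm_errors"),
                                seed=rng.integers(2**31))
        truth = form_embryo(sperm, egg,
                            mosaic_events=_mosaic_from_cfg(
                                cfg.get("mosaic"), genome),
                            seed=rng.integers(2**31))
        _write_cell(truth, parents, cid, outdir, noise, depth,
                    int(config.get("embryo_bin_size", EMBRYO_BIN_SIZE)), rng)
        manifest["cells"].append({"id": cid, "kind": "embryo"})

    for cfg in config.get("sperm", []) or []:
        cid = str(cfg["id"])
        gamete = sperm_gamete(parents.father, cfg.get("kind", "haploid"),
                              seed=rng.integers(2**31))
        _write_cell(gamete, parents, cid, outdir, noise, depth,
                    int(config.get("sperm_bin_size", SPERM_BIN_SIZE)), rng)
        manifest["cells"].append({"id": cid, "kind": "sperm"})
    return manifest


def _write_cell(truth, parents, cid, outdir, noise, depth, bin_size, rng):
    prof = simulate_bin_depth(truth, bin_size, noise,
                              seed=rng.integers(2**31))
    prof.to_tsv(outdir / f"{cid}.bins.tsv")
    alleles = simulate_allele_counts(truth, parents, depth, noise,
                                     seed=rng.integers(2**31))
    alleles.to_tsv(outdir / f"{cid}.alleles.tsv")
    if isinstance(truth, EmbryoTruth):
        sim_io.write_truth_tsv(truth, outdir / f"{cid}.truth.tsv")
    else:
        truth.karyotype_frame().to_csv(outdir / f"{cid}.truth.tsv",
                                       sep="\t", index=False)
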
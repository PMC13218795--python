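"""Sequencing observables: binned read depth and SNP allele counts.

Both observation models are driven by a :class:`~meiotrace.simkit.noise.NoiseModel`
and a seed, and are deterministic given both.  Bin counts are drawn from a
negative binomial whose mean is proportional to the *absolute* local copy
number (total library yield scales with input DNA), which is what lets a
uniformly diploid sperm stand out against a haploid reference profile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..containers import AlleleCountTable, BinnedDepthProfile
from .embryo import EmbryoTruth
from .noise import NoiseModel
from .panel import ParentalGenotypes


def _local_copies(truth, chrom: str, mids: np.ndarray) -> np.ndarray:
    """Mean copy number at bin midpoints, mosaic events included."""
    if isinstance(truth, EmbryoTruth):
        base = float(truth.copy_number(chrom))
        copies = np.full(mids.shape, base)
        for ev in truth.events:
            if ev.chrom != chrom:
                continue
            mask = (mids >= ev.start) & (mids < ev.end)
            copies[mask] += ev.fraction * ev.delta
        return np.maximum(copies, 0.0)
    return np.full(mids.shape, float(truth.copy_number(chrom)))


def simulate_bin_depth(truth, bin_size: int, noise: NoiseModel,
                       seed=0) -> BinnedDepthProfile:
    """Binned read counts for an embryo truth or a gamete.

    The expected count of a bin is
    ``reads_per_bin * (local copies / baseline copies) * GC efficiency``,
    with GC efficiency normalized to mean 1 genome-wide; counts are negative
    binomial with the model's dispersion.  Baseline is diploid for embryos
    and haploid for gametes.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rng = np.random.default_rng(seed)
    genome = truth.genome
    baseline = "diploid" if isinstance(truth, EmbryoTruth) else "haploid"
    baseline_copies = 2.0 if baseline == "diploid" else 1.0

    bins = genome.bins(bin_size)
    mids = ((bins["start"] + bins["end"]) // 2).to_numpy()
    gc = np.concatenate([
        genome.gc_at(chrom, mids[bins["chrom"].to_numpy() == chrom])
        for chrom in genome.chromosomes])
    eff = noise.gc_efficiency(gc)
    eff = eff / eff.mean()

    copies = np.concatenate([
        _local_copies(truth, chrom,
                      mids[bins["chrom"].to_numpy() == chrom])
        for chrom in genome.chromosomes])
    mean = noise.reads_per_bin * (copies / baseline_copies) * eff
    bins = bins.assign(gc=gc, count=noise.draw_counts(mean, rng))
    return BinnedDepthProfile(bins=bins, baseline=baseline)


def _allele_pool(truth, chrom: str, pos: np.ndarray):
    """Allele matrix and clone-fraction weights for one chromosome.

    Returns (A, W): A is (copies x loci) in {0,1}; W the matching weight
    matrix before allele dropout (constitutive copies weigh 1; mosaic gains
    contribute an extra row with weight f on the event span; mosaic losses
    down-weight the lost copy to 1 - f there).
    """
    if isinstance(truth, EmbryoTruth):
        rows = [a for a in truth.maternal[chrom]] + \
               [a for a in truth.paternal[chrom]]
        n_mat = len(truth.maternal[chrom])
        W_rows = [np.ones(len(pos)) for _ in rows]
        for ev in truth.events:
            if ev.chrom != chrom:
                continue
            mask = (pos >= ev.start) & (pos < ev.end)
            idx = ev.source_index + (0 if ev.parent == "maternal" else n_mat)
            if ev.delta > 0:
                extra_w = np.zeros(len(pos))
                extra_w[mask] = ev.fraction * ev.delta
                rows.append(rows[idx])
                W_rows.append(extra_w)
            else:
                W_rows[idx] = W_rows[idx].copy()
                W_rows[idx][mask] = np.maximum(
                    W_rows[idx][mask] + ev.fraction * ev.delta, 0.0)
    else:
        rows = list(truth.copies[chrom])
        W_rows = [np.ones(len(pos)) for _ in rows]
    if not rows:
        return (np.zeros((0, len(pos)), dtype=np.uint8),
                np.zeros((0, len(pos))))
    return np.vstack(rows), np.vstack(W_rows)


def simulate_allele_counts(truth, parents: ParentalGenotypes,
                           depth: float, noise: NoiseModel,
                           seed=0) -> AlleleCountTable:
    """Per-SNP ref/alt read counts for an embryo or a single gamete.

    Reads at each locus are drawn from the cell's allele pool: each genomic
    copy contributes alleles in proportion to its clone fraction, allele
    dropout silences each copy at each locus independently with probability
    ``noise.ado_rate``, per-read error flips alleles with probability
    ``noise.seq_error``, and the read total is Poisson(``depth``).  Loci with
    no amplifiable material yield zero reads.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    panel = truth.panel
    if parents.panel.n_loci != panel.n_loci:
        raise ValueError("parents and truth must share one SNP panel")

    father_gt = parents.father.genotypes()
    mother_gt = parents.mother.genotypes()
    alt = np.zeros(panel.n_loci, dtype=np.int64)
    ref = np.zeros(panel.n_loci, dtype=np.int64)
    for chrom in panel.chromosomes():
        sl = panel.chrom_slice(chrom)
        pos = panel.pos[sl]
        A, W = _allele_pool(truth, chrom, pos)
        if A.shape[0]:
            keep = rng.random(W.shape) >= noise.ado_rate
            W = W * keep
        total_w = W.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_b = np.where(total_w > 0, (W * A).sum(axis=0) / total_w, 0.0)
        p_read = p_b * (1 - noise.seq_error) + (1 - p_b) * noise.seq_error
        n = rng.poisson(depth, size=len(pos))
        n = np.where(total_w > 0, n, 0)
        a = rng.binomial(n, p_read)
        alt[sl] = a
        ref[sl] = n - a
    df = pd.DataFrame({
        "chrom": panel.chrom, "pos": panel.pos,
        "ref_count": ref, "alt_count": alt,
        "father_gt": father_gt, "mother_gt": mother_gt,
    })
    return AlleleCountTable(df=df)
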
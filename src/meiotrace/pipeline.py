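"""High-level per-cell analysis pipelines tying the modules together."""

from __future__ import annotations

from dataclasses import dataclass

from . import depthcnv, origin, spermploidy
from .containers import AlleleCountTable, BinnedDepthProfile


@dataclass
class EmbryoAnalysis:
    cn: depthcnv.CopyNumberProfile
    embryo_class: depthcnv.EmbryoClass
    origin_calls: list[origin.OriginCall]


def analyze_embryo(profile: BinnedDepthProfile,
                   alleles: AlleleCountTable | None = None,
                   reference: BinnedDepthProfile | None = None,
                   min_segment_bp: int = 10_000_000,
                   parents=None) -> EmbryoAnalysis:
    """Normalize, call CNVs, classify, and (if allele data) assign origins."""
    norm = depthcnv.gc_normalize(profile)
    cn = depthcnv.copy_ratio_profile(norm, reference=reference)
    cn = depthcnv.call_chromosome_cnvs(cn)
    cn = depthcnv.call_segmental_cnvs(cn, min_len_bp=min_segment_bp)
    cls = depthcnv.classify_embryo(cn)
    calls: list[origin.OriginCall] = []
    if alleles is not None and cn.aneuploid_chromosomes():
        calls = origin.call_origins(cn, alleles, parents=parents)
    return EmbryoAnalysis(cn=cn, embryo_class=cls, origin_calls=calls)


@dataclass
class SpermAnalysis:
    cn: depthcnv.CopyNumberProfile
    hi: spermploidy.HIResult
    ploidy: spermploidy.PloidyCall


def analyze_sperm(profile: BinnedDepthProfile, alleles: AlleleCountTable,
                  r_diploid: float,
                  reference: BinnedDepthProfile | None = None) -> SpermAnalysis:
    """Haploid-baseline CNV calling + heterozygosity index -> ploidy call.

    ``r_diploid`` is the heterozygous-call rate of a diploid reference cell
    measured over the same panel with the same thresholds.
    """
    norm = depthcnv.gc_normalize(profile)
    cn = depthcnv.copy_ratio_profile(norm, reference=reference)
    cn = depthcnv.call_chromosome_cnvs(cn)
    hi = spermploidy.heterozygosity_index(
        spermploidy.het_rate(alleles), r_diploid)
    return SpermAnalysis(cn=cn, hi=hi,
                         ploidy=spermploidy.call_ploidy(cn, hi))
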
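"""Single-sperm ploidy calling and FISH-style aneuploidy frequencies.

Ploidy integrates two evidence lines:

* the CNV profile on a haploid baseline (flat at 1 = haploid; uniformly
  doubled = diploid; isolated events = aneuploidy), and
* the heterozygosity index HI = log2(R_sample / R_diploid), where R is the
  heterozygous-call rate over the SNP panel.  HI ≈ 0 indicates balanced
  heterozygosity (diploid), HI ≈ -1 genome-wide homozygosity (haploid).

When the two disagree, the CNV profile takes precedence provided enough of
the genome supports it; otherwise the call is ambiguous with both evidence
lines reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AlleleCountTable
from .depthcnv import STATUS_ANEUPLOID, CopyNumberProfile

HI_FLOOR = 1e-4           # rate floor keeping HI finite on error-free haploids
HI_HAPLOID_MAX = -0.7     # HI at or below this is haploid-like
HI_DIPLOID_BAND = 0.3     # |HI| within this is diploid-like

PLOIDY_CLASSES = ("haploid", "diploid", "aneuploid-simple",
                  "aneuploid-complex", "ambiguous")


@dataclass(frozen=True)
class HIResult:
    """Heterozygosity index with a clamping flag for degenerate samples."""

    value: float
    r_sample: float
    r_diploid: float
    clamped: bool = False

    def __float__(self) -> float:
        return self.value


def heterozygosity_index(r_sample: float, r_diploid: float,
                         floor: float = HI_FLOOR) -> HIResult:
    """HI = log2(R_sample / R_diploid).

    ``r_diploid`` must be positive; an ``r_sample`` below ``floor`` (e.g. 0
    on an error-free haploid) is clamped to the floor and flagged.
    """
    if not 0.0 <= r_sample <= 1.0 or not 0.0 <= r_diploid <= 1.0:
        raise ValueError("heterozygosity rates must lie in [0, 1]")
    if r_diploid <= 0:
        raise ValueError("invalid reference: R_diploid must be > 0")
    clamped = r_sample < floor
    eff = max(r_sample, floor)
    return HIResult(value=float(np.log2(eff / r_diploid)),
                    r_sample=r_sample, r_diploid=r_diploid, clamped=clamped)


def het_rate(allele_counts: AlleleCountTable, min_depth: int = 10,
             het_band: tuple[float, float] = (0.2, 0.8)) -> float:
    """Fraction of assessable loci called heterozygous.

    A locus is assessable if its depth is at least ``min_depth``; it is
    called heterozygous if its minor-allele read fraction lies within
    ``het_band`` (inclusive).
    """
    if len(allele_counts) == 0:
        raise ValueError("allele table is empty")
    depth = allele_counts.depth
    assessed = depth >= min_depth
    n = int(assessed.sum())
    if n == 0:
        raise ValueError("no loci meet the depth requirement")
    minor = np.minimum(allele_counts.df["ref_count"].to_numpy()[assessed],
                       allele_counts.df["alt_count"].to_numpy()[assessed])
    frac = minor / depth[assessed]
    het = (frac >= het_band[0]) & (frac <= het_band[1])
    return float(het.mean())


@dataclass
class PloidyCall:
    label: str
    hi: HIResult
    n_events: int
    event_chroms: list[str] = field(default_factory=list)
    note: str = ""


def call_ploidy(cn: CopyNumberProfile, hi: HIResult | float,
                hi_haploid_max: float = HI_HAPLOID_MAX,
                hi_diploid_band: float = HI_DIPLOID_BAND,
                cnv_support: float = 0.8) -> PloidyCall:
    """Integrate a haploid-baseline CNV profile with the HI.

    Decision rules (autosomes only; a sperm carries X or Y but not both):

    * flat profile at copy 1 and HI <= ``hi_haploid_max``  -> haploid
    * all autosomes doubled and |HI| <= ``hi_diploid_band`` -> diploid
    * isolated whole-chromosome events -> aneuploid-simple (1-2) or
      aneuploid-complex (>= 3)
    * conflicting evidence -> CNV wins if >= ``cnv_support`` of autosomes
      back its reading, else ambiguous.
    """
    if cn.baseline != "haploid":
        raise ValueError("sperm ploidy calling expects a haploid baseline")
    hi = hi if isinstance(hi, HIResult) else HIResult(float(hi), np.nan, np.nan)
    auto_calls = [c for c in cn.chromosome_calls if c.chrom not in ("X", "Y")]
    events = [c for c in auto_calls
              if c.event != "none" and c.status == STATUS_ANEUPLOID]
    n_auto = max(len(auto_calls), 1)
    doubled = [c for c in auto_calls
               if c.event == "gain" and c.status == STATUS_ANEUPLOID]
    flat = [c for c in auto_calls if c.event == "none"]
    frac_doubled = len(doubled) / n_auto
    frac_flat = len(flat) / n_auto
    event_chroms = [c.chrom for c in events]

    hi_haploid = hi.value <= hi_haploid_max
    hi_diploid = abs(hi.value) <= hi_diploid_band

    if frac_flat >= cnv_support and hi_haploid and not events:
        return PloidyCall("haploid", hi, 0)
    if frac_doubled >= cnv_support and hi_diploid:
        return PloidyCall("diploid", hi, 0)
    if frac_doubled >= cnv_support:
        return PloidyCall("diploid", hi, 0,
                          note=f"CNV uniformly doubled but HI={hi.value:.2f}; "
                               "CNV precedence")
    if events:
        label = "aneuploid-complex" if len(events) >= 3 else "aneuploid-simple"
        return PloidyCall(label, hi, len(events), event_chroms)
    if frac_flat >= cnv_support and not hi_haploid:
        return PloidyCall("ambiguous", hi, 0,
                          note="flat haploid CNV but HI not haploid-like")
    return PloidyCall("ambiguous", hi, len(events), event_chroms,
                      note="no decision rule satisfied")


@dataclass
class FishCounts:
    """Tabulated FISH signal counts for one probe set.

    Disomy = two signals for a given chromosome, nullisomy = no signal,
    diploidy = two signals for every chromosome in the probe set.
    """

    probe_set: str
    total: int
    disomy: dict[str, int]
    nullisomy: dict[str, int]
    diploidy: int = 0

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total analyzable nuclei must be positive")
        for name, table in (("disomy", self.disomy),
                            ("nullisomy", self.nullisomy)):
            for chrom, count in table.items():
                if not 0 <= count <= self.total:
                    raise ValueError(
                        f"{name} count for chrom {chrom} exceeds total")
        if not 0 <= self.diploidy <= self.total:
            raise ValueError("diploidy count exceeds total")


def fish_frequencies(counts: FishCounts) -> pd.DataFrame:
    """Abnormality frequencies as percentages of analyzable nuclei."""
    rows = []
    for chrom in counts.disomy:
        rows.append({"probe_set": counts.probe_set, "category": "disomy",
                     "chrom": chrom, "count": counts.disomy[chrom]})
    for chrom in counts.nullisomy:
        rows.append({"probe_set": counts.probe_set, "category": "nullisomy",
                     "chrom": chrom, "count": counts.nullisomy[chrom]})
    rows.append({"probe_set": counts.probe_set, "category": "diploidy",
                 "chrom": None, "count": counts.diploidy})
    df = pd.DataFrame(rows)
    df["total"] = counts.total
    df["percent"] = 100.0 * df["count"] / counts.total
    return df
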
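"""Parental-origin assignment of embryonic copy-number events.

Uses informative SNPs — loci where the parents are homozygous for opposite
alleles: pattern AABB (father AA, mother BB) or BBAA (father BB, mother AA).
At such loci every read allele is attributable to one parent without
phasing.

Duplications: among heterozygous embryo calls, the mean B-allele frequency
inside the event region is compared with the non-CNV background by a
Z-test per pattern.  An extra maternal copy pushes AABB-locus BAF above 0.5
(the maternal allele there is B) and BBAA-locus BAF below 0.5; a maternal
duplication is called when Z_AABB > +z and Z_BBAA < -z (default z = 3), a
paternal duplication on the reversed pattern.

Losses: at AABB loci a paternal copy loss leaves only the maternal B allele
(embryo calls BB), a maternal loss only A.  Paternal loss is called when
the BB-call ratio exceeds 0.8, maternal when the AA ratio does; BBAA loci
serve as a symmetric, advisory confirmation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AlleleCountTable
from .depthcnv import CopyNumberProfile
from .simkit.panel import ParentalGenotypes

Z_THRESHOLD = 3.0
LOSS_RATIO_THRESHOLD = 0.8
MIN_INFORMATIVE = 20
MIN_BACKGROUND = 50

PATTERN_AABB = "AABB"   # father AA, mother BB
PATTERN_BBAA = "BBAA"   # father BB, mother AA


def call_genotype(baf: np.ndarray, depth: np.ndarray, min_depth: int = 10,
                  hom_ref_max: float = 0.1, hom_alt_min: float = 0.9,
                  het_band: tuple[float, float] = (0.2, 0.8)) -> np.ndarray:
    """Hard genotype calls from BAF: AA / AB / BB / no-call."""
    calls = np.full(len(baf), "no-call", dtype=object)
    ok = (depth >= min_depth) & ~np.isnan(baf)
    calls[ok & (baf < hom_ref_max)] = "AA"
    calls[ok & (baf > hom_alt_min)] = "BB"
    calls[ok & (baf >= het_band[0]) & (baf <= het_band[1])] = "AB"
    return calls


@dataclass
class InformativeMarkerSet:
    """Informative loci with embryo BAF and genotype calls.

    One row per locus; ``pattern`` in {AABB, BBAA}.
    """

    df: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.df)

    def in_region(self, chrom: str, start: int | None = None,
                  end: int | None = None) -> pd.DataFrame:
        sub = self.df[self.df["chrom"] == chrom]
        if start is not None:
            sub = sub[(sub["pos"] >= start) & (sub["pos"] < end)]
        return sub

    def outside_chromosomes(self, chroms) -> pd.DataFrame:
        return self.df[~self.df["chrom"].isin(set(chroms))]


def select_informative_snps(embryo: AlleleCountTable,
                            parents: ParentalGenotypes | pd.DataFrame | None = None,
                            min_depth: int = 10) -> InformativeMarkerSet:
    """Genome-wide informative-marker table.

    Parental genotypes default to the ``father_gt`` / ``mother_gt`` columns
    carried by the allele table; pass ``parents`` to override (either a
    ParentalGenotypes object or a frame with those columns).  Only loci
    where the parents are homozygous and discordant are retained.
    """
    df = embryo.df.copy()
    if parents is not None:
        pf = parents.to_frame() if isinstance(parents, ParentalGenotypes) else parents
        df = df.drop(columns=["father_gt", "mother_gt"]).merge(
            pf[["chrom", "pos", "father_gt", "mother_gt"]],
            on=["chrom", "pos"], how="inner")
        if len(df) == 0:
            raise ValueError("no overlap between embryo loci and parental genotypes")
    aabb = (df["father_gt"] == "AA") & (df["mother_gt"] == "BB")
    bbaa = (df["father_gt"] == "BB") & (df["mother_gt"] == "AA")
    df = df[aabb | bbaa].copy()
    df["pattern"] = np.where(df["father_gt"] == "AA", PATTERN_AABB,
                             PATTERN_BBAA)
    depth = (df["ref_count"] + df["alt_count"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        baf = np.where(depth > 0, df["alt_count"].to_numpy() / depth, np.nan)
    df["depth"] = depth.astype(int)
    df["baf"] = baf
    df["genotype"] = call_genotype(baf, depth, min_depth=min_depth)
    cols = ["chrom", "pos", "pattern", "depth", "baf", "genotype"]
    return InformativeMarkerSet(df=df[cols].reset_index(drop=True))


@dataclass
class OriginCall:
    chrom: str
    event: str                      # duplication / loss
    origin: str                     # maternal / paternal / undetermined
    z_aabb: float = np.nan
    z_bbaa: float = np.nan
    aa_ratio: float = np.nan
    bb_ratio: float = np.nan
    n_loci: int = 0
    note: str = ""


def baf_z_statistic(markers: InformativeMarkerSet, chrom: str,
                    background_chroms, min_informative: int = MIN_INFORMATIVE,
                    min_background: int = MIN_BACKGROUND) -> dict[str, float]:
    """Z-statistics of regional vs background AB-locus BAF, per pattern.

    Z = (mean regional BAF - mean background BAF) / (SD_background / sqrt(n));
    only loci with a heterozygous embryo call enter either side, and the
    background is restricted to chromosomes free of CNV calls.
    """
    region = markers.in_region(chrom)
    background = markers.df[markers.df["chrom"].isin(set(background_chroms))]
    reg_ab = region[region["genotype"] == "AB"]
    bg_ab = background[background["genotype"] == "AB"]
    if len(reg_ab) < min_informative:
        raise ValueError(
            f"chrom {chrom}: {len(reg_ab)} AB-call informative loci "
            f"(< {min_informative})")
    if len(bg_ab) < min_background:
        raise ValueError(
            f"background has {len(bg_ab)} AB-call informative loci "
            f"(< {min_background})")
    out: dict[str, float] = {}
    per_pattern_min = max(3, min_informative // 4)
    for pattern in (PATTERN_AABB, PATTERN_BBAA):
        reg = reg_ab[reg_ab["pattern"] == pattern]["baf"]
        bg = bg_ab[bg_ab["pattern"] == pattern]["baf"]
        if len(reg) < per_pattern_min or len(bg) < per_pattern_min:
            raise ValueError(
                f"chrom {chrom}: too few AB-call {pattern} loci")
        sd = float(bg.std(ddof=1))
        if sd == 0:
            raise ValueError("zero BAF variance in background loci")
        out[pattern] = float((reg.mean() - bg.mean()) / (sd / np.sqrt(len(reg))))
        out[f"n_{pattern}"] = len(reg)
        out[f"mean_{pattern}"] = float(reg.mean())
    return out


def duplication_origin(chrom: str, z_aabb: float, z_bbaa: float,
                       n_loci: int = 0,
                       z_threshold: float = Z_THRESHOLD) -> OriginCall:
    """Apply the concurrent-shift rule to a gain region's Z pair."""
    if z_aabb > z_threshold and z_bbaa < -z_threshold:
        origin = "maternal"
    elif z_aabb < -z_threshold and z_bbaa > z_threshold:
        origin = "paternal"
    else:
        origin = "undetermined"
    return OriginCall(chrom=chrom, event="duplication", origin=origin,
                      z_aabb=z_aabb, z_bbaa=z_bbaa, n_loci=n_loci)


def loss_origin(markers: InformativeMarkerSet, chrom: str,
                ratio_threshold: float = LOSS_RATIO_THRESHOLD,
                min_informative: int = MIN_INFORMATIVE) -> OriginCall:
    """Genotype-ratio rule for a loss region.

    Computed over AABB loci with a genotype call in the region; BBAA loci
    are evaluated symmetrically as an advisory confirmation (reported in the
    note, never blocking).
    """
    region = markers.in_region(chrom)
    aabb = region[(region["pattern"] == PATTERN_AABB)
                  & (region["genotype"] != "no-call")]
    if len(aabb) < min_informative:
        return OriginCall(chrom=chrom, event="loss", origin="undetermined",
                          n_loci=len(aabb),
                          note=f"only {len(aabb)} callable AABB loci")
    aa_ratio = float((aabb["genotype"] == "AA").mean())
    bb_ratio = float((aabb["genotype"] == "BB").mean())
    if bb_ratio > ratio_threshold:
        origin = "paternal"   # only the maternal (B) allele remains
    elif aa_ratio > ratio_threshold:
        origin = "maternal"   # only the paternal (A) allele remains
    else:
        origin = "undetermined"
    note = ""
    bbaa = region[(region["pattern"] == PATTERN_BBAA)
                  & (region["genotype"] != "no-call")]
    if len(bbaa) >= min_informative and origin != "undetermined":
        confirm = "AA" if origin == "paternal" else "BB"
        rate = float((bbaa["genotype"] == confirm).mean())
        agrees = rate > ratio_threshold
        note = (f"BBAA confirmation {'agrees' if agrees else 'disagrees'} "
                f"({confirm}-ratio {rate:.2f})")
    return OriginCall(chrom=chrom, event="loss", origin=origin,
                      aa_ratio=aa_ratio, bb_ratio=bb_ratio,
                      n_loci=len(aabb), note=note)


def _events_from_cn(cn: CopyNumberProfile) -> list[tuple[str, str]]:
    return [(c.chrom, "duplication" if c.event == "gain" else "loss")
            for c in cn.aneuploid_chromosomes()]


def call_origins(events, embryo: AlleleCountTable,
                 parents: ParentalGenotypes | pd.DataFrame | None = None,
                 background_chroms=None,
                 min_informative: int = MIN_INFORMATIVE,
                 z_threshold: float = Z_THRESHOLD) -> list[OriginCall]:
    """Assign parental origin to every whole-chromosome aneuploid event.

    ``events`` is either a CopyNumberProfile with populated calls or an
    explicit list of ``(chrom, "duplication"|"loss")`` pairs.  The Z-test
    background defaults to all chromosomes not carrying an event.
    """
    if isinstance(events, CopyNumberProfile):
        event_list = _events_from_cn(events)
    else:
        event_list = [(str(c), e) for c, e in events]
    markers = select_informative_snps(embryo, parents=parents)
    if len(markers) == 0:
        raise ValueError("no informative loci available")
    event_chroms = {c for c, _ in event_list}
    if background_chroms is None:
        background_chroms = [c for c in dict.fromkeys(markers.df["chrom"])
                             if c not in event_chroms]
    calls: list[OriginCall] = []
    for chrom, event in event_list:
        region = markers.in_region(chrom)
        if len(region) < min_informative:
            calls.append(OriginCall(chrom=chrom, event=event,
                                    origin="undetermined",
                                    n_loci=len(region),
                                    note="region unanalyzable: "
                                         f"{len(region)} informative loci"))
            continue
        if event == "duplication":
            try:
                z = baf_z_statistic(markers, chrom, background_chroms,
                                    min_informative=min_informative)
            except ValueError as exc:
                calls.append(OriginCall(chrom=chrom, event=event,
                                        origin="undetermined",
                                        n_loci=len(region), note=str(exc)))
                continue
            call = duplication_origin(chrom, z[PATTERN_AABB], z[PATTERN_BBAA],
                                      n_loci=z["n_AABB"] + z["n_BBAA"],
                                      z_threshold=z_threshold)
        else:
            call = loss_origin(markers, chrom,
                               min_informative=min_informative)
        calls.append(call)
    return calls


def origin_summary(calls: list[OriginCall]) -> dict[str, int]:
    """Per-embryo tally of maternal / paternal / undetermined events."""
    return {
        "maternal": sum(c.origin == "maternal" for c in calls),
        "paternal": sum(c.origin == "paternal" for c in calls),
        "undetermined": sum(c.origin == "undetermined" for c in calls),
    }


def calls_frame(calls: list[OriginCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": c.chrom, "event": c.event, "origin": c.origin,
        "Z_AABB": c.z_aabb, "Z_BBAA": c.z_bbaa,
        "AA_ratio": c.aa_ratio, "BB_ratio": c.bb_ratio,
        "n_loci": c.n_loci, "note": c.note,
    } for c in calls])
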
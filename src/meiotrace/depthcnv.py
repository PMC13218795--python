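"""Copy-number inference from binned read depth.

Pipeline: GC normalization (LOESS of count on GC), copy-ratio computation
against a reference level, chromosome-level event calling with an
abnormal-cell-fraction estimate f̂, run-length segmental calling, and the
euploid / mosaic / aneuploid classification:

* f̂ < 0.30           -> euploid (no event reported)
* 0.30 <= f̂ <= 0.70  -> mosaic
* f̂ > 0.70           -> aneuploid

Embryos are then classed E / SA / CA / other: SA = 1-2 whole-chromosome
aneuploid events, CA = >= 3, "other" = only mosaic or segmental findings.
The f̂ estimator assumes single-copy events (|Δcopy| = 1); clearly
multi-copy chromosomes (ratio beyond ``multicopy_ratio``) are reported with
an integer copy estimate and f̂ = 1 instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import BinnedDepthProfile

EUPLOID_MAX_FRACTION = 0.30   # f̂ below this -> euploid
MOSAIC_MAX_FRACTION = 0.70    # f̂ above this -> aneuploid

STATUS_EUPLOID = "euploid"
STATUS_MOSAIC = "mosaic"
STATUS_ANEUPLOID = "aneuploid"

SEX_CHROMS = ("X", "Y")


def status_from_fraction(f: float) -> str:
    """Map an abnormal-cell fraction estimate to the three-way status."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if f < EUPLOID_MAX_FRACTION:
        return STATUS_EUPLOID
    if f <= MOSAIC_MAX_FRACTION:
        return STATUS_MOSAIC
    return STATUS_ANEUPLOID


@dataclass
class ChromosomeCall:
    chrom: str
    event: str                 # gain / loss / none
    median_ratio: float
    fraction: float            # estimated abnormal-cell fraction f̂
    status: str
    copy_estimate: int | None = None
    consistency: float = 1.0   # share of bins deviating in the call direction
    note: str = ""


@dataclass
class SegmentCall:
    chrom: str
    start: int
    end: int
    event: str
    mean_ratio: float
    fraction: float
    status: str


@dataclass
class EmbryoClass:
    """E / SA / CA / other classification of one embryo."""
    whole_chrom_abnormalities: int
    label: str


@dataclass
class CopyNumberProfile:
    """Baseline-relative copy ratios plus event calls."""

    bins: pd.DataFrame = field(repr=False)  # chrom/start/end/gc/count/ratio
    baseline: str = "diploid"
    chromosome_calls: list[ChromosomeCall] = field(default_factory=list)
    segment_calls: list[SegmentCall] = field(default_factory=list)

    @property
    def baseline_copies(self) -> float:
        return 2.0 if self.baseline == "diploid" else 1.0

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    def chromosome_ratio(self, chrom: str) -> float:
        sub = self.bins.loc[self.bins["chrom"] == chrom, "ratio"]
        return float(sub.median())

    def aneuploid_chromosomes(self, include_sex: bool = False) -> list[ChromosomeCall]:
        calls = [c for c in self.chromosome_calls
                 if c.event != "none" and c.status == STATUS_ANEUPLOID]
        if not include_sex:
            calls = [c for c in calls if c.chrom not in SEX_CHROMS]
        return calls

    def calls_frame(self) -> pd.DataFrame:
        rows = [{"chrom": c.chrom, "start": 0, "end": -1, "type": "chromosome",
                 "event": c.event, "ratio": c.median_ratio, "f": c.fraction,
                 "status": c.status} for c in self.chromosome_calls]
        rows += [{"chrom": s.chrom, "start": s.start, "end": s.end,
                  "type": "segment", "event": s.event, "ratio": s.mean_ratio,
                  "f": s.fraction, "status": s.status}
                 for s in self.segment_calls]
        return pd.DataFrame(rows)


def gc_normalize(profile: BinnedDepthProfile, span: float = 0.3,
                 gc_bounds: tuple[float, float] = (0.3, 0.6),
                 min_bins: int = 200) -> BinnedDepthProfile:
    """Divide bin counts by a LOESS fit of count on GC fraction.

    Bins with GC outside ``gc_bounds`` or zero count are masked from the
    fit (but still normalized through the fitted curve).  Output is rescaled
    so the genome-wide median count is preserved.
    """
    bins = profile.bins
    if len(bins) < min_bins:
        raise ValueError(f"need at least {min_bins} bins for GC normalization")
    counts = bins["count"].to_numpy(dtype=float)
    gc = bins["gc"].to_numpy(dtype=float)
    if not counts.any():
        raise ValueError("all bin counts are zero")
    mask = (gc >= gc_bounds[0]) & (gc <= gc_bounds[1]) & (counts > 0)
    if mask.sum() < 10:
        raise ValueError("too few usable bins after GC/zero-count masking")
    if np.ptp(gc[mask]) < 1e-9:
        fitted_all = np.full_like(counts, np.median(counts[mask]))
    else:
        fit = lowess(counts[mask], gc[mask], frac=span, return_sorted=True)
        fitted_all = np.interp(gc, fit[:, 0], fit[:, 1])
    fitted_all = np.maximum(fitted_all, 1e-9)
    norm = counts / fitted_all
    scale = np.median(counts) / max(np.median(norm), 1e-12)
    out = bins.assign(count=norm * scale)
    return BinnedDepthProfile(bins=out, baseline=profile.baseline)


def copy_ratio_profile(profile: BinnedDepthProfile,
                       reference: BinnedDepthProfile | None = None
                       ) -> CopyNumberProfile:
    """Per-bin copy ratio on the profile's ploidy baseline.

    With a reference profile (same bin grid, comparable per-cell coverage)
    the ratio is ``baseline_copies * count / reference_count``, which keeps
    genome-wide ploidy shifts visible.  Without one, the cell's own median
    is the reference level, and a uniform ploidy shift cancels out — the
    heterozygosity index covers that case for sperm.
    """
    bins = profile.bins
    base = 2.0 if profile.baseline == "diploid" else 1.0
    counts = bins["count"].to_numpy(dtype=float)
    if reference is not None:
        rbins = reference.bins
        if len(rbins) != len(bins) or \
                not (rbins["chrom"].to_numpy() == bins["chrom"].to_numpy()).all() or \
                not (rbins["start"].to_numpy() == bins["start"].to_numpy()).all():
            raise ValueError("reference bins do not match profile bins")
        level = rbins["count"].to_numpy(dtype=float)
    else:
        level = np.full_like(counts, np.median(counts[counts > 0]))
    ok = level > 0
    ratio = np.full_like(counts, np.nan)
    ratio[ok] = base * counts[ok] / level[ok]
    return CopyNumberProfile(bins=bins.assign(ratio=ratio),
                             baseline=profile.baseline)


def call_chromosome_cnvs(cn: CopyNumberProfile, min_bins: int = 10,
                         consistency_threshold: float = 0.8,
                         multicopy_ratio: float = 3.5) -> CopyNumberProfile:
    """Populate whole-chromosome event calls.

    Per chromosome: f̂ = |median ratio - baseline| clipped to [0, 1]
    (single-copy-event assumption), direction from the deviation's sign,
    status from the 0.30/0.70 rule.  A whole-chromosome call additionally
    requires >= ``consistency_threshold`` of the chromosome's bins deviating
    in the call direction; otherwise the event is left to segmental calling.
    """
    base = cn.baseline_copies
    calls: list[ChromosomeCall] = []
    for chrom in cn.chromosomes():
        ratios = cn.bins.loc[cn.bins["chrom"] == chrom, "ratio"].dropna()
        if len(ratios) < min_bins:
            warnings.warn(f"chromosome {chrom}: only {len(ratios)} bins, "
                          "no whole-chromosome call", stacklevel=2)
            continue
        med = float(ratios.median())
        dev = med - base
        if cn.baseline == "diploid":
            is_multicopy = med >= multicopy_ratio
        else:
            is_multicopy = dev >= 1.5
        if is_multicopy:
            f = 1.0
            copy_est = int(round(med))
        else:
            f = min(abs(dev), 1.0)
            copy_est = None
        event = "none" if f < EUPLOID_MAX_FRACTION \
            else ("gain" if dev > 0 else "loss")
        consistency = 1.0
        note = ""
        if event != "none":
            signs = np.sign(ratios.to_numpy() - base)
            consistency = float((signs == np.sign(dev)).mean())
            if consistency < consistency_threshold:
                note = "inconsistent-direction: delegated to segmental calling"
                event, f = "none", min(abs(dev), 1.0)
                copy_est = None
        status = status_from_fraction(f) if event != "none" else STATUS_EUPLOID
        calls.append(ChromosomeCall(chrom=chrom, event=event, median_ratio=med,
                                    fraction=f, status=status,
                                    copy_estimate=copy_est,
                                    consistency=consistency, note=note))
    cn.chromosome_calls = calls
    return cn


def call_segmental_cnvs(cn: CopyNumberProfile, min_len_bp: int = 10_000_000,
                        smooth_window: int = 9) -> CopyNumberProfile:
    """Run-length thresholding for sub-chromosomal events.

    Per-bin ratios are first smoothed with a centered rolling median of
    ``smooth_window`` bins (run-length calling on raw low-coverage bins is
    broken by single-bin noise).  Maximal runs of consecutive bins whose
    smoothed ratio deviates from baseline by at least the euploid
    threshold, spanning >= ``min_len_bp``, become segmental calls.
    Chromosomes already carrying a whole-chromosome event call are skipped
    (precedence of the chromosome-level call).
    """
    base = cn.baseline_copies
    called = {c.chrom for c in cn.chromosome_calls if c.event != "none"}
    segments: list[SegmentCall] = []
    for chrom in cn.chromosomes():
        if chrom in called:
            continue
        sub = cn.bins[cn.bins["chrom"] == chrom]
        raw = sub["ratio"].astype(float)
        ratio = raw.rolling(smooth_window, center=True,
                            min_periods=1).median().to_numpy()
        dev = ratio - base
        state = np.where(np.isnan(dev), 0,
                         np.where(dev >= EUPLOID_MAX_FRACTION, 1,
                                  np.where(dev <= -EUPLOID_MAX_FRACTION, -1, 0)))
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        i = 0
        n = len(state)
        while i < n:
            if state[i] == 0:
                i += 1
                continue
            j = i
            while j < n and state[j] == state[i]:
                j += 1
            seg_len = ends[j - 1] - starts[i]
            if seg_len >= min_len_bp:
                seg_ratio = float(np.nanmean(ratio[i:j]))
                f = min(abs(seg_ratio - base), 1.0)
                segments.append(SegmentCall(
                    chrom=chrom, start=int(starts[i]), end=int(ends[j - 1]),
                    event="gain" if state[i] > 0 else "loss",
                    mean_ratio=seg_ratio, fraction=f,
                    status=status_from_fraction(f)))
            i = j
    cn.segment_calls = segments
    return cn


def classify_embryo(cn: CopyNumberProfile,
                    include_sex: bool = False) -> EmbryoClass:
    """E / SA / CA / other from the populated call set.

    Only whole-chromosome events with aneuploid status count toward SA/CA;
    whole-chromosome mosaic events and segmental events of any status put an
    otherwise-euploid embryo in "other".  Sex chromosomes are excluded from
    the count by default.
    """
    aneuploid = cn.aneuploid_chromosomes(include_sex=include_sex)
    n = len(aneuploid)
    if n >= 3:
        label = "CA"
    elif n >= 1:
        label = "SA"
    else:
        has_other = cn.segment_calls or any(
            c.event != "none" and c.status == STATUS_MOSAIC
            for c in cn.chromosome_calls)
        label = "other" if has_other else "E"
    return EmbryoClass(whole_chrom_abnormalities=n, label=label)
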
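"""Cohort-level aggregation of embryo classifications and group statistics.

Percentages are rounded half-up to one decimal, matching how such cohort
fractions are conventionally reported.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

EMBRYO_CLASSES = ("E", "SA", "CA", "other")


def percent(count: int, total: int, decimals: int = 1) -> float:
    """count/total as a percentage, rounded half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(100) * Decimal(count) / Decimal(total)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


@dataclass
class EmbryoRecord:
    """One embryo's classification for cohort aggregation."""

    couple_id: str
    embryo_id: str
    label: str                       # E / SA / CA / other
    abnormal_count: int = 0          # whole-chromosome abnormalities
    maternal_origin: int = 0
    paternal_origin: int = 0

    def __post_init__(self) -> None:
        if self.label not in EMBRYO_CLASSES:
            raise ValueError(f"label must be one of {EMBRYO_CLASSES}")
        if self.abnormal_count < 0:
            raise ValueError("abnormal_count must be non-negative")


def records_frame(records: list[EmbryoRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def records_from_tsv(path) -> list[EmbryoRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"couple_id": str, "embryo_id": str})
    return [EmbryoRecord(**row) for row in df.to_dict("records")]


def category_proportions(records: list[EmbryoRecord]) -> dict[str, float]:
    """Percentage of embryos per class, one decimal."""
    if not records:
        raise ValueError("no records")
    total = len(records)
    return {cls: percent(sum(r.label == cls for r in records), total)
            for cls in EMBRYO_CLASSES}


def couple_exclusivity(records: list[EmbryoRecord],
                       label: str = "CA") -> float:
    """Percentage of couples whose every embryo carries ``label``."""
    if not records:
        raise ValueError("no records")
    by_couple: dict[str, list[str]] = {}
    for r in records:
        by_couple.setdefault(r.couple_id, []).append(r.label)
    exclusive = sum(all(lb == label for lb in labels)
                    for labels in by_couple.values())
    return percent(exclusive, len(by_couple))


def abnormality_band(records: list[EmbryoRecord], lo: int, hi: int) -> float:
    """Percentage of aneuploid embryos (SA or CA) with count in [lo, hi]."""
    aneuploid = [r for r in records if r.label in ("SA", "CA")]
    if not aneuploid:
        raise ValueError("no aneuploid records")
    hit = sum(lo <= r.abnormal_count <= hi for r in aneuploid)
    return percent(hit, len(aneuploid))


def two_sample_ttest(group_a, group_b, welch: bool = False):
    """Classical unpaired two-tailed t-test (pooled variance by default).

    Identical constant groups return (0.0, 1.0) by convention; constant
    groups with different means raise (no valid test exists).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CohortSummary:
    n_embryos: int
    n_couples: int
    class_percent: dict[str, float]
    exclusive_ca_percent: float
    abnormality_band_percent: float | None
    origin_totals: dict[str, int]
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(records: list[EmbryoRecord], band: tuple[int, int] = (4, 15),
              config: dict | None = None) -> CohortSummary:
    """Aggregate embryo records into the standard cohort summary."""
    if not records:
        raise ValueError("no records")
    try:
        band_pct = abnormality_band(records, *band)
    except ValueError:
        band_pct = None
    return CohortSummary(
        n_embryos=len(records),
        n_couples=len({r.couple_id for r in records}),
        class_percent=category_proportions(records),
        exclusive_ca_percent=couple_exclusivity(records),
        abnormality_band_percent=band_pct,
        origin_totals={
            "maternal": sum(r.maternal_origin for r in records),
            "paternal": sum(r.paternal_origin for r in records),
        },
        config=config or {},
    )


def build_report(records: list[EmbryoRecord] | None = None,
                 records_path=None, fish_tables=None,
                 config: dict | None = None, out_path=None) -> dict:
    """Assemble the cohort report (JSON-serializable dict).

    Either ``records`` or ``records_path`` must be provided; a missing or
    unreadable records file raises an error naming the stage.
    """
    if records is None:
        if records_path is None:
            raise ValueError("missing input for stage 'records': provide "
                             "records or records_path")
        try:
            records = records_from_tsv(records_path)
        except FileNotFoundError as exc:
            raise FileNotFoundError(
                f"stage 'records': missing file {records_path}") from exc
    summary = summarize(records, config=config)
    report = {"cohort": summary.to_dict()}
    if fish_tables is not None:
        report["fish"] = [t.to_dict("records") if isinstance(t, pd.DataFrame)
                          else t for t in fish_tables]
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
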
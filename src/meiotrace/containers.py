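"""Shared tabular containers passed between simulation and inference.

Both are thin wrappers over a pandas DataFrame with a fixed schema and a
round-trippable TSV representation, so real data can enter the pipeline
through the same door as simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIN_COLUMNS = ("chrom", "start", "end", "gc", "count")
ALLELE_COLUMNS = ("chrom", "pos", "ref_count", "alt_count",
                  "father_gt", "mother_gt")

VALID_BASELINES = ("diploid", "haploid")


@dataclass
class BinnedDepthProfile:
    """Per-bin read counts (+ GC fraction) along the genome for one cell.

    ``baseline`` declares the expected ploidy of an unremarkable cell of
    this kind: "diploid" for embryo biopsies, "haploid" for single sperm.
    """

    bins: pd.DataFrame
    baseline: str = "diploid"

    def __post_init__(self) -> None:
        if self.baseline not in VALID_BASELINES:
            raise ValueError(f"baseline must be one of {VALID_BASELINES}")
        missing = set(BIN_COLUMNS) - set(self.bins.columns)
        if missing:
            raise ValueError(f"bin table missing columns: {sorted(missing)}")
        b = self.bins
        if (b["count"] < 0).any():
            raise ValueError("bin counts must be non-negative")
        if ((b["gc"] < 0) | (b["gc"] > 1)).any():
            raise ValueError("GC fractions must lie in [0, 1]")
        for _, sub in b.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (ends <= starts).any():
                raise ValueError("bins must have end > start")
            if (starts[1:] < ends[:-1]).any():
                raise ValueError("bins must be sorted and non-overlapping")

    @property
    def baseline_copies(self) -> int:
        return 2 if self.baseline == "diploid" else 1

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    def to_tsv(self, path) -> None:
        self.bins.to_csv(path, sep="\t", index=False,
                         columns=list(BIN_COLUMNS), float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, baseline: str = "diploid") -> "BinnedDepthProfile":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(bins=df, baseline=baseline)


@dataclass
class AlleleCountTable:
    """Per-SNP reference/alternate read counts plus parental genotypes.

    Genotypes are strings in {AA, AB, BB} where A is the reference and B the
    alternate allele.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(ALLELE_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(
                f"allele table missing columns: {sorted(missing)}")
        if ((self.df["ref_count"] < 0) | (self.df["alt_count"] < 0)).any():
            raise ValueError("allele counts must be non-negative")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def depth(self) -> np.ndarray:
        return (self.df["ref_count"] + self.df["alt_count"]).to_numpy()

    @property
    def baf(self) -> np.ndarray:
        """B-allele frequency per locus; NaN where depth is zero."""
        depth = self.depth.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(depth > 0,
                            self.df["alt_count"].to_numpy() / depth, np.nan)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False,
                       columns=list(ALLELE_COLUMNS))

    @classmethod
    def from_tsv(cls, path) -> "AlleleCountTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(df=df)
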
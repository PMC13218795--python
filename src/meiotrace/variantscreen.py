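"""Rare-variant filter chain and carrier-genotype detection for annotated WES tables.

Three gates, applied jointly: population frequency below the MAF cutoff
(default 1%, taking the maximum over gnomAD and ExAC; missing frequencies
are treated as 0, i.e. rare — a documented optimistic default matching
annotation tables where absent entries print as "-"), a damaging functional
class (coding indels, non-synonymous SNVs, stopgains, splice-site changes),
and membership in the gamete-expression/infertility gene panel.

Carrier models per sample per gene: homozygous (any hom variant) or
potential compound heterozygous (two or more *distinct* heterozygous
variants); duplicated records of the same variant never create a
compound-het call.
"""

from __future__ import annotations

from collections.abc import Iterable
from pathlib import Path

import numpy as np
import pandas as pd

MAF_CUTOFF = 0.01

DAMAGING_CLASSES = frozenset({
    "nonsynonymous-SNV", "stopgain", "frameshift-indel", "inframe-indel",
    "splice-site",
})

REQUIRED_COLUMNS = ("sample", "gene", "effect", "zygosity")
FREQ_COLUMNS = ("gnomad", "exac")
VARIANT_KEY = ("chrom", "pos", "ref", "alt")


def load_gene_panel(source: str | Path | Iterable[str]) -> frozenset[str]:
    """Gene panel from a newline-delimited file or an iterable of symbols."""
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = list(source)
    panel = frozenset(s.strip().upper() for s in lines if s.strip())
    if not panel:
        raise ValueError("gene panel is empty")
    return panel


def _freq_matrix(df: pd.DataFrame) -> np.ndarray:
    cols = [c for c in FREQ_COLUMNS if c in df.columns]
    if not cols:
        return np.zeros((len(df), 1))
    mat = df[cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return np.nan_to_num(mat, nan=0.0)  # missing frequency treated as rare


def filter_variants(df: pd.DataFrame, panel: frozenset[str],
                    maf_cut: float = MAF_CUTOFF,
                    freq_rule: str = "max") -> pd.DataFrame:
    """Apply the three-gate filter; returns the surviving subset.

    ``freq_rule="max"`` (default, stricter) requires the maximum frequency
    over the databases to be below the cutoff; ``"all"`` requires each
    reported frequency to be below it independently (identical result when
    missing values count as 0, but kept as an explicit switch).
    """
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    freqs = _freq_matrix(df)
    if freq_rule == "max":
        freq_ok = freqs.max(axis=1) < maf_cut
    elif freq_rule == "all":
        freq_ok = (freqs < maf_cut).all(axis=1)
    else:
        raise ValueError("freq_rule must be 'max' or 'all'")
    class_ok = df["effect"].isin(DAMAGING_CLASSES).to_numpy()
    panel_ok = df["gene"].str.upper().isin(panel).to_numpy()
    return df[freq_ok & class_ok & panel_ok].copy()


def detect_carriers(filtered: pd.DataFrame) -> pd.DataFrame:
    """Per sample per gene carrier model from the surviving variants.

    Returns rows (sample, gene, model) with model in {homozygous,
    potential-compound-het}; samples/genes matching neither model are
    omitted.  Variants are deduplicated by locus + alleles when those
    columns are present.
    """
    df = filtered
    key_cols = [c for c in VARIANT_KEY if c in df.columns]
    if key_cols:
        df = df.drop_duplicates(subset=["sample", "gene", *key_cols])
    rows = []
    for (sample, gene), sub in df.groupby(["sample", "gene"], sort=True):
        if (sub["zygosity"] == "hom").any():
            rows.append({"sample": sample, "gene": gene,
                         "model": "homozygous"})
        elif (sub["zygosity"] == "het").sum() >= 2:
            rows.append({"sample": sample, "gene": gene,
                         "model": "potential-compound-het"})
    return pd.DataFrame(rows, columns=["sample", "gene", "model"])


def carrier_rate(carriers: pd.DataFrame | int, n_samples: int) -> float:
    """Distinct carrier samples / cohort size, as a percentage (one decimal).

    ``carriers`` may be the detect_carriers table or a pre-computed count.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if isinstance(carriers, pd.DataFrame):
        n_carriers = carriers["sample"].nunique() if len(carriers) else 0
    else:
        n_carriers = int(carriers)
    from .cohort import percent  # shared half-up rounding
    return percent(n_carriers, n_samples)
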
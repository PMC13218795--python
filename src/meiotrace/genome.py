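"""Abstract genome geometry.

No alignment is ever performed in this package, so the genome is purely a
coordinate system: ordered chromosome names, lengths, and centromere
positions.  Coordinates are 0-based, half-open.  The default genome uses
hg19-like chromosome length proportions, optionally scaled down so that
whole-genome simulations stay cheap while per-chromosome bin counts remain
realistic enough for median-based copy-number calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# hg19 chromosome lengths (bp), chr prefix dropped.
HG19_CHROM_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560, "Y": 59_373_566,
}

CHROMOSOMES: tuple[str, ...] = tuple(HG19_CHROM_LENGTHS)
AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))


@dataclass(frozen=True)
class Genome:
    """Chromosome name -> length map plus centromere positions.

    Parameters
    ----------
    lengths
        Ordered mapping chromosome -> length in bp.
    centromeres
        Chromosome -> centromere position.  Defaults to mid-chromosome.
    scale
        Record of the linear scale factor relative to a full-size genome
        (1.0 = full size); used by pipelines to scale length thresholds.
    """

    lengths: dict[str, int]
    centromeres: dict[str, int] = field(default_factory=dict)
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("genome must have at least one chromosome")
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        if not self.centromeres:
            object.__setattr__(
                self, "centromeres",
                {c: length // 2 for c, length in self.lengths.items()},
            )

    @classmethod
    def hg19_like(cls, scale: float = 1.0) -> "Genome":
        """A 24-chromosome genome with hg19 length proportions.

        ``scale < 1`` shrinks every chromosome linearly, preserving
        relative sizes; centromeres default to mid-chromosome.
        """
        if not 0 < scale <= 1:
            raise ValueError("scale must be in (0, 1]")
        lengths = {c: max(1, int(round(L * scale)))
                   for c, L in HG19_CHROM_LENGTHS.items()}
        return cls(lengths=lengths, scale=scale)

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.lengths)

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(c for c in self.lengths if c not in ("X", "Y"))

    def bins(self, bin_size: int) -> pd.DataFrame:
        """Tile every chromosome into fixed-size bins (last bin truncated)."""
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        rows = []
        for chrom, length in self.lengths.items():
            starts = np.arange(0, length, bin_size, dtype=np.int64)
            ends = np.minimum(starts + bin_size, length)
            rows.append(pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def gc_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Deterministic smooth GC-fraction track.

        A fixed sinusoid per chromosome (period = length/6, phase set by the
        chromosome's index) standing in for the real GC landscape; values
        stay within [0.38, 0.52] so the default LOESS mask keeps all bins.
        """
        length = self.lengths[chrom]
        idx = list(self.lengths).index(chrom)
        period = max(length / 6.0, 1.0)
        phase = 2.399963 * idx  # golden-angle spacing decorrelates chromosomes
        return 0.45 + 0.07 * np.sin(
            2.0 * np.pi * np.asarray(positions, dtype=float) / period + phase)
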
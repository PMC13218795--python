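"""Observation noise model for single-cell whole-genome amplification data.

Captures the artefacts that matter to downstream inference: bin-level
overdispersion, a smooth monotone GC-efficiency bias, MDA-style allele
dropout, and per-read base error.  Randomness is injected by the simulation
entry points (every one takes a seed or numpy Generator); the model itself
is a pure parameter container.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class NoiseModel:
    """Parameters of the sequencing-observation model.

    Attributes
    ----------
    reads_per_bin
        Expected read count of a bin at baseline copy number (2 for embryo
        material, 1 for sperm).  Default 32 matches ~10 M reads spread over
        ~310 k 10-kb bins (embryos) and ~5 M reads over ~155 k 20-kb bins
        (sperm).
    inverse_dispersion
        Negative-binomial inverse-dispersion r (variance = m + m^2/r).
        Default 44.4 puts the extra-Poisson coefficient of variation at
        ~0.15 for a copy-2 bin in the deep-coverage limit.
    gc_slope
        Log-linear GC-bias slope: efficiency = exp(gc_slope * (gc - 0.45)).
        Monotone in GC by construction.
    ado_rate
        Per-locus, per-haplotype allele-dropout probability (MDA-like).
        Default 0.1 for single cells; use 0 for bulk parental DNA.
    seq_error
        Per-read probability of reporting the opposite allele.
    """

    reads_per_bin: float = 32.0
    inverse_dispersion: float = 44.4
    gc_slope: float = 1.5
    ado_rate: float = 0.1
    seq_error: float = 0.005

    def __post_init__(self) -> None:
        if self.reads_per_bin <= 0:
            raise ValueError("reads_per_bin must be positive")
        if self.inverse_dispersion <= 0:
            raise ValueError("inverse_dispersion must be positive")
        for name in ("ado_rate", "seq_error"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def gc_efficiency(self, gc: np.ndarray) -> np.ndarray:
        """Relative amplification/sequencing efficiency at GC fraction."""
        return np.exp(self.gc_slope * (np.asarray(gc, dtype=float) - 0.45))

    def draw_counts(self, mean: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
        """Negative-binomial counts with the model's dispersion.

        Bins with mean 0 yield count 0 exactly (e.g. nullisomic regions).
        """
        mean = np.asarray(mean, dtype=float)
        r = self.inverse_dispersion
        counts = np.zeros(mean.shape, dtype=np.int64)
        pos = mean > 0
        p = r / (r + mean[pos])
        counts[pos] = rng.negative_binomial(r, p)
        return counts


# Bulk parental DNA: no single-cell amplification artefacts.
BULK_NOISE = NoiseModel(ado_rate=0.0, seq_error=0.001)

# Noise-free observation model used for oracle-style tests.
ZERO_NOISE = NoiseModel(inverse_dispersion=1e9, gc_slope=0.0,
                        ado_rate=0.0, seq_error=0.0)
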
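"""Fertilization: combining two gametes into an embryo ground truth.

The embryo's constitutive karyotype is the sum of the gamete contributions,
kept separated by parent so that parental-origin inference can be scored
against truth.  Post-zygotic (mitotic) abnormalities are layered on top as
mosaic events with an abnormal-cell fraction f; f = 1 denotes a constitutive
segmental event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..genome import Genome
from .meiosis import GameteKaryotype
from .panel import SnpPanel

PARENTS = ("maternal", "paternal")


@dataclass
class MosaicEvent:
    """A copy-number event present in a fraction f of cells.

    Half-open interval [start, end); ``delta`` is the signed copy change of
    the abnormal clone (+1 gain, -1 loss); ``parent`` names the parental
    copy affected; ``source_index`` (resolved by :func:`form_embryo`) is the
    index of the parental copy that is duplicated or lost.
    """

    chrom: str
    start: int
    end: int
    delta: int
    parent: str
    fraction: float = 1.0
    source_index: int = 0

    def __post_init__(self) -> None:
        if self.parent not in PARENTS:
            raise ValueError(f"parent must be one of {PARENTS}")
        if self.delta == 0:
            raise ValueError("delta must be non-zero")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.end <= self.start:
            raise ValueError("event interval must be half-open with end > start")


def whole_chromosome_event(genome: Genome, chrom: str, delta: int,
                           parent: str, fraction: float = 1.0) -> MosaicEvent:
    """Convenience constructor for a whole-chromosome mosaic event."""
    return MosaicEvent(chrom=chrom, start=0, end=genome.lengths[chrom],
                       delta=delta, parent=parent, fraction=fraction)


@dataclass
class EmbryoTruth:
    """Ground-truth karyotype of one embryo, decomposed by parent.

    ``maternal`` / ``paternal`` map chromosome -> list of allele arrays over
    that chromosome's panel loci (one array per constitutive copy).
    """

    panel: SnpPanel
    maternal: dict[str, list[np.ndarray]]
    paternal: dict[str, list[np.ndarray]]
    events: list[MosaicEvent] = field(default_factory=list)
    gamete_errors: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def genome(self) -> Genome:
        return self.panel.genome

    def maternal_copies(self, chrom: str) -> int:
        return len(self.maternal[chrom])

    def paternal_copies(self, chrom: str) -> int:
        return len(self.paternal[chrom])

    def copy_number(self, chrom: str) -> int:
        """Constitutive total copies = maternal + paternal copies."""
        return self.maternal_copies(chrom) + self.paternal_copies(chrom)

    def total_chromosomes(self) -> int:
        return sum(self.copy_number(c) for c in self.maternal)

    def karyotype_frame(self) -> pd.DataFrame:
        chroms = list(self.maternal)
        return pd.DataFrame({
            "chrom": chroms,
            "maternal_copies": [self.maternal_copies(c) for c in chroms],
            "paternal_copies": [self.paternal_copies(c) for c in chroms],
            "total_copies": [self.copy_number(c) for c in chroms],
        })

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"chrom": e.chrom, "start": e.start, "end": e.end,
             "delta": e.delta, "parent": e.parent, "fraction": e.fraction}
            for e in self.events])


def form_embryo(sperm: GameteKaryotype, egg: GameteKaryotype,
                mosaic_events=(), seed=0) -> EmbryoTruth:
    """Fuse two gametes; attach mosaic/segmental events.

    The per-chromosome maternal/paternal decomposition is exactly the sum of
    the two gametes' contributions.  For each mosaic event the affected
    parental copy is chosen at random (reproducibly under ``seed``).
    """
    if sperm.panel.n_loci != egg.panel.n_loci:
        raise ValueError("gametes must share one SNP panel")
    rng = np.random.default_rng(seed)
    panel = egg.panel
    genome = panel.genome
    maternal = {c: [a.copy() for a in egg.copies[c]] for c in egg.copies}
    paternal = {c: [a.copy() for a in sperm.copies[c]] for c in sperm.copies}
    events: list[MosaicEvent] = []
    for ev in mosaic_events:
        if ev.chrom not in genome.lengths:
            raise ValueError(f"unknown chromosome id: {ev.chrom!r}")
        if ev.end > genome.lengths[ev.chrom]:
            raise ValueError(f"event exceeds chromosome {ev.chrom} bounds")
        pool = maternal if ev.parent == "maternal" else paternal
        n_copies = len(pool[ev.chrom])
        if n_copies == 0:
            raise ValueError(
                f"no {ev.parent} copy of chrom {ev.chrom} to alter")
        resolved = MosaicEvent(chrom=ev.chrom, start=ev.start, end=ev.end,
                               delta=ev.delta, parent=ev.parent,
                               fraction=ev.fraction,
                               source_index=int(rng.integers(n_copies)))
        events.append(resolved)
    errors = {c: (egg.errors.get(c, "none"), sperm.errors.get(c, "none"))
              for c in maternal}
    return EmbryoTruth(panel=panel, maternal=maternal, paternal=paternal,
                       events=events, gamete_errors=errors)
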
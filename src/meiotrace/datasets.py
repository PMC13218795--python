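"""Bundled example tallies for a recurrent blastulation-failure cohort.

These are category *counts* typical of such a cohort study — 103
blastulation-failure embryos from 50 couples with recurrent failure, a
58-embryo sporadic-failure comparison group, a large PGT-A blastocyst
reference, and a 109-individual screening cohort with 20 meiotic-variant
carriers.  Only the counts and the derived fractions are meaningful;
per-embryo identities, the euploid/other split of the non-CA remainder, and
individual abnormality counts are synthetic filler constructed to be
consistent with the tallies (documented where arbitrary).
"""

from __future__ import annotations

from .cohort import EmbryoRecord

# Recurrent-failure cohort: 103 embryos / 50 couples; 65 complex-aneuploid
# (CA) embryos; 82 aneuploid (SA+CA) of which 61 carry 4-15 whole-chromosome
# abnormalities; 25 couples produced exclusively CA embryos.
RGQBF_COUNTS = {
    "n_embryos": 103,
    "n_couples": 50,
    "CA": 65,
    "SA": 17,      # fixed so SA + CA = 82 aneuploid embryos
    "E": 11,       # arbitrary split of the remaining 21 embryos
    "other": 10,
    "aneuploid": 82,
    "band_4_15": 61,
    "exclusive_ca_couples": 25,
}

# Sporadic-failure comparison group: 58 embryos / 30 couples.
SGQBF_COUNTS = {
    "n_embryos": 58,
    "n_couples": 30,
    "CA": 1,
    "SA": 24,
    "E": 20,       # arbitrary split of the remaining 33 embryos
    "other": 13,
}

# PGT-A blastocyst reference (successful blastocysts, maternal age < 38).
PGT_BLASTOCYST_COUNTS = {
    "total": 15_397,
    "aneuploid": 3_214,
    "simple_aneuploid": 3_091,
}

# Variant-screening cohort: individuals sequenced / meiotic-variant carriers.
SCREENING_COUNTS = {"n_samples": 109, "n_carriers": 20}


def _spread(n: int, per_couple: int, prefix: str, start: int = 0):
    """Couple ids assigning ``per_couple`` embryos per couple."""
    return [f"{prefix}{start + i // per_couple}" for i in range(n)]


def rgqbf_records() -> list[EmbryoRecord]:
    """Embryo records consistent with the recurrent-failure tallies.

    25 exclusive-CA couples hold two CA embryos each; the other 25 couples
    share the remaining 15 CA and all 38 non-CA embryos, each holding at
    least one non-CA embryo (so exclusivity is exactly 25/50).  Abnormality
    counts: 61 CA embryos at 4-15 abnormalities (set to 8), the other 4 CA
    at 3; SA embryos at 1-2.
    """
    c = RGQBF_COUNTS
    records: list[EmbryoRecord] = []
    ca_counts = [8] * c["band_4_15"] + [3] * (c["CA"] - c["band_4_15"])
    # 25 exclusive couples x 2 CA embryos
    for i in range(50):
        records.append(EmbryoRecord(
            couple_id=f"R{i // 2}", embryo_id=f"R-ca-{i}", label="CA",
            abnormal_count=ca_counts[i]))
    # remaining 15 CA embryos spread over couples R25..R39
    for i in range(50, c["CA"]):
        records.append(EmbryoRecord(
            couple_id=f"R{25 + (i - 50)}", embryo_id=f"R-ca-{i}", label="CA",
            abnormal_count=ca_counts[i]))
    non_ca = (["SA"] * c["SA"] + ["E"] * c["E"] + ["other"] * c["other"])
    # round-robin over the 25 non-exclusive couples: each gets >= 1 non-CA
    for j, label in enumerate(non_ca):
        records.append(EmbryoRecord(
            couple_id=f"R{25 + j % 25}", embryo_id=f"R-x-{j}", label=label,
            abnormal_count=2 if label == "SA" else 0))
    assert len(records) == c["n_embryos"]
    assert len({r.couple_id for r in records}) == c["n_couples"]
    return records


def sgqbf_records() -> list[EmbryoRecord]:
    """Embryo records consistent with the sporadic-failure tallies."""
    c = SGQBF_COUNTS
    labels = (["CA"] * c["CA"] + ["SA"] * c["SA"] + ["E"] * c["E"]
              + ["other"] * c["other"])
    couples = _spread(len(labels), 2, "S")
    return [EmbryoRecord(couple_id=cp, embryo_id=f"S-{i}", label=lb,
                         abnormal_count={"CA": 4, "SA": 1}.get(lb, 0))
            for i, (lb, cp) in enumerate(zip(labels, couples))]
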
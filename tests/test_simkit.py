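"""Simulation-kit tests: meiosis genetics against enumeration oracles,
observation-model expectations against closed forms, and determinism."""

import numpy as np
import pytest

from meiotrace.simkit import (ZERO_NOISE, Haplotypes, NoiseModel,
                              ParentalGenotypes, SnpPanel, form_embryo,
                              simulate_allele_counts, simulate_bin_depth,
                              simulate_gamete, simulate_parents,
                              simulate_tetrad, whole_chromosome_event)


def pair_copy_totals(tetrad, genome):
    """Copies per chromosome pair summed over the four meiotic products
    (X and Y jointly form the male sex pair)."""
    totals = {}
    for c in genome.chromosomes:
        if c in ("X", "Y"):
            continue
        totals[c] = sum(t.copy_number(c) for t in tetrad)
    totals["sex"] = sum(t.copy_number("X") + t.copy_number("Y")
                        for t in tetrad)
    return totals


class TestPanelAndParents:
    def test_degenerate_frequencies_fix_genotypes(self, genome):
        panel = SnpPanel(genome=genome, chrom=np.array(["1", "1"], dtype=object),
                         pos=np.array([100, 200]), b_freq=np.array([0.0, 1.0]))
        parents = simulate_parents(panel, seed=0)
        for hap in (parents.father, parents.mother):
            assert list(hap.genotypes()) == ["AA", "BB"]

    def test_heterozygote_fraction_matches_hardy_weinberg(self, genome):
        # at q = 0.5 the expected het fraction is 2pq = 0.5; 4 sigma band
        n = 10_000
        panel = SnpPanel(genome=genome,
                         chrom=np.full(n, "1", dtype=object),
                         pos=np.arange(n) * 200,
                         b_freq=np.full(n, 0.5))
        parents = simulate_parents(panel, seed=1)
        het = np.mean(parents.mother.genotypes() == "AB")
        assert abs(het - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_simulate_parents_deterministic(self, panel):
        a = simulate_parents(panel, seed=5)
        b = simulate_parents(panel, seed=5)
        assert np.array_equal(a.father.h1, b.father.h1)
        assert np.array_equal(a.mother.h2, b.mother.h2)

    def test_invalid_panels_rejected(self, genome):
        with pytest.raises(ValueError):
            SnpPanel(genome=genome, chrom=np.array([], dtype=object),
                     pos=np.array([], dtype=int), b_freq=np.array([]))
        with pytest.raises(ValueError):  # non-increasing positions
            SnpPanel(genome=genome, chrom=np.array(["1", "1"], dtype=object),
                     pos=np.array([200, 100]), b_freq=np.array([0.5, 0.5]))
        with pytest.raises(ValueError):  # unknown chromosome
            SnpPanel(genome=genome, chrom=np.array(["chr99"], dtype=object),
                     pos=np.array([10]), b_freq=np.array([0.5]))


class TestMeiosis:
    def test_error_free_gamete_has_23_chromosomes(self, parents):
        for hap in (parents.father, parents.mother):
            g = simulate_gamete(hap, seed=3)
            nonzero = [c for c in g.copies if g.copy_number(c) > 0]
            assert len(nonzero) == 23
            assert g.is_euploid_haploid()

    def test_mi_disomy_carries_both_homologs(self, genome):
        # enumeration oracle: under MI nondisjunction the four products are
        # two {homolog1-chromatid, homolog2-chromatid} pairs and two empty,
        # so a parent-heterozygous centromere-proximal locus stays
        # heterozygous in every disomic product (no crossover).
        panel = SnpPanel(genome=genome, chrom=np.array(["21"], dtype=object),
                         pos=np.array([genome.centromeres["21"]]),
                         b_freq=np.array([0.5]))
        parent = Haplotypes(panel=panel, h1=np.array([0]), h2=np.array([1]))
        for seed in range(10):
            tetrad = simulate_tetrad(parent, {"21": "MI"}, recomb_rate=0,
                                     seed=seed)
            disomic = [t for t in tetrad if t.copy_number("21") == 2]
            assert len(disomic) == 2
            for t in disomic:
                alleles = sorted(int(a[0]) for a in t.copies["21"])
                assert alleles == [0, 1]

    def test_mii_disomy_carries_identical_sisters(self, genome):
        panel = SnpPanel(genome=genome, chrom=np.array(["21"], dtype=object),
                         pos=np.array([genome.centromeres["21"]]),
                         b_freq=np.array([0.5]))
        parent = Haplotypes(panel=panel, h1=np.array([0]), h2=np.array([1]))
        for seed in range(10):
            tetrad = simulate_tetrad(parent, {"21": "MII"}, recomb_rate=0,
                                     seed=seed)
            disomic = [t for t in tetrad if t.copy_number("21") == 2]
            assert len(disomic) == 1
            a, b = disomic[0].copies["21"]
            assert np.array_equal(a, b)

    @pytest.mark.parametrize("side", ["father", "mother"])
    def test_tetrad_conservation_random_errors(self, parents, genome, side):
        rng = np.random.default_rng(29)
        hap = getattr(parents, side)
        choices = ["none", "MI", "MII"]
        allowed = [c for c in genome.chromosomes
                   if not (c == "Y" and side == "mother")]
        for rep in range(25):
            spec = {c: rng.choice(["MI", "MII"])
                    for c in rng.choice(allowed, size=4, replace=False)
                    if rng.choice(choices) != "none"}
            tetrad = simulate_tetrad(hap, spec, seed=rng)
            totals = pair_copy_totals(tetrad, genome)
            for c, tot in totals.items():
                if c == "sex" and side == "mother":
                    assert tot == 4  # mother: X pair only, Y absent
                else:
                    assert tot == 4

    def test_whole_genome_diploid_gamete_is_heterozygous(self, parents):
        g = simulate_gamete(parents.mother, whole_genome_diploid=True, seed=7)
        het_seen = 0
        for c in g.genome.autosomes:
            assert g.copy_number(c) == 2
            a, b = g.copies[c]
            het_seen += int(np.any(a != b))
        # unreduced gamete keeps both homologs: most autosomes heterozygous
        assert het_seen >= 20

    def test_tetrad_conservation_whole_genome_diploid(self, parents, genome):
        tetrad = simulate_tetrad(parents.mother, whole_genome_diploid=True,
                                 seed=31)
        totals = pair_copy_totals(tetrad, genome)
        assert all(v == 4 for v in totals.values())

    def test_unknown_chromosome_or_sex_errors(self, parents):
        with pytest.raises(ValueError):
            simulate_gamete(parents.mother, {"chr99": "MI"})
        with pytest.raises(ValueError):
            simulate_gamete(parents.mother, {"1": "inversion"})
        with pytest.raises(ValueError):  # mother carries no Y
            simulate_gamete(parents.mother, {"Y": "MI"})

    def test_gamete_deterministic_under_seed(self, parents):
        g1 = simulate_gamete(parents.father, {"16": "MI"}, seed=12)
        g2 = simulate_gamete(parents.father, {"16": "MI"}, seed=12)
        for c in g1.copies:
            assert len(g1.copies[c]) == len(g2.copies[c])
            for a, b in zip(g1.copies[c], g2.copies[c]):
                assert np.array_equal(a, b)


class TestFormEmbryo:
    def test_two_normal_gametes_give_46_chromosomes(self, parents):
        for seed in range(8):  # composition property holds for every seed
            egg = simulate_gamete(parents.mother, seed=seed)
            sperm = simulate_gamete(parents.father, seed=seed + 100)
            emb = form_embryo(sperm, egg)
            assert emb.total_chromosomes() == 46
            for c in emb.genome.autosomes:
                assert (emb.maternal_copies(c), emb.paternal_copies(c)) == (1, 1)

    def test_maternal_disomy_gives_trisomy_with_2_1_split(self, parents):
        from meiotrace.simkit.scenarios import gamete_with_copy_number
        egg = gamete_with_copy_number(parents.mother, "16", 2, seed=5)
        sperm = simulate_gamete(parents.father, seed=6)
        emb = form_embryo(sperm, egg)
        assert emb.copy_number("16") == 3
        assert (emb.maternal_copies("16"), emb.paternal_copies("16")) == (2, 1)

    def test_nullisomic_egg_gives_maternal_monosomy(self, parents):
        from meiotrace.simkit.scenarios import gamete_with_copy_number
        egg = gamete_with_copy_number(parents.mother, "16", 0, seed=5)
        sperm = simulate_gamete(parents.father, seed=6)
        emb = form_embryo(sperm, egg)
        assert emb.copy_number("16") == 1
        assert emb.maternal_copies("16") == 0

    def test_mosaic_loss_needs_existing_copy(self, parents):
        from meiotrace.simkit.scenarios import gamete_with_copy_number
        egg = gamete_with_copy_number(parents.mother, "16", 0, seed=5)
        sperm = simulate_gamete(parents.father, seed=6)
        ev = whole_chromosome_event(parents.panel.genome, "16", delta=-1,
                                    parent="maternal", fraction=0.5)
        with pytest.raises(ValueError):
            form_embryo(sperm, egg, mosaic_events=[ev])


@pytest.fixture(scope="module")
def flat_embryo(parents):
    egg = simulate_gamete(parents.mother, seed=41)
    sperm = simulate_gamete(parents.father, seed=42)
    return form_embryo(sperm, egg)


@pytest.fixture(scope="module")
def aabb_parents(panel):
    # father AA, mother BB at every locus: all loci AABB-informative
    z = np.zeros(panel.n_loci, dtype=np.uint8)
    o = np.ones(panel.n_loci, dtype=np.uint8)
    return ParentalGenotypes(
        panel=panel,
        father=Haplotypes(panel=panel, h1=z, h2=z, sex="male"),
        mother=Haplotypes(panel=panel, h1=o, h2=o, sex="female"))


class TestBinDepth:
    def test_homogeneous_profile_near_poisson_limit(self, flat_embryo):
        noise = NoiseModel(reads_per_bin=200, inverse_dispersion=1e9,
                           gc_slope=0.0)
        prof = simulate_bin_depth(flat_embryo, 10_000, noise, seed=1)
        auto = prof.bins[~prof.bins["chrom"].isin(["X", "Y"])]
        counts = auto["count"].to_numpy(dtype=float)
        assert abs(counts.mean() - 200) < 2
        cv = counts.std() / counts.mean()
        poisson_cv = 1 / np.sqrt(200)
        assert abs(cv - poisson_cv) < 0.25 * poisson_cv

    def test_trisomy_and_mosaic_depth_ratios(self, parents, noise):
        from meiotrace.simkit.scenarios import gamete_with_copy_number
        egg = gamete_with_copy_number(parents.mother, "16", 2, seed=43)
        sperm = simulate_gamete(parents.father, seed=44)
        ev = whole_chromosome_event(parents.panel.genome, "4", delta=1,
                                    parent="paternal", fraction=0.5)
        emb = form_embryo(sperm, egg, mosaic_events=[ev])
        prof = simulate_bin_depth(emb, 10_000, noise, seed=45)
        bins = prof.bins
        disomic = bins["chrom"].isin(
            [c for c in emb.genome.autosomes if c not in ("16", "4")])
        base = bins.loc[disomic, "count"].mean()
        tri = bins.loc[bins["chrom"] == "16", "count"].mean()
        mos = bins.loc[bins["chrom"] == "4", "count"].mean()
        assert abs(tri / base - 1.5) < 0.05      # 3/2 expectation ratio
        assert abs(mos / base - 1.25) < 0.05     # (2 + 0.5)/2

    def test_bin_depth_deterministic(self, flat_embryo, noise):
        p1 = simulate_bin_depth(flat_embryo, 10_000, noise, seed=9)
        p2 = simulate_bin_depth(flat_embryo, 10_000, noise, seed=9)
        assert p1.bins.equals(p2.bins)


class TestAlleleCounts:
    def test_disomic_baf_half_and_trisomic_two_thirds(self, aabb_parents):
        from meiotrace.simkit.scenarios import gamete_with_copy_number
        parents = aabb_parents
        egg = gamete_with_copy_number(parents.mother, "16", 2, seed=2)
        sperm = simulate_gamete(parents.father, seed=3)
        emb = form_embryo(sperm, egg)
        table = simulate_allele_counts(emb, parents, depth=60,
                                       noise=ZERO_NOISE, seed=4)
        df = table.df.assign(baf=table.baf)
        disomic = df[~df["chrom"].isin(["16", "X", "Y"])]["baf"].dropna()
        trisomic = df[df["chrom"] == "16"]["baf"].dropna()
        assert abs(disomic.mean() - 0.5) < 0.01
        # maternal trisomy at AABB loci: allele pool A + B + B -> BAF 2/3
        assert abs(trisomic.mean() - 2 / 3) < 0.01

    def test_paternal_loss_leaves_only_maternal_allele(self, aabb_parents):
        from meiotrace.simkit.scenarios import gamete_with_copy_number
        parents = aabb_parents
        egg = simulate_gamete(parents.mother, seed=5)
        sperm = gamete_with_copy_number(parents.father, "9", 0, seed=6)
        emb = form_embryo(sperm, egg)
        table = simulate_allele_counts(emb, parents, depth=40,
                                       noise=ZERO_NOISE, seed=7)
        sub = table.df[table.df["chrom"] == "9"]
        assert (sub["ref_count"] == 0).all()       # only maternal B remains
        assert (sub["alt_count"] > 0).all()

    def test_allele_counts_deterministic(self, aabb_parents, parents, noise):
        egg = simulate_gamete(parents.mother, seed=8)
        sperm = simulate_gamete(parents.father, seed=9)
        emb = form_embryo(sperm, egg)
        t1 = simulate_allele_counts(emb, parents, 30, noise, seed=10)
        t2 = simulate_allele_counts(emb, parents, 30, noise, seed=10)
        assert t1.df.equals(t2.df)
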
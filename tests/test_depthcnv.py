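"""Copy-number module tests: normalization oracles, exact threshold
boundaries, segmental calling against ground truth, and recovery rates."""

import numpy as np
import pandas as pd
import pytest

from meiotrace import depthcnv
from meiotrace.containers import BinnedDepthProfile
from meiotrace.simkit import (MosaicEvent, NoiseModel, form_embryo,
                              simulate_bin_depth, simulate_gamete,
                              whole_chromosome_event)
from meiotrace.simkit.scenarios import gamete_with_copy_number

MIN_SEG_BP = 100_000  # 10 Mb at the 1/100 genome scale used in tests


def flat_profile(n_bins=400, count=100.0, gc=None, n_chroms=4,
                 baseline="diploid"):
    """Synthetic profile: ``n_chroms`` chromosomes of equal bin counts."""
    per = n_bins // n_chroms
    rows = []
    for i in range(n_chroms):
        chrom = str(i + 1)
        starts = np.arange(per) * 10_000
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + 10_000,
            "gc": gc[i * per:(i + 1) * per] if gc is not None else 0.45,
            "count": count}))
    return BinnedDepthProfile(bins=pd.concat(rows, ignore_index=True),
                              baseline=baseline)


def ratio_profile(chrom_ratios: dict, bins_per_chrom=40, baseline="diploid"):
    """CopyNumberProfile with fixed per-bin ratios per chromosome."""
    rows = []
    for chrom, ratio in chrom_ratios.items():
        starts = np.arange(bins_per_chrom) * 10_000
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + 10_000,
            "gc": 0.45, "count": 100.0, "ratio": ratio}))
    return depthcnv.CopyNumberProfile(bins=pd.concat(rows, ignore_index=True),
                                      baseline=baseline)


class TestGcNormalize:
    def test_constant_gc_is_pure_rescaling(self):
        prof = flat_profile()
        prof.bins["count"] = np.linspace(50, 150, len(prof.bins))
        out = depthcnv.gc_normalize(prof)
        r = out.bins["count"].to_numpy() / prof.bins["count"].to_numpy()
        assert np.allclose(r, r[0])  # between-bin ratios unchanged

    def test_linear_gc_trend_removed(self):
        rng = np.random.default_rng(0)
        gc = rng.uniform(0.35, 0.55, 400)
        prof = flat_profile(gc=gc)
        prof.bins["count"] = 300.0 * prof.bins["gc"]  # pure GC signal
        out = depthcnv.gc_normalize(prof)
        means = out.bins.groupby("chrom")["count"].mean()
        assert means.max() / means.min() < 1.02

    def test_normalization_reduces_bias_on_simulated_data(self, parents):
        noise = NoiseModel(reads_per_bin=100, gc_slope=3.0)
        egg = simulate_gamete(parents.mother, seed=1)
        sperm = simulate_gamete(parents.father, seed=2)
        prof = simulate_bin_depth(form_embryo(sperm, egg), 10_000, noise,
                                  seed=3)
        auto = ~prof.bins["chrom"].isin(["X", "Y"])

        def rmse(bins):
            c = bins.loc[auto, "count"].to_numpy(dtype=float)
            return np.sqrt(np.mean((c / np.median(c) - 1.0) ** 2))

        assert rmse(depthcnv.gc_normalize(prof).bins) < rmse(prof.bins)

    def test_degenerate_inputs_rejected(self):
        prof = flat_profile()
        zero = BinnedDepthProfile(bins=prof.bins.assign(count=0.0))
        with pytest.raises(ValueError):
            depthcnv.gc_normalize(zero)
        small = BinnedDepthProfile(bins=prof.bins.iloc[:50])
        with pytest.raises(ValueError):
            depthcnv.gc_normalize(small)

    def test_median_preserved(self):
        rng = np.random.default_rng(1)
        prof = flat_profile(gc=rng.uniform(0.35, 0.55, 400))
        prof.bins["count"] = rng.poisson(100, 400).astype(float)
        out = depthcnv.gc_normalize(prof)
        assert np.isclose(out.bins["count"].median(),
                          prof.bins["count"].median(), rtol=1e-6)


class TestCopyRatio:
    def test_profile_equal_to_reference_gives_baseline(self):
        prof = flat_profile()
        cn = depthcnv.copy_ratio_profile(prof, reference=flat_profile())
        assert np.allclose(cn.bins["ratio"], 2.0)

    def test_sperm_duplicated_chromosome_rises_to_two(self):
        # haploid baseline: a gain takes the chromosome from 1 to 2 copies
        prof = flat_profile(baseline="haploid")
        prof.bins.loc[prof.bins["chrom"] == "2", "count"] = 200.0
        ref = flat_profile(baseline="haploid")
        cn = depthcnv.copy_ratio_profile(prof, reference=ref)
        assert np.isclose(cn.chromosome_ratio("2"), 2.0)
        assert np.isclose(cn.chromosome_ratio("1"), 1.0)

    def test_embryo_trisomy_ratio_three(self, parents, noise):
        egg = gamete_with_copy_number(parents.mother, "16", 2, seed=7)
        sperm = simulate_gamete(parents.father, seed=8)
        prof = simulate_bin_depth(form_embryo(sperm, egg), 10_000, noise,
                                  seed=9)
        cn = depthcnv.copy_ratio_profile(depthcnv.gc_normalize(prof))
        assert abs(cn.chromosome_ratio("16") - 3.0) < 0.15

    def test_reference_mismatch_rejected(self):
        prof = flat_profile(n_bins=400)
        ref = flat_profile(n_bins=200, n_chroms=2)
        with pytest.raises(ValueError):
            depthcnv.copy_ratio_profile(prof, reference=ref)


class TestChromosomeCalls:
    @pytest.mark.parametrize("ratio,event,f,status", [
        (3.0, "gain", 1.0, "aneuploid"),
        (2.5, "gain", 0.5, "mosaic"),
        (2.2, "none", 0.2, "euploid"),
        (1.5, "loss", 0.5, "mosaic"),
        (1.0, "loss", 1.0, "aneuploid"),
    ])
    def test_fraction_estimates_and_status(self, ratio, event, f, status):
        cn = ratio_profile({"1": ratio, "2": 2.0, "3": 2.0})
        depthcnv.call_chromosome_cnvs(cn)
        call = cn.chromosome_calls[0]
        assert (call.event, call.status) == (event, status)
        assert np.isclose(call.fraction, f)

    @pytest.mark.parametrize("f,status", [
        (0.29, "euploid"), (0.30, "mosaic"),
        (0.70, "mosaic"), (0.71, "aneuploid"),
    ])
    def test_status_boundaries_exact(self, f, status):
        assert depthcnv.status_from_fraction(f) == status

    def test_multicopy_gain_reports_integer_copies(self):
        cn = ratio_profile({"1": 4.0, "2": 2.0})
        depthcnv.call_chromosome_cnvs(cn)
        call = cn.chromosome_calls[0]
        assert call.copy_estimate == 4
        assert call.fraction == 1.0 and call.status == "aneuploid"

    def test_inconsistent_direction_delegates_to_segmental(self):
        # one arm gained, the other lost: chromosome median deviates but
        # direction is split, so the whole-chromosome call must stand down
        cn = ratio_profile({"1": 2.0, "2": 2.0, "3": 2.0}, bins_per_chrom=60)
        mask = cn.bins["chrom"] == "1"
        half = cn.bins[mask].index[:30]
        cn.bins.loc[half, "ratio"] = 3.0
        depthcnv.call_chromosome_cnvs(cn)
        call = next(c for c in cn.chromosome_calls if c.chrom == "1")
        assert call.event == "none" and "delegated" in call.note
        depthcnv.call_segmental_cnvs(cn, min_len_bp=MIN_SEG_BP)
        assert any(s.chrom == "1" and s.event == "gain"
                   for s in cn.segment_calls)

    def test_short_chromosome_warns_and_skips(self):
        cn = ratio_profile({"1": 2.0})
        few = ratio_profile({"2": 3.0}, bins_per_chrom=5)
        cn.bins = pd.concat([cn.bins, few.bins], ignore_index=True)
        with pytest.warns(UserWarning, match="bins"):
            depthcnv.call_chromosome_cnvs(cn)
        assert [c.chrom for c in cn.chromosome_calls] == ["1"]


class TestSegmentalCalls:
    def test_flat_profile_has_no_segments(self):
        cn = ratio_profile({"1": 2.0, "2": 2.0})
        depthcnv.call_chromosome_cnvs(cn)
        depthcnv.call_segmental_cnvs(cn, min_len_bp=MIN_SEG_BP)
        assert cn.segment_calls == []

    def test_injected_segment_recovered(self, parents, noise):
        # 20% of chromosome 4 (scaled ~380 kb) single-copy paternal gain
        genome = parents.panel.genome
        length = genome.lengths["4"]
        ev_start, ev_end = 0, int(0.2 * length)
        egg = simulate_gamete(parents.mother, seed=21)
        sperm = simulate_gamete(parents.father, seed=22)
        emb = form_embryo(sperm, egg, mosaic_events=[
            MosaicEvent(chrom="4", start=ev_start, end=ev_end, delta=1,
                        parent="paternal", fraction=1.0)])
        prof = simulate_bin_depth(emb, 10_000, noise, seed=23)
        cn = depthcnv.copy_ratio_profile(depthcnv.gc_normalize(prof))
        depthcnv.call_chromosome_cnvs(cn)
        depthcnv.call_segmental_cnvs(cn, min_len_bp=MIN_SEG_BP)
        segs = [s for s in cn.segment_calls if s.chrom == "4"]
        assert len(segs) >= 1
        best = max(segs, key=lambda s: min(s.end, ev_end) - max(s.start, ev_start))
        overlap = min(best.end, ev_end) - max(best.start, ev_start)
        assert overlap / (ev_end - ev_start) >= 0.9
        assert best.event == "gain"

    def test_whole_chromosome_event_not_duplicated_as_segment(
            self, parents, noise):
        egg = gamete_with_copy_number(parents.mother, "16", 2, seed=24)
        sperm = simulate_gamete(parents.father, seed=25)
        prof = simulate_bin_depth(form_embryo(sperm, egg), 10_000, noise,
                                  seed=26)
        cn = depthcnv.copy_ratio_profile(depthcnv.gc_normalize(prof))
        depthcnv.call_chromosome_cnvs(cn)
        depthcnv.call_segmental_cnvs(cn, min_len_bp=MIN_SEG_BP)
        assert any(c.chrom == "16" and c.event == "gain"
                   for c in cn.chromosome_calls)
        assert not any(s.chrom == "16" for s in cn.segment_calls)


class TestClassification:
    def make_cn(self, ratios):
        cn = ratio_profile({**{str(i): 2.0 for i in range(1, 23)}, **ratios})
        return depthcnv.call_chromosome_cnvs(cn)

    def test_no_events_is_euploid(self):
        assert depthcnv.classify_embryo(self.make_cn({})).label == "E"

    def test_two_whole_chromosome_events_is_simple_aneuploidy(self):
        cn = self.make_cn({"16": 3.0, "9": 1.0})
        cls = depthcnv.classify_embryo(cn)
        assert (cls.label, cls.whole_chrom_abnormalities) == ("SA", 2)

    def test_three_events_is_complex_aneuploidy(self):
        cn = self.make_cn({"16": 3.0, "9": 1.0, "21": 3.0})
        assert depthcnv.classify_embryo(cn).label == "CA"

    def test_segmental_only_is_other(self):
        cn = self.make_cn({})
        cn.segment_calls = [depthcnv.SegmentCall(
            chrom="4", start=0, end=150_000, event="loss", mean_ratio=1.0,
            fraction=1.0, status="aneuploid")]
        assert depthcnv.classify_embryo(cn).label == "other"

    def test_whole_chromosome_mosaic_is_other_not_counted(self):
        cn = self.make_cn({"16": 2.5})  # f = 0.5 -> mosaic
        cls = depthcnv.classify_embryo(cn)
        assert (cls.label, cls.whole_chrom_abnormalities) == ("other", 0)

    def test_classification_is_pure_function_of_calls(self):
        cn = self.make_cn({"16": 3.0})
        assert depthcnv.classify_embryo(cn).label == \
            depthcnv.classify_embryo(cn).label


class TestRecovery:
    def test_constitutive_events_recovered_with_high_sensitivity(
            self, parents, noise):
        # 200 embryos, 1-3 constitutive whole-chromosome events each
        rng = np.random.default_rng(71)
        autosomes = list(parents.panel.genome.autosomes)
        found, total, wrong_dir = 0, 0, 0
        for _ in range(200):
            k = int(rng.integers(1, 4))
            chroms = rng.choice(autosomes, size=k, replace=False)
            truth = {}
            egg_err, sperm_err = {}, {}
            for c in chroms:
                copies = int(rng.integers(0, 2)) * 2  # 0 or 2
                truth[c] = "loss" if copies == 0 else "gain"
                (egg_err if rng.integers(2) else sperm_err)[c] = \
                    str(rng.choice(["MI", "MII"]))
            egg = simulate_gamete(parents.mother, egg_err, seed=rng)
            sperm = simulate_gamete(parents.father, sperm_err, seed=rng)
            # resolve realized gamete outcome (random product per chrom)
            emb = form_embryo(sperm, egg, seed=rng)
            prof = simulate_bin_depth(emb, 10_000, noise, seed=rng)
            cn = depthcnv.copy_ratio_profile(depthcnv.gc_normalize(prof))
            depthcnv.call_chromosome_cnvs(cn)
            calls = {c.chrom: c.event for c in cn.chromosome_calls
                     if c.event != "none" and c.status == "aneuploid"}
            for c in autosomes:
                cn_true = emb.copy_number(c)
                if cn_true == 2:
                    continue
                total += 1
                expect = "gain" if cn_true > 2 else "loss"
                if c in calls:
                    if calls[c] == expect:
                        found += 1
                    else:
                        wrong_dir += 1
        assert total > 100
        assert found / total >= 0.95
        assert wrong_dir == 0

    def test_fraction_estimate_monotone_in_true_fraction(self, parents, noise):
        genome = parents.panel.genome
        fs = [0.2, 0.4, 0.6, 0.8, 1.0]
        means = []
        for f in fs:
            vals = []
            for rep in range(12):
                egg = simulate_gamete(parents.mother, seed=900 + rep)
                sperm = simulate_gamete(parents.father, seed=950 + rep)
                emb = form_embryo(sperm, egg, mosaic_events=[
                    whole_chromosome_event(genome, "4", 1, "maternal",
                                           fraction=f)], seed=rep)
                prof = simulate_bin_depth(emb, 10_000, noise,
                                          seed=10_000 * rep + int(f * 10))
                cn = depthcnv.copy_ratio_profile(depthcnv.gc_normalize(prof))
                vals.append(abs(cn.chromosome_ratio("4") - 2.0))
            means.append(np.mean(vals))
        diffs = np.diff(means)
        assert (diffs > -0.03).all()       # non-decreasing within noise
        assert means[-1] > means[0] + 0.5  # strong overall trend
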
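"""Synthetic-data engine: truth profiles, Poisson counts, mixing, thinning."""

import numpy as np
import pandas as pd
import pytest

from cnascreen import annotations, make_bins
from cnascreen.normalize import to_log2ratio
from cnascreen.simulate import (
    DilutionSpec,
    TruthProfile,
    downsample,
    expected_normal_counts,
    in_silico_mix,
    make_fixture_suite,
    mcrpc_like,
    simulate_counts,
    umuc5_like,
    vcap_like,
)
from cnascreen.tumor_content import expected_log2


class TestTruthProfile:
    def test_overlapping_intervals_rejected(self):
        iv = pd.DataFrame(
            [("chr1", 0, 2_000_000, 3), ("chr1", 1_000_000, 3_000_000, 1)],
            columns=["chrom", "start", "end", "cn"],
        )
        with pytest.raises(ValueError, match="overlap"):
            TruthProfile(intervals=iv, chrom_sizes={"chr1": 10_000_000})

    def test_bin_copy_numbers_overlap_weighted(self):
        iv = pd.DataFrame([("chr1", 50_000, 150_000, 4)], columns=["chrom", "start", "end", "cn"])
        truth = TruthProfile(intervals=iv, chrom_sizes={"chr1": 300_000}, sex="female")
        bins = make_bins({"chr1": 300_000}, 100_000)
        cn = truth.bin_copy_numbers(bins)
        assert cn.tolist() == [3.0, 3.0, 2.0]  # half of bins 1-2 at n=4

    def test_male_x_baseline_one(self, mini_truth):
        bins = make_bins(mini_truth.chrom_sizes, 500_000)
        cn = mini_truth.bin_copy_numbers(bins)
        on_x = bins.is_x()
        # non-amplified X territory sits at one copy
        assert np.median(cn[on_x]) == 1.0

    def test_stock_truths_have_expected_drivers(self):
        ar = [iv for _, iv in vcap_like(20).intervals.iterrows() if iv["cn"] >= 10]
        assert ar and ar[0]["chrom"] == "chrX"
        egfr = [iv for _, iv in umuc5_like(20).intervals.iterrows() if iv["cn"] == 20]
        assert egfr and egfr[0]["chrom"] == "chr7"
        assert (mcrpc_like(20).intervals["cn"] == 0).sum() == 2  # PTEN and RB1

    def test_round_trip_dict(self, mini_truth):
        back = TruthProfile.from_dict(mini_truth.to_dict())
        assert back.label == mini_truth.label
        assert back.intervals.equals(mini_truth.intervals)


class TestSimulateCounts:
    def test_pure_tumor_region_hits_model_level(self):
        sizes = {"chr1": 20_000_000}
        iv = pd.DataFrame([("chr1", 5_000_000, 10_000_000, 4)], columns=["chrom", "start", "end", "cn"])
        truth = TruthProfile(intervals=iv, chrom_sizes=sizes, sex="female")
        bins = make_bins(sizes, 100_000)
        counts = simulate_counts(truth, DilutionSpec(1.0, 1.0, seed=1), bins)
        profile = to_log2ratio(counts, reference_counts=expected_normal_counts(bins, "female", counts.total_reads))
        inside = (bins.table["start"] >= 5_000_000).to_numpy() & (bins.table["end"] <= 10_000_000).to_numpy()
        assert np.nanmean(profile.log2ratio[inside]) == pytest.approx(1.0, abs=0.05)

    def test_read_yield_matches_coverage(self):
        """0.005x at 189 bp fragments on the full genome: ~80k reads."""
        sizes = annotations.chrom_sizes(1)
        truth = TruthProfile(
            intervals=pd.DataFrame(columns=["chrom", "start", "end", "cn"]),
            chrom_sizes=sizes, sex="male",
        )
        bins = make_bins(sizes, 5_000_000)
        counts = simulate_counts(truth, DilutionSpec(0.0, 0.005, mean_read_length=189, seed=2), bins)
        expected = 0.005 * truth.genome_length / 189
        assert counts.total_reads == pytest.approx(expected, abs=4 * np.sqrt(expected))
        assert counts.effective_coverage == pytest.approx(0.005, rel=0.02)

    def test_seeded_determinism(self, mini_truth):
        bins = make_bins(mini_truth.chrom_sizes, 500_000)
        a = simulate_counts(mini_truth, DilutionSpec(0.3, 0.1, seed=9), bins)
        b = simulate_counts(mini_truth, DilutionSpec(0.3, 0.1, seed=9), bins)
        assert (a.count == b.count).all()

    def test_gc_bias_requires_annotation(self, mini_truth):
        bins = make_bins(mini_truth.chrom_sizes, 500_000)
        with pytest.raises(ValueError, match="GC"):
            simulate_counts(mini_truth, DilutionSpec(0.3, 0.1, seed=9), bins, gc_bias_strength=0.5)

    def test_gc_bias_shapes_counts(self, mini_truth):
        from cnascreen.simulate import assign_synthetic_gc

        bins = assign_synthetic_gc(make_bins(mini_truth.chrom_sizes, 500_000), seed=3)
        flat = TruthProfile(
            intervals=pd.DataFrame(columns=["chrom", "start", "end", "cn"]),
            chrom_sizes=mini_truth.chrom_sizes, sex="male",
        )
        counts = simulate_counts(flat, DilutionSpec(0.0, 1.0, seed=4), bins, gc_bias_strength=2.0)
        gc = bins.table["gc"].to_numpy()
        slope = np.polyfit(gc, counts.count / counts.count.mean(), 1)[0]
        assert slope > 1.0  # strong positive GC trend induced

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DilutionSpec(1.5, 0.1)
        with pytest.raises(ValueError):
            DilutionSpec(0.5, 0.0)


class TestInSilicoMix:
    def _pair(self, mini_truth, coverage=0.5):
        bins = make_bins(mini_truth.chrom_sizes, 500_000)
        tumor = simulate_counts(mini_truth, DilutionSpec(1.0, coverage, seed=1), bins)
        flat = TruthProfile(
            intervals=pd.DataFrame(columns=["chrom", "start", "end", "cn"]),
            chrom_sizes=mini_truth.chrom_sizes, sex="male",
        )
        normal = simulate_counts(flat, DilutionSpec(0.0, coverage, seed=2), bins)
        return tumor, normal

    def test_zero_fraction_is_pure_normal_downsample(self, mini_truth):
        tumor, normal = self._pair(mini_truth)
        mixed = in_silico_mix(tumor, normal, 0.0, 100_000, seed=3)
        assert (mixed.count <= normal.count).all()
        assert mixed.total_reads == pytest.approx(100_000, abs=3 * np.sqrt(100_000))

    def test_unit_fraction_is_pure_tumor_downsample(self, mini_truth):
        tumor, normal = self._pair(mini_truth)
        mixed = in_silico_mix(tumor, normal, 1.0, 100_000, seed=3)
        assert (mixed.count <= tumor.count).all()

    def test_half_mix_expectation(self, mini_truth):
        tumor, normal = self._pair(mini_truth)
        total = 200_000
        sums = np.zeros_like(tumor.count)
        n_rep = 50
        for s in range(n_rep):
            sums += in_silico_mix(tumor, normal, 0.5, total, seed=s).count
        expected = 0.5 * total * (
            tumor.count / tumor.count.sum() + normal.count / normal.count.sum()
        )
        observed = sums / n_rep
        keep = expected > 50
        assert np.abs(observed[keep] - expected[keep]).max() / expected[keep].mean() < 0.02

    def test_insufficient_reads_rejected(self, mini_truth):
        tumor, normal = self._pair(mini_truth)
        with pytest.raises(ValueError):
            in_silico_mix(tumor, normal, 0.5, 10**9, seed=0)


class TestDownsample:
    def test_full_target_unchanged(self, mini_truth):
        bins = make_bins(mini_truth.chrom_sizes, 500_000)
        counts = simulate_counts(mini_truth, DilutionSpec(0.5, 0.2, seed=5), bins)
        out = downsample(counts, counts.total_reads, seed=1)
        assert (out.count == counts.count).all()

    def test_per_bin_expectation(self, mini_truth):
        bins = make_bins(mini_truth.chrom_sizes, 500_000)
        counts = simulate_counts(mini_truth, DilutionSpec(0.5, 0.2, seed=5), bins)
        p = 0.25
        target = int(p * counts.total_reads)
        sums = np.zeros_like(counts.count)
        for s in range(100):
            sums += downsample(counts, target, seed=s).count
        observed = sums / 100
        expected = (target / counts.total_reads) * counts.count
        keep = expected > 20
        assert np.abs(observed[keep] - expected[keep]).max() / expected[keep].mean() < 0.03

    def test_total_near_target(self, mini_truth):
        bins = make_bins(mini_truth.chrom_sizes, 500_000)
        counts = simulate_counts(mini_truth, DilutionSpec(0.5, 0.2, seed=5), bins)
        out = downsample(counts, 20_000, seed=3)
        assert abs(out.total_reads - 20_000) <= 3 * np.sqrt(20_000)

    def test_target_above_available(self, mini_truth):
        bins = make_bins(mini_truth.chrom_sizes, 500_000)
        counts = simulate_counts(mini_truth, DilutionSpec(0.5, 0.05, seed=5), bins)
        with pytest.raises(ValueError):
            downsample(counts, counts.total_reads + 1, seed=0)
        out = downsample(counts, counts.total_reads + 1, seed=0, allow_unchanged=True)
        assert (out.count == counts.count).all()


class TestFixtureSuite:
    def test_deterministic_and_well_formed(self, tmp_path):
        kwargs = dict(seed=5, fractions=(0.1, 0.0), coverage=0.05, bin_width=500_000)
        a = make_fixture_suite(tmp_path / "a", **kwargs)
        b = make_fixture_suite(tmp_path / "b", **kwargs)
        assert [p.name for p in a] == [p.name for p in b]
        for pa, pb in zip(a, b):
            assert pa.read_bytes() == pb.read_bytes()

    def test_truths_include_high_level_amplification(self, tmp_path):
        import json

        files = make_fixture_suite(tmp_path, seed=1, fractions=(0.1,), coverage=0.05,
                                   bin_width=500_000)
        truth_files = [p for p in files if p.suffix == ".json"]
        payloads = [json.loads(p.read_text()) for p in truth_files]
        assert any(
            iv["cn"] >= 10 and iv["chrom"] == "chrX"
            for payload in payloads
            for iv in payload["intervals"]
        )

    def test_count_totals_match_requested_coverage(self, tmp_path):
        from cnascreen.genome_bins import read_counts_table

        files = make_fixture_suite(tmp_path, seed=2, fractions=(0.25,), coverage=0.1,
                                   bin_width=500_000)
        tsvs = [p for p in files if p.suffixes[-2:] == [".counts", ".tsv"]]
        assert tsvs
        for path in tsvs:
            counts = read_counts_table(path)
            assert counts.effective_coverage == pytest.approx(0.1, rel=0.01)


def test_mixture_convergence_invariant(mini_truth):
    """Simulated interval means converge to expected_log2(n, f) at 1x."""
    bins = make_bins(mini_truth.chrom_sizes, 100_000)
    counts = simulate_counts(mini_truth, DilutionSpec(0.5, 1.0, seed=8), bins)
    profile = to_log2ratio(
        counts, reference_counts=expected_normal_counts(bins, "male", counts.total_reads)
    )
    table = bins.table
    for _, iv in mini_truth.intervals.iterrows():
        inside = (
            (table["chrom"] == iv["chrom"]).to_numpy()
            & (table["start"] >= iv["start"]).to_numpy()
            & (table["end"] <= iv["end"]).to_numpy()
        )
        if inside.sum() < 10:
            continue
        normal = mini_truth.normal_copy(iv["chrom"])
        level = expected_log2(iv["cn"], 0.5, normal_copy=normal)
        assert np.nanmean(profile.log2ratio[inside]) == pytest.approx(level, abs=0.05)
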
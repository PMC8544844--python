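"""Consecutive-method ROH detection, length classes and F_ROH."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autozyg import (
    ROHParams,
    ROHSegment,
    classify_roh_lengths,
    detect_roh_consecutive,
    enumerate_valid_intervals,
    froh,
    froh_by_bin,
    froh_by_threshold,
    froh_table,
    roh_summary,
)
from autozyg.genotypes import MISSING

from conftest import make_dataset


def segment(length_bp, breed="B1", individual="ind0", chrom=1, start=1_000_000):
    return ROHSegment(
        individual_id=individual,
        breed=breed,
        chromosome=chrom,
        start_bp=start,
        end_bp=start + length_bp,
        n_snps=20,
        n_het=0,
        n_missing=0,
        start_idx=0,
        end_idx=19,
    )


def assert_constraints(seg, ds, params):
    """Assert the five run constraints directly from the genotype matrix."""
    ind = ds.index_of(seg.individual_id)
    idx = np.arange(seg.start_idx, seg.end_idx + 1)
    g = ds.genotypes[ind, idx]
    pos = ds.map.position_bp[idx]
    assert (ds.map.chromosome[idx] == seg.chromosome).all()
    assert g[0] in (0, 2) and g[-1] in (0, 2)
    assert (g == 1).sum() <= params.max_het
    assert (g == MISSING).sum() <= params.max_missing
    assert np.all(np.diff(pos) <= params.max_gap_bp)
    assert len(idx) >= params.min_snps
    assert pos[-1] - pos[0] >= params.min_length_bp


class TestScanner:
    def test_single_clean_run(self):
        # 20 homozygous markers spanning 100 kb .. 2 Mb
        positions = np.linspace(100_000, 2_000_000, 20).astype(np.int64)
        ds = make_dataset(np.zeros((1, 20)), positions=positions)
        segs = detect_roh_consecutive(ds)
        assert len(segs) == 1
        assert (segs[0].start_bp, segs[0].end_bp, segs[0].n_snps) == (
            100_000,
            2_000_000,
            20,
        )

    def test_alternating_het_yields_nothing(self):
        g = np.tile([0, 1], 50)[None, :]
        ds = make_dataset(g)
        assert detect_roh_consecutive(ds) == []

    def test_gap_violation_splits_runs(self):
        pos = np.concatenate(
            [np.arange(20) * 100_000 + 100_000,
             np.arange(20) * 100_000 + 10_000_000]
        )
        ds = make_dataset(np.zeros((1, 40)), positions=pos)
        segs = detect_roh_consecutive(ds)
        assert len(segs) == 2
        assert segs[0].end_bp < segs[1].start_bp

    def test_planted_hets_containment_in_oracle(self):
        # 200 markers at 10 kb spacing: too short for the 1 Mb minimum
        # unless we stretch spacing; use 20 kb so candidate runs qualify
        g = np.zeros(200, dtype=np.int8)
        g[[50, 60, 150]] = 1
        pos = (np.arange(200) + 1) * 20_000
        ds = make_dataset(g[None, :], positions=pos)
        params = ROHParams()
        segs = detect_roh_consecutive(ds, params)
        oracle = enumerate_valid_intervals(g, pos, params)
        assert segs  # something detected
        for s in segs:
            assert_constraints(s, ds, params)
            assert any(i <= s.start_idx and s.end_idx <= j for i, j in oracle)

    def test_unsorted_positions_rejected(self):
        # enforced at the container boundary: the marker map refuses
        # non-increasing positions, so the scanner never sees them
        with pytest.raises(ValueError, match="increasing"):
            make_dataset(np.zeros((1, 3)), positions=[100, 300, 200])

    def test_random_vectors_contained_in_oracle_maximal_set(self, rng):
        params = ROHParams(min_snps=10, min_length_bp=500_000)
        for _ in range(50):
            n = int(rng.integers(30, 400))
            g = rng.choice(
                [0, 1, 2, MISSING], size=n, p=[0.45, 0.2, 0.3, 0.05]
            ).astype(np.int8)
            pos = np.cumsum(rng.integers(10_000, 1_500_000, size=n))
            ds = make_dataset(g[None, :], positions=pos)
            segs = detect_roh_consecutive(ds, params)
            oracle = enumerate_valid_intervals(g, pos, params)
            for s in segs:
                assert_constraints(s, ds, params)
                assert any(i <= s.start_idx and s.end_idx <= j for i, j in oracle)

    def test_planted_runs_recovered_exactly(self):
        """On a fully heterozygous background, planted runs are recovered
        with exact bp boundaries and nothing else is detected."""
        from autozyg import plant_roh

        chrom = [1] * 300 + [2] * 300
        positions = np.tile((np.arange(300, dtype=np.int64) + 1) * 100_000, 2)
        ds = make_dataset(
            np.ones((3, 600), dtype=np.int8), chrom=chrom, positions=positions
        )
        placements = [
            (0, 1, 5_000_000, 9_000_000),
            (1, 2, 12_000_000, 16_000_000),
            (2, 1, 20_000_000, 26_000_000),
        ]
        planted = plant_roh(ds, placements)
        segs = detect_roh_consecutive(planted)
        assert len(segs) == len(placements)
        for (ind, chrom_k, start, end), s in zip(placements, sorted(
            segs, key=lambda x: (x.individual_id, x.chromosome)
        )):
            on_chrom = np.flatnonzero(planted.map.chromosome == chrom_k)
            pos = planted.map.position_bp[on_chrom]
            inside = pos[(pos >= start) & (pos <= end)]
            assert s.individual_id == planted.ids[ind]
            assert s.chromosome == chrom_k
            assert s.start_bp == inside[0] and s.end_bp == inside[-1]
            assert s.n_het == 0 and s.n_missing == 0


class TestOracle:
    def test_fully_heterozygous_is_empty(self):
        g = np.ones(30, dtype=np.int8)
        pos = (np.arange(30) + 1) * 100_000
        assert enumerate_valid_intervals(g, pos) == []

    def test_fully_homozygous_single_interval(self):
        g = np.zeros(20, dtype=np.int8)
        pos = np.linspace(100_000, 2_100_000, 20).astype(np.int64)
        assert enumerate_valid_intervals(g, pos) == [(0, 19)]

    def test_scale_limit_enforced(self):
        g = np.zeros(2001, dtype=np.int8)
        with pytest.raises(ValueError, match="2000"):
            enumerate_valid_intervals(g, np.arange(2001) * 1000)

    def test_overlapping_maximal_intervals_both_reported(self):
        # hets at 50, 60, 150: maximal intervals [0,149] and [51,199]
        g = np.zeros(200, dtype=np.int8)
        g[[50, 60, 150]] = 1
        pos = (np.arange(200) + 1) * 20_000
        oracle = enumerate_valid_intervals(g, pos)
        assert oracle == [(0, 149), (51, 199)]


class TestLengthClasses:
    def test_bin_assignment(self):
        segs = [segment(3_000_000), segment(16_000_000), segment(1_200_000)]
        table = classify_roh_lengths(segs)
        assert table.loc["B1", "2-4"] == 1
        assert table.loc["B1", ">16"] == 1  # half-open: 16.0 falls upward
        assert table.loc["B1", "1-2"] == 1

    def test_bins_partition_total(self, rng):
        segs = [segment(int(l)) for l in rng.uniform(1e6, 3e7, 100)]
        table = classify_roh_lengths(segs)
        assert table.values.sum() == 100


class TestSummary:
    def test_counts_and_means(self):
        ds = make_dataset(np.zeros((3, 5)), breeds=["X", "X", "Y"])
        segs = [
            segment(3_110_000, breed="X", individual="ind0"),
            segment(1_000_000, breed="X", individual="ind0", start=6_000_000),
            segment(1_000_000, breed="X", individual="ind0", start=9_000_000),
            segment(1_000_000, breed="X", individual="ind1"),
        ]
        summary, per_chrom = roh_summary(segs, ds)
        assert summary.loc["X", "n_roh_total"] == 4
        assert summary.loc["X", "mean_roh_per_individual"] == pytest.approx(2.0)
        assert summary.loc["Y", "n_roh_total"] == 0
        assert per_chrom.loc["X", 1] == 4

    def test_mean_length(self):
        ds = make_dataset(np.zeros((1, 5)))
        summary, _ = roh_summary([segment(3_110_000)], ds)
        assert summary.loc["B1", "mean_length_mbp"] == pytest.approx(3.11)

    def test_matches_hand_loop_oracle(self, rng):
        breeds = ["A"] * 4 + ["B"] * 3 + ["C"] * 3
        ds = make_dataset(np.zeros((10, 5)), breeds=breeds)
        segs = []
        for _ in range(60):
            ind = int(rng.integers(0, 10))
            segs.append(
                segment(
                    int(rng.uniform(1e6, 1e7)),
                    breed=breeds[ind],
                    individual=f"ind{ind}",
                    start=int(rng.integers(0, int(1e8))),
                )
            )
        summary, _ = roh_summary(segs, ds)
        for b in "ABC":
            mine = [s for s in segs if s.breed == b]
            n_ind = breeds.count(b)
            assert summary.loc[b, "n_roh_total"] == len(mine)
            assert summary.loc[b, "mean_roh_per_individual"] == pytest.approx(
                len(mine) / n_ind
            )
            assert summary.loc[b, "mean_length_mbp"] == pytest.approx(
                sum(s.length_bp for s in mine) / len(mine) / 1e6
            )


class TestFroh:
    def test_no_segments_is_zero(self):
        assert froh([], 100_000_000) == 0.0

    def test_whole_genome_is_one(self):
        assert froh([segment(100_000_000, start=0)], 100_000_000) == 1.0

    def test_forced_arithmetic(self):
        segs = [segment(2_000_000), segment(3_000_000, start=50_000_000)]
        assert froh(segs, 100_000_000, 1_000_000) == pytest.approx(0.05)

    def test_threshold_vector_forced_arithmetic(self):
        segs = [segment(1_500_000), segment(5_000_000, start=50_000_000)]
        vec = froh_by_threshold(segs, 100_000_000)
        assert vec == pytest.approx([0.065, 0.05, 0.05, 0.0, 0.0])

    def test_single_long_segment_constant_across_thresholds(self):
        vec = froh_by_threshold([segment(20_000_000)], 100_000_000)
        assert np.allclose(vec, 0.2)

    def test_bin_and_threshold_views_agree(self):
        segs = [segment(1_500_000), segment(5_000_000, start=50_000_000)]
        bins = froh_by_bin(segs, 100_000_000)
        vec = froh_by_threshold(segs, 100_000_000)
        # cumulative tail sums of the disjoint bins reproduce the thresholds
        assert np.allclose(bins[::-1].cumsum()[::-1], vec)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.integers(min_value=1, max_value=40_000_000), min_size=0, max_size=30
        )
    )
    def test_threshold_vector_non_increasing(self, lengths):
        segs = [segment(l, start=i * int(5e7)) for i, l in enumerate(lengths)]
        vec = froh_by_threshold(segs, int(2e9))
        assert np.all(np.diff(vec) <= 1e-15)

    def test_froh_table_shape_and_breeds(self):
        ds = make_dataset(np.zeros((2, 5)), breeds=["X", "Y"])
        segs = [segment(2_000_000, breed="X", individual="ind0")]
        table = froh_table(segs, ds)
        assert list(table.index) == ["ind0", "ind1"]
        assert table.loc["ind1"].drop("breed").eq(0).all()
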
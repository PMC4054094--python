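"""Read counting and depth normalization."""

import numpy as np
import pytest
from scipy import stats

from covbias.coverage import (
    CountTrack,
    ReadSet,
    count_reads,
    downsample,
    quantile_normalize,
    rpm_normalize,
)
from covbias.windows import build_mask, partition_accessible


def make_windows(length=40_000, width=20_000):
    return partition_accessible(build_mask({"chr1": "A" * length}), width)


class TestCountReads:
    def test_no_reads(self):
        ws = make_windows()
        track = count_reads(ws, ReadSet(positions={"chr1": np.empty(0, dtype=np.int64)}))
        assert track.counts.tolist() == [0, 0]

    def test_half_open_boundary_assignment(self):
        ws = make_windows()
        reads = ReadSet.from_positions({"chr1": [0, 19_999, 20_000]})
        track = count_reads(ws, reads)
        assert track.counts.tolist() == [2, 1]

    def test_random_reads_match_linear_scan(self, rng):
        seq = "A" * 30_000 + "N" * 5_000 + "A" * 25_000
        ws = partition_accessible(build_mask({"chr1": seq}), 10_000)
        pos = rng.integers(0, 60_000, size=10_000)
        track = count_reads(ws, ReadSet.from_positions({"chr1": pos}))
        spans = ws.table[["start", "end"]].to_numpy()
        expected = [int(sum(1 for p in pos if s <= p < e)) for s, e in spans]
        assert track.counts.tolist() == expected
        # conservation: counted + discarded = non-duplicate reads
        assert int(track.counts.sum()) + track.discarded == len(pos)

    def test_duplicates_excluded(self):
        ws = make_windows()
        reads = ReadSet.from_positions({"chr1": [5, 6, 7]}, dup={"chr1": [0, 1, 0]})
        track = count_reads(ws, reads)
        assert track.counts.tolist() == [2, 0]
        assert reads.duplicates_removed == 1 and track.library_size == 2

    def test_unknown_chromosome_is_an_error(self):
        ws = make_windows()
        with pytest.raises(ValueError, match="chrZ"):
            count_reads(ws, ReadSet.from_positions({"chrZ": [1]}))


class TestRpm:
    def test_unit_scaling(self):
        t = CountTrack(counts=[10], library_size=1_000_000)
        assert rpm_normalize(t).counts.tolist() == [10.0]
        t2 = CountTrack(counts=[7], library_size=7_000_000)
        assert rpm_normalize(t2).counts.tolist() == [1.0]

    def test_sum_identity_on_random_track(self, rng):
        counts = rng.integers(0, 50, size=200)
        t = CountTrack(counts=counts, library_size=123_456)
        out = rpm_normalize(t)
        assert out.counts.sum() == pytest.approx(1e6 * counts.sum() / 123_456)
        assert out.state == "rpm"

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError, match="zero library size"):
            rpm_normalize(CountTrack(counts=[1], library_size=0))


class TestDownsample:
    def test_identity_and_empty(self):
        reads = ReadSet.from_positions({"chr1": [1, 5, 9], "chr2": [3]})
        same = downsample(reads, 4, seed=0)
        assert {c: a.tolist() for c, a in same.positions.items()} == {
            "chr1": [1, 5, 9], "chr2": [3]}
        empty = downsample(reads, 0, seed=0)
        assert empty.total_mapped == 0

    def test_exceeding_target_names_both_numbers(self):
        reads = ReadSet.from_positions({"chr1": [1, 2]})
        with pytest.raises(ValueError, match="3 exceeds mapped reads 2"):
            downsample(reads, 3, seed=0)

    def test_deterministic_given_seed(self, rng):
        pos = {"chr1": rng.integers(0, 10_000, 500)}
        reads = ReadSet.from_positions(pos)
        a = downsample(reads, 100, seed=42)
        b = downsample(reads, 100, seed=42)
        assert np.array_equal(a.positions["chr1"], b.positions["chr1"])
        assert a.total_mapped == 100

    def test_mean_split_matches_hypergeometric_expectation(self):
        # 10 000 reads, 70/30 over two windows; downsample to 1 000, 200 seeds
        pos = np.concatenate([np.arange(7_000), 20_000 + np.arange(3_000)])
        reads = ReadSet.from_positions({"chr1": pos})
        fracs = []
        for seed in range(200):
            ds = downsample(reads, 1_000, seed=seed)
            fracs.append((ds.positions["chr1"] < 20_000).mean())
        se = np.sqrt(0.7 * 0.3 / 1_000)  # binomial se per replicate
        assert abs(np.mean(fracs) - 0.7) < 3 * se / np.sqrt(200)

    def test_per_window_distribution_is_hypergeometric(self):
        # chi-square GOF of the kept-in-window-1 count over 200 replicate seeds
        n1, n2, target = 120, 80, 50
        pos = np.concatenate([np.arange(n1), 10_000 + np.arange(n2)])
        reads = ReadSet.from_positions({"chr1": pos})
        draws = np.array(
            [int((downsample(reads, target, seed=s).positions["chr1"] < 10_000).sum())
             for s in range(200)]
        )
        ks = np.arange(n1 + 1)
        pmf = stats.hypergeom.pmf(ks, n1 + n2, n1, target)
        # pool tail bins with tiny expectation
        keep = pmf * 200 >= 1
        obs = np.array([(draws == k).sum() for k in ks])
        f_obs = np.append(obs[keep], obs[~keep].sum())
        f_exp = np.append(pmf[keep] * 200, pmf[~keep].sum() * 200)
        p = stats.chisquare(f_obs, f_exp).pvalue
        assert p > 0.01


class TestQuantileNormalize:
    def test_identical_tracks_are_fixed_point(self):
        t = CountTrack(counts=[3.0, 1.0, 2.0], library_size=6)
        out = quantile_normalize([t, t])
        for o in out:
            assert o.counts.tolist() == [3.0, 1.0, 2.0]
            assert o.state == "quantile"

    def test_rank_mean_example(self):
        a = CountTrack(counts=[1, 2, 3], library_size=6)
        b = CountTrack(counts=[4, 5, 6], library_size=15)
        oa, ob = quantile_normalize([a, b])
        assert oa.counts.tolist() == [2.5, 3.5, 4.5]
        assert ob.counts.tolist() == [2.5, 3.5, 4.5]

    def test_ties_get_mean_of_rank_range(self):
        a = CountTrack(counts=[0.0, 0.0, 10.0], library_size=10)
        b = CountTrack(counts=[1.0, 2.0, 3.0], library_size=6)
        oa, _ = quantile_normalize([a, b])
        # sorted means: (0.5, 1.0, 6.5); the tied zeros share mean(0.5, 1.0)
        assert oa.counts.tolist() == [0.75, 0.75, 6.5]

    def test_random_instance_against_sort_oracle(self, rng):
        X = rng.random((100, 4)) * 100  # continuous: ties a.s. absent
        tracks = [CountTrack(counts=X[:, j], library_size=1) for j in range(4)]
        out = quantile_normalize(tracks)
        # independent oracle: replace each column by the row-means of the
        # column-sorted matrix, mapped back through each column's argsort
        mean_sorted = np.sort(X, axis=0).mean(axis=1)
        for j, o in enumerate(out):
            expected = np.empty(100)
            expected[np.argsort(X[:, j])] = mean_sorted
            np.testing.assert_allclose(o.counts, expected)
            # identical multiset of values across outputs
            np.testing.assert_allclose(np.sort(o.counts), mean_sorted)
            # rank order preserved within each track
            assert np.array_equal(np.argsort(o.counts), np.argsort(X[:, j]))

    def test_length_mismatch_rejected(self):
        a = CountTrack(counts=[1, 2], library_size=3)
        b = CountTrack(counts=[1], library_size=1)
        with pytest.raises(ValueError, match="length mismatch"):
            quantile_normalize([a, b])
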
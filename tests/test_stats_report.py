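"""Exact tests, RPKM, DE classes, profiles, z-scores, rank tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chromkit.genome_intervals import GenomicInterval, IntervalSet
from chromkit.stats_report import (
    ContingencyTable,
    aggregate_profile,
    classify_de,
    fisher_exact_2x2,
    percent_of_total,
    rank_tests,
    rpkm,
    zscore_matrix,
)


def fisher_enumeration(a, b, c, d):
    """Integer-arithmetic enumeration oracle for the two-tailed exact test."""
    r1, r2, c1 = a + b, c + d, a + c
    w_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = math.comb(r1 + r2, c1)
    s = sum(
        math.comb(r1, x) * math.comb(r2, c1 - x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if math.comb(r1, x) * math.comb(r2, c1 - x) <= w_obs
    )
    return s / total


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[5, 5], [5, 5]], 1.0),
            ([[10, 0], [0, 10]], 2 / math.comb(20, 10)),
            ([[3, 1], [1, 3]], None),  # checked against enumeration below
        ],
    )
    def test_known_tables(self, table, expected):
        p = fisher_exact_2x2(table)
        if expected is None:
            expected = fisher_enumeration(*np.ravel(table))
        assert p == pytest.approx(expected, rel=1e-7)

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            t = rng.integers(0, 40, size=4)
            if t.sum() == 0:
                continue
            ours = fisher_exact_2x2(t.reshape(2, 2))
            ref = sps.fisher_exact(t.reshape(2, 2), alternative="two-sided")[1]
            assert ours == pytest.approx(ref, rel=1e-7)

    def test_validation(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 1)
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])


class TestRpkm:
    def test_hand_value(self):
        assert rpkm([1000], [2.0], 10_000_000)[0] == pytest.approx(50.0)

    def test_zero_counts_and_scaling_laws(self):
        assert rpkm([0], [1.0], 1e6)[0] == 0.0
        base = rpkm([100, 200], [1.0, 2.0], 1e6)
        assert np.allclose(rpkm([100, 200], [1.0, 2.0], 2e6), base / 2)
        assert np.allclose(rpkm([200, 400], [1.0, 2.0], 1e6), base * 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rpkm([1], [0.0], 1e6)
        with pytest.raises(ValueError):
            rpkm([1], [1.0], 0)


class TestClassifyDE:
    def test_inclusive_boundaries(self):
        out = classify_de([-0.58, 0.58, 0.0, -0.57, 0.9])
        assert out.tolist() == ["down", "up", "unchanged", "unchanged", "up"]

    def test_partition_and_monotone(self):
        fc = np.linspace(-2, 2, 101)
        out = classify_de(fc)
        rank = {"down": 0, "unchanged": 1, "up": 2}
        ranks = [rank[c] for c in out]
        assert ranks == sorted(ranks) and len(out) == 101

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_de([np.nan])


class TestPercent:
    @pytest.mark.parametrize(
        "part,total,expected",
        [(2439, 3320, 73.5), (881, 3320, 26.5), (3423, 3583, 95.5), (1, 8, 12.5),
         (1, 16, 6.3)],  # 6.25 rounds half-up to 6.3
    )
    def test_half_up_rounding(self, part, total, expected):
        assert percent_of_total(part, total) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            percent_of_total(1, 0)
        with pytest.raises(ValueError):
            percent_of_total(5, 4)


class TestAggregateProfile:
    def track(self, segments):
        return IntervalSet([GenomicInterval("chr1", s, e, score=v) for s, e, v in segments])

    def test_constant_track_flat_profile(self):
        t = self.track([(0, 100_000, 3.0)])
        prof = aggregate_profile(t, [("chr1", 50_000, "+")], half_window=2000, bin=100)
        assert np.allclose(prof.means, 3.0)
        assert prof.offsets[0] == -1950 and prof.offsets[-1] == 1950

    def test_step_track_read_off_directly(self):
        t = self.track([(1000, 2000, 4.0)])
        prof = aggregate_profile(t, [("chr1", 1000, "+")], half_window=1000, bin=500)
        assert prof.means.tolist() == [0.0, 0.0, 4.0, 4.0]

    def test_minus_strand_flip(self):
        t = self.track([(1000, 2000, 4.0)])
        plus = aggregate_profile(t, [("chr1", 1000, "+")], 1000, 500)
        minus = aggregate_profile(t, [("chr1", 1000, "-")], 1000, 500)
        assert minus.means.tolist() == plus.means[::-1].tolist()

    def test_symmetric_track_strand_invariant(self):
        t = self.track([(900, 1100, 2.0)])
        plus = aggregate_profile(t, [("chr1", 1000, "+")], 1000, 100)
        minus = aggregate_profile(t, [("chr1", 1000, "-")], 1000, 100)
        assert np.allclose(plus.means, minus.means)

    def test_bin_must_divide(self):
        with pytest.raises(ValueError):
            aggregate_profile(self.track([]), [], half_window=1000, bin=300)


class TestZscore:
    def test_row_standardization(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f1"])
        z = zscore_matrix(df)
        assert np.allclose(z.to_numpy(), [[-1.0, 0.0, 1.0]])  # sample sd = 1
        assert np.allclose(z.mean(axis=1), 0) and np.allclose(z.std(axis=1, ddof=1), 1)

    def test_location_invariance(self):
        df = pd.DataFrame([[1.0, 5.0, 9.0]], index=["f"])
        assert np.allclose(zscore_matrix(df).to_numpy(), zscore_matrix(df + 100).to_numpy())

    def test_constant_row_names_factor(self):
        df = pd.DataFrame([[2.0, 2.0, 2.0]], index=["flat_factor"])
        with pytest.raises(ValueError, match="flat_factor"):
            zscore_matrix(df)


class TestRankTests:
    def test_identical_samples_p1(self):
        assert rank_tests([1, 2, 3], [1, 2, 3], "wilcoxon_two_tailed") == pytest.approx(1.0)

    def test_exact_smallest_attainable_3v3(self):
        p = rank_tests([1, 2, 3], [101, 102, 103], "wilcoxon_two_tailed")
        assert p == pytest.approx(0.1)  # 2/20 rank assignments

    def test_t_test_type_one_error_calibration(self):
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            x, y = rng.normal(size=(2, 12))
            if rank_tests(x, y, "t_two_tailed") < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            rank_tests([2, 2, 2], [2, 2, 2], "t_two_tailed")

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            rank_tests([1, 2], [3, 4], "ks")
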
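"""Hub construction, normalization, down-sampling, loop calling, clustering."""

import numpy as np
import pandas as pd
import pytest

from chromkit.genome_intervals import GeneModel, GenomicInterval, IntervalSet
from chromkit.loop_hubs import (
    AnchorHub,
    InteractionPair,
    bin_pairs,
    build_hubs,
    call_promoter_loops,
    cluster_interaction_profiles,
    count_hub_overlap_with_peaks,
    downsample_pairs,
    filter_normalize_hubs,
    loop_frequency_table,
    read_pairs,
    write_pairs,
)


def pair(s1, e1, s2, e2, freq, chrom="chr1", cond="Ctrl"):
    return InteractionPair(
        GenomicInterval(chrom, s1, e1), GenomicInterval(chrom, s2, e2), freq, cond
    )


class TestBinPairs:
    def test_snap_to_same_bin_gives_self_pair(self):
        out = bin_pairs([pair(12_000, 12_500, 12_900, 13_000, 3)], resolution=25_000)
        assert len(out) == 1 and out[0].is_self
        assert (out[0].anchor1.start, out[0].anchor1.end) == (0, 25_000)

    def test_coincident_pairs_aggregate(self):
        out = bin_pairs(
            [pair(0, 100, 30_000, 30_100, 3), pair(30_050, 30_060, 50, 60, 4)],
            resolution=25_000,
        )
        assert len(out) == 1 and out[0].frequency == 7

    def test_empty_and_total_conservation(self):
        assert bin_pairs([], 1000) == []
        rng = np.random.default_rng(1)
        pairs = [
            pair(int(a), int(a) + 10, int(b), int(b) + 10, int(f))
            for a, b, f in zip(
                rng.integers(0, 10**6, 50), rng.integers(0, 10**6, 50), rng.integers(0, 30, 50)
            )
        ]
        out = bin_pairs(pairs, 25_000)
        assert sum(p.frequency for p in out) == sum(p.frequency for p in pairs)


class TestHubs:
    def test_hand_summed_totals(self):
        pairs = [pair(0, 100, 200, 300, 5), pair(0, 100, 400, 500, 7)]
        hubs = {
            (h.anchor.start): h.total_frequency for h in build_hubs(pairs)
        }
        assert hubs == {0: 12, 200: 5, 400: 7}

    def test_self_pair_counted_once(self):
        hubs = build_hubs([pair(0, 100, 0, 100, 4)])
        assert len(hubs) == 1 and hubs[0].total_frequency == 4

    def test_empty(self):
        assert build_hubs([]) == []

    def test_total_identity(self):
        rng = np.random.default_rng(3)
        pairs = bin_pairs(
            [
                pair(int(a), int(a) + 10, int(b), int(b) + 10, int(f))
                for a, b, f in zip(
                    rng.integers(0, 10**6, 80), rng.integers(0, 10**6, 80),
                    rng.integers(0, 20, 80),
                )
            ],
            25_000,
        )
        hubs = build_hubs(pairs)
        non_self = sum(p.frequency for p in pairs if not p.is_self)
        selfs = sum(p.frequency for p in pairs if p.is_self)
        assert sum(h.total_frequency for h in hubs) == 2 * non_self + selfs


class TestFilterNormalize:
    def hubs(self, totals):
        return [
            AnchorHub(GenomicInterval("chr1", i * 1000, (i + 1) * 1000), t)
            for i, t in enumerate(totals)
        ]

    def test_hand_arithmetic(self):
        out = filter_normalize_hubs(self.hubs([12, 5, 20, 10]), min_frequency=10)
        assert sorted(h.total_frequency for h in out) == [10, 12, 20]
        normalized = sorted(h.normalized_frequency for h in out)
        assert normalized == pytest.approx([5 / 7, 6 / 7, 10 / 7])

    def test_mean_is_exactly_one(self):
        rng = np.random.default_rng(0)
        out = filter_normalize_hubs(self.hubs(rng.integers(0, 200, 500)), 10)
        assert abs(np.mean([h.normalized_frequency for h in out]) - 1.0) < 1e-12

    def test_single_and_uniform(self):
        assert filter_normalize_hubs(self.hubs([37]), 10)[0].normalized_frequency == 1.0
        out = filter_normalize_hubs(self.hubs([10, 10, 10]), 10)
        assert all(h.normalized_frequency == 1.0 for h in out)

    def test_empty_after_filter_rejected(self):
        with pytest.raises(ValueError, match="empty hub set"):
            filter_normalize_hubs(self.hubs([3, 4]), 10)


class TestDownsample:
    def test_identity_and_zero(self):
        pairs = [pair(0, 100, 200, 300, 10), pair(0, 100, 400, 500, 5)]
        same = downsample_pairs(pairs, 15, seed=0)
        assert [p.frequency for p in same] == [10, 5]
        zero = downsample_pairs(pairs, 0, seed=0)
        assert [p.frequency for p in zero] == [0, 0]

    def test_target_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            downsample_pairs([pair(0, 1, 2, 3, 5)], 6, seed=0)

    def test_exact_conservation_and_reproducibility(self):
        rng = np.random.default_rng(5)
        pairs = [
            pair(i * 1000, i * 1000 + 10, i * 1000 + 500, i * 1000 + 510, int(f))
            for i, f in enumerate(rng.integers(0, 100, 40))
        ]
        a = downsample_pairs(pairs, 700, seed=11)
        b = downsample_pairs(pairs, 700, seed=11)
        assert sum(p.frequency for p in a) == 700
        assert [p.frequency for p in a] == [p.frequency for p in b]

    def test_binomial_expectation_over_seeds(self):
        pairs = [pair(0, 100, 200, 300, 1000), pair(0, 100, 400, 500, 1000)]
        draws = np.array(
            [downsample_pairs(pairs, 1000, seed=s)[0].frequency for s in range(200)]
        )
        # hypergeometric: mean 500, per-draw var n*p*q*(N-n)/(N-1)
        var = 1000 * 0.25 * (1000 / 1999)
        assert abs(draws.mean() - 500) < 3 * np.sqrt(var / 200)


class TestLoopCalling:
    @pytest.fixture()
    def setup(self):
        genes = [
            GeneModel("g1", "chr1", "+", 30_000, (GenomicInterval("chr1", 30_000, 40_000),))
        ]
        peaks = IntervalSet([GenomicInterval("chr1", 230_000, 231_000)])
        return genes, peaks

    def test_promoter_peak_pair_retained_with_gene(self, setup):
        genes, peaks = setup
        pairs = bin_pairs([pair(29_000, 31_000, 230_000, 230_500, 40)], 25_000)
        loops = call_promoter_loops(pairs, peaks, genes, p_threshold=None)
        assert len(loops) == 1 and loops[0].gene_id == "g1"
        assert loops[0].promoter_anchor.start == 25_000

    def test_pair_touching_neither_dropped(self, setup):
        genes, peaks = setup
        pairs = bin_pairs([pair(600_000, 600_100, 800_000, 800_100, 40)], 25_000)
        assert call_promoter_loops(pairs, peaks, genes, p_threshold=None) == []

    def test_self_loop_dropped(self, setup):
        genes, peaks = setup
        big_peaks = IntervalSet([GenomicInterval("chr1", 29_000, 29_500)])
        pairs = bin_pairs([pair(29_000, 29_100, 30_500, 30_600, 40)], 25_000)
        assert call_promoter_loops(pairs, big_peaks, genes, p_threshold=None) == []

    def test_background_quantile_filter(self, setup):
        genes, peaks = setup
        # many weak non-candidate pairs + one strong candidate at same distance
        background = [
            pair(400_000 + i * 50_000, 400_100 + i * 50_000,
                 600_000 + i * 50_000, 600_100 + i * 50_000, 5)
            for i in range(50)
        ]
        strong = pair(29_000, 31_000, 230_000, 230_500, 50)
        weak = pair(29_500, 31_500, 255_000, 255_400, 2)
        pairs = bin_pairs(background + [strong, weak], 25_000)
        loops = call_promoter_loops(pairs, peaks, genes, p_threshold=0.01)
        assert [lp.frequency["Ctrl"] for lp in loops] == [50]


class TestClustering:
    def archetype_table(self, seed=1, n_per=50, sigma=0.1, log2m=2.0):
        rng = np.random.default_rng(seed)
        archetypes = [(log2m, log2m), (log2m, -log2m), (0.0, 0.0), (-log2m, -log2m)]
        rows, labels = [], []
        for c, (m1, m2) in enumerate(archetypes, start=1):
            for i in range(n_per):
                base = 100.0
                rows.append(
                    {
                        "Ctrl": base,
                        "TGFB1": base * 2 ** (m1 + rng.normal(0, sigma)),
                        "TGFB1_LOF": base * 2 ** (m2 + rng.normal(0, sigma)),
                    }
                )
                labels.append(c)
        df = pd.DataFrame(rows, index=[f"locus_{i}" for i in range(len(rows))])
        return df, np.array(labels)

    def test_identity_ratio_gives_zero_profiles(self):
        df = pd.DataFrame({"Ctrl": [10, 20, 30, 40], "T": [10, 20, 30, 40]})
        res = cluster_interaction_profiles(df, k=4, ctrl="Ctrl", seed=0)
        assert np.allclose(res.profiles.to_numpy(), 0.0)

    def test_planted_archetypes_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        df, labels = self.archetype_table(seed=1)
        res = cluster_interaction_profiles(df, k=4, ctrl="Ctrl", seed=1)
        assert adjusted_rand_score(labels, res.labels) >= 0.9

    def test_degenerate_input_still_returns_k_centroids(self):
        df = pd.DataFrame({"Ctrl": [10.0] * 6, "T": [10.0] * 6})
        res = cluster_interaction_profiles(df, k=4, ctrl="Ctrl", seed=0)
        assert res.centroids.shape[0] == 4
        assert set(res.sizes) == {1, 2, 3, 4}

    def test_fewer_loci_than_k_rejected(self):
        df = pd.DataFrame({"Ctrl": [1, 2], "T": [1, 2]})
        with pytest.raises(ValueError):
            cluster_interaction_profiles(df, k=4, ctrl="Ctrl")

    def test_missing_ctrl_rejected(self):
        with pytest.raises(ValueError):
            cluster_interaction_profiles(pd.DataFrame({"A": [1, 2, 3, 4]}), k=2, ctrl="Ctrl")


class TestHubOverlap:
    def test_counts_and_percentage(self):
        hubs = [
            AnchorHub(GenomicInterval("chr1", i * 1000, (i + 1) * 1000), 10)
            for i in range(8)
        ]
        peaks = IntervalSet(
            [GenomicInterval("chr1", 500, 600), GenomicInterval("chr1", 3500, 3600)]
        )
        assert count_hub_overlap_with_peaks(hubs, peaks) == (2, 8, 25.0)
        assert count_hub_overlap_with_peaks(hubs, IntervalSet())[2] == 0.0
        with pytest.raises(ValueError):
            count_hub_overlap_with_peaks([], peaks)


class TestPairIO:
    def test_roundtrip(self, tmp_path):
        pairs = [pair(0, 100, 200, 300, 5), pair(1000, 1100, 5000, 5100, 9)]
        write_pairs(pairs, tmp_path / "p.bedpe")
        back = read_pairs(tmp_path / "p.bedpe", condition="Ctrl")
        assert [(p.anchor1.start, p.anchor2.start, p.frequency) for p in back] == [
            (0, 200, 5), (1000, 5000, 9)
        ]

    def test_malformed_named_line(self, tmp_path):
        p = tmp_path / "bad.bedpe"
        p.write_text("chr1\t0\t100\tchr1\t200\t300\n")
        with pytest.raises(ValueError, match="line 1"):
            read_pairs(p)
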
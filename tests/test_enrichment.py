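import numpy as np
import pandas as pd
import pytest
from itertools import permutations
from scipy import stats as ss

import diffislands as di
from diffislands.enrichment import (_block_layout, _merge, _overlap_bp,
                                    _permute_layout, _points_in_intervals,
                                    genic_mask)

from oracles import fisher_two_sided_exact, mwu_exact_greater


def make_track(intervals, kind="gene", chrom="1"):
    if not intervals:
        return di.AnnotationTrack(chrom=np.empty(0, object),
                                  start=np.empty(0, np.int64),
                                  end=np.empty(0, np.int64), kind=kind)
    s, e = zip(*intervals)
    return di.AnnotationTrack(chrom=np.array([chrom] * len(s), dtype=object),
                              start=np.array(s), end=np.array(e), kind=kind)


def make_island(start1, end, chrom="1", typ="HDI"):
    return di.Island(chrom=chrom, start=start1, end=end, type=typ, n_snps=1,
                     n_fdr_snps=1, mean_fst=0.3, mean_het=0.3, mean_z=2.0)


class TestIntervalHelpers:
    def test_merge_and_overlap(self):
        s, e = _merge(np.array([5, 0, 3]), np.array([8, 2, 6]))
        assert s.tolist() == [0, 3] and e.tolist() == [2, 8]
        ov = _overlap_bp(np.array([1, 4]), np.array([5, 9]),
                         np.array([0, 6]), np.array([2, 7]))
        assert ov.tolist() == [1, 1]

    def test_points_in_intervals(self):
        mask = _points_in_intervals(np.array([0, 5, 10]),
                                    np.array([1, 8]), np.array([6, 12]))
        assert mask.tolist() == [False, True, True]


class TestBlockPermutation:
    def test_features_covering_genome_force_p_one(self):
        islands = [make_island(101, 200), make_island(301, 320)]
        feats = make_track([(0, 1000)])
        res = di.permute_block_overlap(islands, feats, {"1": 1000},
                                       n_perm=200, seed=0)
        assert res.p_value == 1.0
        assert res.statistic == 2

    def test_no_features_gives_all_ties(self):
        islands = [make_island(101, 200)]
        res = di.permute_block_overlap(islands, make_track([]), {"1": 1000},
                                       n_perm=100, seed=0)
        assert res.statistic == 0 and res.p_value == 1.0

    def test_matches_exhaustive_enumeration_on_tiny_instance(self):
        """2 islands and 3 gaps: compare the sampled null distribution of
        bp overlap against enumeration of all 5! block orderings."""
        islands = [make_island(101, 200), make_island(401, 450)]
        feats = make_track([(150, 480)])
        chrom_len = 700
        (s, e) = (np.array([100, 400]), np.array([200, 450]))
        blocks, is_isl = _block_layout(s, e, chrom_len)
        fs, fe = np.array([150]), np.array([480])

        exact = []
        for order in set(permutations(range(5))):
            order = np.asarray(order)
            pos = np.cumsum(np.r_[0, blocks[order][:-1]])
            isl = is_isl[order]
            exact.append(_overlap_bp(pos[isl], pos[isl] + blocks[order][isl],
                                     fs, fe).sum())
        exact = np.array(sorted(exact), dtype=float)

        rng = np.random.default_rng(1)
        sampled = np.array(sorted(
            _overlap_bp(*_permute_layout(blocks, is_isl, rng), fs, fe).sum()
            for _ in range(4000)), dtype=float)
        # same support and matching distribution
        assert set(np.unique(sampled)) <= set(np.unique(exact))
        assert abs(sampled.mean() - exact.mean()) < 3 * exact.std() / np.sqrt(4000) + 1.0

    def test_pvalues_uniform_under_independent_tracks(self):
        """One-sided block-permutation p-values are uniform when the
        feature track is generated independently of the islands."""
        ps = []
        for seed in range(200):
            r = np.random.default_rng(seed + 1)
            islands, cur = [], 0
            for _ in range(8):
                s = cur + int(r.integers(50, 500))
                e = s + int(r.integers(100, 400))
                islands.append(make_island(s + 1, e))
                cur = e
            L = cur + int(r.integers(100, 1000))
            fs = np.sort(r.integers(0, L - 100, 10))
            feats = make_track(list(zip(fs, np.minimum(fs + int(r.integers(20, 80)), L))))
            res = di.permute_block_overlap(islands, feats, {"1": L}, n_perm=500,
                                           seed=seed, statistic="bp",
                                           alternative="greater")
            ps.append(res.p_value)
        assert ss.kstest(ps, "uniform").pvalue > 0.01

    def test_island_longer_than_chromosome_rejected(self):
        with pytest.raises(ValueError):
            di.permute_block_overlap([make_island(1, 2000)], make_track([(0, 10)]),
                                     {"1": 1000}, n_perm=10, seed=0)


class TestConditionedPermutation:
    def test_single_feasible_gap_gives_degenerate_null(self):
        # genes occupy everything except one island-sized gap
        genes = make_track([(0, 400), (500, 1000)])
        isl = make_island(401, 500)        # exactly fills the gap
        res = di.conditioned_permute([isl], genes, {"1": 1000}, n_perm=50,
                                     seed=0, statistic="distance")
        assert res.p_value == 1.0
        assert res.null_q05 == res.null_q95 == res.statistic

    def test_placements_reproduce_uniform_distance_distribution(self):
        """One gene on an otherwise empty chromosome: the null mean
        distance matches the closed form for a uniformly placed island."""
        L, a, b, size = 10_000, 4_000, 5_000, 200
        genes = make_track([(a, b)])
        isl = make_island(1, size)         # observed at the far left
        res = di.conditioned_permute([isl], genes, {"1": L}, n_perm=4000,
                                     seed=3, statistic="distance")
        # left placements: starts 0..a-size, distance a-(x+size);
        # right placements: starts b..L-size, distance x-b
        w_l, w_r = a - size + 1, L - size - b + 1
        mean_l, mean_r = (a - size) / 2, (L - size - b) / 2
        expected = (w_l * mean_l + w_r * mean_r) / (w_l + w_r)
        assert res.null_mean == pytest.approx(expected, rel=0.05)

    def test_no_nongenic_islands_rejected(self):
        genes = make_track([(0, 1000)])
        with pytest.raises(ValueError):
            di.conditioned_permute([make_island(101, 200)], genes, {"1": 1000})

    def test_genic_mask_shared_predicate(self):
        genes = make_track([(150, 250)])
        islands = [make_island(101, 160), make_island(301, 400)]
        assert genic_mask(islands, genes).tolist() == [True, False]


class TestFisher:
    def flags(self, genic):
        n = len(genic)
        return di.SnpCategoryFlags(
            snp_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
            genic=np.array(genic, bool),
            non_synonymous=np.zeros(n, bool))

    def test_balanced_table_is_null(self):
        genic = [True] * 10 + [False] * 10 + [True] * 10 + [False] * 10
        in_set = [f"s{i}" for i in range(20)]
        res = di.fisher_category_test(in_set, [f"s{i}" for i in range(40)],
                                      self.flags(genic), "genic")
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        genic = [True] * 8 + [False] * 2 + [True] * 2 + [False] * 8
        in_set = [f"s{i}" for i in range(10)]
        res = di.fisher_category_test(in_set, [f"s{i}" for i in range(20)],
                                      self.flags(genic), "genic")
        assert res.p_value == pytest.approx(
            fisher_two_sided_exact([[8, 2], [2, 8]]), abs=1e-12)
        assert res.extra["table"] == [[8, 2], [2, 8]]

    def test_symmetry_under_simultaneous_swap(self):
        genic = [True] * 8 + [False] * 2 + [True] * 2 + [False] * 8
        universe = [f"s{i}" for i in range(20)]
        a = di.fisher_category_test(universe[:10], universe, self.flags(genic), "genic")
        swapped = [not g for g in genic[10:]] + [not g for g in genic[:10]]
        b = di.fisher_category_test(universe[:10], universe,
                                    self.flags(swapped[:10] + swapped[10:]), "genic")
        assert a.p_value == pytest.approx(b.p_value)

    def test_empty_margin_degenerates(self):
        res = di.fisher_category_test([f"s{i}" for i in range(4)],
                                      [f"s{i}" for i in range(8)],
                                      self.flags([False] * 8), "genic")
        assert res.p_value == 1.0


class TestMannWhitney:
    def test_identical_samples_near_half(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        res = di.mwu_fst_compare(x, x.copy())
        assert 0.4 < res.p_value < 0.7

    def test_complete_separation(self):
        res = di.mwu_fst_compare(np.linspace(1, 2, 10), np.linspace(0, 0.5, 10))
        assert res.statistic == 100
        assert res.p_value < 1e-4

    def test_small_samples_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(6):
            x = rng.normal(0.5, 0.3, 5)
            y = rng.normal(0.3, 0.3, 5)
            res = di.mwu_fst_compare(x, y)
            assert res.p_value == pytest.approx(mwu_exact_greater(x, y), abs=1e-12)

    def test_all_tied_degenerates(self):
        res = di.mwu_fst_compare(np.ones(4), np.ones(6))
        assert res.p_value == 1.0


class TestWeightedTTest:
    def test_unit_weights_reduce_to_students_t(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(1.0, 1, 15), rng.normal(1.4, 1, 12)
        res = di.weighted_ttest_recomb(x, np.ones(15), y, np.ones(12))
        t_ref, p_ref = ss.ttest_ind(x, y)
        assert res.statistic == pytest.approx(t_ref, abs=1e-10)
        assert res.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_duplicate_equals_double_weight(self):
        x = np.array([1.0, 1.4, 2.0])
        y = np.array([0.7, 1.1])
        dup = di.weighted_ttest_recomb(np.r_[x, x[1]], np.ones(4), y, np.ones(2))
        wt = di.weighted_ttest_recomb(x, np.array([1.0, 2.0, 1.0]), y, np.ones(2))
        assert dup.statistic == pytest.approx(wt.statistic, abs=1e-10)
        assert dup.p_value == pytest.approx(wt.p_value, abs=1e-10)

    def test_hand_computed_weighted_means(self):
        res = di.weighted_ttest_recomb([0.8, 1.1], [2.0, 1.0],
                                       [1.2, 1.4, 1.3], [1.0, 1.0, 1.0])
        assert res.extra["mean1"] == pytest.approx((2 * 0.8 + 1.1) / 3)
        assert res.extra["mean2"] == pytest.approx(1.3)
        assert res.direction == "depleted"

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            di.weighted_ttest_recomb([1.0], [0.0], [2.0], [1.0])


class TestAncova:
    def test_noiseless_lines_recovered_exactly(self):
        rate_ng, rate_g = np.linspace(1, 5, 10), np.linspace(1, 5, 12)
        res = di.ancova_size_recomb(
            np.r_[10 ** (6.0 - 0.5 * rate_ng), 10 ** (6.5 - 1.0 * rate_g)],
            np.r_[rate_ng, rate_g],
            np.r_[np.zeros(10), np.ones(12)])
        assert res["slope_nongenic"] == pytest.approx(-0.5, abs=1e-10)
        assert res["slope_genic"] == pytest.approx(-1.0, abs=1e-10)
        assert res["p_interaction"] < 1e-6

    def test_equal_slopes_interaction_null_is_calibrated(self):
        rng = np.random.default_rng(14)
        n_sig = 0
        for _ in range(100):
            rate = rng.uniform(1, 5, 30)
            genic = rng.integers(0, 2, 30)
            y = 5.0 - 0.5 * rate + rng.normal(0, 0.3, 30)
            res = di.ancova_size_recomb(10 ** y, rate, genic)
            if res["p_interaction"] < 0.05:
                n_sig += 1
        assert n_sig <= 10

    def test_constant_rate_within_class_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            di.ancova_size_recomb([1e5, 1e6, 1e5, 1e6, 1e5, 1e6],
                                  [1.0, 1.0, 1.0, 2.0, 3.0, 4.0],
                                  [0, 0, 0, 1, 1, 1])


class TestContinentAssignment:
    def freqs(self, rows, pops):
        return pd.DataFrame(rows, columns=pops)

    def test_private_allele_assigned_with_full_contrast(self):
        pops = ["p1", "p2", "p3", "p4"]
        groups = dict(zip(pops, ["Africa", "Eurasia", "East Asia", "America"]))
        f = self.freqs([[1.0, 0.0, 0.0, 0.0]], pops)
        assign, hist = di.assign_continent(f, groups)
        assert assign.iloc[0] == "Africa"
        assert hist["Africa"] == 1

    def test_flat_frequencies_tie_break_deterministic(self):
        pops = ["p1", "p2", "p3", "p4"]
        groups = dict(zip(pops, ["Africa", "Eurasia", "East Asia", "America"]))
        f = self.freqs([[0.5, 0.5, 0.5, 0.5]], pops)
        assign, _ = di.assign_continent(f, groups)
        assert assign.iloc[0] == "Africa"    # first group in the fixed order

    def test_matches_bruteforce_contrast(self):
        rng = np.random.default_rng(15)
        pops = [f"p{i}" for i in range(8)]
        glist = ["Africa", "Africa", "Eurasia", "Eurasia",
                 "East Asia", "East Asia", "America", "America"]
        groups = dict(zip(pops, glist))
        f = self.freqs(rng.random((20, 8)), pops)
        assign, _ = di.assign_continent(f, groups)
        for i in range(20):
            deltas = {}
            for g in ("Africa", "Eurasia", "East Asia", "America"):
                inside = [p for p, gg in groups.items() if gg == g]
                outside = [p for p in pops if p not in inside]
                deltas[g] = abs(f.loc[i, inside].mean() - f.loc[i, outside].mean())
            assert assign.iloc[i] == max(deltas, key=deltas.get)


class TestHotspots:
    def recmap(self, rates, w=100):
        n = len(rates)
        return di.RecombinationMap(
            chrom=np.array(["1"] * n, dtype=object),
            start=np.arange(n) * w, end=(np.arange(n) + 1) * w,
            rate=np.array(rates, dtype=float))

    def test_no_window_above_threshold(self):
        assert len(di.hotspot_islands(self.recmap([1, 5, 10, 9.9]))) == 0

    def test_adjacent_hot_windows_merge(self):
        track = di.hotspot_islands(self.recmap([9, 11, 12, 9]))
        assert len(track) == 1
        assert (track.start[0], track.end[0]) == (100, 300)

    def test_threshold_is_strict(self):
        assert len(di.hotspot_islands(self.recmap([10.0, 10.0]))) == 0
        assert len(di.hotspot_islands(self.recmap([10.000001]))) == 1


class TestChromCountCorrelation:
    def test_proportional_counts_give_unit_correlation(self):
        res = di.chrom_count_correlation([2, 4, 6, 8], [10, 20, 30, 40])
        assert res.statistic == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0])
        res = di.chrom_count_correlation(x, y)
        r_ref = np.corrcoef(x, y)[0, 1]
        assert res.statistic == pytest.approx(r_ref, abs=1e-12)

    def test_independent_counts_rarely_significant(self):
        rng = np.random.default_rng(16)
        n_sig, rs = 0, []
        for _ in range(100):
            x = rng.poisson(10, 22).astype(float)
            y = rng.poisson(1000, 22).astype(float)
            res = di.chrom_count_correlation(x, y)
            rs.append(abs(res.statistic))
            n_sig += res.p_value < 0.05
        assert n_sig <= 12
        assert np.mean(rs) < 0.3

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            di.chrom_count_correlation([3, 3, 3], [1, 2, 3])
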
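import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ancestry_select.diversity_features import (_exact_spearman_pvalue,
                                                decile_spearman,
                                                haplotype_diversity,
                                                pearson_between_scans,
                                                profile_window_stats,
                                                window_features, window_pi)
from ancestry_select.io_formats import (GeneAnnotation, RecombinationMap,
                                        VariantTable)
from ancestry_select.selection_scan import EUR, LLRProfile
from _oracles import (count_haplotypes, interval_union_length, pairwise_pi,
                      spearman_perm_pvalue)


def make_variants(geno, pos=None, chrom="chr1"):
    geno = np.asarray(geno, dtype=np.int8)
    n = geno.shape[0]
    pos = np.asarray(pos) if pos is not None else np.arange(1, n + 1) * 7
    return VariantTable(np.array([chrom] * n, dtype=object), pos,
                        np.array(["A"] * n, dtype=object),
                        np.array(["T"] * n, dtype=object), geno,
                        [f"s{i}" for i in range(geno.shape[1])])


class TestWindowPi:
    def test_identical_sequences_give_zero(self):
        assert window_pi(np.zeros((10, 4), dtype=np.int8), 100) == 0.0

    def test_two_haploids_single_difference(self):
        g = np.zeros((1, 2), dtype=np.int8)
        g[0, 1] = 1
        # 2 * 0.25 * n/(n-1) = 2 * 0.25 * 2 -> 1 diff / 100 sites
        assert window_pi(g, 100) == pytest.approx(0.01)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            g = rng.integers(0, 2, (rng.integers(1, 15), 6)).astype(np.int8)
            assert window_pi(g, 50) == pytest.approx(pairwise_pi(g, 50))

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            window_pi(np.zeros((3, 1), dtype=np.int8), 10)


def full_cover_tracts(samples, ancestry, end=10_000, chrom="chr1"):
    return pd.DataFrame([{"sample": s, "chrom": chrom, "start": 0,
                          "end": end, "ancestry": ancestry}
                         for s in samples])


class TestHaplotypeDiversity:
    def test_identical_samples_give_mean_one(self):
        geno = np.zeros((6, 8), dtype=np.int8)
        v = make_variants(geno, pos=np.arange(1, 7) * 30)
        pops = {"P1": [f"s{i}" for i in range(4)],
                "P2": [f"s{i}" for i in range(4, 8)]}
        tracts = full_cover_tracts(v.samples, 0)
        out = haplotype_diversity(v, tracts, pops, ancestry=0)
        assert out["P1"].mean == 1.0 and out["P1"].sd == 0.0

    def test_counts_distinct_haplotype_strings(self):
        # one window with haplotypes {01, 01, 11, 10} in each population
        geno = np.array([[0, 0, 1, 1, 0, 0, 1, 1],
                        [1, 1, 1, 0, 1, 1, 1, 0]], dtype=np.int8)
        v = make_variants(geno, pos=[10, 20])
        pops = {"P1": [f"s{i}" for i in range(4)],
                "P2": [f"s{i}" for i in range(4, 8)]}
        out = haplotype_diversity(v, full_cover_tracts(v.samples, 0), pops,
                                  ancestry=0, window_bp=200)
        assert out["P1"].mean == 3.0 and out["P2"].mean == 3.0

    def test_matches_set_counting_oracle_per_window(self):
        rng = np.random.default_rng(5)
        n_sites = 40
        geno = rng.integers(0, 2, (n_sites, 10)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 2000), n_sites, replace=False))
        v = make_variants(geno, pos=pos)
        pops = {"A": [f"s{i}" for i in range(5)],
                "B": [f"s{i}" for i in range(5, 10)]}
        out = haplotype_diversity(v, full_cover_tracts(v.samples, 1,
                                                       end=2000), pops,
                                  ancestry=1, window_bp=200)
        # equal population sizes -> no down-sampling: recount directly
        expected = {"A": [], "B": []}
        for w in np.unique((pos - 1) // 200):
            in_w = (pos - 1) // 200 == w
            expected["A"].append(count_haplotypes(geno[in_w][:, :5]))
            expected["B"].append(count_haplotypes(geno[in_w][:, 5:]))
        for p in ("A", "B"):
            assert out[p].mean == pytest.approx(np.mean(expected[p]))
            assert out[p].n_windows == len(expected[p])

    def test_windows_need_ancestry_coverage_in_both_populations(self):
        geno = np.zeros((2, 4), dtype=np.int8)
        v = make_variants(geno, pos=[10, 20])
        pops = {"P1": ["s0", "s1"], "P2": ["s2", "s3"]}
        # population 2 has the wrong ancestry everywhere -> no windows
        tracts = pd.concat([full_cover_tracts(["s0", "s1"], 0),
                            full_cover_tracts(["s2", "s3"], 1)])
        with pytest.warns(UserWarning):
            out = haplotype_diversity(v, tracts, pops, ancestry=0)
        assert out["P1"].n_windows == 0

    def test_down_sampling_is_stable_across_seeds(self):
        rng = np.random.default_rng(2)
        geno = rng.integers(0, 2, (30, 12)).astype(np.int8)
        pos = np.arange(1, 31) * 25
        v = make_variants(geno, pos=pos)
        pops = {"big": [f"s{i}" for i in range(8)],
                "small": [f"s{i}" for i in range(8, 12)]}
        tracts = full_cover_tracts(v.samples, 0)
        means = [haplotype_diversity(v, tracts, pops, ancestry=0,
                                     seed=s)["big"].mean for s in range(20)]
        assert np.std(means) < 0.5
        # small population is never down-sampled: identical every seed
        small = {haplotype_diversity(v, tracts, pops, ancestry=0,
                                     seed=s)["small"].mean for s in range(5)}
        assert len(small) == 1


class TestWindowFeatures:
    def _annotation(self):
        return GeneAnnotation(np.array(["g1", "g2"], dtype=object),
                              np.array(["chr1", "chr1"], dtype=object),
                              np.array([0, 100]), np.array([150, 250]))

    def test_window_inside_exon_has_density_one(self):
        ann = GeneAnnotation(np.array(["g1"], dtype=object),
                             np.array(["chr1"], dtype=object),
                             np.array([0]), np.array([1000]))
        m = RecombinationMap({"chr1": ([0, 1000], [0.0, 0.02])})
        density, _ = window_features(ann, m, [("chr1", 200, 400)])
        assert density[0] == 1.0

    def test_overlapping_exons_use_interval_union(self):
        # exons [0,150) and [100,250) fully cover the window [0,200)
        m = RecombinationMap({"chr1": ([0, 1000], [0.0, 0.02])})
        density, _ = window_features(self._annotation(), m,
                                     [("chr1", 0, 200)])
        assert density[0] == 1.0

    def test_union_matches_grid_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            iv = [(int(a), int(a + rng.integers(1, 50)))
                  for a in rng.integers(0, 300, 5)]
            ann = GeneAnnotation(
                np.array([f"g{i}" for i in range(5)], dtype=object),
                np.array(["chr1"] * 5, dtype=object),
                np.array([a for a, _ in iv]), np.array([b for _, b in iv]))
            m = RecombinationMap({"chr1": ([0, 400], [0.0, 0.01])})
            density, _ = window_features(ann, m, [("chr1", 50, 250)])
            assert density[0] * 200 == pytest.approx(
                interval_union_length(iv, 50, 250))

    def test_uniform_map_gives_constant_rate(self):
        ann = self._annotation()
        m = RecombinationMap({"chr1": ([0, 1_000_000], [0.0, 1.0])})
        _, rate = window_features(ann, m, [("chr1", 0, 200_000),
                                           ("chr1", 500_000, 700_000)])
        np.testing.assert_allclose(rate, 1.0)


class TestDecileSpearman:
    def test_perfect_monotone_relation(self):
        x = np.linspace(0, 1, 100)
        rho, p = decile_spearman(x, x)
        assert rho == pytest.approx(1.0)
        rho2, _ = decile_spearman(x, np.exp(3 * x))  # increasing transform
        assert rho2 == pytest.approx(1.0)

    def test_requires_ten_pairs(self):
        with pytest.raises(ValueError):
            decile_spearman(np.arange(9), np.arange(9))

    def test_exact_pvalue_matches_full_enumeration_small_n(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            bx = rng.random(6)
            by = rng.random(6)
            rho = stats.spearmanr(bx, by).statistic
            dp = _exact_spearman_pvalue(rho, 6)
            brute = spearman_perm_pvalue(bx, by)
            assert dp == pytest.approx(brute, abs=1e-12)

    def test_null_rho_is_rarely_extreme(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rho, _ = decile_spearman(rng.random(1000), rng.random(1000))
            hits += abs(rho) < 0.65
        assert hits >= 9

    def test_remainder_spreads_over_leading_bins(self):
        x = np.arange(23, dtype=float)
        rho, _ = decile_spearman(x, x)
        assert rho == pytest.approx(1.0)


def make_profile(llr, pos=None, chrom="chr1"):
    llr = np.asarray(llr, dtype=float)
    n = llr.size
    pos = pos if pos is not None else np.arange(1, n + 1) * 1000
    return LLRProfile(np.array([chrom] * n, dtype=object), np.asarray(pos),
                      np.arange(n) * 0.1, np.arange(n), llr,
                      np.full(n, 0.01), EUR)


class TestPearsonBetweenScans:
    def test_self_correlation_is_one(self):
        p = make_profile(np.random.default_rng(0).gamma(2, 3, 50))
        r, _ = pearson_between_scans(p, p)
        assert r == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        llr = np.random.default_rng(1).gamma(2, 3, 50)
        r, _ = pearson_between_scans(make_profile(llr), make_profile(-llr))
        assert r == pytest.approx(-1.0)

    def test_mismatched_aim_sets_rejected(self):
        p1 = make_profile(np.ones(10))
        p2 = make_profile(np.ones(10), pos=np.arange(1, 11) * 999)
        with pytest.raises(ValueError, match="identical AIM sets"):
            pearson_between_scans(p1, p2)

    def test_independent_profiles_are_uncorrelated(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            r, _ = pearson_between_scans(make_profile(rng.gamma(2, 3, 2000)),
                                         make_profile(rng.gamma(2, 3, 2000)))
            hits += abs(r) < 0.1
        assert hits >= 9


class TestProfileWindowStats:
    def test_schema_and_window_centering(self):
        rng = np.random.default_rng(4)
        geno = rng.integers(0, 2, (50, 6)).astype(np.int8)
        v = make_variants(geno, pos=np.sort(rng.choice(
            np.arange(1, 300_000), 50, replace=False)))
        ann = GeneAnnotation(np.array(["g1"], dtype=object),
                             np.array(["chr1"], dtype=object),
                             np.array([0]), np.array([50_000]))
        m = RecombinationMap({"chr1": ([0, 300_000], [0.0, 6.0])})
        prof = make_profile(rng.gamma(2, 3, 3),
                            pos=np.array([60_000, 150_000, 240_000]))
        df = profile_window_stats(prof, v, ann, m, window_bp=100_000)
        assert list(df.columns) == ["chrom", "pos", "llr", "pi",
                                    "exon_density", "recomb_rate"]
        np.testing.assert_allclose(df["recomb_rate"], 20.0)  # 6 cM / 0.3 Mb
        assert df["exon_density"].iloc[0] > 0
        assert df["exon_density"].iloc[2] == 0.0
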
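import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ancestry_select import synthetic_data as sd
from ancestry_select.admix_simulator import Demography, simulate
from ancestry_select.io_formats import RecombinationMap
from ancestry_select.local_ancestry_hmm import (AIMPanel, AdmixtureModel,
                                                bootstrap_t, emission_loglik,
                                                fit_admixture,
                                                forward_backward,
                                                generations_per_year,
                                                select_aims, total_loglik,
                                                transition_matrix, viterbi,
                                                viterbi_tracts)
from _oracles import enumerate_hmm
from conftest import make_synthetic_dataset


def _emission_table(panel, epsilon):
    fa, fb = panel.frequencies()
    def emit(obs, k, i):
        if obs < 0:
            return 1.0
        f = (fa, fb)[k][i]
        p1 = f * (1 - epsilon) + (1 - f) * epsilon
        return p1 if obs == 1 else 1 - p1
    return emit


class TestSelectAims:
    def test_uninformative_sites_are_all_removed(self, uniform_map):
        n = 10
        counts_a = np.tile([10, 10], (n, 1))   # freq 0.50
        counts_b = np.tile([11, 9], (n, 1))    # freq 0.45 -> diff 0.05
        with pytest.warns(UserWarning):
            panel = select_aims(counts_a, counts_b,
                                np.array(["chr1"] * n, dtype=object),
                                np.arange(1, n + 1) * 10_000, uniform_map)
        assert panel.n_sites == 0

    def test_greedy_spacing_rule(self):
        """Sites at 1 bp, 1,001 bp and 4,001 bp (10 cM/Mb map, all fully
        informative): the middle site violates both the 2.5 kb and 0.01 cM
        minima from the first retained site and is dropped."""
        recmap = RecombinationMap({"chr1": ([0, 1_000_000], [0.0, 10.0])})
        counts_a = np.tile([0, 20], (3, 1))
        counts_b = np.tile([20, 0], (3, 1))
        panel = select_aims(counts_a, counts_b,
                            np.array(["chr1"] * 3, dtype=object),
                            np.array([1, 1001, 4001]), recmap)
        assert list(panel.pos) == [1, 4001]

    def test_cm_criterion_binds_independently(self):
        # 1 cM/Mb: 4 kb = 0.004 cM < 0.01 cM, so bp spacing alone is not enough
        recmap = RecombinationMap({"chr1": ([0, 1_000_000], [0.0, 1.0])})
        counts_a = np.tile([0, 20], (2, 1))
        counts_b = np.tile([20, 0], (2, 1))
        panel = select_aims(counts_a, counts_b,
                            np.array(["chr1"] * 2, dtype=object),
                            np.array([1, 4001]), recmap)
        assert list(panel.pos) == [1]


class TestTransitionMatrix:
    def test_zero_distance_is_identity(self):
        np.testing.assert_allclose(
            transition_matrix(AdmixtureModel(74, 0.3), 0.0), np.eye(2))

    def test_large_distance_reaches_stationarity(self):
        T = transition_matrix(AdmixtureModel(74, 0.3), 1e6)
        np.testing.assert_allclose(T, [[0.3, 0.7], [0.3, 0.7]], atol=1e-12)

    def test_closed_form_value(self):
        # t=74, m=0.646, d=0.01 M: exp(-0.74) + (1-exp(-0.74)) * 0.646
        T = transition_matrix(AdmixtureModel(74, 0.646), 0.01)
        assert T[0, 0] == pytest.approx(
            np.exp(-0.74) + (1 - np.exp(-0.74)) * 0.646)
        assert T[0, 0] == pytest.approx(0.815, abs=5e-4)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(AdmixtureModel(10, 0.5), -0.1)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0.1, 500), st.floats(0.01, 0.99), st.floats(0, 10))
    def test_rows_sum_to_one(self, t, m, d):
        T = transition_matrix(AdmixtureModel(t, m), d)
        np.testing.assert_allclose(T.sum(axis=1), [1.0, 1.0], atol=1e-12)


class TestEmissionLoglik:
    def test_pseudocount_plug_in(self):
        # panel fixed alt (0 ref / 100 alt), eps=0, obs=1 -> log(100.5/101)
        assert emission_loglik(1, (0, 100), 0.0) == pytest.approx(
            np.log(100.5 / 101.0))

    def test_missing_is_uninformative(self):
        assert emission_loglik(-1, (5, 5), 0.01) == 0.0

    def test_epsilon_half_is_ancestry_symmetric(self):
        ll_a = emission_loglik(1, (0, 100), 0.499999)
        ll_b = emission_loglik(1, (100, 0), 0.499999)
        assert ll_a == pytest.approx(ll_b, abs=1e-4)

    def test_empty_panel_is_a_data_error(self):
        with pytest.raises(ValueError):
            emission_loglik(1, (0, 0), 0.01)


class TestForwardBackwardExact:
    def test_matches_exhaustive_enumeration(self, random_panel):
        """Posterior and total likelihood equal the sum over all 2^8 paths."""
        rng = np.random.default_rng(1)
        model = AdmixtureModel(74, 0.6)
        g = rng.integers(0, 2, (8, 2)).astype(np.int8)
        g[3, 0] = -1
        post = forward_backward(g, random_panel, model)
        emit = _emission_table(random_panel, 0.01)
        decay = np.exp(-model.t * random_panel.distances_morgans())
        q = np.full(8, model.m)
        for s in range(2):
            emis = np.array([[emit(g[i, s], k, i) for k in (0, 1)]
                             for i in range(8)])
            ll, marg, _, _ = enumerate_hmm(emis, decay, q)
            assert ll == pytest.approx(post.loglik[s], abs=1e-10)
            np.testing.assert_allclose(post.prob_a[s], marg, atol=1e-10)

    def test_posterior_is_prior_when_sites_uninformative(self):
        n = 6
        panel = AIMPanel(np.array(["chr1"] * n, dtype=object),
                         np.arange(1, n + 1) * 1000, np.arange(n) * 0.1,
                         np.tile([10, 10], (n, 1)), np.tile([10, 10], (n, 1)))
        model = AdmixtureModel(50, 0.37)
        g = np.random.default_rng(0).integers(0, 2, (n, 3)).astype(np.int8)
        post = forward_backward(g, panel, model)
        np.testing.assert_allclose(post.prob_a, model.m, atol=1e-12)

    def test_fully_informative_panels_pin_the_posterior(self):
        n = 6
        panel = AIMPanel(np.array(["chr1"] * n, dtype=object),
                         np.arange(1, n + 1) * 1000, np.arange(n) * 0.1,
                         np.tile([0, 500], (n, 1)), np.tile([500, 0], (n, 1)))
        g = np.ones((n, 1), dtype=np.int8)  # pure ancestry-A emission
        post = forward_backward(g, panel, AdmixtureModel(74, 0.5),
                                epsilon=0.0)
        assert np.all(post.prob_a > 0.99)

    def test_chromosomes_are_independent_chains(self, random_panel):
        """Splitting the panel into two chromosomes must equal the product
        of the per-chromosome likelihoods."""
        g = np.random.default_rng(2).integers(0, 2, (8, 2)).astype(np.int8)
        model = AdmixtureModel(30, 0.5)
        split = AIMPanel(
            np.array(["chr1"] * 4 + ["chr2"] * 4, dtype=object),
            random_panel.pos, random_panel.cm,
            random_panel.counts_a, random_panel.counts_b)
        ll_split = total_loglik(g, split, model)
        parts = 0.0
        for sl in (slice(0, 4), slice(4, 8)):
            sub = AIMPanel(np.array(["chr1"] * 4, dtype=object),
                           random_panel.pos[sl], random_panel.cm[sl],
                           random_panel.counts_a[sl],
                           random_panel.counts_b[sl])
            parts += total_loglik(g[sl], sub, model)
        assert ll_split == pytest.approx(parts, abs=1e-10)


class TestViterbi:
    def test_matches_exhaustive_argmax(self, random_panel):
        rng = np.random.default_rng(4)
        model = AdmixtureModel(74, 0.6)
        g = rng.integers(0, 2, (8, 2)).astype(np.int8)
        paths, pathll = viterbi(g, random_panel, model)
        emit = _emission_table(random_panel, 0.01)
        decay = np.exp(-model.t * random_panel.distances_morgans())
        q = np.full(8, model.m)
        for s in range(2):
            emis = np.array([[emit(g[i, s], k, i) for k in (0, 1)]
                             for i in range(8)])
            _, _, best, best_lp = enumerate_hmm(emis, decay, q)
            np.testing.assert_array_equal(paths[s], best)
            assert pathll[s] == pytest.approx(best_lp, abs=1e-10)

    def test_path_probability_bounded_by_total_likelihood(self, random_panel):
        g = np.random.default_rng(5).integers(0, 2, (8, 3)).astype(np.int8)
        model = AdmixtureModel(50, 0.4)
        post = forward_backward(g, random_panel, model)
        _, pathll = viterbi(g, random_panel, model)
        assert np.all(pathll <= post.loglik + 1e-12)

    def test_tract_conversion_uses_midpoints(self):
        n = 4
        panel = AIMPanel(np.array(["chr1"] * n, dtype=object),
                         np.array([100, 200, 300, 400]),
                         np.arange(n) * 0.5,
                         np.tile([0, 9], (n, 1)), np.tile([9, 0], (n, 1)))
        paths = np.array([[0, 0, 1, 1]], dtype=np.int8)
        df = viterbi_tracts(paths, panel, samples=["s"],
                            chrom_lengths_bp={"chr1": 500})
        assert df["start"].tolist() == [0, 250]
        assert df["end"].tolist() == [250, 500]
        assert df["ancestry"].tolist() == [0, 1]

    def test_single_ancestry_simulation_yields_one_tract(self):
        panel, fa, fb, recmap, lengths_cm = make_synthetic_dataset(
            77, n_chrom=1, spacing_bp=20_000, min_diff=0.25)
        d = Demography.one_pulse(1.0, 0, size=20)
        tracts = simulate(d, lengths_cm, n_sample_haploids=3, seed=1)
        g = sd.emit_observations(tracts, panel.chrom, panel.cm, fa, fb,
                                 sd.EmissionModel(0.0), seed=2)
        paths, _ = viterbi(g, panel, AdmixtureModel(10, 0.5))
        df = viterbi_tracts(paths, panel)
        assert len(df) == 3 and set(df["ancestry"]) == {0}


class TestFitAndBootstrap:
    def test_m_equals_mean_posterior_at_convergence(self):
        panel, fa, fb, _, lengths_cm = make_synthetic_dataset(31, n_chrom=2)
        d = Demography.one_pulse(0.65, 50, size=500)
        tracts = simulate(d, lengths_cm, n_sample_haploids=10, seed=3)
        g = sd.emit_observations(tracts, panel.chrom, panel.cm, fa, fb, seed=4)
        model, post = fit_admixture(g, panel)
        assert model.m == pytest.approx(post.mean_ancestry_a(), abs=2e-3)

    def test_single_dataset_parameter_recovery(self):
        panel, fa, fb, _, lengths_cm = make_synthetic_dataset(55)
        d = Demography.one_pulse(0.65, 74, size=1000)
        tracts = simulate(d, lengths_cm, n_sample_haploids=30, seed=6)
        g = sd.emit_observations(tracts, panel.chrom, panel.cm, fa, fb, seed=7)
        model, _ = fit_admixture(g, panel)
        assert abs(model.m - 0.65) < 0.05
        assert abs(model.t - 74) / 74 < 0.3

    def test_identity_resample_reproduces_windowed_estimate(self):
        panel, fa, fb, _, lengths_cm = make_synthetic_dataset(
            61, n_chrom=1, spacing_bp=10_000)
        d = Demography.one_pulse(0.6, 60, size=500)
        tracts = simulate(d, lengths_cm, n_sample_haploids=10, seed=8)
        g = sd.emit_observations(tracts, panel.chrom, panel.cm, fa, fb, seed=9)
        model, _ = fit_admixture(g, panel)
        ests = bootstrap_t(g, panel, model, window=100, B=3, seed=0,
                           resample=False)
        arr = next(iter(ests.values()))
        assert arr.size == 3 and np.all(arr == arr[0])

    def test_short_chromosome_skipped_with_warning(self, random_panel):
        g = np.zeros((8, 2), dtype=np.int8)
        with pytest.warns(UserWarning, match="shorter"):
            out = bootstrap_t(g, random_panel, AdmixtureModel(50, 0.5),
                              window=200, B=2)
        assert out == {}

    def test_bootstrap_spread_shrinks_with_more_aims(self):
        panel, fa, fb, _, lengths_cm = make_synthetic_dataset(
            62, n_chrom=1, spacing_bp=5000)
        d = Demography.one_pulse(0.6, 60, size=500)
        tracts = simulate(d, lengths_cm, n_sample_haploids=10, seed=10)
        g = sd.emit_observations(tracts, panel.chrom, panel.cm, fa, fb,
                                 seed=11)
        model, _ = fit_admixture(g, panel)
        n = panel.n_sites
        small = panel.subset(np.arange(n // 4))
        sd_small = np.std(bootstrap_t(g[:n // 4], small, model, window=50,
                                      B=30, seed=1)["chr1"], ddof=1)
        sd_full = np.std(bootstrap_t(g, panel, model, window=50, B=30,
                                     seed=1)["chr1"], ddof=1)
        assert sd_full < sd_small


class TestGenerationsPerYear:
    @pytest.mark.parametrize("t,expected", [(74, 1.28), (125, 2.16),
                                            (58, 1.00)])
    def test_reported_rates(self, t, expected):
        assert generations_per_year(t) == expected

    def test_degenerate_span_rejected(self):
        with pytest.raises(ValueError):
            generations_per_year(10, 2015, 2015)


class TestEndToEndConcordance:
    def test_posterior_recovers_simulated_tracts(self):
        """With informative panels (|f_A - f_B| >= 0.3 on average) and dense
        AIMs, posterior calls match the simulated tracts at >= 90% of sites."""
        panel, fa, fb, _, lengths_cm = make_synthetic_dataset(
            91, n_chrom=2, spacing_bp=2500, min_diff=0.25)
        assert np.mean(np.abs(fa - fb)) >= 0.3
        d = Demography.one_pulse(0.65, 74, size=1000)
        tracts = simulate(d, lengths_cm, n_sample_haploids=10, seed=12)
        g = sd.emit_observations(tracts, panel.chrom, panel.cm, fa, fb,
                                 sd.EmissionModel(0.01), seed=13)
        model, post = fit_admixture(g, panel)
        truth = np.stack([t.ancestry_at_sites(panel.chrom, panel.cm)
                          for t in tracts])
        concordance = np.mean((post.prob_a > 0.5) == (truth == 0))
        assert concordance >= 0.9, concordance
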
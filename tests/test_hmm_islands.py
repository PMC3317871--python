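import numpy as np
import pandas as pd
import pytest

import diffislands as di
from diffislands.hmm_islands import (STATE_H, STATE_I, STATE_L, _em_fit,
                                     _emissions, _forward_backward,
                                     bic_advantage, stationary_distribution)

from oracles import hmm_path_posteriors, sample_hmm

TRUE_MU = np.array([-1.0, 0.0, 1.0])
TRUE_SD = np.array([0.6, 0.6, 0.6])
TRUE_A = np.array([[0.95, 0.05, 0.0],
                   [0.02, 0.96, 0.02],
                   [0.0, 0.05, 0.95]])


def random_params(rng, constrained=True):
    mu = np.sort(rng.normal(0, 1.5, 3))
    sigma = rng.uniform(0.4, 1.2, 3)
    A = rng.dirichlet(np.ones(3), size=3)
    if constrained:
        A[0, 2] = A[2, 0] = 0.0
        A /= A.sum(axis=1, keepdims=True)
    pi = rng.dirichlet(np.ones(3))
    return mu, sigma, A, pi


class TestExhaustiveOracles:
    def test_posterior_matches_path_enumeration(self):
        rng = np.random.default_rng(0)
        for trial in range(8):
            n = int(rng.integers(3, 9))
            mu, sigma, A, pi = random_params(rng, constrained=trial % 2 == 0)
            z = rng.normal(0, 1.5, n)
            g_ref, xi_ref, _, ll_ref = hmm_path_posteriors(z, mu, sigma, A, pi)
            B = _emissions(z, mu, sigma)
            ll, gamma, xi, _ = _forward_backward(B, A, pi)
            assert ll == pytest.approx(ll_ref, abs=1e-10)
            assert np.allclose(gamma, g_ref, atol=1e-10)
            assert np.allclose(xi, xi_ref, atol=1e-10)

    def test_viterbi_matches_path_enumeration(self):
        rng = np.random.default_rng(1)
        for trial in range(8):
            n = int(rng.integers(3, 9))
            mu, sigma, A, pi = random_params(rng, constrained=trial % 2 == 0)
            z = rng.normal(0, 1.5, n)
            params = di.HMMParams(means=mu, sds=sigma, transmat=A, startprob=pi)
            _, _, path_ref, _ = hmm_path_posteriors(z, mu, sigma, A, pi)
            assert np.array_equal(di.viterbi(z, params), path_ref)

    def test_one_em_iteration_sufficient_statistics(self):
        """gamma and pooled xi from scaled forward-backward on a 4-site
        chain equal the brute-force expectations over all 3^4 paths."""
        rng = np.random.default_rng(2)
        mu, sigma, A, pi = random_params(rng)
        z = np.array([-1.2, 0.3, 0.8, -0.1])
        g_ref, xi_ref, _, _ = hmm_path_posteriors(z, mu, sigma, A, pi)
        B = _emissions(z, mu, sigma)
        _, gamma, xi, _ = _forward_backward(B, A, pi)
        assert np.allclose(gamma, g_ref, atol=1e-10)
        assert np.allclose(xi, xi_ref, atol=1e-10)


class TestEMProperties:
    def test_loglik_non_decreasing_along_iterations(self):
        rng = np.random.default_rng(3)
        _, z = sample_hmm(600, TRUE_MU, TRUE_SD, TRUE_A,
                          stationary_distribution(TRUE_A), rng)
        mu, sigma, A, pi = random_params(rng)
        lls = []
        for _ in range(40):
            B = _emissions(z, mu, sigma)
            ll, gamma, xi, _ = _forward_backward(B, A, pi)
            lls.append(ll)
            denom = xi.sum(axis=1, keepdims=True)
            A = xi / denom
            pi = gamma[0] / gamma[0].sum()
            w = gamma.sum(axis=0)
            mu = (gamma * z[:, None]).sum(axis=0) / w
            sigma = np.sqrt((gamma * (z[:, None] - mu) ** 2).sum(axis=0) / w)
        assert (np.diff(lls) >= -1e-8).all()

    def test_structural_zeros_survive_em_exactly(self):
        rng = np.random.default_rng(4)
        _, z = sample_hmm(800, TRUE_MU, TRUE_SD, TRUE_A,
                          stationary_distribution(TRUE_A), rng)
        p = di.baum_welch(z, n_restarts=4, seed=0)
        assert p.transmat[0, 2] == 0.0
        assert p.transmat[2, 0] == 0.0
        p.validate(constrained=True)

    def test_restart_objective_monotonicity_asserted_in_engine(self):
        rng = np.random.default_rng(5)
        z = rng.normal(0, 1, 400)
        mu, sigma, A, pi = random_params(rng)
        fit = _em_fit(z, mu, sigma, A, pi, tol=1e-6, max_iter=80,
                      sigma_floor=1e-4, trans_pseudocount=0.0)
        assert fit is None or np.isfinite(fit[4])

    def test_parameter_recovery_single_seed(self):
        rng = np.random.default_rng(6)
        _, z = sample_hmm(20_000, TRUE_MU, TRUE_SD, TRUE_A,
                          stationary_distribution(TRUE_A), rng)
        p = di.baum_welch(z, n_restarts=4, seed=1)
        assert np.allclose(p.means, TRUE_MU, atol=0.08)
        assert np.allclose(p.transmat, TRUE_A, atol=0.03)


class TestViterbiLimits:
    def test_absorbing_start_ignores_observations(self):
        params = di.HMMParams(means=np.array([-1.0, 0.0, 1.0]),
                              sds=np.ones(3),
                              transmat=np.eye(3),
                              startprob=np.array([0.0, 1.0, 0.0]))
        z = np.array([5.0, -5.0, 4.0, -4.0])
        assert (di.viterbi(z, params) == STATE_I).all()

    def test_identical_emissions_leave_path_to_dynamics(self):
        A = np.array([[0.9, 0.1, 0.0],
                      [0.05, 0.9, 0.05],
                      [0.0, 0.1, 0.9]])
        params = di.HMMParams(means=np.zeros(3), sds=np.ones(3), transmat=A,
                              startprob=np.array([0.1, 0.8, 0.1]))
        z = np.zeros(6)
        assert (di.viterbi(z, params) == STATE_I).all()

    def test_posterior_lis_identities(self):
        rng = np.random.default_rng(7)
        _, z = sample_hmm(300, TRUE_MU, TRUE_SD, TRUE_A,
                          stationary_distribution(TRUE_A), rng)
        params = di.HMMParams(means=TRUE_MU, sds=TRUE_SD, transmat=TRUE_A,
                              startprob=stationary_distribution(TRUE_A))
        dec = di.posterior_lis(z, params)
        assert np.allclose(dec.gamma.sum(axis=1), 1.0, atol=1e-12)
        lis_i = 1.0 - dec.gamma[:, STATE_I]
        assert np.allclose(dec.lis_l + lis_i + dec.lis_h, 2.0, atol=1e-12)

    def test_extreme_observation_is_confidently_high(self):
        params = di.HMMParams(means=np.array([-2.0, 0.0, 2.0]),
                              sds=np.array([0.5, 0.5, 0.5]),
                              transmat=TRUE_A,
                              startprob=stationary_distribution(TRUE_A))
        z = np.array([0.0, 0.0, 7.0, 0.0, 0.0])
        dec = di.posterior_lis(z, params)
        assert dec.lis_h[2] < 1e-3


class TestFdrSelect:
    def test_toy_vector_selects_exactly_two(self):
        mask = di.fdr_select(np.array([0.0005, 0.0012, 0.0020]), alpha=0.001)
        assert mask.tolist() == [True, True, False]

    def test_all_zero_lis_selects_everything(self):
        assert di.fdr_select(np.zeros(5), alpha=0.001).all()

    def test_nothing_selected_when_minimum_exceeds_alpha(self):
        assert not di.fdr_select(np.array([0.01, 0.2, 0.5]), alpha=0.001).any()

    def test_matches_bruteforce_over_prefixes(self):
        rng = np.random.default_rng(8)
        lis = rng.random(50) ** 3
        alpha = 0.05
        srt = np.sort(lis)
        best_k = 0
        for k in range(1, 51):
            if srt[:k].mean() <= alpha:
                best_k = k
        assert di.fdr_select(lis, alpha).sum() == best_k


class TestIslandCalling:
    def decode_frame(self, viterbi, fdr_h=None, fdr_l=None):
        n = len(viterbi)
        return pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(n)],
            "chrom": "1",
            "pos": np.arange(1, n + 1) * 1000,
            "fst": np.linspace(0.1, 0.2, n),
            "h_bp": 0.3,
            "z": np.zeros(n),
            "viterbi": np.asarray(viterbi, dtype=np.int8),
            "fdr_h": np.zeros(n, bool) if fdr_h is None else np.asarray(fdr_h),
            "fdr_l": np.zeros(n, bool) if fdr_l is None else np.asarray(fdr_l),
        })

    def test_run_without_fdr_snp_is_dropped(self):
        t = self.decode_frame([1, 2, 2, 2, 1, 1])
        assert di.call_islands(t) == []

    def test_all_intermediate_gives_no_islands(self):
        assert di.call_islands(self.decode_frame([1] * 6)) == []

    def test_two_runs_one_supported(self):
        v = [2, 2, 1, 1, 2, 2, 2, 1]
        fdr_h = [False] * 8
        fdr_h[5] = True
        (isl,) = di.call_islands(self.decode_frame(v, fdr_h=fdr_h))
        assert isl.type == "HDI"
        assert (isl.start, isl.end) == (5000, 7000)
        assert isl.n_snps == 3 and isl.n_fdr_snps == 1
        assert isl.length_bp == 2001

    def test_low_runs_called_independently(self):
        v = [0, 0, 1, 2, 2]
        t = self.decode_frame(v, fdr_h=[False] * 5,
                              fdr_l=[True, False, False, False, False])
        (isl,) = di.call_islands(t)
        assert isl.type == "LDI" and isl.n_snps == 2


class TestSummaries:
    def test_single_snp_island_means_equal_snp_values(self):
        isl = di.Island(chrom="1", start=500, end=500, type="HDI", n_snps=1,
                        n_fdr_snps=1, mean_fst=0.42, mean_het=0.33, mean_z=2.2)
        df = di.summarize_islands([isl])
        assert df.loc[0, "mean_fst"] == 0.42
        assert df.loc[0, "length_bp"] == 1

    def test_recmap_weighted_mean_rate(self):
        recmap = di.RecombinationMap(
            chrom=np.array(["1", "1"], dtype=object),
            start=np.array([0, 1000]), end=np.array([1000, 2000]),
            rate=np.array([1.0, 3.0]))
        isl = di.Island(chrom="1", start=501, end=1500, type="HDI", n_snps=5,
                        n_fdr_snps=1, mean_fst=0.3, mean_het=0.3, mean_z=2.0)
        df = di.summarize_islands([isl], recmap)
        assert df.loc[0, "mean_rec_rate"] == pytest.approx(2.0)

    def test_island_outside_map_gets_missing_rate(self):
        recmap = di.RecombinationMap(chrom=np.array(["2"], dtype=object),
                                     start=np.array([0]), end=np.array([1000]),
                                     rate=np.array([1.0]))
        isl = di.Island(chrom="1", start=1, end=10, type="LDI", n_snps=1,
                        n_fdr_snps=1, mean_fst=0.0, mean_het=0.2, mean_z=-2.5)
        df = di.summarize_islands([isl], recmap)
        assert np.isnan(df.loc[0, "mean_rec_rate"])

    def test_aggregate_extrema_bracket_islands(self):
        islands = [di.Island(chrom="1", start=1, end=100, type="HDI", n_snps=3,
                             n_fdr_snps=1, mean_fst=f, mean_het=0.3, mean_z=2.0)
                   for f in (0.2, 0.4, 0.6)]
        agg = di.summarize_by_type(di.summarize_islands(islands))
        assert agg.loc["HDI", ("mean_fst", "min")] <= 0.2
        assert agg.loc["HDI", ("mean_fst", "max")] >= 0.6


class TestModelCheck:
    def test_featureless_chromosome_fails_bic(self):
        rng = np.random.default_rng(9)
        z = rng.normal(0, 1, 2000)
        p = di.baum_welch(z, n_restarts=8, seed=2)
        assert bic_advantage(z, p) <= 0.0

    def test_island_bearing_chromosome_passes_bic(self):
        rng = np.random.default_rng(10)
        z = rng.normal(0, 1, 2000)
        z[800:900] = rng.normal(3.0, 0.5, 100)
        p = di.baum_welch(z, n_restarts=8, seed=3)
        assert bic_advantage(z, p) > 0.0

    def test_hmmlearn_crosscheck_posteriors(self):
        """Forward-backward under fixed parameters agrees with the
        independent hmmlearn implementation."""
        hmm = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(11)
        _, z = sample_hmm(500, TRUE_MU, TRUE_SD, TRUE_A,
                          stationary_distribution(TRUE_A), rng)
        params = di.HMMParams(means=TRUE_MU, sds=TRUE_SD, transmat=TRUE_A,
                              startprob=stationary_distribution(TRUE_A))
        m = hmm.GaussianHMM(n_components=3, covariance_type="diag",
                            init_params="", params="")
        m.startprob_ = params.startprob
        m.transmat_ = params.transmat
        m.means_ = TRUE_MU[:, None]
        m.covars_ = (TRUE_SD ** 2)[:, None]
        ll_ref, gamma_ref = m.score_samples(z[:, None])
        dec = di.posterior_lis(z, params)
        assert np.allclose(dec.gamma, gamma_ref, atol=1e-8)
        B = _emissions(z, params.means, params.sds)
        ll, *_ = _forward_backward(B, params.transmat, params.startprob)
        assert ll == pytest.approx(ll_ref, abs=1e-8)
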
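"""Emission model, exact inference, EM fitting and state-count selection."""

import itertools
import math

import numpy as np
import pytest

from kayakpace import (
    AthleteSequence,
    Event,
    HMMParams,
    PacingStateModel,
    align_states,
    em_fit,
    emission_logdensity,
    emission_mean,
    forward_backward,
    mixture_mean,
    permute_states,
    published_params,
    select_n_states,
    viterbi,
)
from kayakpace.hmm import aic as compute_aic
from kayakpace.hmm import loglikelihood
from kayakpace.synthetic import simulate_score_sequences


def random_params(rng, n_states, n_dim=4, n_cov=0, names=()):
    return HMMParams(
        startprob=rng.dirichlet(np.ones(n_states)),
        transmat=rng.dirichlet(np.ones(n_states), size=n_states),
        coefs=rng.normal(size=(n_states, n_dim, 1 + n_cov)),
        variances=rng.uniform(0.3, 1.5, size=(n_states, n_dim)),
        covariate_names=names,
    )


def brute_force(params, seq):
    """Enumerate all state paths: exact total likelihood and best path."""
    n = params.n_states
    T = len(seq)
    total = 0.0
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(n), repeat=T):
        lp = math.log(params.startprob[path[0]]) + emission_logdensity(
            params, path[0], seq.observations[0], seq.covariates[0]
        )
        for t in range(1, T):
            lp += math.log(params.transmat[path[t - 1], path[t]])
            lp += emission_logdensity(
                params, path[t], seq.observations[t], seq.covariates[t]
            )
        total += math.exp(lp)
        if lp > best_lp:
            best_lp, best_path = lp, path
    return math.log(total), best_path


class TestEmissionModel:
    def test_published_womens_baseline_state1(self):
        params = published_params(Event.W_K1_500)
        m = emission_mean(params, 0, np.zeros(4))
        assert m == pytest.approx([0.173, 0.230, -0.003, -0.028])

    def test_published_state3_world_champs(self):
        # intercept plus the championship effect, Open age group
        params = published_params(Event.W_K1_500)
        z = np.array([0, 0, 0, 1.0])  # WorldChampsOlympics
        assert emission_mean(params, 2, z)[0] == pytest.approx(-0.373 + 0.618)

    def test_zero_coefficients_zero_mean(self):
        params = HMMParams(
            startprob=[1.0], transmat=[[1.0]],
            coefs=np.zeros((1, 4, 3)), variances=np.ones((1, 4)),
            covariate_names=("a", "b"),
        )
        assert np.allclose(emission_mean(params, 0, [1.0, 1.0]), 0.0)

    def test_mixture_degenerate_probability(self):
        params = published_params(Event.W_K1_500)
        z = np.zeros(4)
        assert np.allclose(
            mixture_mean(params, [0, 0, 1, 0], z), emission_mean(params, 2, z)
        )

    def test_mixture_uniform_average(self):
        params = published_params(Event.W_K1_500)
        m = mixture_mean(params, [0.25] * 4, np.zeros(4))
        assert m[0] == pytest.approx((0.173 - 0.418 - 0.373 + 0.063) / 4)

    def test_mixture_two_state_toy(self):
        params = HMMParams(
            startprob=[0.5, 0.5], transmat=np.eye(2),
            coefs=np.array([[[1.0]], [[3.0]]]).reshape(2, 1, 1),
            variances=np.ones((2, 1)),
        )
        assert mixture_mean(params, [0.5, 0.5], np.zeros(0))[0] == pytest.approx(2.0)

    def test_mixture_rejects_improper_probabilities(self):
        params = published_params(Event.W_K1_500)
        with pytest.raises(ValueError):
            mixture_mean(params, [0.5, 0.5, 0.5, 0.5], np.zeros(4))

    def test_logdensity_at_mean_closed_form(self):
        params = HMMParams(
            startprob=[1.0], transmat=[[1.0]],
            coefs=np.zeros((1, 4, 1)), variances=np.ones((1, 4)),
        )
        ld = emission_logdensity(params, 0, np.zeros(4), np.zeros(0))
        assert ld == pytest.approx(-2.0 * math.log(2 * math.pi))

    def test_logdensity_matches_full_covariance_oracle(self, rng):
        from scipy.stats import multivariate_normal

        params = random_params(rng, 3, n_cov=2, names=("u", "v"))
        z = np.array([1.0, 0.0])
        o = rng.normal(size=4)
        for j in range(3):
            m = emission_mean(params, j, z)
            oracle = multivariate_normal(m, np.diag(params.variances[j])).logpdf(o)
            assert emission_logdensity(params, j, o, z) == pytest.approx(
                oracle, abs=1e-12
            )


class TestExactInference:
    def test_single_state_posteriors(self, rng):
        params = random_params(rng, 1)
        seq = AthleteSequence("a", rng.normal(size=(5, 4)), np.zeros((5, 0)))
        gamma, _, ll = forward_backward(params, seq)
        assert np.allclose(gamma, 1.0)
        direct = sum(
            emission_logdensity(params, 0, seq.observations[t], seq.covariates[t])
            for t in range(5)
        )
        assert ll == pytest.approx(direct)
        assert np.all(viterbi(params, seq) == 0)

    @pytest.mark.parametrize("n,T", [(2, 3), (2, 6), (3, 4), (3, 6)])
    def test_matches_path_enumeration(self, n, T):
        rng = np.random.default_rng(100 * n + T)
        params = random_params(rng, n, n_dim=2)
        seq = AthleteSequence("a", rng.normal(size=(T, 2)), np.zeros((T, 0)))
        ll_oracle, path_oracle = brute_force(params, seq)
        _, _, ll = forward_backward(params, seq)
        assert ll == pytest.approx(ll_oracle, abs=1e-10)
        assert tuple(viterbi(params, seq)) == path_oracle

    def test_posterior_normalisation(self, rng):
        params = random_params(rng, 4)
        seq = AthleteSequence("a", rng.normal(size=(12, 4)), np.zeros((12, 0)))
        gamma, xi, _ = forward_backward(params, seq)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(xi.sum(axis=(1, 2)), 1.0, atol=1e-9)

    def test_no_underflow_on_long_sequences(self, rng):
        params = random_params(rng, 3)
        seq = AthleteSequence(
            "a", 50.0 + rng.normal(size=(500, 4)), np.zeros((500, 0))
        )
        _, _, ll = forward_backward(params, seq)
        assert np.isfinite(ll)

    def test_viterbi_tie_breaks_to_lowest_state(self):
        params = HMMParams(
            startprob=[0.5, 0.5],
            transmat=[[0.5, 0.5], [0.5, 0.5]],
            coefs=np.zeros((2, 2, 1)),
            variances=np.ones((2, 2)),
        )
        seq = AthleteSequence("a", np.zeros((6, 2)), np.zeros((6, 0)))
        assert np.all(viterbi(params, seq) == 0)

    def test_likelihood_matches_hmmlearn(self, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        params = random_params(rng, 3)
        seqs = [
            AthleteSequence(f"a{i}", rng.normal(size=(T, 4)), np.zeros((T, 0)))
            for i, T in enumerate([6, 9, 4])
        ]
        h = hmmlearn.GaussianHMM(n_components=3, covariance_type="diag", init_params="")
        h.startprob_ = params.startprob
        h.transmat_ = params.transmat
        h.means_ = params.coefs[:, :, 0]
        h.covars_ = params.variances
        X = np.vstack([s.observations for s in seqs])
        assert loglikelihood(params, seqs) == pytest.approx(
            h.score(X, [len(s) for s in seqs]), abs=1e-6
        )

    def test_label_permutation_leaves_likelihood_unchanged(self, rng):
        params = random_params(rng, 3)
        seqs = [
            AthleteSequence("a", rng.normal(size=(8, 4)), np.zeros((8, 0)))
        ]
        perm = np.array([2, 0, 1])
        assert loglikelihood(permute_states(params, perm), seqs) == pytest.approx(
            loglikelihood(params, seqs)
        )


@pytest.fixture(scope="module")
def fit_100x30(score_dataset_100x30):
    seqs, _ = score_dataset_100x30
    return em_fit(seqs, 4, n_restarts=10, seed=3)


class TestEMFit:
    def test_single_state_reduces_to_ols(self, rng):
        n_obs = 60
        Z = (rng.uniform(size=(n_obs, 2)) < 0.4).astype(float)
        X = np.hstack([np.ones((n_obs, 1)), Z])
        b_true = rng.normal(size=(4, 3))
        Y = X @ b_true.T + 0.3 * rng.standard_normal((n_obs, 4))
        seqs = [
            AthleteSequence("a", Y[:30], Z[:30], ("u", "v")),
            AthleteSequence("b", Y[30:], Z[30:], ("u", "v")),
        ]
        fit = em_fit(seqs, 1, n_restarts=1, seed=0)
        b_ols = np.linalg.solve(X.T @ X, X.T @ Y).T
        assert np.allclose(fit.params.coefs[0], b_ols, atol=1e-6)
        resid = Y - X @ b_ols.T
        assert np.allclose(
            fit.params.variances[0], (resid**2).mean(axis=0), atol=1e-6
        )

    def test_loglik_nondecreasing(self, womens_params_nocov):
        seqs, _ = simulate_score_sequences(womens_params_nocov, 20, 15, seed=4)
        fit = em_fit(seqs, 3, n_restarts=3, seed=9)
        h = fit.loglik_history
        assert np.all(np.diff(h) >= -1e-8 * (np.abs(h[:-1]) + 1.0))

    def test_transition_rows_on_simplex(self, womens_params_nocov):
        seqs, _ = simulate_score_sequences(womens_params_nocov, 20, 15, seed=4)
        fit = em_fit(seqs, 4, n_restarts=3, seed=9)
        A = fit.params.transmat
        assert np.all(A >= 0)
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(fit.params.startprob.sum(), 1.0)

    def test_parameter_recovery(self, womens_params_nocov, fit_100x30):
        fit = fit_100x30
        perm = align_states(fit.params, womens_params_nocov)
        est = permute_states(fit.params, perm)
        assert np.abs(est.transmat - womens_params_nocov.transmat).max() < 0.05
        assert (
            np.abs(est.coefs[:, :, 0] - womens_params_nocov.coefs[:, :, 0]).max()
            < 0.05
        )

    def test_decoded_self_transitions_match_truth(
        self, womens_params_nocov, fit_100x30
    ):
        fit = fit_100x30
        perm = align_states(fit.params, womens_params_nocov)
        inv = np.empty(4, dtype=int)
        inv[perm] = np.arange(4)
        trans = np.zeros((4, 4))
        for p in fit.decoded:
            mapped = inv[p]
            np.add.at(trans, (mapped[:-1], mapped[1:]), 1)
        freq = trans / trans.sum(axis=1, keepdims=True)
        assert (
            np.abs(np.diag(freq) - np.diag(womens_params_nocov.transmat)).max()
            < 0.05
        )

    def test_posterior_rows_sum_to_one(self, womens_params_nocov):
        seqs, _ = simulate_score_sequences(womens_params_nocov, 10, 10, seed=6)
        fit = em_fit(seqs, 2, n_restarts=2, seed=0)
        for g in fit.posteriors:
            assert np.allclose(g.sum(axis=1), 1.0, atol=1e-9)

    def test_too_few_observations_rejected(self, rng):
        seqs = [AthleteSequence("a", rng.normal(size=(5, 4)), np.zeros((5, 0)))]
        with pytest.raises(ValueError):
            em_fit(seqs, 4, n_restarts=1, seed=0)


class TestAIC:
    def test_closed_form_k(self):
        params = published_params(Event.W_K1_500)
        # n=4 states, d=4 dims, c=4 covariates
        assert params.n_parameters() == 3 + 12 + 80 + 16

    def test_zero_loglik_single_state(self, rng):
        from kayakpace.hmm import FitResult

        params = HMMParams(
            startprob=[1.0], transmat=[[1.0]],
            coefs=np.zeros((1, 4, 5)), variances=np.ones((1, 4)),
            covariate_names=("a", "b", "c", "d"),
        )
        fit = FitResult(
            params=params, loglik=0.0, aic=0.0, posteriors=[], decoded=[],
            n_restarts=1, seed=0, best_restart=0,
            loglik_history=np.array([0.0]), converged=True,
        )
        assert compute_aic(fit) == pytest.approx(48.0)

    def test_aic_differences_track_nested_fits(self, womens_params_nocov):
        seqs, _ = simulate_score_sequences(womens_params_nocov, 20, 20, seed=8)
        f2 = em_fit(seqs, 2, n_restarts=3, seed=1)
        f3 = em_fit(seqs, 3, n_restarts=3, seed=1)
        dk = f3.params.n_parameters() - f2.params.n_parameters()
        assert f3.aic - f2.aic == pytest.approx(
            -2 * (f3.loglik - f2.loglik) + 2 * dk, abs=1e-8
        )


class TestSelection:
    def test_single_gaussian_selects_one_state(self):
        params = HMMParams(
            startprob=[1.0], transmat=[[1.0]],
            coefs=np.array([0.1, 0.2, 0.0, -0.1]).reshape(1, 4, 1),
            variances=np.full((1, 4), 0.04),
        )
        seqs, _ = simulate_score_sequences(params, 50, 30, seed=2)
        best, table = select_n_states(seqs, range(1, 4), n_restarts=10, seed=5)
        assert best == 1
        assert set(table) == {1, 2, 3}

    def test_model_class_surface(self, womens_params_nocov):
        seqs, _ = simulate_score_sequences(womens_params_nocov, 15, 12, seed=13)
        res = PacingStateModel(seqs, 2).fit(n_restarts=2, seed=0)
        assert res.params.n_states == 2
        assert len(res.decoded) == 15
        assert "transition matrix" in res.summary()
        assert res.aic == pytest.approx(
            -2 * res.loglik + 2 * res.params.n_parameters()
        )

    def test_params_json_round_trip(self, tmp_path):
        params = published_params(Event.M_K1_1000)
        path = tmp_path / "model.json"
        params.save(path)
        loaded = HMMParams.load(path)
        assert np.array_equal(loaded.coefs, params.coefs)
        assert np.array_equal(loaded.transmat, params.transmat)
        assert loaded.covariate_names == params.covariate_names
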
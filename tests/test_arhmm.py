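import itertools

import numpy as np
import pytest

from bwdyn import arhmm, simulate
from bwdyn.arhmm import ARHMMParams, emission_stats, forward_backward, label_states


def enumerate_posteriors(params, y):
    """Brute-force smoothing marginals by summing over every state path."""
    le = emission_stats(params, y)
    Tm1, K = le.shape
    tot = -np.inf
    logps = {}
    for path in itertools.product(range(K), repeat=Tm1):
        lp = np.log(params.pi0[path[0]]) + le[0, path[0]]
        for t in range(1, Tm1):
            lp += np.log(params.A[path[t - 1], path[t]]) + le[t, path[t]]
        logps[path] = lp
        tot = np.logaddexp(tot, lp)
    gamma = np.zeros((Tm1, K))
    xi = np.zeros((Tm1 - 1, K, K))
    for path, lp in logps.items():
        w = np.exp(lp - tot)
        for t, s in enumerate(path):
            gamma[t, s] += w
        for t in range(Tm1 - 1):
            xi[t, path[t], path[t + 1]] += w
    return gamma, xi, tot


class TestEmissionStats:
    def test_density_at_its_mean(self, random_params):
        p = random_params
        y = np.concatenate([[25.0], 25.0 + np.cumsum(np.full(3, p.eta0[1]))])
        le = emission_stats(p, y)
        expected = -0.5 * np.log(2 * np.pi * p.total_var[1])
        assert le[0, 1] == pytest.approx(expected)

    def test_zero_intercept_variance_reduces_to_ar_noise(self):
        p = ARHMMParams(K=2, pi0=[0.5, 0.5], A=np.eye(2) * 0.8 + 0.1,
                        eta0=[0.3, -0.3], sigma0_sq=[0.0, 0.0], sigma_sq=[0.2, 0.2])
        y = np.array([20.0, 20.4, 20.1])
        le = emission_stats(p, y)
        dy = np.diff(y)
        manual = -0.5 * (np.log(2 * np.pi * 0.2) + (dy[:, None] - p.eta0) ** 2 / 0.2)
        np.testing.assert_allclose(le, manual)

    def test_middle_state_wins_at_zero_difference(self):
        p = ARHMMParams(K=3, pi0=np.full(3, 1 / 3), A=np.full((3, 3), 1 / 3),
                        eta0=[0.6, 0.0, -0.9], sigma0_sq=np.zeros(3),
                        sigma_sq=np.full(3, 0.25))
        y = np.array([25.0, 25.0])
        le = emission_stats(p, y)
        assert np.argmax(le[0]) == 1


class TestForwardBackward:
    def test_single_state_degenerate(self):
        p = ARHMMParams(K=1, pi0=[1.0], A=[[1.0]], eta0=[0.1],
                        sigma0_sq=[0.0], sigma_sq=[0.3])
        y = np.array([20.0, 20.3, 20.1, 20.6])
        post = forward_backward(p, y)
        np.testing.assert_allclose(post.gamma, 1.0)
        assert post.loglik == pytest.approx(emission_stats(p, y).sum())

    def test_symmetric_states_give_uniform_posterior(self):
        p = ARHMMParams(K=3, pi0=np.full(3, 1 / 3), A=np.full((3, 3), 1 / 3),
                        eta0=np.zeros(3), sigma0_sq=np.zeros(3),
                        sigma_sq=np.full(3, 0.3))
        y = np.array([20.0, 20.5, 19.9, 20.2, 20.4])
        post = forward_backward(p, y)
        np.testing.assert_allclose(post.gamma, 1 / 3, atol=1e-12)

    def test_matches_exhaustive_enumeration(self, random_params):
        rng = np.random.default_rng(11)
        y = rng.normal(25.0, 1.0, size=6)
        post = forward_backward(random_params, y)
        gamma_bf, xi_bf, ll_bf = enumerate_posteriors(random_params, y)
        assert post.loglik == pytest.approx(ll_bf, abs=1e-8)
        np.testing.assert_allclose(post.gamma, gamma_bf, atol=1e-8)
        np.testing.assert_allclose(post.xi, xi_bf, atol=1e-8)

    def test_posterior_marginal_consistency(self, random_params):
        rng = np.random.default_rng(5)
        y = rng.normal(25.0, 1.0, size=40)
        post = forward_backward(random_params, y)
        np.testing.assert_allclose(post.gamma.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(post.xi.sum(axis=2), post.gamma[:-1], atol=1e-8)
        np.testing.assert_allclose(post.xi.sum(axis=1), post.gamma[1:], atol=1e-8)

    def test_loglik_matches_hmmlearn(self, random_params):
        hmm = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(8)
        y = rng.normal(25.0, 1.0, size=30)
        dy = np.diff(y)
        m = hmm.GaussianHMM(n_components=3, covariance_type="diag", init_params="")
        m.startprob_ = random_params.pi0
        m.transmat_ = random_params.A
        m.means_ = random_params.eta0[:, None]
        m.covars_ = random_params.total_var[:, None]
        expected = m.score(dy[:, None])
        assert forward_backward(random_params, y).loglik == pytest.approx(expected, abs=1e-8)

    def test_too_short_trace_rejected(self, random_params):
        with pytest.raises(arhmm.ARHMMError):
            forward_backward(random_params, np.array([20.0]))


class TestFit:
    def test_single_state_closed_form(self):
        rng = np.random.default_rng(0)
        traces = [rng.normal(0.2, 0.4, size=50).cumsum() + 25 for _ in range(5)]
        fit = arhmm.fit_arhmm(traces, K=1, n_init=1, seed=0, mode="collapsed")
        dys = np.concatenate([np.diff(t) for t in traces])
        assert fit.params.eta0[0] == pytest.approx(dys.mean(), abs=1e-8)
        assert fit.params.sigma_sq[0] == pytest.approx(dys.var(), abs=1e-6)

    def test_parameter_recovery_and_labels(self):
        # traces drawn from the collapsed model itself (no event forcing,
        # homogeneous chain), so estimator and generator coincide
        from conftest import exact_model_config

        cfg = exact_model_config()
        traces, truth = simulate.simulate_cohort(cfg, seed=21, truncate_at_death=False)
        fit = arhmm.fit_arhmm(traces, K=3, n_init=3, seed=0, mode="collapsed")
        assert fit.state_labels == ("growth", "steady", "decline")
        # each drift within 3 Monte-Carlo SE of truth
        se = np.sqrt(fit.params.total_var / fit.state_counts)
        err = np.abs(fit.params.eta0 - np.asarray(cfg.eta0))
        assert np.all(err < 3 * se + 1e-3)

    def test_objective_monotone(self, small_cohort):
        cfg, traces, truth = small_cohort
        for mode in ("collapsed", "random_intercept"):
            fit = arhmm.fit_arhmm(traces[:10], K=3, n_init=1, seed=1, mode=mode,
                                  max_iter=80, tol=1e-10)
            steps = np.diff(fit.elbo_trace)
            assert np.all(steps >= -1e-6 * np.abs(fit.elbo_trace[:-1]))

    def test_random_intercept_matches_collapsed_in_limit(self, small_cohort):
        cfg, traces, truth = small_cohort
        fitc = arhmm.fit_arhmm(traces[:15], K=3, n_init=2, seed=0, mode="collapsed")
        fitv = arhmm.fit_arhmm(traces[:15], K=3, n_init=2, seed=0,
                               mode="random_intercept", fix_sigma0=1e-10,
                               max_iter=500, tol=1e-10)
        np.testing.assert_allclose(fitv.params.eta0, fitc.params.eta0, atol=1e-3)

    def test_decoding_accuracy_on_well_separated_states(self, small_cohort, fitted_collapsed):
        cfg, traces, truth = small_cohort
        acc = [
            np.mean(arhmm.decode(fitted_collapsed.params, tr).map_path
                    == truth.state_paths[tr.animal_id][1:])
            for tr in traces
        ]
        assert np.mean(acc) > 0.9

    def test_all_short_traces_rejected(self):
        with pytest.raises(arhmm.ARHMMError):
            arhmm.fit_arhmm([np.array([20.0, 20.5])], K=2)


class TestLabels:
    def test_sign_based_labeling(self):
        p = ARHMMParams(K=3, pi0=np.full(3, 1 / 3), A=np.full((3, 3), 1 / 3),
                        eta0=[0.5, 0.0, -0.6], sigma0_sq=np.zeros(3),
                        sigma_sq=np.full(3, 0.2))
        assert label_states(p) == {0: "growth", 1: "steady", 2: "decline"}

    def test_permutation_invariance(self):
        p = ARHMMParams(K=3, pi0=np.full(3, 1 / 3), A=np.full((3, 3), 1 / 3),
                        eta0=[-0.6, 0.5, 0.0], sigma0_sq=np.zeros(3),
                        sigma_sq=np.full(3, 0.2))
        assert label_states(p) == {0: "decline", 1: "growth", 2: "steady"}

    def test_tie_broken_by_smaller_noise_variance(self):
        p = ARHMMParams(K=3, pi0=np.full(3, 1 / 3), A=np.full((3, 3), 1 / 3),
                        eta0=[0.5, 0.5, -0.6], sigma0_sq=np.zeros(3),
                        sigma_sq=[0.1, 0.3, 0.2])
        lab = label_states(p)
        assert lab[0] == "steady" and lab[1] == "growth" and lab[2] == "decline"

    def test_non_three_state_gets_ordinal_ranks(self):
        p = ARHMMParams(K=2, pi0=[0.5, 0.5], A=np.full((2, 2), 0.5),
                        eta0=[-0.2, 0.4], sigma0_sq=np.zeros(2), sigma_sq=[0.2, 0.2])
        assert label_states(p) == {1: "rank0", 0: "rank1"}

    def test_relabeling_preserves_likelihood(self, random_params):
        rng = np.random.default_rng(2)
        y = rng.normal(25, 1, size=20)
        ll = forward_backward(random_params, y).loglik
        relabeled, perm = arhmm.relabel_params(random_params)
        assert forward_backward(relabeled, y).loglik == pytest.approx(ll, abs=1e-10)


class TestDecode:
    def test_argmax_rule(self, random_params):
        rng = np.random.default_rng(4)
        y = rng.normal(25, 1, size=10)
        post = arhmm.decode(random_params, y)
        np.testing.assert_array_equal(post.map_path, np.argmax(post.gamma, axis=1))

    def test_exact_tie_goes_to_lowest_index(self):
        gamma = np.array([[0.4, 0.4, 0.2], [0.1, 0.7, 0.2]])
        assert np.argmax(gamma, axis=1).tolist() == [0, 1]


class TestModelOrder:
    def test_single_state_data_selects_one_state(self):
        rng = np.random.default_rng(6)
        traces = [rng.normal(0.1, 0.3, size=60).cumsum() + 25 for _ in range(20)]
        best, dic = arhmm.select_model_order(traces[:14], traces[14:], K_range=[1, 2, 3],
                                             n_init=2, seed=0)
        assert best == 1

    def test_true_order_beats_one_state(self, small_cohort):
        cfg, traces, truth = small_cohort
        train, heldout = arhmm.train_test_split_traces(traces, 0.7, seed=0)
        best, dic = arhmm.select_model_order(train, heldout, K_range=[1, 3],
                                             n_init=2, seed=0)
        assert dic[3] < dic[1]
        assert best == 3

    def test_empty_range_rejected(self, small_cohort):
        cfg, traces, truth = small_cohort
        with pytest.raises(arhmm.ARHMMError):
            arhmm.select_model_order(traces[:5], traces[5:8], K_range=[])


class TestTrainTestSplit:
    def test_stratified_by_diet_and_disjoint(self, small_cohort):
        cfg, traces, truth = small_cohort
        train, heldout = arhmm.train_test_split_traces(traces, 0.7, seed=3)
        ids = {t.animal_id for t in train} & {t.animal_id for t in heldout}
        assert not ids
        assert len(train) + len(heldout) == len(traces)
        for diet in cfg.diets:
            n_tr = sum(t.diet == diet for t in train)
            n_all = sum(t.diet == diet for t in traces)
            assert n_tr == round(0.7 * n_all)
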
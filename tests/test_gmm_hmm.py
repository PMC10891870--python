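"""GMM-HMM: trellis correctness vs exhaustive enumeration and hmmlearn,
EM monotonicity/fixed point, parameter recovery, classification."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from conftest import make_tiny_hmm
from pigvoc.gmm_hmm import (
    ClassHMM,
    GMMHMMClassifier,
    baum_welch,
    classify,
    forward_backward,
    init_model,
    load_model,
    sample_sequence,
    save_model,
    viterbi,
)


def log_gauss(x, mu, var):
    return -0.5 * (np.log(2 * np.pi * var) + (x - mu) ** 2 / var)


def brute_force(model, obs):
    """Log-likelihood and best path by enumerating every state path."""
    N, T = model.n_states, obs.shape[0]
    path_logs = []
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(N), repeat=T):
        with np.errstate(divide="ignore"):
            lp = np.log(model.pi[path[0]])
            for t in range(1, T):
                lp += np.log(model.trans[path[t - 1], path[t]])
        if not np.isfinite(lp):
            continue
        for t in range(T):
            comp = [np.log(model.weights[path[t], k])
                    + np.sum(log_gauss(obs[t], model.means[path[t], k],
                                       model.variances[path[t], k]))
                    for k in range(model.n_components)]
            lp += logsumexp(comp)
        path_logs.append(lp)
        if lp > best_lp:
            best_lp, best_path = lp, path
    return logsumexp(path_logs), best_lp, np.array(best_path)


class TestTrellis:
    @pytest.mark.parametrize("seed", range(5))
    def test_forward_matches_enumeration(self, seed, tiny_hmm):
        rng = np.random.default_rng(seed)
        obs = rng.standard_normal((6, 1)) + rng.uniform(0, 6)
        res = forward_backward(tiny_hmm, obs)
        ll, _, _ = brute_force(tiny_hmm, obs)
        assert abs(res.log_likelihood - ll) <= 1e-10

    def test_alpha_beta_terminations_agree(self, tiny_hmm, rng):
        # logsumexp(alpha_t + beta_t) equals the total log-likelihood at
        # every t; t=0 is the beta-initialization form, t=T-1 the alpha one
        obs = rng.standard_normal((8, 1)) + 2.0
        res = forward_backward(tiny_hmm, obs)
        for t in range(obs.shape[0]):
            ll_t = float(logsumexp(res.log_alpha[t] + res.log_beta[t]))
            assert abs(ll_t - res.log_likelihood) <= 1e-8

    def test_gamma_rows_normalized(self, tiny_hmm, rng):
        obs = rng.standard_normal((10, 1)) + 1.0
        res = forward_backward(tiny_hmm, obs)
        np.testing.assert_allclose(res.gamma.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(res.gamma_mix.sum(axis=2), res.gamma, atol=1e-10)

    def test_xi_consistent_with_gamma(self, tiny_hmm, rng):
        obs = rng.standard_normal((7, 1)) + 1.0
        res = forward_backward(tiny_hmm, obs)
        np.testing.assert_allclose(res.xi.sum(axis=2), res.gamma[:-1], atol=1e-10)

    def test_single_state_is_iid_gmm(self, rng):
        m = make_tiny_hmm(n_states=1)
        obs = rng.standard_normal((12, 1))
        res = forward_backward(m, obs)
        direct = float(np.sum(log_gauss(obs[:, 0], m.means[0, 0, 0],
                                        m.variances[0, 0, 0])))
        assert res.log_likelihood == pytest.approx(direct, abs=1e-10)

    def test_matches_hmmlearn_forward(self, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        m = make_tiny_hmm(dim=2)
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="diag",
                                   init_params="")
        ref.startprob_ = m.pi
        ref.transmat_ = m.trans
        ref.means_ = m.means[:, 0, :]
        ref.covars_ = m.variances[:, 0, :]
        obs = rng.standard_normal((15, 2)) + 2.0
        assert forward_backward(m, obs).log_likelihood == pytest.approx(
            float(ref.score(obs)), abs=1e-8)


class TestViterbi:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration(self, seed, tiny_hmm):
        rng = np.random.default_rng(seed)
        obs = rng.standard_normal((6, 1)) * 2 + 3
        ali = viterbi(tiny_hmm, obs)
        _, best_lp, best_path = brute_force(tiny_hmm, obs)
        assert ali.log_score == pytest.approx(best_lp, abs=1e-10)
        np.testing.assert_array_equal(ali.state_ids, best_path)

    def test_left_to_right_path_monotone(self, tiny_hmm, rng):
        obs = rng.standard_normal((20, 1))
        ali = viterbi(tiny_hmm, obs)
        assert ali.state_ids[0] == 0
        assert np.all(np.diff(ali.state_ids) >= 0)

    def test_single_state_score(self, rng):
        m = make_tiny_hmm(n_states=1)
        obs = rng.standard_normal((9, 1))
        ali = viterbi(m, obs)
        assert np.all(ali.state_ids == 0)
        direct = float(np.sum(log_gauss(obs[:, 0], m.means[0, 0, 0],
                                        m.variances[0, 0, 0])))
        assert ali.log_score == pytest.approx(direct, abs=1e-10)


class TestInitModel:
    def test_even_division_counts(self):
        seqs = [np.arange(10, dtype=float)[:, None]]
        m = init_model(seqs, n_states=5, n_components=1)
        # each state sees exactly 2 consecutive frames -> mean of the pair
        np.testing.assert_allclose(m.means[:, 0, 0], [0.5, 2.5, 4.5, 6.5, 8.5])

    def test_k1_state_mean_is_block_mean(self, rng):
        seq = rng.standard_normal((12, 3))
        m = init_model([seq], n_states=3, n_components=1)
        np.testing.assert_allclose(m.means[0, 0], seq[:4].mean(axis=0), atol=1e-12)

    def test_duplicated_sequences_same_model(self, rng):
        seq = rng.standard_normal((15, 2))
        a = init_model([seq], 3, 2, seed=0)
        b = init_model([seq, seq], 3, 2, seed=0)
        np.testing.assert_allclose(a.means, b.means)
        np.testing.assert_allclose(a.weights, b.weights)

    def test_short_sequences_skipped_then_error(self, rng):
        good = rng.standard_normal((10, 2))
        with pytest.warns(UserWarning):
            m = init_model([good, rng.standard_normal((2, 2))], 5, 1)
        assert m.n_states == 5
        with pytest.raises(ValueError):
            init_model([rng.standard_normal((2, 2))], 5, 1)

    def test_topology(self, rng):
        m = init_model([rng.standard_normal((20, 2))], 4, 1)
        np.testing.assert_array_equal(m.pi, [1, 0, 0, 0])
        assert m.trans[-1, -1] == 1.0
        for i in range(3):
            assert m.trans[i, i] == m.trans[i, i + 1] == 0.5


class TestBaumWelch:
    def test_loglik_non_decreasing(self, rng):
        true = make_tiny_hmm()
        seqs = [sample_sequence(true, 30, rng)[0] for _ in range(10)]
        init = init_model(seqs, 3, 1)
        _, hist = baum_welch(init, seqs, max_iter=15)
        assert np.all(np.diff(hist) >= -1e-8)

    def test_fixed_point_at_truth(self, rng):
        true = make_tiny_hmm(means=np.array([[[-4.0]], [[0.0]], [[4.0]]]))
        seqs = [sample_sequence(true, 60, rng)[0] for _ in range(200)]
        fit, _ = baum_welch(true, seqs, max_iter=1)
        assert np.max(np.abs(fit.means - true.means)) < 1e-1
        assert np.max(np.abs(fit.trans - true.trans)) < 5e-2

    def test_parameter_recovery_3state(self, rng):
        # self-loops chosen so the three states have comparable expected
        # durations over T = 80, the regime the flat start assumes
        true = ClassHMM(
            pi=np.array([1.0, 0, 0]),
            trans=np.array([[0.96, 0.04, 0], [0, 0.96, 0.04], [0, 0, 1.0]]),
            weights=np.ones((3, 1)),
            means=np.array([[[0.0, 0.0]], [[3.0, -3.0]], [[6.0, 3.0]]]),
            variances=np.ones((3, 1, 2)) * 0.5,
        )
        seqs = [sample_sequence(true, 80, rng)[0] for _ in range(100)]
        init = init_model(seqs, 3, 1)
        fit, hist = baum_welch(init, seqs, max_iter=30)
        # left-to-right flat start keeps the state order identifiable
        assert np.max(np.abs(fit.means[:, 0, :] - true.means[:, 0, :])) < 0.1
        for i in range(2):
            assert abs(fit.trans[i, i + 1] - true.trans[i, i + 1]) < 0.05

    def test_zero_transitions_stay_zero(self, rng):
        true = make_tiny_hmm()
        seqs = [sample_sequence(true, 30, rng)[0] for _ in range(5)]
        fit, _ = baum_welch(init_model(seqs, 3, 1), seqs, max_iter=10)
        mask = make_tiny_hmm().trans == 0
        np.testing.assert_array_equal(fit.trans[mask], 0.0)
        fit.validate()  # all ClassHMM invariants hold after EM


class TestClassify:
    def test_simulated_sequences_recovered(self):
        a = make_tiny_hmm(means=np.array([[[0.0]], [[1.0]], [[2.0]]]))
        b = make_tiny_hmm(means=np.array([[[6.0]], [[7.0]], [[8.0]]]))
        a.label, b.label = "a", "b"
        hits = 0
        rng = np.random.default_rng(0)
        for _ in range(100):
            obs, _ = sample_sequence(a, 20, rng)
            hits += classify([a, b], obs)[0] == "a"
        assert hits >= 95

    def test_tie_breaks_to_first(self, rng):
        a = make_tiny_hmm()
        b = make_tiny_hmm()
        a.label, b.label = "first", "second"
        obs = rng.standard_normal((10, 1))
        label, scores = classify([a, b], obs)
        assert label == "first"
        assert scores[0] == scores[1]

    def test_forward_scoring_option(self, rng):
        a = make_tiny_hmm(means=np.array([[[0.0]], [[1.0]], [[2.0]]]))
        b = make_tiny_hmm(means=np.array([[[9.0]], [[10.0]], [[11.0]]]))
        a.label, b.label = "a", "b"
        obs, _ = sample_sequence(a, 15, np.random.default_rng(3))
        assert classify([a, b], obs, scoring="forward")[0] == "a"


def test_model_json_round_trip(tmp_path, rng):
    m = init_model([rng.standard_normal((20, 4))], 3, 2, label="howl")
    path = tmp_path / "howl.json"
    save_model(m, path)
    back = load_model(path)
    np.testing.assert_allclose(back.means, m.means)
    np.testing.assert_allclose(back.trans, m.trans)
    assert back.label == "howl"


def test_classifier_estimator_contract(rng):
    a = make_tiny_hmm(means=np.array([[[0.0]], [[2.0]], [[4.0]]]))
    b = make_tiny_hmm(means=np.array([[[8.0]], [[10.0]], [[12.0]]]))
    X, y = [], []
    for lab, m in (("a", a), ("b", b)):
        for _ in range(8):
            X.append(sample_sequence(m, 25, rng)[0])
            y.append(lab)
    clf = GMMHMMClassifier(n_states=3, n_components=1, max_iter=10)
    clf.fit(X, y)
    assert list(clf.classes_) == ["a", "b"]
    assert clf.score(X, y) >= 0.9  # sklearn ClassifierMixin accuracy
    alis = clf.align(X, y)
    for ali in alis:
        assert ali.state_ids[0] == 0 and np.all(np.diff(ali.state_ids) >= 0)
    # get_params/set_params round trip
    clf2 = GMMHMMClassifier(**clf.get_params())
    assert clf2.get_params() == clf.get_params()
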
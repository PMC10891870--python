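"""Hybrid decoding: prior estimation, posterior-to-likelihood scaling and
per-class Viterbi over scaled likelihoods."""

import itertools

import numpy as np
import pytest

from conftest import make_tiny_hmm
from pigvoc.dnn import DNNParams, init_params
from pigvoc.features import splice
from pigvoc.gmm_hmm import Alignment, GMMHMMClassifier, sample_sequence
from pigvoc.hybrid import (
    DNNHMMClassifier,
    HybridModel,
    decode,
    estimate_state_priors,
    load_hybrid,
    save_hybrid,
    scaled_log_likelihoods,
    viterbi_scaled,
)


def ali(label, states):
    return Alignment(np.asarray(states, int), 0.0, label)


class TestStatePriors:
    def test_equal_occupancy_uniform(self):
        alis = [ali("a", [0, 1]), ali("b", [0, 1])]
        p = estimate_state_priors(alis, ["a", "b"], 2)
        np.testing.assert_allclose(p, 0.25)

    def test_add_one_smoothing_arithmetic(self):
        # 10 frames in unit 0, S_out = 25: p = (10+1)/(10+25) = 11/35
        alis = [ali("a", [0] * 10)]
        p = estimate_state_priors(alis, list("abcde"), 5)
        assert p[0] == pytest.approx(11 / 35)
        assert p[1] == pytest.approx(1 / 35)

    def test_sums_to_one(self, rng):
        alis = [ali("a", rng.integers(0, 3, 20)), ali("b", rng.integers(0, 3, 7))]
        p = estimate_state_priors(alis, ["a", "b"], 3)
        assert p.sum() == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_state_priors([], ["a"], 5)


def uniform_hybrid(n_classes=2, n_states=3, width=6, seed=0):
    labels = [f"c{i}" for i in range(n_classes)]
    tiny = make_tiny_hmm(n_states=n_states)
    return HybridModel(
        dnn=init_params([width, 8, n_classes * n_states], seed=seed),
        priors=np.full(n_classes * n_states, 1.0 / (n_classes * n_states)),
        class_labels=labels,
        n_states=n_states,
        pis={lab: tiny.pi for lab in labels},
        transes={lab: tiny.trans for lab in labels},
    )


class TestScaledLogLikelihoods:
    def test_posterior_over_prior(self):
        model = uniform_hybrid()
        model.priors = np.full(6, 1.0 / 6)
        model.priors[0] = 0.25
        model.priors[1:] = 0.75 / 5
        # craft a DNN emitting fixed posteriors via zero weights + bias logits
        for w in model.dnn.weights:
            w[:] = 0.0
        model.dnn.biases[-1][:] = 0.0
        model.dnn.biases[-1][0] = np.log(0.5 / (0.5 / 5))  # posterior 0.5 on unit 0
        sllh = scaled_log_likelihoods(model, np.zeros((1, 6)))
        assert sllh[0, 0] == pytest.approx(np.log(0.5 / 0.25))

    def test_uniform_priors_preserve_ranking(self, rng):
        model = uniform_hybrid(seed=4)
        X = rng.standard_normal((5, 6))
        from pigvoc.dnn import forward

        post = forward(model.dnn, X)
        sllh = scaled_log_likelihoods(model, X)
        np.testing.assert_array_equal(np.argsort(post, axis=1),
                                      np.argsort(sllh, axis=1))

    def test_prior_constant_shift(self, rng):
        model = uniform_hybrid(seed=2)
        X = rng.standard_normal((4, 6))
        a = scaled_log_likelihoods(model, X)
        model2 = uniform_hybrid(seed=2)
        model2.priors = model.priors * 1.0  # same
        b = scaled_log_likelihoods(model2, X) - np.log(2.0)
        model2.priors = model.priors  # unchanged; shift applied manually
        np.testing.assert_allclose(a - np.log(2.0), b, atol=1e-12)


class TestDecode:
    def test_tiny_instance_matches_enumeration(self, rng):
        model = uniform_hybrid(n_classes=2, n_states=3, seed=9)
        X = rng.standard_normal((6, 6))
        label, scores, path = decode(model, X)
        sllh = scaled_log_likelihoods(model, X)
        tiny = make_tiny_hmm(n_states=3)
        for c in range(2):
            best = -np.inf
            for p in itertools.product(range(3), repeat=6):
                with np.errstate(divide="ignore"):
                    lp = np.log(tiny.pi[p[0]])
                    for t in range(1, 6):
                        lp += np.log(tiny.trans[p[t - 1], p[t]])
                if not np.isfinite(lp):
                    continue
                lp += sum(sllh[t, c * 3 + p[t]] for t in range(6))
                best = max(best, lp)
            assert scores[c] == pytest.approx(best, abs=1e-10)

    def test_single_frame_score(self, rng):
        model = uniform_hybrid(n_classes=2, n_states=3, seed=1)
        X = rng.standard_normal((1, 6))
        label, scores, path = decode(model, X)
        sllh = scaled_log_likelihoods(model, X)
        # pi = [1,0,0]: score is the state-0 entry of each class
        assert scores[0] == pytest.approx(sllh[0, 0])
        assert scores[1] == pytest.approx(sllh[0, 3])
        assert list(path) == [0]

    def test_per_frame_constant_invariance(self, rng):
        model = uniform_hybrid(seed=3)
        X = rng.standard_normal((8, 6))
        _, scores, _ = decode(model, X)
        sllh = scaled_log_likelihoods(model, X)
        shift = rng.standard_normal(8)
        tiny = make_tiny_hmm(n_states=3)
        with np.errstate(divide="ignore"):
            lp, lt = np.log(tiny.pi), np.log(tiny.trans)
        for c in range(2):
            _, s = viterbi_scaled(lp, lt, sllh[:, c * 3:(c + 1) * 3] + shift[:, None])
            assert s - shift.sum() == pytest.approx(scores[c], abs=1e-9)


def test_exact_posteriors_reproduce_gmm_viterbi(rng):
    """If the network emitted exactly the per-frame GMM state posteriors
    p(q|x) = b_q(x) p(q) / p(x) with matching priors, the scaled
    log-likelihoods equal log b_q(x) minus a per-frame constant, so the
    hybrid Viterbi score equals the GMM-HMM Viterbi score up to a
    path-independent constant and the best path is identical."""
    from pigvoc.gmm_hmm import _log_gauss_mix, viterbi
    from scipy.special import logsumexp as lse

    m = make_tiny_hmm(means=np.array([[[0.0]], [[2.0]], [[4.0]]]))
    obs, _ = sample_sequence(m, 12, rng)
    _, log_b = _log_gauss_mix(m, obs)
    priors = np.array([0.5, 0.3, 0.2])
    log_post = log_b + np.log(priors)  # unnormalized frame posteriors
    log_px = lse(log_post, axis=1, keepdims=True)
    sllh = (log_post - log_px) - np.log(priors)  # what decode would see
    with np.errstate(divide="ignore"):
        path, score = viterbi_scaled(np.log(m.pi), np.log(m.trans), sllh)
    ref = viterbi(m, obs)
    np.testing.assert_array_equal(path, ref.state_ids)
    assert score + float(log_px.sum()) == pytest.approx(ref.log_score, abs=1e-9)


def test_trained_hybrid_learns_separable_classes(rng):
    a = make_tiny_hmm(means=np.array([[[0.0]], [[2.0]], [[4.0]]]))
    b = make_tiny_hmm(means=np.array([[[10.0]], [[12.0]], [[14.0]]]))
    X, y = [], []
    for lab, m in (("a", a), ("b", b)):
        for _ in range(10):
            X.append(sample_sequence(m, 30, rng)[0])
            y.append(lab)
    gmm = GMMHMMClassifier(n_states=3, n_components=1, max_iter=10).fit(X, y)
    hyb = DNNHMMClassifier(gmm_hmm=gmm, context=1, hidden=(16,), epochs=20,
                           batch_size=20, random_state=0).fit(X, y)
    assert hyb.score(X, y) >= gmm.score(X, y) - 0.05


def test_hybrid_json_round_trip(tmp_path, rng):
    model = uniform_hybrid(seed=6)
    path = tmp_path / "hybrid.json"
    save_hybrid(model, path)
    back = load_hybrid(path)
    X = rng.standard_normal((4, 6))
    np.testing.assert_allclose(scaled_log_likelihoods(model, X),
                               scaled_log_likelihoods(back, X), atol=1e-12)
    assert back.class_labels == model.class_labels
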
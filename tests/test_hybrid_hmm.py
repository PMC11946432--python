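"""Hybrid HMM: transitions, emissions, decoding oracles, degree readout."""

import itertools

import numpy as np
import pandas as pd
import pytest

from roadhypno.fusion import FeatureMatrix
from roadhypno.hybrid_hmm import (DEFAULT_COEFFICIENTS, DEFAULT_INTERCEPT,
                                  EmissionModel, HmmSpec, HybridHmm,
                                  emission_likelihood, estimate_transitions,
                                  forward_filter, hypnosis_degree, predict,
                                  train_emissions, train_from_matrices,
                                  viterbi_path)


# ---------------------------------------------------------------------------
# brute-force oracles


def enumerate_likelihood(pi, a, emissions):
    """Total likelihood by summing over every state path."""
    t_len, n = emissions.shape
    total = 0.0
    for path in itertools.product(range(n), repeat=t_len):
        p = pi[path[0]] * emissions[0, path[0]]
        for t in range(1, t_len):
            p *= a[path[t - 1], path[t]] * emissions[t, path[t]]
        total += p
    return total


def enumerate_viterbi(pi, a, emissions):
    """Best path by exhaustive enumeration; lexicographic tie-break."""
    t_len, n = emissions.shape
    best, best_p = None, -1.0
    for path in itertools.product(range(n), repeat=t_len):
        p = pi[path[0]] * emissions[0, path[0]]
        for t in range(1, t_len):
            p *= a[path[t - 1], path[t]] * emissions[t, path[t]]
        if p > best_p + 1e-300 and p > best_p:
            best, best_p = path, p
    return np.array(best), best_p


def random_hmm(rng, n_states, t_len):
    pi = rng.dirichlet(np.ones(n_states))
    a = rng.dirichlet(np.ones(n_states), size=n_states)
    emissions = rng.uniform(0.05, 2.0, size=(t_len, n_states))
    return pi, a, emissions


# ---------------------------------------------------------------------------
# transitions


class TestEstimateTransitions:
    def test_counting_no_smoothing(self):
        spec = estimate_transitions([np.array(["n", "n", "h", "h"])],
                                    states=["n", "h"], kappa=0.0)
        np.testing.assert_allclose(spec.transitions, [[0.5, 0.5], [0.0, 1.0]])

    def test_self_loop(self):
        spec = estimate_transitions([np.array(["n", "n", "n"])],
                                    states=["n", "h"], kappa=0.0)
        assert spec.transitions[0, 0] == 1.0

    def test_empty_row_pure_smoothing(self):
        spec = estimate_transitions([np.array(["n", "n"])],
                                    states=["n", "h"], kappa=1.0)
        np.testing.assert_allclose(spec.transitions[1], [0.5, 0.5])

    def test_unknown_label_error(self):
        with pytest.raises(ValueError, match="unknown state"):
            estimate_transitions([np.array(["n", "x"])], states=["n", "h"])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        seqs = [rng.choice(["n", "h"], size=30) for _ in range(4)]
        spec = estimate_transitions(seqs, states=["n", "h"], kappa=1.0)
        np.testing.assert_allclose(spec.transitions.sum(axis=1), 1.0, atol=1e-10)
        assert spec.initial.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# decoding vs. oracles


class TestForward:
    def test_single_state_posterior_and_loglik(self):
        emis = np.array([[0.3], [0.5], [0.2]])
        post, _, ll = forward_filter(np.array([1.0]), np.array([[1.0]]), emis)
        np.testing.assert_allclose(post, 1.0)
        assert ll == pytest.approx(np.log(0.3 * 0.5 * 0.2))

    def test_uniform_emissions_give_chain_marginals(self):
        pi = np.array([0.7, 0.3])
        a = np.array([[0.9, 0.1], [0.2, 0.8]])
        emis = np.ones((6, 2))
        post, _, _ = forward_filter(pi, a, emis)
        marg = pi.copy()
        for t in range(6):
            if t > 0:
                marg = marg @ a
            np.testing.assert_allclose(post[t], marg, atol=1e-10)

    def test_toy_likelihood_matches_enumeration(self):
        pi = np.array([0.6, 0.4])
        a = np.array([[0.7, 0.3], [0.4, 0.6]])
        emis = np.array([[0.9, 0.1], [0.2, 0.7], [0.5, 0.5]])
        _, _, ll = forward_filter(pi, a, emis)
        assert ll == pytest.approx(np.log(enumerate_likelihood(pi, a, emis)),
                                   abs=1e-12)

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        pi, a, emis = random_hmm(rng, 3, 40)
        post, _, _ = forward_filter(pi, a, emis)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)

    def test_loglik_invariant_to_per_step_emission_scaling(self):
        rng = np.random.default_rng(2)
        pi, a, emis = random_hmm(rng, 2, 20)
        _, _, ll1 = forward_filter(pi, a, emis)
        scales = rng.uniform(0.5, 2.0, size=(20, 1))
        _, _, ll2 = forward_filter(pi, a, emis * scales)
        assert ll2 - ll1 == pytest.approx(np.log(scales).sum(), abs=1e-9)

    def test_all_zero_emission_row_error(self):
        with pytest.raises(ValueError, match="all-zero emission"):
            forward_filter(np.array([0.5, 0.5]), np.full((2, 2), 0.5),
                           np.array([[1.0, 1.0], [0.0, 0.0]]))


class TestViterbi:
    @pytest.mark.parametrize("n_states,t_len", [(2, 5), (2, 8), (3, 5)])
    def test_matches_enumeration(self, n_states, t_len):
        rng = np.random.default_rng(100 * n_states + t_len)
        for _ in range(10):
            pi, a, emis = random_hmm(rng, n_states, t_len)
            path, score = viterbi_path(pi, a, emis)
            ref_path, ref_p = enumerate_viterbi(pi, a, emis)
            assert np.log(ref_p) == pytest.approx(score, abs=1e-10)
            np.testing.assert_array_equal(path, ref_path)

    def test_dominant_emissions_recover_path(self):
        rng = np.random.default_rng(3)
        true = rng.integers(0, 2, size=30)
        emis = np.full((30, 2), 1e-6)
        emis[np.arange(30), true] = 1.0
        pi = np.array([0.5, 0.5])
        a = np.full((2, 2), 0.5)
        path, _ = viterbi_path(pi, a, emis)
        np.testing.assert_array_equal(path, true)

    def test_exact_tie_prefers_lower_index(self):
        pi = np.array([0.5, 0.5])
        a = np.full((2, 2), 0.5)
        emis = np.ones((4, 2))
        path, _ = viterbi_path(pi, a, emis)
        np.testing.assert_array_equal(path, 0)

    def test_viterbi_score_below_total_likelihood(self):
        rng = np.random.default_rng(4)
        pi, a, emis = random_hmm(rng, 2, 12)
        _, _, ll = forward_filter(pi, a, emis)
        _, score = viterbi_path(pi, a, emis)
        assert score <= ll + 1e-12


# ---------------------------------------------------------------------------
# emissions


def _separable_matrix(n=400, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.array(["normal"] * (n // 2) + ["hypnosis"] * (n // 2))
    x = rng.normal(size=(n, 3))
    x[labels == "hypnosis", 0] += 4.0  # cleanly separated along feature 0
    df = pd.DataFrame(x, columns=["f1", "f2", "f3"])
    return FeatureMatrix(times=np.arange(n, dtype=float), data=df, labels=labels)


class TestTrainEmissions:
    def test_separable_posteriors_confident(self):
        m = _separable_matrix()
        model = train_emissions(m)
        post = model.posteriors(m.values)
        true_idx = (m.labels == "hypnosis").astype(int)
        frac = np.mean(post[np.arange(len(m)), true_idx] > 0.9)
        assert frac >= 0.95

    def test_posteriors_normalized(self):
        m = _separable_matrix(seed=1)
        model = train_emissions(m)
        post = model.posteriors(m.values)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-8)

    def test_uninformative_features_recover_priors(self):
        rng = np.random.default_rng(5)
        n = 2000
        labels = np.where(rng.random(n) < 0.3, "hypnosis", "normal")
        df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        m = FeatureMatrix(times=np.arange(n, dtype=float), data=df, labels=labels)
        model = train_emissions(m)
        post = model.posteriors(m.values)
        priors = np.array([(labels == "normal").mean(),
                           (labels == "hypnosis").mean()])
        assert np.abs(post - priors).mean() < 0.05

    def test_deterministic_under_fixed_seed(self):
        m = _separable_matrix(seed=2)
        p1 = train_emissions(m).posteriors(m.values)
        p2 = train_emissions(m).posteriors(m.values)
        np.testing.assert_array_equal(p1, p2)

    def test_state_with_too_few_examples_error(self):
        m = _separable_matrix()
        m.labels = np.array(["normal"] * (len(m) - 1) + ["hypnosis"])
        with pytest.raises(ValueError, match="fewer than 2"):
            train_emissions(m)


class TestEmissionLikelihood:
    def _dummy_model(self, priors):
        # bypass boosters: fabricate a model whose posteriors we control
        model = EmissionModel(states=["normal", "hypnosis"], feature_names=["x"],
                              boosters=[], platt=[], priors=np.asarray(priors))
        return model

    def test_posterior_equal_prior_gives_one(self, monkeypatch):
        model = self._dummy_model([0.5, 0.5])
        monkeypatch.setattr(model, "posteriors",
                            lambda x: np.array([[0.5, 0.5]]))
        np.testing.assert_allclose(emission_likelihood(model, np.zeros((1, 1))),
                                   1.0)

    def test_hard_posterior_scaled_and_floored(self, monkeypatch):
        model = self._dummy_model([0.5, 0.5])
        monkeypatch.setattr(model, "posteriors",
                            lambda x: np.array([[1.0, 0.0]]))
        out = emission_likelihood(model, np.zeros((1, 1)))
        assert out[0, 0] == pytest.approx(2.0)
        assert out[0, 1] >= 1e-12  # floored, never exactly zero

    def test_feature_dimension_mismatch_error(self):
        m = _separable_matrix()
        model = train_emissions(m)
        with pytest.raises(ValueError, match="expected 3 features"):
            model.posteriors(np.zeros((1, 5)))


# ---------------------------------------------------------------------------
# degree readout


class TestHypnosisDegree:
    def test_zero_vector_returns_intercept(self):
        assert hypnosis_degree(np.zeros(14)) == pytest.approx(0.471)

    def test_unit_speed_slot(self):
        x = np.zeros(14)
        x[0] = 1.0
        assert hypnosis_degree(x) == pytest.approx(0.702)

    def test_all_ones_named_slots(self):
        x = np.zeros(14)
        named = [0, 3, 4, 5, 6, 7, 8, 9, 11, 13]
        x[named] = 1.0
        assert hypnosis_degree(x) == pytest.approx(0.827)

    def test_reserved_slots_carry_zero_weight(self):
        x = np.zeros(14)
        x[[1, 2, 10, 12]] = 99.0
        assert hypnosis_degree(x) == pytest.approx(DEFAULT_INTERCEPT)

    def test_wrong_length_error(self):
        with pytest.raises(ValueError, match="expected 14 slots"):
            hypnosis_degree(np.zeros(10))

    def test_matrix_input_vectorized(self):
        rows = np.zeros((3, 14))
        rows[1, 0] = 1.0
        out = hypnosis_degree(rows)
        np.testing.assert_allclose(out, [0.471, 0.702, 0.471])


# ---------------------------------------------------------------------------
# end-to-end bundle


class TestEndToEnd:
    def test_predict_recovers_latent_path(self, small_matrices):
        bundle = train_from_matrices(small_matrices[:3])
        res = predict(small_matrices[3], bundle)
        acc = np.mean(res.viterbi_labels == small_matrices[3].labels)
        assert acc >= 0.9
        np.testing.assert_allclose(res.posteriors.sum(axis=1), 1.0, atol=1e-10)
        assert res.hypnosis_degree is not None
        assert len(res.hypnosis_degree) == len(small_matrices[3])

    def test_no_hypnosis_recording_low_posterior(self, small_matrices):
        bundle = train_from_matrices(small_matrices[:3])
        m = small_matrices[3]
        normal_mask = m.labels == "normal"
        sub = FeatureMatrix(times=m.times[normal_mask],
                            data=m.data[normal_mask].reset_index(drop=True),
                            labels=m.labels[normal_mask])
        res = predict(sub, bundle)
        assert res.posteriors[:, 1].mean() < 0.5

    def test_deterministic_rerun_bitwise(self, small_matrices):
        b1 = train_from_matrices(small_matrices[:3])
        b2 = train_from_matrices(small_matrices[:3])
        r1 = predict(small_matrices[3], b1)
        r2 = predict(small_matrices[3], b2)
        np.testing.assert_array_equal(r1.posteriors, r2.posteriors)
        np.testing.assert_array_equal(r1.viterbi, r2.viterbi)
        np.testing.assert_array_equal(r1.hypnosis_degree, r2.hypnosis_degree)

    def test_missing_modality_column_error(self, small_matrices):
        bundle = train_from_matrices(small_matrices[:3])
        m = small_matrices[3]
        crippled = FeatureMatrix(times=m.times, data=m.data.drop(columns=["beta"]),
                                 labels=m.labels)
        with pytest.raises(ValueError, match="missing feature column.*beta"):
            predict(crippled, bundle)

    def test_save_load_round_trip(self, small_matrices, tmp_path):
        bundle = train_from_matrices(small_matrices[:3])
        bundle.save(tmp_path / "model")
        back = HybridHmm.load(tmp_path / "model")
        np.testing.assert_allclose(back.spec.transitions,
                                   bundle.spec.transitions)
        r1 = predict(small_matrices[3], bundle)
        r2 = predict(small_matrices[3], back)
        np.testing.assert_allclose(r1.posteriors, r2.posteriors, atol=1e-12)
        np.testing.assert_array_equal(r1.viterbi, r2.viterbi)


def test_hmm_spec_validation():
    with pytest.raises(ValueError):
        HmmSpec(states=["a", "b"], initial=[0.5, 0.6],
                transitions=[[0.5, 0.5], [0.5, 0.5]])
    with pytest.raises(ValueError):
        HmmSpec(states=["a", "b"], initial=[0.5, 0.5],
                transitions=[[0.9, 0.2], [0.5, 0.5]])
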
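"""Discriminant scores: worked scalar values, Bayes oracle, limit behavior."""

import numpy as np
import pytest

from nblda import (
    CountMatrix,
    NBLDAModel,
    SizeFactors,
    TestSample,
    ValidationError,
    fit,
    labels_from_names,
    nblda_score,
    plda_score,
    predict,
)

from conftest import make_model, oracle_posteriors


def single_gene_model(lam, d, phi):
    K = 1 if np.isscalar(d) else len(d)
    d_arr = np.array([[d]]) if np.isscalar(d) else np.array(d)[:, None]
    pi_arr = np.array([1.0]) if K == 1 else np.full(K, 1.0 / K)
    return NBLDAModel(
        lambda_g=np.array([float(lam)]),
        d_kg=d_arr,
        pi_k=pi_arr,
        phi_hat=np.array([float(phi)]),
        sf=SizeFactors(s=np.array([1.0]), method="total_count", denominator=1.0),
        class_names=[f"c{k}" for k in range(K)],
        gene_ids=["g1"],
    )


class TestFit:
    def test_plug_in_estimates(self, small_counts, small_labels):
        model = fit(small_counts, small_labels)
        np.testing.assert_array_equal(model.lambda_g, small_counts.counts.sum(axis=1))
        # priors are empirical class frequencies
        np.testing.assert_allclose(model.pi_k, [0.5, 0.5])
        # d_kg via the +1 smoothed ratio, per class
        sf = model.sf.s
        for k in (1, 2):
            cols = small_labels.labels == k
            expect = (small_counts.counts[:, cols].sum(axis=1) + 1) / (
                sf[cols].sum() * model.lambda_g + 1
            )
            np.testing.assert_allclose(model.d_kg[k - 1], expect)

    def test_balanced_gene_with_equal_factors_gives_unit_effect(self):
        cm = CountMatrix(np.array([[5, 5]]), ["g1"], ["a", "b"])
        lv = labels_from_names(["k1", "k2"])
        model = fit(cm, lv)
        # s = (0.5, 0.5), lambda = 10 -> d = (5+1)/(0.5*10+1) = 1 for both classes
        np.testing.assert_allclose(model.d_kg, np.ones((2, 1)))

    def test_all_zero_gene_permitted_with_positive_effect(self):
        cm = CountMatrix(np.array([[0, 0], [3, 7]]), ["g1", "g2"], ["a", "b"])
        lv = labels_from_names(["k1", "k2"])
        model = fit(cm, lv)
        assert model.lambda_g[0] == 0
        np.testing.assert_allclose(model.d_kg[:, 0], 1.0)  # (0+1)/(s*0+1)
        assert np.all(model.d_kg > 0)

    def test_unbalanced_priors(self):
        cm = CountMatrix(np.arange(1, 9).reshape(2, 4), ["g1", "g2"], list("abcd"))
        lv = labels_from_names(["x", "x", "x", "y"])
        model = fit(cm, lv)
        np.testing.assert_allclose(model.pi_k, [0.75, 0.25])

    def test_label_length_mismatch_rejected(self, small_counts):
        with pytest.raises(ValidationError):
            fit(small_counts, labels_from_names(["a", "b"]))


class TestScoreValues:
    def test_nblda_single_gene_worked_value(self):
        # X*=4, s*=1, lambda=10, d=2, phi=0.5, pi=1:
        # 4*(ln2 - ln11) - 2*ln11 = -11.6148...
        model = single_gene_model(lam=10, d=2.0, phi=0.5)
        sv = nblda_score(model, TestSample(np.array([4]), ["g1"]), s_star=1.0)
        expect = 4 * (np.log(2) - np.log(11)) - 2 * np.log(11)
        assert sv.scores[0] == pytest.approx(expect, abs=1e-12)
        assert sv.scores[0] == pytest.approx(-11.6148, abs=1e-4)

    def test_plda_single_gene_worked_value(self):
        # X*=10, lambda=10, d=1.5, s*=1, pi=1: 10*ln1.5 - 15 = -10.9454...
        model = single_gene_model(lam=10, d=1.5, phi=0.0)
        sv = plda_score(model, TestSample(np.array([10]), ["g1"]), s_star=1.0)
        assert sv.scores[0] == pytest.approx(10 * np.log(1.5) - 15, abs=1e-12)
        assert sv.scores[0] == pytest.approx(-10.9454, abs=1e-4)

    def test_zero_dispersion_reduces_to_poisson_score(self):
        rng = np.random.default_rng(10)
        model = make_model(rng, G=30, K=3, phi_scale=0.0)
        x = TestSample(rng.poisson(5, size=30))
        nb = nblda_score(model, x, 0.8).scores
        pl = plda_score(model, x, 0.8).scores
        np.testing.assert_allclose(nb, pl, atol=1e-10)

    def test_symmetric_classes_tie_to_first(self):
        model = single_gene_model(lam=10, d=[1.2, 1.2], phi=0.3)
        sv = nblda_score(model, TestSample(np.array([7]), ["g1"]), 1.0)
        assert sv.scores[0] == sv.scores[1]
        assert sv.predicted == 1

    def test_null_effects_plda_constant(self):
        rng = np.random.default_rng(11)
        model = make_model(rng, G=20, K=2)
        model.d_kg[:] = 1.0
        model.pi_k[:] = 0.5
        x = TestSample(rng.poisson(5, size=20))
        sv = plda_score(model, x, 0.7)
        expect = -0.7 * model.lambda_g.sum() + np.log(0.5)
        np.testing.assert_allclose(sv.scores, expect)

    def test_invalid_inputs_rejected(self):
        model = single_gene_model(lam=10, d=2.0, phi=0.5)
        with pytest.raises(ValidationError, match="positive"):
            nblda_score(model, TestSample(np.array([4]), ["g1"]), s_star=0.0)
        with pytest.raises(ValidationError, match="genes"):
            nblda_score(model, TestSample(np.array([4, 5])), s_star=1.0)
        with pytest.raises(ValidationError):
            NBLDAModel(
                lambda_g=np.array([10.0]),
                d_kg=np.array([[-1.0]]),
                pi_k=np.array([1.0]),
                phi_hat=np.array([0.5]),
                sf=SizeFactors(np.array([1.0]), "total_count", 1.0),
                class_names=["c"],
                gene_ids=["g1"],
            )


class TestLimitEquivalence:
    def test_gap_vanishes_monotonically_as_phi_to_zero(self):
        rng = np.random.default_rng(12)
        model = make_model(rng, G=40, K=2, phi_scale=0.0, lam_scale=5.0)
        x = TestSample(rng.poisson(3, size=40))
        gaps = []
        for phi in (1e-2, 1e-4, 1e-6):
            model.phi_hat[:] = phi
            gap = np.max(
                np.abs(nblda_score(model, x, 1.0).scores - plda_score(model, x, 1.0).scores)
            )
            gaps.append(gap)
        assert gaps[0] > gaps[1] > gaps[2]
        # gap ~ phi * sum_g a_g (X*_g + a_g/2) with a_g = s* lambda_g d_kg
        a_max = float(np.max(model.lambda_g[None, :] * model.d_kg))
        bound = 1e-6 * 40 * a_max * (x.counts.max() + a_max / 2)
        assert gaps[2] < bound


class TestPredictAndPosteriors:
    def test_posteriors_match_bruteforce_bayes(self):
        """Softmax of the discriminant score equals direct Bayes posteriors
        from the full NB pmf (all class-independent constants kept)."""
        rng = np.random.default_rng(13)
        for _ in range(25):
            K = int(rng.integers(2, 4))
            G = int(rng.integers(1, 11))
            model = make_model(rng, G=G, K=K, phi_scale=0.8, lam_scale=10.0)
            x = TestSample(rng.integers(0, 50, size=G))
            s_star = float(rng.uniform(0.3, 2.0))
            ours = nblda_score(model, x, s_star).posteriors()
            oracle = oracle_posteriors(model, x, s_star)
            np.testing.assert_allclose(ours, oracle, atol=1e-8)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(14)
        model = make_model(rng, G=25, K=4)
        x = TestSample(rng.poisson(8, size=25))
        post = nblda_score(model, x, 1.1).posteriors()
        assert abs(post.sum() - 1.0) < 1e-12

    def test_gene_permutation_invariance(self):
        rng = np.random.default_rng(15)
        model = make_model(rng, G=20, K=2)
        x = rng.poisson(6, size=20)
        base = nblda_score(model, TestSample(x), 0.9).scores
        perm = rng.permutation(20)
        pmodel = NBLDAModel(
            lambda_g=model.lambda_g[perm],
            d_kg=model.d_kg[:, perm],
            pi_k=model.pi_k,
            phi_hat=model.phi_hat[perm],
            sf=model.sf,
            class_names=model.class_names,
            gene_ids=[model.gene_ids[i] for i in perm],
        )
        permuted = nblda_score(pmodel, TestSample(x[perm]), 0.9).scores
        np.testing.assert_allclose(permuted, base, rtol=1e-12)

    def test_single_class_always_predicted_with_posterior_one(self, small_counts):
        with pytest.warns(UserWarning):
            lv = labels_from_names(["only"] * 4)
        model = fit(small_counts, lv)
        preds, post = predict(model, small_counts)
        assert np.all(preds == 1)
        np.testing.assert_allclose(post, 1.0)

    def test_predict_uses_models_size_factor_method(self, small_counts, small_labels):
        model = fit(small_counts, small_labels, sf_method="total_count")
        # a test sample equal to training sample 0 gets s* = s_0, and the
        # per-sample scores agree with calling the score function directly
        preds, post = predict(model, small_counts.sample(0))
        sv = nblda_score(model, small_counts.sample(0), model.sf.s[0])
        assert preds[0] == sv.predicted
        np.testing.assert_allclose(post[0], sv.posteriors())

    def test_gene_id_mismatch_rejected(self, small_counts, small_labels):
        model = fit(small_counts, small_labels)
        bad = CountMatrix(small_counts.counts, ["x1", "x2", "x3"], small_counts.sample_ids)
        with pytest.raises(ValidationError):
            predict(model, bad)
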
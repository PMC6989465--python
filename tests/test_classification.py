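import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gma.classification import (
    LLGMN,
    CanonicalizationParams,
    canonicalize,
    classify_interval,
    entropy,
    fit_canonicalization,
)
from gma.synthetic import gaussian_class_specs, generate_index_samples


class TestCanonicalization:
    def test_two_sample_arithmetic(self):
        params = fit_canonicalization(np.array([[0.0], [2.0]]))
        assert params.mu[0] == 1.0 and params.sigma[0] == 1.0

    def test_self_canonicalization_standardizes(self, rng):
        x = rng.random((62, 25)) * 10  # reference-set size: 31 WM + 31 FM
        params = fit_canonicalization(x)
        z = canonicalize(x, params)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-9)

    def test_zero_variance_error_names_position(self):
        x = np.ones((5, 3))
        x[:, 0] = np.arange(5)
        x[:, 2] = np.arange(5)
        with pytest.raises(ValueError, match=r"\[1\]"):
            fit_canonicalization(x)

    def test_unit_shift_maps_to_one(self):
        params = CanonicalizationParams(np.array([2.0]), np.array([3.0]))
        assert canonicalize(np.array([5.0]), params)[0] == pytest.approx(1.0)

    def test_round_trip_recovers_input(self, rng):
        x = rng.random((10, 4))
        params = fit_canonicalization(x)
        z = canonicalize(x, params)
        np.testing.assert_allclose(z * params.sigma + params.mu, x, atol=1e-10)

    def test_dimension_mismatch_raises(self):
        params = CanonicalizationParams(np.zeros(3), np.ones(3))
        with pytest.raises(ValueError, match="mismatch"):
            canonicalize(np.zeros(4), params)


class TestLLGMN:
    def test_posteriors_normalized_on_random_inputs(self, rng):
        Z, y, _ = generate_index_samples(gaussian_class_specs(4, dim=5), 20, seed=0)
        model = LLGMN(4, seed=0).fit(Z, y)
        probe = rng.standard_normal((500, 5)) * 3
        post = model.predict_proba(probe)
        assert np.all(post >= 0)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_separated_classes_high_training_accuracy(self):
        specs = gaussian_class_specs(2, dim=5, separation=6.0)
        Z, y, _ = generate_index_samples(specs, 50, seed=1)
        model = LLGMN(2, seed=0).fit(Z, y)
        assert (model.predict(Z) == y).mean() >= 0.99

    def test_class_mean_classified_to_its_class(self):
        specs = gaussian_class_specs(3, dim=4, separation=6.0)
        Z, y, _ = generate_index_samples(specs, 40, seed=2)
        model = LLGMN(3, seed=0).fit(Z, y)
        means = np.stack([specs[f"class{c}"][0] for c in range(3)])
        assert list(model.predict(means)) == [0, 1, 2]

    def test_symmetry_plane_posterior_is_half(self):
        specs = gaussian_class_specs(2, dim=2, separation=3.0)
        Z, y, _ = generate_index_samples(specs, 400, seed=3)
        model = LLGMN(2, l2=0.1, seed=0).fit(Z, y)
        # means are 3*e0 and 3*e1; the symmetry plane contains t*(1,1)
        # (probe points stay inside the training cloud, where the fitted
        # posterior is constrained by data rather than the ridge prior)
        probe = np.array([[0.0, 0.0], [1.0, 1.0], [1.5, 1.5]])
        post = model.predict_proba(probe)
        np.testing.assert_allclose(post[:, 0], 0.5, atol=0.1)

    def test_sample_order_invariance(self, rng):
        Z, y, _ = generate_index_samples(gaussian_class_specs(2, dim=3), 30, seed=4)
        perm = rng.permutation(len(y))
        m1 = LLGMN(2, seed=0).fit(Z, y)
        m2 = LLGMN(2, seed=0).fit(Z[perm], y[perm])
        probe = rng.standard_normal((50, 3))
        np.testing.assert_allclose(
            m1.predict_proba(probe), m2.predict_proba(probe), atol=1e-4
        )

    def test_posterior_field_matches_gaussian_bayes(self):
        # one component per class on shared-spherical data: the network can
        # represent the exact Bayes posterior
        specs = gaussian_class_specs(2, dim=2, separation=2.0)
        Z, y, _ = generate_index_samples(specs, 1000, seed=5)
        model = LLGMN(2, l2=1e-3, seed=0).fit(Z, y)
        probe = np.random.default_rng(6).normal(0, 1.5, (400, 2))
        mu0, mu1 = specs["class0"][0], specs["class1"][0]
        d0 = ((probe - mu0) ** 2).sum(axis=1)
        d1 = ((probe - mu1) ** 2).sum(axis=1)
        bayes = 1.0 / (1.0 + np.exp(-(d1 - d0) / 2))
        mae = np.abs(model.predict_proba(probe)[:, 0] - bayes).mean()
        assert mae < 0.05

    def test_missing_class_rejected(self):
        Z = np.zeros((4, 2))
        with pytest.raises(ValueError, match=r"classes \[2\]"):
            LLGMN(3).fit(Z, [0, 0, 1, 1])

    def test_nonfinite_input_rejected(self):
        Z, y, _ = generate_index_samples(gaussian_class_specs(2, dim=2), 10, seed=0)
        model = LLGMN(2, seed=0).fit(Z, y)
        with pytest.raises(ValueError, match="non-finite"):
            model.predict_proba(np.array([[np.nan, 0.0]]))

    def test_serialization_round_trip(self, tmp_path, rng):
        Z, y, _ = generate_index_samples(gaussian_class_specs(2, dim=3), 20, seed=7)
        model = LLGMN(2, seed=0).fit(Z, y)
        model.save(tmp_path / "model.json")
        clone = LLGMN.load(tmp_path / "model.json")
        probe = rng.standard_normal((20, 3))
        np.testing.assert_allclose(
            model.predict_proba(probe), clone.predict_proba(probe), atol=1e-12
        )


class TestEntropy:
    def test_one_hot_is_zero(self):
        assert entropy(np.array([1.0, 0.0, 0.0, 0.0])) == 0.0

    def test_uniform_is_log_c(self):
        assert entropy(np.full(4, 0.25)) == pytest.approx(np.log(4))

    def test_skewed_posterior_value(self):
        y = np.array([0.7, 0.1, 0.1, 0.1])
        expected = -(0.7 * np.log(0.7) + 3 * 0.1 * np.log(0.1))
        assert entropy(y) == pytest.approx(expected)
        assert entropy(y) == pytest.approx(0.9404, abs=5e-4)

    def test_base_conversion(self):
        assert entropy(np.full(4, 0.25), base=2) == pytest.approx(2.0)


class TestClassifyInterval:
    def test_confident_posterior_assigned_wm(self):
        y = np.array([[0.9, 0.05, 0.03, 0.02]])
        res = classify_interval(y, s_th=1.0, i1_upper=10.0, i1_lower=10.0)
        assert res.gm_type == 1 and res.reason == "none" and res.label == "WM"
        assert res.entropy == pytest.approx(0.43, abs=0.02)

    def test_uniform_posterior_rejected_by_entropy(self):
        res = classify_interval(np.full((3, 4), 0.25), s_th=1.0,
                                i1_upper=10.0, i1_lower=10.0)
        assert res.gm_type == 0 and res.reason == "entropy"
        assert res.entropy == pytest.approx(np.log(4))

    def test_no_movement_overrides_confident_posterior(self):
        y = np.array([[0.99, 0.005, 0.003, 0.002]])
        res = classify_interval(y, s_th=1.0, i1_upper=0.0, i1_lower=10.0)
        assert res.gm_type == 0 and res.reason == "no_movement"
        res = classify_interval(y, s_th=1.0, i1_upper=10.0, i1_lower=0.0)
        assert res.gm_type == 0 and res.reason == "no_movement"

    def test_zero_threshold_rejects_everything(self, rng):
        for _ in range(20):
            y = rng.dirichlet(np.ones(4), size=3)
            res = classify_interval(y, s_th=0.0, i1_upper=10.0, i1_lower=10.0)
            assert res.gm_type == 0

    def test_posteriors_averaged_before_argmax(self):
        y = np.array([[0.9, 0.1, 0.0, 0.0], [0.1, 0.8, 0.05, 0.05]])
        res = classify_interval(y, s_th=np.log(4), i1_upper=1.0, i1_lower=1.0)
        np.testing.assert_allclose(res.posterior, y.mean(axis=0))

    def test_empty_interval_raises(self):
        with pytest.raises(ValueError, match="empty"):
            classify_interval(np.empty((0, 4)))

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10_000),
           s_lo=st.floats(0, 1.4), s_hi=st.floats(0, 1.4))
    def test_lowering_threshold_never_unrejects(self, seed, s_lo, s_hi):
        lo, hi = sorted((s_lo, s_hi))
        y = np.random.default_rng(seed).dirichlet(np.ones(4), size=2)
        res_lo = classify_interval(y, s_th=lo, i1_upper=1.0, i1_lower=1.0)
        res_hi = classify_interval(y, s_th=hi, i1_upper=1.0, i1_lower=1.0)
        if res_hi.gm_type == 0:
            assert res_lo.gm_type == 0
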
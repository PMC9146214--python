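"""ELM core: random layer, ridge solve, preprocessing, derived lifetimes."""

import time

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flimelm as fl
from flimelm import elm_core


class TestInit:
    def test_deterministic_weights(self):
        a = elm_core.init_model(m=256, L=500, n=3, seed=5)
        b = elm_core.init_model(m=256, L=500, n=3, seed=5)
        assert np.array_equal(a.W, b.W) and np.array_equal(a.b, b.b)

    def test_weights_uniform_in_unit_interval(self):
        m = elm_core.init_model(m=64, L=300, seed=1)
        assert m.W.min() >= -1 and m.W.max() <= 1
        assert abs(m.W.mean()) < 0.02

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            elm_core.init_model(L=0)
        with pytest.raises(ValueError):
            elm_core.init_model(activation="softplus9000")

    def test_parameter_count_convention(self):
        m = elm_core.init_model(m=256, L=500, n=3)
        assert m.n_parameters == 500 * 256 + 500 + 500 * 3


class TestHiddenMatrix:
    def test_zero_weights_give_half(self):
        model = elm_core.init_model(m=8, L=4, seed=0)
        model = elm_core.ELMModel(W=np.zeros((4, 8)), b=np.zeros(4))
        A = elm_core.hidden_matrix(model, np.random.default_rng(0).normal(size=(6, 8)))
        assert np.allclose(A, 0.5)

    def test_sigmoid_of_log_three_halves(self):
        # sigmoid(ln 1.5) = 1.5 / 2.5 = 0.6 exactly
        model = elm_core.ELMModel(W=np.array([[np.log(1.5)]]), b=np.array([0.0]))
        A = elm_core.hidden_matrix(model, np.array([[1.0]]))
        assert A[0, 0] == pytest.approx(0.6, abs=1e-12)

    def test_sigmoid_output_in_open_unit_interval(self):
        model = elm_core.init_model(m=16, L=32, seed=3)
        A = elm_core.hidden_matrix(model, np.random.default_rng(1).normal(size=(10, 16)))
        assert np.all(A > 0) and np.all(A < 1)

    def test_dimension_mismatch_rejected(self):
        model = elm_core.init_model(m=16, L=8, seed=0)
        with pytest.raises(ValueError):
            elm_core.hidden_matrix(model, np.ones((3, 9)))


class TestFit:
    def test_lambda_zero_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(0)
        model = elm_core.init_model(m=10, L=10, n=2, lam=0.0, seed=1)
        X = rng.normal(size=(50, 10))
        Y = rng.normal(size=(50, 2))
        trained = elm_core.fit(model, X, Y)
        A = 1.0 / (1.0 + np.exp(-(X @ model.W.T + model.b)))  # independent route
        beta_oracle = np.linalg.pinv(A) @ Y
        assert np.allclose(trained.beta, beta_oracle, rtol=1e-8, atol=1e-10)

    def test_huge_lambda_shrinks_beta_to_zero(self):
        rng = np.random.default_rng(2)
        model = elm_core.init_model(m=6, L=12, n=1, lam=1e12, seed=2)
        trained = elm_core.fit(model, rng.normal(size=(40, 6)), rng.normal(size=(40, 1)))
        assert np.all(np.abs(trained.beta) < 1e-6)

    def test_normal_equation_residual(self, mono_model_small, mono_ts_small):
        A = elm_core.hidden_matrix(mono_model_small, mono_ts_small.X)
        beta = mono_model_small.beta
        lhs = (A.T @ A + mono_model_small.lam * np.eye(mono_model_small.L)) @ beta
        rhs = A.T @ mono_ts_small.Y
        assert np.linalg.norm(lhs - rhs) / np.linalg.norm(rhs) < 1e-8

    def test_empty_or_nonfinite_training_data_rejected(self):
        model = elm_core.init_model(m=4, L=4, seed=0)
        with pytest.raises(ValueError):
            elm_core.fit(model, np.empty((0, 4)), np.empty((0, 1)))
        with pytest.raises(ValueError):
            elm_core.fit(model, np.full((3, 4), np.nan), np.ones((3, 1)))

    def test_training_is_single_solve_not_iterative(self, mono_ts_small):
        """Training time is that of one linear solve, far below any iterative fit."""
        start = time.perf_counter()
        fl.train_elm(mono_ts_small, L=500, lam=1e-3, seed=0)
        elapsed = time.perf_counter() - start
        assert elapsed < 10.0  # one 500x500 solve; an iterative 1500-sample fit cannot approach this


class TestPreprocess:
    def test_unit_peak(self):
        x = elm_core.preprocess(np.array([1.0, 4.0, 2.0]))
        assert x.max() == 1.0

    def test_scale_invariance(self):
        counts = np.random.default_rng(0).poisson(30, size=64).astype(float)
        assert np.allclose(elm_core.preprocess(counts), elm_core.preprocess(10 * counts))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            elm_core.preprocess(np.zeros(16))
        with pytest.raises(ValueError):
            elm_core.preprocess_batch(np.zeros((2, 16)))


class TestPredict:
    def test_untrained_model_rejected(self):
        model = elm_core.init_model(m=256, L=8, seed=0)
        with pytest.raises(ValueError):
            elm_core.predict(model, np.ones(256))

    def test_noiseless_mono_recovery_within_validation_error(self, mono_model_5k, irf, irf_spec):
        """A clean tau = 3 ns decay is recovered within the held-out error scale."""
        y = fl.noiseless_decay(fl.DecayModel.mono(3.0, intensity=1e5), irf, irf_spec.h)
        pred = elm_core.predict(mono_model_5k, y)
        # validation 95th-percentile |error| of this configuration is ~0.4 ns
        # (dominated by low-count exemplars); a clean decay must do far better
        assert abs(pred.tau - 3.0) < 0.2
        assert pred.tau_amp == pred.tau_int == pred.tau

    def test_near_interpolation_with_rich_basis_and_no_ridge(self):
        """L >> H with lambda = 0 reproduces training targets almost exactly."""
        ts = fl.sample_training_set(fl.TrainingConfig(model="mono", n_samples=60), seed=3)
        model = fl.train_elm(ts, L=400, lam=0.0, seed=1)
        pred = elm_core.predict_params(model, ts.X)
        assert np.median(np.abs(pred - ts.Y)) < 1e-3

    def test_bi_model_returns_three_raw_outputs(self, bi_model_20k):
        assert bi_model_20k.n == 3
        pred = elm_core.predict(bi_model_20k, np.exp(-np.arange(256) / 40.0))
        assert set(pred.params) == {"tau1", "tau2", "alpha"}

    def test_outputs_clipped_to_training_ranges(self, mono_model_5k):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(50, 256))
        X /= X.max(axis=1, keepdims=True)
        P = elm_core.predict_params(mono_model_5k, X)
        assert P.min() >= 0.1 and P.max() <= 5.0

    def test_prediction_deterministic(self, mono_model_5k):
        x = np.exp(-np.arange(256) / 30.0)
        a = elm_core.predict(mono_model_5k, x).tau
        b = elm_core.predict(mono_model_5k, x).tau
        assert a == b


class TestDerivedLifetimes:
    def test_reference_values(self):
        assert fl.tau_amp(0.3, 3.0, 0.5) == pytest.approx(1.65, abs=1e-12)
        assert fl.tau_int(0.3, 3.0, 0.5) == pytest.approx(2.754545454545, abs=1e-9)

    @pytest.mark.parametrize("alpha,expected", [(1.0, 0.3), (0.0, 3.0)])
    def test_degenerate_alpha(self, alpha, expected):
        assert fl.tau_amp(0.3, 3.0, alpha) == pytest.approx(expected)
        assert fl.tau_int(0.3, 3.0, alpha) == pytest.approx(expected)

    def test_out_of_range_alpha_rejected(self):
        with pytest.raises(ValueError):
            fl.tau_amp(0.3, 3.0, 1.2)

    @settings(derandomize=True, max_examples=200)
    @given(
        t1=st.floats(0.01, 10), t2=st.floats(0.01, 10), a=st.floats(0, 1)
    )
    def test_intensity_weighted_at_least_amplitude_weighted(self, t1, t2, a):
        assert fl.tau_int(t1, t2, a) >= fl.tau_amp(t1, t2, a) - 1e-12
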
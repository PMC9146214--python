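"""Simulator: IRF shape, decay convolution, Poisson noise, training sets, phantoms."""

import numpy as np
import pytest
from scipy import stats

import flimelm as fl
from flimelm.tcspc_sim import PHANTOM_LAYOUTS


class TestIRF:
    def test_peak_is_exactly_one_at_t0(self, irf_spec, irf):
        assert irf[irf_spec.peak_index] == 1.0
        assert irf.argmax() == irf_spec.peak_index

    def test_two_bin_offset_value(self, irf):
        # exp(-4 ln2 (2*0.039)^2 / 0.1673^2) evaluated by hand
        expected = np.exp(-4 * np.log(2) * (2 * 0.039) ** 2 / 0.1673**2)
        assert irf[13 + 2] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.547, abs=5e-4)

    def test_symmetric_about_peak(self, irf_spec, irf):
        p = irf_spec.peak_index
        for k in range(1, 12):
            assert irf[p + k] == pytest.approx(irf[p - k], rel=1e-12)

    def test_values_in_unit_interval(self, irf, irf_spec):
        # far-tail values underflow to 0 in float64; near the peak all positive
        assert np.all(irf >= 0) and np.all(irf <= 1)
        p = irf_spec.peak_index
        assert np.all(irf[max(0, p - 10) : p + 10] > 0)

    @pytest.mark.parametrize(
        "kwargs", [dict(fwhm=-1), dict(h=0), dict(t0=0), dict(t0=300), dict(T=1)]
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            fl.IRFSpec(**kwargs)


class TestNoiselessDecay:
    def test_delta_irf_gives_pure_exponential(self, delta_irf, irf_spec):
        tau = 1.7
        y = fl.noiseless_decay(fl.DecayModel.mono(tau, intensity=1000), delta_irf, irf_spec.h)
        ratios = y[1:50] / y[:49]
        assert np.allclose(ratios, np.exp(-irf_spec.h / tau), rtol=1e-10)

    def test_degenerate_mixture_equals_mono(self, irf, irf_spec):
        y_bi = fl.noiseless_decay(fl.DecayModel.bi(1.2, 3.3, 1.0), irf, irf_spec.h)
        y_mono = fl.noiseless_decay(fl.DecayModel.mono(1.2), irf, irf_spec.h)
        assert np.allclose(y_bi, y_mono, rtol=1e-12)

    def test_sums_to_configured_intensity(self, irf, irf_spec):
        y = fl.noiseless_decay(fl.DecayModel.bi(0.4, 2.8, 0.3, intensity=1000), irf, irf_spec.h)
        assert y.sum() == pytest.approx(1000.0, rel=1e-9)

    def test_background_added_per_bin(self, irf, irf_spec):
        m = fl.DecayModel.mono(2.0, intensity=500, background=0.25)
        y = fl.noiseless_decay(m, irf, irf_spec.h)
        assert y.sum() == pytest.approx(500 + 0.25 * irf_spec.T, rel=1e-9)
        assert y.min() >= 0.25

    def test_nonpositive_lifetime_rejected(self):
        with pytest.raises(ValueError):
            fl.DecayModel.mono(-2.0)
        with pytest.raises(ValueError):
            fl.DecayModel(tau=(1.0, 2.0), alpha=(0.6, 0.6))


class TestPoisson:
    def test_zero_mean_gives_zero_counts(self):
        h = fl.add_poisson(np.zeros(256), seed=3)
        assert h.counts.sum() == 0

    def test_same_seed_identical(self):
        mu = np.linspace(0, 40, 256)
        a = fl.add_poisson(mu, seed=11)
        b = fl.add_poisson(mu, seed=11)
        assert np.array_equal(a.counts, b.counts)

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            fl.add_poisson(np.full(8, -1.0), seed=0)

    def test_mean_equals_variance_monte_carlo(self):
        """Poisson replicates have matching per-bin mean and variance."""
        rng = np.random.default_rng(7)
        mu = 50.0
        draws = np.array([fl.add_poisson(np.full(256, mu), rng).counts for _ in range(2000)])
        se_mean = np.sqrt(mu / draws.shape[0])
        assert abs(draws.mean() - mu) < 3 * se_mean / np.sqrt(256)
        # chi-square dispersion test across replicates, pooled over bins
        disp = draws.var(axis=0, ddof=1) / mu
        n = draws.shape[0] - 1
        z = (disp - 1.0) * np.sqrt(n / 2.0)  # approx N(0,1) per bin
        pooled = z.mean() * np.sqrt(256)
        assert abs(pooled) < stats.norm.ppf(1 - 0.005)

    def test_total_counts_match_configured_intensity(self, irf, irf_spec):
        rng = np.random.default_rng(21)
        intensity = 300.0
        y = fl.noiseless_decay(fl.DecayModel.mono(1.5, intensity=intensity), irf, irf_spec.h)
        totals = np.array([fl.add_poisson(y, rng).total for _ in range(1000)])
        se = np.sqrt(intensity / len(totals))
        assert abs(totals.mean() - intensity) < 4 * se


class TestTrainingSet:
    def test_mono_shapes_and_ranges(self):
        ts = fl.sample_training_set(fl.TrainingConfig(model="mono", n_samples=500), seed=1)
        assert ts.X.shape == (500, 256)
        assert ts.Y.shape == (500, 1)
        assert ts.Y.min() >= 0.1 and ts.Y.max() <= 5.0
        assert np.allclose(ts.X.max(axis=1), 1.0)

    def test_bi_target_columns_within_declared_ranges(self):
        ts = fl.sample_training_set(fl.TrainingConfig(model="bi", n_samples=500), seed=2)
        assert ts.Y.shape == (500, 3)
        t1, t2, a = ts.Y.T
        assert t1.min() >= 0.1 and t1.max() <= 1.0
        assert t2.min() >= 1.0 and t2.max() <= 3.0
        assert a.min() >= 0.0 and a.max() <= 1.0

    def test_deterministic_for_fixed_seed(self):
        cfg = fl.TrainingConfig(model="bi", n_samples=200)
        a = fl.sample_training_set(cfg, seed=9)
        b = fl.sample_training_set(cfg, seed=9)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.Y, b.Y)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_samples=0),
            dict(tau_range=(2.0, 1.0)),
            dict(model="tri"),
            dict(alpha_range=(-0.2, 0.5)),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            fl.TrainingConfig(**kwargs)


class TestPhantoms:
    def test_mono_gradient_limits(self):
        cube = fl.make_phantom_cube("mono_gradient", dims=(32, 16), seed=0)
        tau = cube.gt_maps["tau"]
        assert np.allclose(tau[0], 0.1) and np.allclose(tau[-1], 5.0)
        assert cube.counts.shape == (32, 16, 256)

    def test_bi_alpha_gradient_fixed_components(self):
        cube = fl.make_phantom_cube("bi_alpha_gradient", dims=(16, 16), seed=0)
        assert np.allclose(cube.gt_maps["tau1"], 0.3)
        assert np.allclose(cube.gt_maps["tau2"], 3.0)
        assert np.allclose(cube.gt_maps["alpha"][0], 0.0)
        assert np.allclose(cube.gt_maps["alpha"][-1], 1.0)

    def test_three_region_tau_amp_sweep(self):
        cube = fl.make_phantom_cube("three_region_counts", dims=(30, 8), seed=0)
        ta = cube.gt_maps["tau_amp"]
        assert ta[0, 0] == pytest.approx(0.3) and ta[-1, 0] == pytest.approx(2.5)
        assert len(np.unique(cube.gt_maps["region"])) == 3

    def test_two_population_has_probe_and_cell(self, two_pop_cube):
        probe = two_pop_cube.gt_maps["probe"].astype(bool)
        ta = two_pop_cube.gt_maps["tau_amp"]
        assert 0.05 < probe.mean() < 0.6
        assert ta[probe].max() < ta[~probe].min()  # populations separated in tau_A

    def test_zero_intensity_gives_empty_cube(self):
        cube = fl.make_phantom_cube("mono_gradient", dims=(8, 8), seed=0, intensity_scale=0.0)
        assert cube.counts.sum() == 0

    def test_unknown_layout_rejected(self):
        with pytest.raises(ValueError):
            fl.make_phantom_cube("spiral", dims=(8, 8), seed=0)

    def test_counts_are_integer_and_nonnegative(self):
        for layout in PHANTOM_LAYOUTS:
            cube = fl.make_phantom_cube(layout, dims=(12, 12), seed=3)
            assert np.issubdtype(cube.counts.dtype, np.integer)
            assert cube.counts.min() >= 0
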
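"""Shared fixtures: IRF, training sets, trained models, phantom cubes.

Expensive artifacts (trained networks, the two-population cube) are
session-scoped so every test sees the identical seeded object.
"""

from __future__ import annotations

import numpy as np
import pytest

import flimelm as fl
from flimelm import pipeline


@pytest.fixture(scope="session")
def irf_spec() -> fl.IRFSpec:
    return fl.IRFSpec()


@pytest.fixture(scope="session")
def irf(irf_spec) -> np.ndarray:
    return fl.make_irf(irf_spec)


@pytest.fixture(scope="session")
def delta_irf(irf_spec) -> np.ndarray:
    """Idealized instantaneous IRF in the first bin (decay time origin at 0)."""
    d = np.zeros(irf_spec.T)
    d[0] = 1.0
    return d


@pytest.fixture(scope="session")
def mono_ts_small():
    return fl.sample_training_set(fl.TrainingConfig(model="mono", n_samples=1500), seed=101)


@pytest.fixture(scope="session")
def mono_model_small(mono_ts_small):
    return fl.train_elm(mono_ts_small, L=200, lam=1e-3, seed=7)


@pytest.fixture(scope="session")
def mono_model_5k():
    """Mono network at the scaled benchmark training size (5,000 samples)."""
    ts = fl.sample_training_set(fl.TrainingConfig(model="mono", n_samples=5000), seed=42)
    return fl.train_elm(ts, L=500, lam=1e-3, seed=7)


@pytest.fixture(scope="session")
def bi_model_20k():
    """Bi-exponential network at the full training size (20,000 samples)."""
    ts = fl.sample_training_set(fl.TrainingConfig(model="bi", n_samples=20000), seed=44)
    return fl.train_elm(ts, L=500, lam=1e-3, seed=7)


@pytest.fixture(scope="session")
def two_pop_cube():
    return fl.make_phantom_cube("two_population_cells", dims=(64, 64), seed=5)


@pytest.fixture(scope="session")
def nlsf_mono(irf, irf_spec):
    return pipeline.NLSFEstimator(irf, irf_spec.h, order=1)


@pytest.fixture(scope="session")
def nlsf_bi(irf, irf_spec):
    return pipeline.NLSFEstimator(irf, irf_spec.h, order=2)
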
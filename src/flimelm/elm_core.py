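"""Extreme-learning-machine regression from TCSPC histograms to lifetimes.

The estimator is a single-hidden-layer feed-forward network whose input
weights ``W`` and biases ``b`` are drawn at random and frozen; only the linear
output layer ``beta`` is learned, by ridge-regularized least squares

    beta = argmin ||A beta - Y||^2 + lambda ||beta||^2,
    A[i, l] = phi(w_l . x_i + b_l),

which reduces training to a single linear solve — no back-propagation, no
iteration.  Inputs are unit-peak-normalized 256-bin histograms; outputs are
either a single lifetime (mono-exponential model) or the triple
(tau1, tau2, alpha) of a bi-exponential model, from which the
amplitude-weighted and intensity-weighted average lifetimes are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg
from scipy.special import expit

from .tcspc_sim import Histogram, TrainingSet

__all__ = [
    "ELMModel",
    "LifetimePrediction",
    "ACTIVATIONS",
    "init_model",
    "hidden_matrix",
    "fit",
    "preprocess",
    "preprocess_batch",
    "predict",
    "predict_params",
    "train_elm",
    "tau_amp",
    "tau_int",
]

ACTIVATIONS = {
    "sigmoid": expit,
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
}

#: default parameter clip ranges applied to raw network outputs
_DEFAULT_RANGES = {
    "tau": (0.1, 5.0),
    "tau1": (0.1, 1.0),
    "tau2": (1.0, 3.0),
    "alpha": (0.0, 1.0),
}


@dataclass(frozen=True)
class ELMModel:
    """Random-feature network state.

    ``W`` (L x m) and ``b`` (L,) are fixed at initialization; ``beta``
    (L x n) exists only after training.  ``output_names`` labels the columns
    of ``beta`` and ``output_ranges`` gives the physical interval each output
    is clipped to at prediction time (the training ranges: a linear readout
    can extrapolate to unphysical values such as negative lifetimes).
    """

    W: np.ndarray
    b: np.ndarray
    activation: str = "sigmoid"
    lam: float = 1e-3
    seed: int | None = None
    beta: np.ndarray | None = None
    output_names: tuple[str, ...] = ("tau",)
    output_ranges: tuple[tuple[float, float], ...] = ((0.1, 5.0),)

    @property
    def m(self) -> int:
        return self.W.shape[1]

    @property
    def L(self) -> int:
        return self.W.shape[0]

    @property
    def n(self) -> int:
        return len(self.output_names)

    @property
    def trained(self) -> bool:
        return self.beta is not None

    @property
    def n_parameters(self) -> int:
        """Total parameter count L*m + L + L*n (input weights, biases, readout)."""
        return self.L * self.m + self.L + self.L * self.n


@dataclass(frozen=True)
class LifetimePrediction:
    """Lifetime parameters recovered for one histogram.

    ``tau_amp`` and ``tau_int`` are always recomputed from the raw outputs,
    never regressed directly; for a mono model all three coincide.
    """

    params: dict[str, float]
    tau_amp: float
    tau_int: float

    def __getattr__(self, name: str) -> float:
        try:
            return self.params[name]
        except KeyError:
            raise AttributeError(name) from None


def init_model(
    m: int = 256,
    L: int = 500,
    n: int = 1,
    activation: str = "sigmoid",
    lam: float = 1e-3,
    seed: int = 0,
    output_names: tuple[str, ...] | None = None,
    output_ranges: tuple[tuple[float, float], ...] | None = None,
) -> ELMModel:
    """Draw the frozen random layer: W, b i.i.d. uniform on [-1, 1]."""
    if m < 1 or L < 1 or n < 1:
        raise ValueError("m, L and n must all be >= 1")
    if activation not in ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}; choose from {sorted(ACTIVATIONS)}")
    if lam < 0:
        raise ValueError("ridge parameter lambda must be non-negative")
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(L, m))
    b = rng.uniform(-1.0, 1.0, size=L)
    if output_names is None:
        if n == 1:
            output_names = ("tau",)
        elif n == 3:
            output_names = ("tau1", "tau2", "alpha")
        else:
            output_names = tuple(f"y{j}" for j in range(n))
    if len(output_names) != n:
        raise ValueError("output_names length must equal n")
    if output_ranges is None:
        output_ranges = tuple(_DEFAULT_RANGES.get(name, (-np.inf, np.inf)) for name in output_names)
    return ELMModel(
        W=W,
        b=b,
        activation=activation,
        lam=lam,
        seed=seed,
        output_names=tuple(output_names),
        output_ranges=tuple(tuple(r) for r in output_ranges),
    )


def hidden_matrix(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Hidden-layer output A[i, l] = phi(w_l . x_i + b_l) for rows x_i of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.m:
        raise ValueError(f"input has {X.shape[1]} features, model expects {model.m}")
    phi = ACTIVATIONS[model.activation]
    return phi(X @ model.W.T + model.b)


def fit(model: ELMModel, X: np.ndarray, Y: np.ndarray) -> ELMModel:
    """Learn the output weights by one ridge solve of the normal equations.

    ``beta = (A^T A + lambda I)^-1 A^T Y`` computed via a symmetric
    positive-definite solve; with ``lambda = 0`` the minimum-norm
    least-squares solution is returned instead (SVD), matching the
    Moore-Penrose pseudoinverse.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    Y = Y.reshape(len(Y), -1)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if X.shape[0] == 0:
        raise ValueError("cannot train on an empty sample")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("training data must be finite")
    if Y.shape[1] != model.n:
        raise ValueError(f"Y has {Y.shape[1]} columns, model expects n={model.n}")
    A = hidden_matrix(model, X)
    if model.lam == 0.0:
        beta, *_ = np.linalg.lstsq(A, Y, rcond=None)
    else:
        G = A.T @ A
        G[np.diag_indices_from(G)] += model.lam
        try:
            beta = scipy.linalg.solve(G, A.T @ Y, assume_a="pos")
        except scipy.linalg.LinAlgError:
            # ridge as an augmented least-squares problem, always solvable
            aug_A = np.vstack([A, np.sqrt(model.lam) * np.eye(model.L)])
            aug_Y = np.vstack([Y, np.zeros((model.L, Y.shape[1]))])
            beta, *_ = np.linalg.lstsq(aug_A, aug_Y, rcond=None)
    if squeeze:
        beta = beta.reshape(model.L, 1)
    return replace(model, beta=beta)


def preprocess(hist: Histogram | np.ndarray) -> np.ndarray:
    """Unit-peak normalization: counts divided by their maximum.

    Makes inference invariant to total intensity; an all-zero histogram has
    no defined shape and must be masked upstream.
    """
    counts = hist.counts if isinstance(hist, Histogram) else np.asarray(hist)
    counts = np.asarray(counts, dtype=float)
    peak = counts.max()
    if peak <= 0:
        raise ValueError("cannot preprocess an all-zero histogram; mask the pixel upstream")
    return counts / peak


def preprocess_batch(counts: np.ndarray) -> np.ndarray:
    """Row-wise unit-peak normalization of an (N, T) count matrix."""
    counts = np.asarray(counts, dtype=float)
    peaks = counts.max(axis=1, keepdims=True)
    if np.any(peaks <= 0):
        raise ValueError("batch contains all-zero histograms; mask them upstream")
    return counts / peaks


def predict_params(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Raw network outputs for preprocessed inputs, clipped to training ranges."""
    if not model.trained:
        raise ValueError("model is untrained; call fit() first")
    raw = hidden_matrix(model, X) @ model.beta
    lo = np.array([r[0] for r in model.output_ranges])
    hi = np.array([r[1] for r in model.output_ranges])
    return np.clip(raw, lo, hi)


def predict(model: ELMModel, hist: Histogram | np.ndarray) -> LifetimePrediction:
    """Recover lifetime parameters for one histogram (preprocessing included)."""
    x = preprocess(hist)
    out = predict_params(model, x[None, :])[0]
    params = dict(zip(model.output_names, (float(v) for v in out)))
    if set(model.output_names) >= {"tau1", "tau2", "alpha"}:
        ta = tau_amp(params["tau1"], params["tau2"], params["alpha"])
        ti = tau_int(params["tau1"], params["tau2"], params["alpha"])
    elif "tau" in params:
        ta = ti = params["tau"]
    else:
        ta = ti = float("nan")
    return LifetimePrediction(params=params, tau_amp=ta, tau_int=ti)


def train_elm(
    ts: TrainingSet,
    L: int = 500,
    lam: float = 1e-3,
    activation: str = "sigmoid",
    seed: int = 0,
) -> ELMModel:
    """Initialize and fit a model matched to a training set's targets."""
    names = ts.param_names
    ranges = tuple(ts.ranges[name] for name in names)
    model = init_model(
        m=ts.X.shape[1],
        L=L,
        n=len(names),
        activation=activation,
        lam=lam,
        seed=seed,
        output_names=names,
        output_ranges=ranges,
    )
    return fit(model, ts.X, ts.Y)


def tau_amp(tau1: float, tau2: float, alpha: float) -> float:
    """Amplitude-weighted average lifetime alpha*tau1 + (1-alpha)*tau2 (ns)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("lifetimes must be positive")
    return alpha * tau1 + (1.0 - alpha) * tau2


def tau_int(tau1: float, tau2: float, alpha: float) -> float:
    """Intensity-weighted average lifetime (ns).

    ``(alpha*tau1^2 + (1-alpha)*tau2^2) / (alpha*tau1 + (1-alpha)*tau2)``;
    always >= the amplitude-weighted lifetime (Cauchy-Schwarz), with equality
    iff the two components coincide or one amplitude vanishes.
    """
    denom = tau_amp(tau1, tau2, alpha)
    if denom == 0:
        raise ZeroDivisionError("amplitude-weighted lifetime is zero")
    return (alpha * tau1**2 + (1.0 - alpha) * tau2**2) / denom
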
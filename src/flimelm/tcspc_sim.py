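"""Synthetic TCSPC decay simulation for time-domain FLIM.

Time-correlated single-photon counting (TCSPC) accumulates, per pixel, a
histogram of photon arrival times over many excitation cycles.  The expected
histogram of a fluorophore mixture is an exponential decay convolved with the
instrument response function (IRF),

    h(t) = IRF(t) * P * sum_k alpha_k exp(-t / tau_k) + background,

and the recorded counts are Poisson-distributed around that expectation.  This
module builds the pieces of that model — a Gaussian IRF, mono- and
bi-exponential decays, Poisson noise — and uses them to generate training sets
for the regression network and phantom image cubes with known ground truth.

Conventions
-----------
Arrays are 0-based; bin ``k`` spans time ``[k*h, (k+1)*h)`` with ``h`` the bin
width in ns.  The IRF peak position ``t0`` is stored 1-based (bin numbering
``t = 1..T``), matching how TCSPC hardware and file headers usually report it;
it maps to array index ``t0 - 1``.  Convolution is linear (full, truncated to
the first ``T`` bins), never circular: wrapping would alias the decay tail of
long lifetimes into the early bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "IRFSpec",
    "DecayModel",
    "Histogram",
    "DataCube",
    "TrainingConfig",
    "TrainingSet",
    "DEFAULT_IRF",
    "PHANTOM_LAYOUTS",
    "make_irf",
    "noiseless_decay",
    "add_poisson",
    "sample_training_set",
    "make_phantom_cube",
]

_FOUR_LN2 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class IRFSpec:
    """Gaussian instrument-response parameters.

    Parameters
    ----------
    fwhm : float
        Full width at half maximum of the Gaussian IRF, in ns.
    t0 : int
        1-based index of the IRF peak bin.
    h : float
        Width of one TCSPC time bin, in ns.
    T : int
        Number of time bins in the histogram.
    """

    fwhm: float = 0.1673
    t0: int = 14
    h: float = 0.039
    T: int = 256

    def __post_init__(self) -> None:
        if not (self.fwhm > 0):
            raise ValueError(f"fwhm must be positive, got {self.fwhm}")
        if not (self.h > 0):
            raise ValueError(f"bin width h must be positive, got {self.h}")
        if not (isinstance(self.T, (int, np.integer)) and self.T >= 2):
            raise ValueError(f"T must be an integer >= 2, got {self.T}")
        if not (isinstance(self.t0, (int, np.integer)) and 1 <= self.t0 <= self.T):
            raise ValueError(f"t0 must be in [1, T={self.T}], got {self.t0}")

    @property
    def window(self) -> float:
        """Measurement window T*h in ns."""
        return self.T * self.h

    @property
    def peak_index(self) -> int:
        """0-based array index of the IRF peak."""
        return int(self.t0) - 1

    def bin_centers(self) -> np.ndarray:
        """Bin-center times (k + 1/2) * h in ns, length T."""
        return (np.arange(self.T) + 0.5) * self.h


DEFAULT_IRF = IRFSpec()


@dataclass(frozen=True)
class DecayModel:
    """Exponential decay mixture with amplitude fractions.

    ``tau`` and ``alpha`` are the component lifetimes (ns) and amplitude
    fractions; ``intensity`` is the expected total photon count of the decay
    signal (background excluded); ``background`` is a constant dark-count
    expectation per bin.
    """

    tau: tuple[float, ...]
    alpha: tuple[float, ...] = (1.0,)
    intensity: float = 1000.0
    background: float = 0.0

    def __post_init__(self) -> None:
        tau = tuple(float(t) for t in np.atleast_1d(self.tau))
        alpha = tuple(float(a) for a in np.atleast_1d(self.alpha))
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "alpha", alpha)
        if len(tau) not in (1, 2):
            raise ValueError("only mono- and bi-exponential models are supported")
        if len(tau) != len(alpha):
            raise ValueError("tau and alpha must have the same length")
        if any(t <= 0 for t in tau):
            raise ValueError(f"all lifetimes must be positive, got {tau}")
        if any(a < 0 for a in alpha):
            raise ValueError(f"amplitude fractions must be non-negative, got {alpha}")
        if abs(sum(alpha) - 1.0) > 1e-9:
            raise ValueError(f"amplitude fractions must sum to 1, got {alpha}")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if self.background < 0:
            raise ValueError("background must be non-negative")

    @property
    def K(self) -> int:
        return len(self.tau)

    @classmethod
    def mono(cls, tau: float, intensity: float = 1000.0, background: float = 0.0) -> "DecayModel":
        return cls(tau=(tau,), alpha=(1.0,), intensity=intensity, background=background)

    @classmethod
    def bi(
        cls,
        tau1: float,
        tau2: float,
        alpha: float,
        intensity: float = 1000.0,
        background: float = 0.0,
    ) -> "DecayModel":
        """Two-component model with the (alpha, 1 - alpha) convention."""
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {alpha}")
        return cls(
            tau=(tau1, tau2), alpha=(alpha, 1.0 - alpha), intensity=intensity, background=background
        )


@dataclass(frozen=True)
class Histogram:
    """Per-pixel photon counts over T bins."""

    counts: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class DataCube:
    """X x Y x T photon-count cube plus per-pixel ground-truth maps."""

    counts: np.ndarray
    gt_maps: dict[str, np.ndarray]
    irf: IRFSpec
    layout: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise ValueError("counts must be an X x Y x T array")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.shape[2] != self.irf.T:
            raise ValueError(
                f"temporal dimension {counts.shape[2]} does not match IRF T={self.irf.T}"
            )
        for name, m in self.gt_maps.items():
            if np.shape(m) != counts.shape[:2]:
                raise ValueError(f"gt map {name!r} shape {np.shape(m)} != {counts.shape[:2]}")
        self.counts = counts

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    def pixel_totals(self) -> np.ndarray:
        return self.counts.sum(axis=2)


def make_irf(spec: IRFSpec) -> np.ndarray:
    """Evaluate the unit-peak Gaussian IRF on the bin grid.

    ``IRF(t) = exp(-((t - t0) * h)^2 * 4 ln 2 / FWHM^2)`` for bins
    ``t = 1..T``; the value at ``t0`` is exactly 1.
    """
    if not isinstance(spec, IRFSpec):
        spec = IRFSpec(*spec)
    offsets = (np.arange(spec.T) - spec.peak_index) * spec.h
    return np.exp(-(offsets**2) * _FOUR_LN2 / spec.fwhm**2)


def _decay_curves(tau: np.ndarray, alpha: np.ndarray, T: int, h: float) -> np.ndarray:
    """Rows of sum_k alpha_k exp(-t*h/tau_k) for t = 0..T-1.

    ``tau`` and ``alpha`` are (N, K) arrays; returns (N, T).
    """
    t = np.arange(T) * h
    # (N, K, T) -> sum over K
    return np.einsum("nk,nkt->nt", alpha, np.exp(-t[None, None, :] / tau[:, :, None]))


def noiseless_decay(model: DecayModel, irf: np.ndarray, h: float | None = None) -> np.ndarray:
    """Expected per-bin counts of one decay: IRF (*) mixture, scaled, plus background.

    The linear convolution of the IRF with ``sum_k alpha_k exp(-t*h/tau_k)``
    is truncated to the first ``T`` bins and rescaled so the signal part sums
    to ``model.intensity``; the constant ``model.background`` is then added to
    every bin.
    """
    if h is None:
        h = DEFAULT_IRF.h
    irf = np.asarray(irf, dtype=float)
    T = irf.shape[0]
    tau = np.asarray(model.tau, dtype=float)[None, :]
    alpha = np.asarray(model.alpha, dtype=float)[None, :]
    decay = _decay_curves(tau, alpha, T, h)[0]
    y = np.convolve(irf, decay)[:T]
    total = y.sum()
    if model.intensity == 0 or total == 0:
        y = np.zeros(T)
    else:
        y = y * (model.intensity / total)
    return y + model.background


def add_poisson(expected: np.ndarray, seed: int | np.random.Generator) -> Histogram:
    """Draw independent Poisson counts around the expected curve.

    ``seed`` may be an integer or a ``numpy.random.Generator``; a fixed
    integer seed makes the draw reproducible.
    """
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < 0):
        raise ValueError("expected counts must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    counts = rng.poisson(expected)
    return Histogram(counts=counts, bin_width=DEFAULT_IRF.h)


# ---------------------------------------------------------------------------
# training sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainingConfig:
    """Sampling recipe for a synthetic training set.

    Lifetime ranges follow the decay-model convention: a single ``tau_range``
    for mono-exponential sets, ``tau1_range``/``tau2_range``/``alpha_range``
    for bi-exponential ones.  Per-histogram intensity (expected total photon
    count) is drawn uniformly from ``intensity_range``, spanning the low-count
    regime (tens of photons) up to bright pixels (thousands).
    """

    model: str = "mono"
    n_samples: int = 20_000
    tau_range: tuple[float, float] = (0.1, 5.0)
    tau1_range: tuple[float, float] = (0.1, 1.0)
    tau2_range: tuple[float, float] = (1.0, 3.0)
    alpha_range: tuple[float, float] = (0.0, 1.0)
    intensity_range: tuple[float, float] = (25.0, 2000.0)
    background: float = 0.0
    irf: IRFSpec = field(default_factory=IRFSpec)

    def __post_init__(self) -> None:
        if self.model not in ("mono", "bi"):
            raise ValueError(f"model must be 'mono' or 'bi', got {self.model!r}")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        for name in ("tau_range", "tau1_range", "tau2_range", "alpha_range", "intensity_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} is inverted: {(lo, hi)}")
        for name in ("tau_range", "tau1_range", "tau2_range"):
            if getattr(self, name)[0] <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.alpha_range[0] and self.alpha_range[1] <= 1):
            raise ValueError("alpha_range must lie in [0, 1]")
        if self.background < 0:
            raise ValueError("background must be non-negative")

    @property
    def param_names(self) -> tuple[str, ...]:
        return ("tau",) if self.model == "mono" else ("tau1", "tau2", "alpha")

    @property
    def ranges(self) -> dict[str, tuple[float, float]]:
        if self.model == "mono":
            return {"tau": self.tau_range}
        return {"tau1": self.tau1_range, "tau2": self.tau2_range, "alpha": self.alpha_range}


@dataclass
class TrainingSet:
    """Preprocessed histograms ``X`` (H x T) paired with targets ``Y`` (H x n)."""

    X: np.ndarray
    Y: np.ndarray
    config: TrainingConfig
    seed: int

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.config.param_names

    @property
    def ranges(self) -> dict[str, tuple[float, float]]:
        return self.config.ranges


def _simulate_batch(
    tau: np.ndarray,
    alpha: np.ndarray,
    intensity: np.ndarray,
    irf: np.ndarray,
    h: float,
    background: float,
    rng: np.random.Generator,
    intensity_mode: str = "total",
) -> np.ndarray:
    """Poisson histograms for N decays given (N, K) parameters.

    ``intensity_mode='total'`` scales each expected curve so its signal sums
    to the given intensity; ``'peak'`` scales so its maximum bin equals it.
    """
    T = irf.shape[0]
    decays = _decay_curves(tau, alpha, T, h)
    expected = fftconvolve(decays, irf[None, :], axes=1)[:, :T]
    expected = np.clip(expected, 0.0, None)  # fft round-off can go ~-1e-16
    if intensity_mode == "total":
        norm = expected.sum(axis=1, keepdims=True)
    elif intensity_mode == "peak":
        norm = expected.max(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown intensity_mode {intensity_mode!r}")
    norm[norm == 0] = 1.0
    expected = expected * (np.asarray(intensity)[:, None] / norm) + background
    return rng.poisson(expected)


def sample_training_set(config: TrainingConfig, seed: int) -> TrainingSet:
    """Simulate a seeded training set of Poisson histograms with ground truth.

    Parameters are drawn uniformly and independently over the configured
    ranges; each histogram is unit-peak normalized (see
    :func:`flimelm.elm_core.preprocess`) so the regression input is invariant
    to total intensity.
    """
    from .elm_core import preprocess_batch  # local import to avoid a cycle

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    H = config.n_samples
    if config.model == "mono":
        tau = rng.uniform(*config.tau_range, size=(H, 1))
        alpha = np.ones((H, 1))
        Y = tau.copy()
    else:
        tau1 = rng.uniform(*config.tau1_range, size=H)
        tau2 = rng.uniform(*config.tau2_range, size=H)
        a = rng.uniform(*config.alpha_range, size=H)
        tau = np.column_stack([tau1, tau2])
        alpha = np.column_stack([a, 1.0 - a])
        Y = np.column_stack([tau1, tau2, a])
    intensity = rng.uniform(*config.intensity_range, size=H)
    counts = _simulate_batch(
        tau, alpha, intensity, make_irf(config.irf), config.irf.h, config.background, rng
    )
    # An all-zero histogram (possible only at vanishing intensity) cannot be
    # normalized; with intensity >= 25 its probability is below 1e-10.
    dead = counts.sum(axis=1) == 0
    if np.any(dead):
        counts[dead, 0] = 1
    X = preprocess_batch(counts)
    return TrainingSet(X=X, Y=Y, config=config, seed=seed)


# ---------------------------------------------------------------------------
# phantom cubes
# ---------------------------------------------------------------------------

PHANTOM_LAYOUTS = (
    "mono_gradient",
    "bi_alpha_gradient",
    "three_region_counts",
    "two_population_cells",
)


def _tau_maps_bi(tau1, tau2, alpha):
    tau_amp = alpha * tau1 + (1 - alpha) * tau2
    with np.errstate(invalid="ignore", divide="ignore"):
        tau_int = (alpha * tau1**2 + (1 - alpha) * tau2**2) / tau_amp
    return tau_amp, tau_int


def make_phantom_cube(
    layout: str,
    dims: tuple[int, int] = (64, 64),
    seed: int = 0,
    irf: IRFSpec = DEFAULT_IRF,
    intensity_scale: float = 1.0,
    count_bands: Sequence[tuple[float, float]] = ((40, 400), (400, 1000), (1000, 2000)),
) -> DataCube:
    """Build a synthetic FLIM data cube with per-pixel ground truth.

    Layouts
    -------
    ``mono_gradient``
        Single lifetime varying linearly 0.1 -> 5 ns from the top row to the
        bottom row; per-pixel total counts uniform in [25, 500].
    ``bi_alpha_gradient``
        Fixed (tau1, tau2) = (0.3, 3.0) ns with the amplitude fraction alpha
        varying 0 -> 1 top to bottom; counts uniform in [25, 500].
    ``three_region_counts``
        Three horizontal intensity bands (``count_bands``, low/middle/high
        total counts) with a bi-exponential decay (tau1 = 0.3, tau2 = 2.5 ns)
        whose amplitude-weighted lifetime sweeps 0.3 -> 2.5 ns top to bottom.
    ``two_population_cells``
        A cell-like field (longer lifetimes, moderate counts) with bright
        blob-shaped short-lifetime nanoprobe regions and a dim border that an
        intensity filter should reject; used for phasor-projection tests.

    ``intensity_scale`` multiplies every pixel's expected counts (0 gives an
    all-zero cube).
    """
    if layout not in PHANTOM_LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; choose from {PHANTOM_LAYOUTS}")
    ny, nx = dims
    rng = np.random.default_rng(np.random.SeedSequence([seed, PHANTOM_LAYOUTS.index(layout)]))
    row = np.repeat(np.linspace(0.0, 1.0, ny)[:, None], nx, axis=1)  # 0 at top

    if layout == "mono_gradient":
        tau = 0.1 + row * (5.0 - 0.1)
        intensity = rng.uniform(25, 500, size=dims)
        tau_flat = tau.ravel()[:, None]
        alpha_flat = np.ones_like(tau_flat)
        gt = {"tau": tau, "tau_amp": tau, "tau_int": tau.copy()}
    elif layout == "bi_alpha_gradient":
        tau1 = np.full(dims, 0.3)
        tau2 = np.full(dims, 3.0)
        a = row.copy()
        intensity = rng.uniform(25, 500, size=dims)
        tau_flat = np.column_stack([tau1.ravel(), tau2.ravel()])
        alpha_flat = np.column_stack([a.ravel(), 1 - a.ravel()])
        tau_amp, tau_int = _tau_maps_bi(tau1, tau2, a)
        gt = {"tau1": tau1, "tau2": tau2, "alpha": a, "tau_amp": tau_amp, "tau_int": tau_int}
    elif layout == "three_region_counts":
        tau1 = np.full(dims, 0.3)
        tau2 = np.full(dims, 2.5)
        a = 1.0 - row  # tau_amp sweeps 0.3 (top) -> 2.5 (bottom)
        intensity = np.empty(dims)
        bands = np.array_split(np.arange(ny), 3)
        for band_rows, (lo, hi) in zip(bands, count_bands):
            intensity[band_rows, :] = rng.uniform(lo, hi, size=(len(band_rows), nx))
        tau_flat = np.column_stack([tau1.ravel(), tau2.ravel()])
        alpha_flat = np.column_stack([a.ravel(), 1 - a.ravel()])
        tau_amp, tau_int = _tau_maps_bi(tau1, tau2, a)
        gt = {
            "tau1": tau1,
            "tau2": tau2,
            "alpha": a,
            "tau_amp": tau_amp,
            "tau_int": tau_int,
            "region": np.repeat(
                np.concatenate([np.full(len(b), i) for i, b in enumerate(bands)])[:, None],
                nx,
                axis=1,
            ).astype(float),
        }
    else:  # two_population_cells
        tau1 = np.full(dims, 0.3)
        tau2 = np.full(dims, 2.5)
        # cell autofluorescence: short component is minor -> long tau_amp.
        # Counts emulate a full multi-cycle acquisition (thousands of photons
        # per retained pixel), the regime the low-count protocol thins down.
        a = rng.uniform(0.10, 0.50, size=dims)
        intensity = rng.uniform(1000, 4000, size=dims)
        probe = np.zeros(dims, dtype=bool)
        yy, xx = np.mgrid[0:ny, 0:nx]
        n_blobs = max(4, (ny * nx) // 450)
        for _ in range(n_blobs):
            cy = rng.uniform(0.15 * ny, 0.85 * ny)
            cx = rng.uniform(0.15 * nx, 0.85 * nx)
            r = rng.uniform(0.06, 0.12) * min(ny, nx)
            probe |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        # gold-nanoprobe blobs: dominant short component, strongly luminescent
        a[probe] = rng.uniform(0.70, 0.95, size=int(probe.sum()))
        intensity[probe] = rng.uniform(2000, 8000, size=int(probe.sum()))
        border = np.zeros(dims, dtype=bool)
        border[:2, :] = border[-2:, :] = True
        border[:, :2] = border[:, -2:] = True
        intensity[border] = rng.uniform(0, 20, size=int(border.sum()))
        tau_flat = np.column_stack([tau1.ravel(), tau2.ravel()])
        alpha_flat = np.column_stack([a.ravel(), 1 - a.ravel()])
        tau_amp, tau_int = _tau_maps_bi(tau1, tau2, a)
        gt = {
            "tau1": tau1,
            "tau2": tau2,
            "alpha": a,
            "tau_amp": tau_amp,
            "tau_int": tau_int,
            "probe": probe.astype(float),
        }

    intensity = intensity * intensity_scale
    counts = _simulate_batch(
        tau_flat, alpha_flat, intensity.ravel(), make_irf(irf), irf.h, 0.0, rng
    ).reshape(ny, nx, irf.T)
    return DataCube(counts=counts.astype(np.uint32), gt_maps=gt, irf=irf, layout=layout)
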
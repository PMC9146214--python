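"""Classical per-histogram lifetime estimators used as comparison baselines.

* ``nlsf_fit`` — deconvolution-based nonlinear least-squares fitting of the
  IRF-convolved exponential model (damped least squares with positivity
  bounds), the conventional iterative approach.
* ``cmm_tau`` — center-of-mass method: the histogram centroid minus the IRF
  centroid estimates the intensity-weighted lifetime, non-iteratively.
* ``bcmm_fit`` — bi-exponential center-of-mass method: the first three
  temporal moments of the decay determine (tau1, tau2, alpha) through a
  two-node quadrature (Prony) system; an optional fixed-point bias correction
  compensates the finite measurement window.
* ``phasor_point`` — the first-harmonic cosine/sine transform of a histogram
  to phasor coordinates (g, s), calibrated against the IRF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.special import gammainc

from .tcspc_sim import Histogram

__all__ = [
    "FitResult",
    "BCMMResult",
    "nlsf_fit",
    "cmm_tau",
    "bcmm_fit",
    "phasor_point",
    "DEFAULT_MONO_INIT",
    "DEFAULT_BI_INIT",
]

#: default NLSF starting lifetimes (ns): mid-range mono, split bi components
DEFAULT_MONO_INIT = (2.5,)
DEFAULT_BI_INIT = (0.5, 2.0, 0.5)


def _counts_of(hist) -> np.ndarray:
    counts = hist.counts if isinstance(hist, Histogram) else np.asarray(hist)
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("histogram must be a 1-D vector of counts")
    return counts


@dataclass(frozen=True)
class FitResult:
    """Outcome of one nonlinear least-squares fit."""

    params: dict[str, float]
    converged: bool
    residual_norm: float
    n_iterations: int


@dataclass(frozen=True)
class BCMMResult:
    """Outcome of one bi-exponential moment fit."""

    tau1: float
    tau2: float
    alpha: float
    tau_amp: float
    converged: bool
    window_warning: bool
    n_iterations: int = 0


def _model_curve(x: np.ndarray, irf: np.ndarray, h: float, order: int) -> np.ndarray:
    T = irf.shape[0]
    t = np.arange(T) * h
    if order == 1:
        amp, tau = x
        decay = amp * np.exp(-t / tau)
    else:
        amp, tau1, tau2, alpha = x
        decay = amp * (alpha * np.exp(-t / tau1) + (1.0 - alpha) * np.exp(-t / tau2))
    return np.convolve(irf, decay)[:T]


def nlsf_fit(
    hist,
    irf: np.ndarray,
    order: int = 1,
    init: tuple[float, ...] | None = None,
    bounds: tuple | None = None,
    h: float = 0.039,
    max_nfev: int = 200,
) -> FitResult:
    """Fit the IRF-convolved decay model by damped least squares.

    Free parameters are an amplitude scale plus ``tau`` (``order=1``) or
    ``(tau1, tau2, alpha)`` (``order=2``).  ``init`` gives the lifetime (and
    alpha) starting point; the amplitude start is matched to the histogram
    total.  Non-convergence is reported through ``converged``, never raised —
    the last iterate is returned.  The estimate is sensitive to the starting
    point, a documented weakness of iterative fitting.
    """
    counts = _counts_of(hist)
    irf = np.asarray(irf, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("cannot fit an all-zero histogram")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if init is None:
        init = DEFAULT_MONO_INIT if order == 1 else DEFAULT_BI_INIT
    init = tuple(float(v) for v in init)
    # amplitude start: match total counts of the model at the init lifetimes
    unit = _model_curve((1.0, *init), irf, h, order)
    amp0 = counts.sum() / max(unit.sum(), 1e-300)
    x0 = np.array([amp0, *init])
    if bounds is None:
        if order == 1:
            lo, hi = [0.0, 1e-3], [np.inf, 50.0]
        else:
            lo, hi = [0.0, 1e-3, 1e-3, 0.0], [np.inf, 50.0, 50.0, 1.0]
    else:
        lo, hi = bounds
    x0 = np.clip(x0, lo, hi)

    def residual(x):
        return _model_curve(x, irf, h, order) - counts

    res = least_squares(residual, x0, bounds=(lo, hi), method="trf", max_nfev=max_nfev)
    if order == 1:
        params = {"amp": res.x[0], "tau": res.x[1]}
    else:
        amp, tau1, tau2, alpha = res.x
        if tau1 > tau2:  # report components in increasing-lifetime order
            tau1, tau2, alpha = tau2, tau1, 1.0 - alpha
        params = {
            "amp": amp,
            "tau1": tau1,
            "tau2": tau2,
            "alpha": alpha,
            "tau_amp": alpha * tau1 + (1 - alpha) * tau2,
        }
    params = {k: float(v) for k, v in params.items()}
    return FitResult(
        params=params,
        converged=bool(res.success),
        residual_norm=float(np.linalg.norm(res.fun)),
        n_iterations=int(res.nfev),
    )


def _centroid(values: np.ndarray, h: float) -> float:
    """Bin-center first moment of a non-negative vector, in ns."""
    t = (np.arange(values.shape[0]) + 0.5) * h
    return float((t * values).sum() / values.sum())


def cmm_tau(
    hist,
    irf: np.ndarray | None = None,
    h: float = 0.039,
    correct_window: bool = False,
    background: float = 0.0,
) -> float:
    """Center-of-mass lifetime: histogram centroid minus IRF centroid (ns).

    For an exponential decay observed over an infinite window the centroid
    equals the lifetime; a finite window ``T_w`` shortens it to
    ``tau - T_w exp(-T_w/tau) / (1 - exp(-T_w/tau))``.  With
    ``correct_window=True`` that relation is inverted numerically to undo the
    truncation bias.  The estimate is invariant to histogram scaling.
    """
    counts = _counts_of(hist) - background
    counts = np.clip(counts, 0.0, None)
    total = counts.sum()
    if total <= 0:
        raise ValueError("histogram total must be positive")
    m = _centroid(counts, h)
    window = counts.shape[0] * h
    if irf is not None:
        irf = np.asarray(irf, dtype=float)
        shift = _centroid(irf, h) - 0.5 * h  # decay time origin at the IRF peak bin start
        m -= shift
        window -= shift
    if not correct_window:
        return m
    if m >= window / 2:  # centroid of a flat histogram; no finite tau reproduces it
        return m

    def bias(tau):
        x = window / tau
        return tau - window * np.exp(-x) / (1.0 - np.exp(-x)) - m

    return float(brentq(bias, 1e-6, 1e4, xtol=1e-12))


def _prony_two_node(m1: float, m2: float, m3: float):
    """Nodes and weights of the two-point quadrature matching moments.

    Given power moments ``m_j = w1 tau1^j + w2 tau2^j`` (j = 1..3, w1+w2=1),
    the nodes solve ``x^2 - c1 x - c0 = 0`` with Hankel coefficients from
    ``[[1, m1], [m1, m2]] @ [c0, c1] = [m2, m3]``.  Returns
    ``(tau1, tau2, w1)`` with tau1 <= tau2, or None if the system is
    degenerate or the roots unphysical.
    """
    det = m2 - m1 * m1
    if det <= 0:
        return None
    c0 = (m2 * m2 - m1 * m3) / det
    c1 = (m3 - m1 * m2) / det
    disc = c1 * c1 + 4.0 * c0
    if disc < 0:
        return None
    root = np.sqrt(disc)
    tau1 = (c1 - root) / 2.0
    tau2 = (c1 + root) / 2.0
    if tau1 <= 0 or tau2 <= tau1:
        return None
    w1 = (tau2 - m1) / (tau2 - tau1)
    if not 0.0 <= w1 <= 1.0:
        return None
    return tau1, tau2, w1


def _power_moments(counts: np.ndarray, h: float, shift: float) -> tuple[float, float, float]:
    t = (np.arange(counts.shape[0]) + 0.5) * h - shift
    total = counts.sum()
    mu1 = (t * counts).sum() / total
    mu2 = (t**2 * counts).sum() / total
    mu3 = (t**3 * counts).sum() / total
    return mu1, mu2 / 2.0, mu3 / 6.0


def _truncated_power_moments(tau1, tau2, alpha, window):
    """Continuous model power moments m_j over a finite window [0, window]."""
    taus = np.array([tau1, tau2])
    amps = np.array([alpha, 1.0 - alpha])
    x = window / taus
    ms = []
    denom = (amps * taus * gammainc(1, x)).sum()
    for j in (1, 2, 3):
        num = (amps * taus ** (j + 1) * gammainc(j + 1, x)).sum()
        ms.append(num / denom)
    return tuple(ms)


def _windowed_model_moments(tau1, tau2, alpha, T, h):
    """Power moments of the bin-sampled, window-truncated model decay.

    Evaluating the mixture on the same bin grid the estimator sees folds both
    the finite-window truncation and the discretization into the reference
    moments, so the bias-correction fixed point is exact on noiseless data.
    """
    t = np.arange(T) * h
    d = alpha * np.exp(-t / tau1) + (1.0 - alpha) * np.exp(-t / tau2)
    return np.array(_power_moments(d, h, 0.0))


def _infinite_power_moments(tau1, tau2, alpha):
    taus = np.array([tau1, tau2])
    amps = np.array([alpha, 1.0 - alpha])
    s = [(amps * taus**j).sum() for j in (1, 2, 3, 4)]
    return s[1] / s[0], s[2] / s[0], s[3] / s[0]


def bcmm_fit(
    hist,
    h: float = 0.039,
    irf: np.ndarray | None = None,
    background: float = 0.0,
    bias_correction: bool = True,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> BCMMResult:
    """Bi-exponential lifetime recovery from the first three temporal moments.

    The background-subtracted, IRF-centroid-shifted decay's power moments
    ``m_j = mu_j / j!`` equal ``w1 tau1^j + w2 tau2^j`` for an untruncated
    bi-exponential, so the two lifetimes are the nodes of a two-point Prony
    system and ``alpha`` follows from the node weights.  A finite measurement
    window biases the raw moments (severely so for the third moment whenever
    ``window < ~10 tau2``); with ``bias_correction=True`` the moments are
    iteratively re-centered using the model's own truncated-moment formulas
    until the recovered parameters are self-consistent.

    Degenerate inputs (effectively mono-exponential) or unphysical moment
    systems yield ``converged=False`` with the centroid lifetime in both
    components, never an exception.  ``window_warning`` flags
    ``window < 5 * tau2_hat``, where truncation bias is material.
    """
    counts = _counts_of(hist) - background
    counts = np.clip(counts, 0.0, None)
    if counts.sum() <= 0:
        raise ValueError("histogram total must be positive")
    shift = 0.0
    window = counts.shape[0] * h
    if irf is not None:
        irf = np.asarray(irf, dtype=float)
        shift = _centroid(irf, h) - 0.5 * h
        window -= shift
    meas = np.array(_power_moments(counts, h, shift))
    n_bins = int(round(window / h))

    sol = _prony_two_node(*meas)
    n_it = 0
    corrected = None
    if bias_correction:
        # Window-bias correction: solve the *windowed* moment equations
        # m_j(tau1, tau2, alpha) = measured m_j, seeded by the closed-form
        # Prony solution (or a coarse centroid split when truncation makes
        # the raw Prony system degenerate).  Parameters are transformed
        # (log lifetimes, logit alpha) so the solver stays in the physical
        # domain.
        from scipy.optimize import root
        from scipy.special import expit, logit

        if sol is None:
            m1 = meas[0]
            theta0 = (max(0.3 * m1, 1e-3), 1.2 * m1, 0.5)
        else:
            t1, t2, w1 = sol
            theta0 = (t1, t2, min(max(_weights_to_alpha(t1, t2, w1), 1e-4), 1 - 1e-4))

        def equations(u):
            u = np.clip(u, -14.0, 14.0)  # keep lifetimes finite and positive
            t1, t2, a = np.exp(u[0]), np.exp(u[1]), expit(u[2])
            return _windowed_model_moments(t1, t2, a, n_bins, h) - meas

        u0 = np.array([np.log(theta0[0]), np.log(theta0[1]), logit(theta0[2])])
        result = root(equations, u0, method="hybr", options={"maxfev": 40 * max_iter})
        n_it = int(result.nfev)
        if result.success:
            x = np.clip(result.x, -14.0, 14.0)
            t1, t2 = np.exp(x[0]), np.exp(x[1])
            a = float(expit(x[2]))
            if t1 > t2:
                t1, t2 = t2, t1
                a = 1.0 - a
            if t2 / t1 < 1 + 1e-6:  # components merged: effectively mono
                corrected = None
                sol = None
            else:
                corrected = (float(t1), float(t2), a)
    if corrected is not None:
        tau1, tau2, alpha = corrected
    elif sol is not None and not bias_correction:
        tau1, tau2, w1 = sol
        alpha = _weights_to_alpha(tau1, tau2, w1)
    else:
        tau = _centroid(counts, h) - shift
        return BCMMResult(
            tau1=tau,
            tau2=tau,
            alpha=1.0,
            tau_amp=tau,
            converged=False,
            window_warning=window < 5 * tau,
            n_iterations=n_it,
        )
    ta = alpha * tau1 + (1 - alpha) * tau2
    return BCMMResult(
        tau1=float(tau1),
        tau2=float(tau2),
        alpha=float(alpha),
        tau_amp=float(ta),
        converged=True,
        window_warning=bool(window < 5 * tau2),
        n_iterations=n_it,
    )


def _weights_to_alpha(tau1: float, tau2: float, w1: float) -> float:
    """Quadrature weights w_k are intensity fractions alpha_k tau_k / sum."""
    a1 = w1 / tau1
    a2 = (1.0 - w1) / tau2
    return a1 / (a1 + a2)


def phasor_point(
    hist,
    irf: np.ndarray | None = None,
    harmonic: int = 1,
    half_bin_correction: bool = True,
) -> tuple[float, float]:
    """Phasor coordinates (g, s) of a histogram at a window harmonic.

    ``g + i s = sum_k c_k exp(i omega t_k) / sum_k c_k`` with
    ``omega = 2 pi harmonic / (T h)``.  When an IRF is given, the histogram
    phasor is divided by the IRF's own phasor (phase/modulation calibration),
    so the IRF's calibrated phasor is exactly (1, 0).  For uncalibrated
    transforms (time origin at bin 0), ``half_bin_correction`` applies the
    half-sample phase ``exp(i omega h / 2)`` that places binned counts at bin
    centers; with it, noiseless mono-exponential decays land on the universal
    semicircle to within the bin-discretization error (~(2 pi / T)^2 / 8).
    The factor cancels identically in the calibration ratio, so it is never
    applied on top of an IRF calibration.
    """
    counts = _counts_of(hist)
    total = counts.sum()
    if total <= 0:
        raise ValueError("histogram total must be positive")
    T = counts.shape[0]
    theta = 2.0 * np.pi * harmonic / T
    phase = np.exp(1j * theta * np.arange(T))
    z = (counts * phase).sum() / total
    if irf is not None:
        irf = np.asarray(irf, dtype=float)
        z_irf = (irf * phase).sum() / irf.sum()
        z = z / z_irf
    elif half_bin_correction:
        z = z * np.exp(1j * theta / 2.0)
    return float(z.real), float(z.imag)
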
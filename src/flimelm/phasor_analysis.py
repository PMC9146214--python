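"""Phasor-domain analysis: chord fitting, semicircle geometry, projection scores.

Every decay maps to a point (g, s) in the phasor plane; mono-exponential
decays lie on the universal semicircle ``(g - 1/2)^2 + s^2 = 1/4, s >= 0``
and two-component mixtures lie on the chord between their component points.
For a field of view containing two lifetime populations (e.g. cellular
autofluorescence and short-lifetime gold nanoprobes), fitting a line through
the pixel cloud, intersecting it with the semicircle to obtain endpoints A
and B, and projecting each pixel onto the chord yields a per-pixel score
``rho`` in [0, 1] — a phasor projection image that separates the two
populations without fitting any decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baselines import phasor_point
from .tcspc_sim import DataCube, make_irf

__all__ = [
    "PhasorCloud",
    "fit_line",
    "circle_intersections",
    "project_score",
    "projection_image",
    "phasor_cloud_from_cube",
    "pixel_phasors",
]


@dataclass
class PhasorCloud:
    """Per-pixel phasor points with the fitted chord and projection scores."""

    g: np.ndarray
    s: np.ndarray
    slope: float
    intercept: float
    A: tuple[float, float]
    B: tuple[float, float]
    scores: np.ndarray
    valid_mask: np.ndarray | None = None
    harmonic: int = 1

    @property
    def D(self) -> float:
        """Euclidean distance between the chord endpoints."""
        return float(np.hypot(self.A[0] - self.B[0], self.A[1] - self.B[1]))


def fit_line(g: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Least-squares line s = a*g + b through the phasor points."""
    g = np.asarray(g, dtype=float)
    s = np.asarray(s, dtype=float)
    if g.size < 2:
        raise ValueError("need at least two points to fit a line")
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(s))):
        raise ValueError("phasor points must be finite")
    if np.ptp(g) == 0:
        raise ValueError("degenerate vertical cloud: all g coordinates equal")
    a, b = np.polyfit(g, s, 1)
    return float(a), float(b)


def circle_intersections(a: float, b: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """Intersections of s = a*g + b with the universal semicircle.

    Returns (A, B) with A the larger-g point (toward (1, 0), the
    zero-lifetime end).  Raises if the line misses the circle.
    """
    # substitute into (g - 1/2)^2 + (a g + b)^2 = 1/4
    qa = 1.0 + a * a
    qb = 2.0 * a * b - 1.0
    qc = b * b
    disc = qb * qb - 4.0 * qa * qc
    if disc < 0:
        raise ValueError(
            f"line s = {a:g}*g + {b:g} does not intersect the universal "
            f"semicircle (discriminant {disc:.3g} < 0)"
        )
    root = np.sqrt(disc)
    g_hi = (-qb + root) / (2.0 * qa)
    g_lo = (-qb - root) / (2.0 * qa)
    A = (float(g_hi), float(a * g_hi + b))
    B = (float(g_lo), float(a * g_lo + b))
    return A, B


def project_score(
    point: tuple[float, float] | np.ndarray,
    A: tuple[float, float],
    B: tuple[float, float],
) -> float | np.ndarray:
    """Normalized scalar projection of phasor points onto the chord B -> A.

    ``rho = [(g - g_b)(g_a - g_b) + (s - s_b)(s_a - s_b)] / D^2`` with ``D``
    the chord length, so ``rho(B) = 0`` and ``rho(A) = 1`` and the score is
    affine along the chord.
    """
    ga, sa = A
    gb, sb = B
    d2 = (ga - gb) ** 2 + (sa - sb) ** 2
    if d2 == 0:
        raise ValueError("chord endpoints coincide (D = 0)")
    point = np.asarray(point, dtype=float)
    g = point[..., 0]
    s = point[..., 1]
    rho = ((g - gb) * (ga - gb) + (s - sb) * (sa - sb)) / d2
    return float(rho) if rho.ndim == 0 else rho


def pixel_phasors(
    cube: DataCube,
    mask: np.ndarray,
    harmonic: int = 1,
    calibrate: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized phasor transform of every retained pixel of a cube."""
    counts = cube.counts.reshape(-1, cube.irf.T)[mask.ravel()]
    totals = counts.sum(axis=1).astype(float)
    if np.any(totals <= 0):
        raise ValueError("masked-in pixels must have positive totals")
    T = cube.irf.T
    theta = 2.0 * np.pi * harmonic / T
    phase = np.exp(1j * theta * np.arange(T))
    z = (counts * phase).sum(axis=1) / totals
    if calibrate:
        irf = make_irf(cube.irf)
        z = z / ((irf * phase).sum() / irf.sum())
    else:
        z = z * np.exp(1j * theta / 2.0)  # bin-center phase
    return z.real, z.imag


def phasor_cloud_from_cube(
    cube: DataCube,
    threshold: float = 100.0,
    harmonic: int = 1,
    polarity: str = "short",
) -> PhasorCloud:
    """Filter a cube by total counts, fit the chord, and score every pixel.

    ``polarity='short'`` assigns rho = 1 to the larger-g (shorter-lifetime)
    endpoint; ``'long'`` flips the labeling so rho increases with lifetime.
    """
    if polarity not in ("short", "long"):
        raise ValueError("polarity must be 'short' or 'long'")
    totals = cube.pixel_totals()
    mask = totals >= threshold
    if not mask.any():
        raise ValueError("intensity threshold removed every pixel")
    g, s = pixel_phasors(cube, mask, harmonic=harmonic)
    a, b = fit_line(g, s)
    A, B = circle_intersections(a, b)
    if polarity == "long":
        A, B = B, A
    scores = project_score(np.column_stack([g, s]), A, B)
    return PhasorCloud(
        g=g, s=s, slope=a, intercept=b, A=A, B=B, scores=scores, valid_mask=mask, harmonic=harmonic
    )


def projection_image(cloud: PhasorCloud, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Write per-pixel scores back to image positions; masked pixels are NaN."""
    if cloud.valid_mask is None:
        raise ValueError("cloud carries no pixel index map")
    mask = np.asarray(cloud.valid_mask, dtype=bool)
    if shape is not None and mask.shape != tuple(shape):
        raise ValueError(f"index map shape {mask.shape} does not match requested {shape}")
    if int(mask.sum()) != cloud.scores.size:
        raise ValueError("score count does not match the number of retained pixels")
    img = np.full(mask.shape, np.nan)
    img[mask] = cloud.scores
    return img
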
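"""Evaluation statistics for lifetime estimators.

The photon-economy figure of merit

    F = sqrt(I) * (delta_x / x)

compares an estimator's precision to the photon-limited optimum: ``I`` is the
mean detected photon count, ``delta_x`` the sample standard deviation of the
estimates over Monte-Carlo replicates, ``x`` the true parameter.  F = 1 is
the shot-noise bound for an ideal estimator; larger is worse, and F is
(approximately) independent of the photon count for an efficient estimator.

Also provided: the coefficient of determination R^2, per-sample absolute
error and relative bias, MSE/MAE, SSIM between reconstructed and ground-truth
images, and per-region (mu, sigma) lifetime summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
from skimage.metrics import structural_similarity

__all__ = [
    "MetricsReport",
    "f_value",
    "r_squared",
    "bias_and_error",
    "mse",
    "mae",
    "ssim_image",
    "region_stats",
]


def f_value(estimates: np.ndarray, gt_param: float, photon_count: float | np.ndarray) -> float:
    """Photon-economy F-value sqrt(I) * std(estimates) / gt_param.

    ``photon_count`` may be a scalar or the per-replicate counts, in which
    case the mean count is used.  The standard deviation uses the sample
    (n - 1) convention.  Identical estimates give the degenerate F = 0.
    """
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size < 2:
        raise ValueError("F-value needs at least two estimates")
    if not gt_param > 0:
        raise ValueError("ground-truth parameter must be positive")
    mean_count = float(np.mean(photon_count))
    if not mean_count > 0:
        raise ValueError("photon count must be positive")
    return float(np.sqrt(mean_count) * estimates.std(ddof=1) / gt_param)


def r_squared(pred: np.ndarray, gt: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if pred.shape != gt.shape or pred.size < 2:
        raise ValueError("pred and gt must have equal length >= 2")
    ss_tot = float(((gt - gt.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("ground truth is constant; R^2 undefined")
    ss_res = float(((pred - gt) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def bias_and_error(pred: np.ndarray, gt: np.ndarray | float) -> tuple[np.ndarray, float]:
    """Per-sample absolute error |gt - pred| and mean relative bias.

    Bias is ``mean((pred - gt) / gt)``: overestimation is positive.
    """
    pred = np.asarray(pred, dtype=float)
    gt_arr = np.broadcast_to(np.asarray(gt, dtype=float), pred.shape)
    if np.any(gt_arr == 0):
        raise ValueError("relative bias undefined for zero ground truth")
    abs_err = np.abs(gt_arr - pred)
    bias = float(np.mean((pred - gt_arr) / gt_arr))
    return abs_err, bias


def mse(pred: np.ndarray, gt: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    return float(np.mean((pred - gt) ** 2))


def mae(pred: np.ndarray, gt: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    return float(np.mean(np.abs(pred - gt)))


def ssim_image(img1: np.ndarray, img2: np.ndarray, dynamic_range: float | None = None) -> float:
    """Mean structural similarity between two images.

    ``dynamic_range`` defaults to the joint value range of the two images.
    """
    img1 = np.asarray(img1, dtype=float)
    img2 = np.asarray(img2, dtype=float)
    if img1.shape != img2.shape:
        raise ValueError(f"shape mismatch: {img1.shape} vs {img2.shape}")
    if dynamic_range is None:
        lo = min(img1.min(), img2.min())
        hi = max(img1.max(), img2.max())
        dynamic_range = hi - lo if hi > lo else 1.0
    return float(structural_similarity(img1, img2, data_range=dynamic_range))


def region_stats(
    lifetime_image: np.ndarray,
    regions: dict[str, np.ndarray] | np.ndarray,
) -> dict[str, tuple[float, float]]:
    """Per-region (mu, sigma) of valid pixels.

    ``regions`` is either a mapping of region name to boolean mask or an
    integer label image (each label becomes a region).  NaN pixels (masked or
    out of range) are excluded.  Sigma uses the population (ddof = 0)
    convention, matching how per-image spread is quoted alongside mu.
    """
    img = np.asarray(lifetime_image, dtype=float)
    if not isinstance(regions, dict):
        labels = np.asarray(regions)
        regions = {str(v): labels == v for v in np.unique(labels)}
    out: dict[str, tuple[float, float]] = {}
    for name, mask in regions.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != img.shape:
            raise ValueError(f"region {name!r} mask shape mismatch")
        vals = img[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"region {name!r} has no valid pixels")
        out[name] = (float(vals.mean()), float(vals.std(ddof=0)))
    return out


@dataclass
class MetricsReport:
    """Bundle of evaluation statistics for one estimator on one dataset."""

    f_value: float | None = None
    r2: float | None = None
    bias: float | None = None
    mse: float | None = None
    mae: float | None = None
    ssim: float | None = None
    region_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload
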
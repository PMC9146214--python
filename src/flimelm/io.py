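"""File formats: HDF5 cubes/models/training sets, CSV histograms, TIFF stacks.

HDF5 cube layout: ``/counts`` (uint32, X x Y x T), ``/gt/<param>`` (float32,
X x Y), with IRF metadata as root attributes (``bin_width_ns``, ``t0`` in the
1-based bin convention, ``fwhm_ns``, ``layout``).  TIFF export writes T pages
of X x Y with a YAML sidecar for the same metadata.  Histogram sets go to CSV
with one histogram per row plus a companion ground-truth CSV.
"""

from __future__ import annotations

import pathlib

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .elm_core import ELMModel
from .tcspc_sim import DataCube, IRFSpec, TrainingConfig, TrainingSet

__all__ = [
    "save_cube",
    "load_cube",
    "save_cube_tiff",
    "load_cube_tiff",
    "save_model",
    "load_model",
    "save_training_set",
    "load_training_set",
    "histograms_to_csv",
    "histograms_from_csv",
]


def _irf_attrs(attrs, irf: IRFSpec) -> None:
    attrs["bin_width_ns"] = irf.h
    attrs["t0"] = int(irf.t0)
    attrs["fwhm_ns"] = irf.fwhm
    attrs["n_bins"] = int(irf.T)


def _irf_from_attrs(attrs) -> IRFSpec:
    return IRFSpec(
        fwhm=float(attrs["fwhm_ns"]),
        t0=int(attrs["t0"]),
        h=float(attrs["bin_width_ns"]),
        T=int(attrs["n_bins"]),
    )


def save_cube(path, cube: DataCube) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=cube.counts.astype(np.uint32), compression="gzip")
        g = f.create_group("gt")
        for name, m in cube.gt_maps.items():
            g.create_dataset(name, data=np.asarray(m, dtype=np.float32))
        _irf_attrs(f.attrs, cube.irf)
        f.attrs["layout"] = cube.layout


def load_cube(path) -> DataCube:
    with h5py.File(path, "r") as f:
        counts = f["counts"][...]
        gt = {name: f["gt"][name][...].astype(float) for name in f.get("gt", {})}
        irf = _irf_from_attrs(f.attrs)
        layout = str(f.attrs.get("layout", ""))
    return DataCube(counts=counts, gt_maps=gt, irf=irf, layout=layout)


def save_cube_tiff(path, cube: DataCube) -> None:
    """Multi-page TIFF (T pages of X x Y) plus a YAML metadata sidecar."""
    path = pathlib.Path(path)
    tifffile.imwrite(path, np.moveaxis(cube.counts.astype(np.uint32), 2, 0))
    meta = {
        "bin_width_ns": float(cube.irf.h),
        "t0": int(cube.irf.t0),
        "fwhm_ns": float(cube.irf.fwhm),
        "n_bins": int(cube.irf.T),
        "layout": cube.layout,
    }
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def load_cube_tiff(path) -> DataCube:
    path = pathlib.Path(path)
    counts = np.moveaxis(tifffile.imread(path), 0, 2)
    with open(path.with_suffix(".yaml")) as fh:
        meta = yaml.safe_load(fh)
    irf = IRFSpec(
        fwhm=meta["fwhm_ns"], t0=meta["t0"], h=meta["bin_width_ns"], T=meta["n_bins"]
    )
    return DataCube(counts=counts, gt_maps={}, irf=irf, layout=meta.get("layout", ""))


def save_model(path, model: ELMModel) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=model.W)
        f.create_dataset("b", data=model.b)
        if model.beta is not None:
            f.create_dataset("beta", data=model.beta)
        f.attrs["activation"] = model.activation
        f.attrs["lambda"] = model.lam
        f.attrs["seed"] = -1 if model.seed is None else int(model.seed)
        f.attrs["output_names"] = list(model.output_names)
        f.attrs["output_ranges"] = np.asarray(model.output_ranges, dtype=float)


def load_model(path) -> ELMModel:
    with h5py.File(path, "r") as f:
        W = f["W"][...]
        b = f["b"][...]
        beta = f["beta"][...] if "beta" in f else None
        seed = int(f.attrs["seed"])
        ranges = tuple(tuple(float(v) for v in row) for row in f.attrs["output_ranges"])
        names = tuple(
            n.decode() if isinstance(n, bytes) else str(n) for n in f.attrs["output_names"]
        )
        return ELMModel(
            W=W,
            b=b,
            activation=str(f.attrs["activation"]),
            lam=float(f.attrs["lambda"]),
            seed=None if seed < 0 else seed,
            beta=beta,
            output_names=names,
            output_ranges=ranges,
        )


def save_training_set(path, ts: TrainingSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=ts.X.astype(np.float32), compression="gzip")
        f.create_dataset("Y", data=ts.Y)
        f.attrs["model"] = ts.config.model
        f.attrs["seed"] = int(ts.seed)
        f.attrs["n_samples"] = int(ts.config.n_samples)
        f.attrs["intensity_range"] = list(ts.config.intensity_range)
        f.attrs["background"] = ts.config.background
        for name, rng in ts.config.ranges.items():
            f.attrs[f"range_{name}"] = list(rng)
        _irf_attrs(f.attrs, ts.config.irf)


def load_training_set(path) -> TrainingSet:
    with h5py.File(path, "r") as f:
        X = f["X"][...].astype(float)
        Y = f["Y"][...]
        model = str(f.attrs["model"])
        kwargs = dict(
            model=model,
            n_samples=int(f.attrs["n_samples"]),
            intensity_range=tuple(f.attrs["intensity_range"]),
            background=float(f.attrs["background"]),
            irf=_irf_from_attrs(f.attrs),
        )
        if model == "mono":
            kwargs["tau_range"] = tuple(f.attrs["range_tau"])
        else:
            kwargs["tau1_range"] = tuple(f.attrs["range_tau1"])
            kwargs["tau2_range"] = tuple(f.attrs["range_tau2"])
            kwargs["alpha_range"] = tuple(f.attrs["range_alpha"])
        config = TrainingConfig(**kwargs)
        seed = int(f.attrs["seed"])
    return TrainingSet(X=X, Y=Y, config=config, seed=seed)


def histograms_to_csv(path, counts: np.ndarray, gt: pd.DataFrame | None = None) -> None:
    """One histogram per row; optional companion ``<stem>_gt.csv`` of targets."""
    path = pathlib.Path(path)
    pd.DataFrame(np.atleast_2d(counts)).to_csv(path, index=False, header=False)
    if gt is not None:
        gt.to_csv(path.with_name(path.stem + "_gt.csv"), index=False)


def histograms_from_csv(path) -> np.ndarray:
    return pd.read_csv(path, header=None).to_numpy()
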
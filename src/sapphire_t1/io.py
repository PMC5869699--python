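"""NIfTI + sidecar plumbing for series, truth maps and fitted maps."""

from __future__ import annotations

import json
import math
from pathlib import Path

import nibabel as nib
import numpy as np

from .cardiac_timing import load_timing_sidecar, save_timing_sidecar
from .fitting import T1MapResult
from .phantom import PhantomSeries

__all__ = [
    "write_nifti",
    "read_nifti",
    "write_series",
    "read_series",
    "write_t1_map",
]


def _affine(pixel_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = pixel_mm
    return aff


def write_nifti(path, array: np.ndarray, pixel_mm: float = 1.0) -> None:
    """Write a 2-D map or a (frames, ny, nx) stack as x-y(-frame) NIfTI."""
    arr = np.asarray(array)
    if arr.ndim == 3:  # (frame, ny, nx) -> (ny, nx, frame)
        arr = np.moveaxis(arr, 0, -1)
    dtype = np.complex64 if np.iscomplexobj(arr) else np.float32
    img = nib.Nifti1Image(arr.astype(dtype), _affine(pixel_mm))
    nib.save(img, str(path))


def read_nifti(path, as_stack: bool = False) -> np.ndarray:
    arr = np.asanyarray(nib.load(str(path)).dataobj)
    if as_stack and arr.ndim == 3:
        arr = np.moveaxis(arr, -1, 0)
    return arr


def write_series(out_dir, name: str, series: PhantomSeries, pixel_mm: float = 1.0) -> dict:
    """Write one series: complex NIfTI stack, timing sidecars, truth maps.

    Returns a manifest entry mapping artifact kind to file name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    write_nifti(out_dir / f"{name}.nii.gz", series.frames, pixel_mm)
    files["series"] = f"{name}.nii.gz"
    save_timing_sidecar(
        series.timings, out_dir / f"{name}_timing.csv", out_dir / f"{name}_timing.json"
    )
    files["timing_csv"] = f"{name}_timing.csv"
    files["timing_json"] = f"{name}_timing.json"
    for key, arr in (
        ("truth_t1", series.truth_t1_map),
        ("truth_m0", series.truth_m0_map),
        ("labels", series.label_map),
    ):
        if arr is not None:
            write_nifti(out_dir / f"{name}_{key}.nii.gz", np.asarray(arr, float), pixel_mm)
            files[key] = f"{name}_{key}.nii.gz"
    meta = {"snr": None if math.isinf(series.snr) else series.snr, "seed": series.seed}
    with open(out_dir / f"{name}_meta.json", "w") as fh:
        json.dump(meta, fh)
    files["meta"] = f"{name}_meta.json"
    return files


def read_series(dir_path, name: str) -> PhantomSeries:
    dir_path = Path(dir_path)
    frames = read_nifti(dir_path / f"{name}.nii.gz", as_stack=True)
    timings = load_timing_sidecar(dir_path / f"{name}_timing.csv")
    kwargs = {}
    for key, attr in (("truth_t1", "truth_t1_map"), ("truth_m0", "truth_m0_map"), ("labels", "label_map")):
        p = dir_path / f"{name}_{key}.nii.gz"
        if p.exists():
            kwargs[attr] = read_nifti(p)
    meta_path = dir_path / f"{name}_meta.json"
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        kwargs["snr"] = meta.get("snr") or math.inf
        kwargs["seed"] = meta.get("seed")
    return PhantomSeries(frames=frames, timings=timings, **kwargs)


def write_t1_map(out_dir, name: str, result: T1MapResult, pixel_mm: float = 1.0) -> dict:
    """Write fitted maps and fit diagnostics for one series."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for key, arr in (
        ("t1", result.t1_map),
        ("m0", result.m0_map),
        ("inv_eff", result.inv_eff_map),
        ("residual", result.residual_map),
    ):
        write_nifti(out_dir / f"{name}_{key}.nii.gz", arr, pixel_mm)
        files[key] = f"{name}_{key}.nii.gz"
    write_nifti(out_dir / f"{name}_polarity.nii.gz", result.polarity_map.astype(np.float32), pixel_mm)
    files["polarity"] = f"{name}_polarity.nii.gz"
    diag = {
        "method": result.method,
        "n_fitted": int(np.isfinite(result.t1_map).sum()),
        "n_converged": int(result.converged_mask.sum()),
    }
    with open(out_dir / f"{name}_fit.json", "w") as fh:
        json.dump(diag, fh, indent=1)
    files["diagnostics"] = f"{name}_fit.json"
    return files
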
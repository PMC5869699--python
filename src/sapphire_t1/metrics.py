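"""Quantitative evaluation of T1 maps.

Accuracy is the mean fitted T1 (per pixel across repetitions, or per ROI);
precision is the standard deviation (across repetitions per pixel, or
within a region).  The coefficient of variation CoV = SD / mean summarizes
stability of an estimate across conditions.  The septal full-width at half
maximum (FWHM) of a blood-to-blood line profile measures the usable
myocardial wall thickness, and the extracellular volume fraction combines
native and post-contrast T1 of myocardium and blood with the hematocrit:

    ECV = (1 - Hct) * (1/T1_myo_post - 1/T1_myo_native)
                    / (1/T1_blood_post - 1/T1_blood_native)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "RegionReport",
    "accuracy_precision_maps",
    "cov",
    "fwhm_profile",
    "ecv",
    "segment_sectors",
    "region_report",
]


@dataclass
class RegionReport:
    """Per-region statistics of a T1 map."""

    region_id: int
    n_pixels: int
    mean_t1: float
    precision: float  # intra-region SD, ms
    cov: float
    extras: dict = field(default_factory=dict)


def accuracy_precision_maps(t1_maps: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean (accuracy) and sample SD (precision) across repetitions."""
    maps = [np.asarray(m, dtype=float) for m in t1_maps]
    if len(maps) < 2:
        raise ValueError("need at least 2 repetitions")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("repetition maps differ in shape")
    stack = np.stack(maps)
    return stack.mean(axis=0), stack.std(axis=0, ddof=1)


def cov(values) -> float:
    """Coefficient of variation: sample SD / mean."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean == 0:
        raise ValueError("CoV undefined for zero mean")
    return float(values.std(ddof=1) / mean)


def _crossing(x0, v0, x1, v1, level):
    """Linear-interpolated position where the profile crosses ``level``."""
    if v1 == v0:
        return x0
    return x0 + (level - v0) / (v1 - v0) * (x1 - x0)


def fwhm_profile(
    t1_map: np.ndarray,
    line: tuple[tuple[float, float], tuple[float, float]],
    pixel_mm: float = 1.0,
    oversample: int = 8,
    plateau_frac: float = 0.2,
) -> float:
    """FWHM (mm) of the dip (or peak) in a line profile through a T1 map.

    The profile is sampled by bilinear interpolation along the segment from
    ``line[0]`` to ``line[1]`` (pixel coordinates, (row, col)).  The plateau
    level is the median of the outer ``plateau_frac`` of samples on each end,
    the extremum is the sample furthest from the plateau, and the FWHM is the
    distance between the two half-level crossings flanking the extremum
    (sub-pixel by linear interpolation).
    """
    (r0, c0), (r1, c1) = line
    length_px = math.hypot(r1 - r0, c1 - c0)
    if length_px <= 0:
        raise ValueError("degenerate line")
    n = max(int(math.ceil(length_px * oversample)) + 1, 8)
    rows = np.linspace(r0, r1, n)
    cols = np.linspace(c0, c1, n)
    vals = map_coordinates(np.asarray(t1_map, dtype=float), [rows, cols], order=1)
    if np.any(~np.isfinite(vals)):
        raise ValueError("profile crosses background/NaN pixels")
    positions = np.linspace(0.0, length_px * pixel_mm, n)

    n_end = max(int(round(plateau_frac * n)), 2)
    plateau = float(np.median(np.concatenate([vals[:n_end], vals[-n_end:]])))
    i_ext = int(np.argmax(np.abs(vals - plateau)))
    extremum = float(vals[i_ext])
    if extremum == plateau:
        raise ValueError("no dip or peak found on the profile")
    half = 0.5 * (plateau + extremum)

    def toward_plateau(v):
        # signed distance from the extremum side of the half level
        return (v - half) * np.sign(plateau - extremum)

    left = None
    for i in range(i_ext, 0, -1):
        if toward_plateau(vals[i - 1]) >= 0 > toward_plateau(vals[i]):
            left = _crossing(positions[i - 1], vals[i - 1], positions[i], vals[i], half)
            break
    right = None
    for i in range(i_ext, n - 1):
        if toward_plateau(vals[i + 1]) >= 0 > toward_plateau(vals[i]):
            right = _crossing(positions[i], vals[i], positions[i + 1], vals[i + 1], half)
            break
    if left is None or right is None:
        raise ValueError("profile does not cross the half level on both sides")
    return float(right - left)


def ecv(
    native_t1_myo: float,
    post_t1_myo: float,
    native_t1_blood: float,
    post_t1_blood: float,
    hct: float,
) -> float:
    """Extracellular volume fraction from native/post-contrast T1 and hematocrit."""
    for v in (native_t1_myo, post_t1_myo, native_t1_blood, post_t1_blood):
        if v <= 0:
            raise ValueError("T1 values must be > 0")
    if not (0.0 < hct < 1.0):
        raise ValueError("hematocrit must lie in (0, 1)")
    dr1_blood = 1.0 / post_t1_blood - 1.0 / native_t1_blood
    if dr1_blood <= 0:
        raise ValueError("blood delta-R1 must be positive (post-contrast T1 < native)")
    dr1_myo = 1.0 / post_t1_myo - 1.0 / native_t1_myo
    return float((1.0 - hct) * dr1_myo / dr1_blood)


def segment_sectors(
    mask: np.ndarray,
    lv_center: tuple[float, float],
    rv_insertion_angle: float = 0.0,
    n_sectors: int = 6,
) -> np.ndarray:
    """Equal-span angular sectors of a myocardial mask (labels 1..n_sectors).

    Angles are measured counterclockwise (mathematical convention, image rows
    increase downward) starting at the anterior RV insertion angle.  Six
    sectors for basal/mid slices, four for apical.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty myocardial mask")
    if n_sectors not in (4, 6):
        raise ValueError("n_sectors must be 4 or 6")
    rows, cols = np.nonzero(mask)
    theta = np.arctan2(-(rows - lv_center[0]), cols - lv_center[1])
    rel = np.mod(theta - rv_insertion_angle, 2 * np.pi)
    sector = np.minimum((rel / (2 * np.pi / n_sectors)).astype(int), n_sectors - 1) + 1
    labels = np.zeros(mask.shape, dtype=np.int16)
    labels[rows, cols] = sector
    return labels


def region_report(
    t1_map: np.ndarray,
    label_map: np.ndarray,
    region_ids: Sequence[int] | None = None,
    extras: dict | None = None,
) -> list[RegionReport]:
    """Mean, intra-region SD and CoV of a T1 map per labeled region."""
    t1_map = np.asarray(t1_map, dtype=float)
    label_map = np.asarray(label_map)
    if region_ids is None:
        region_ids = [int(l) for l in np.unique(label_map) if l != 0]
    reports = []
    for rid in region_ids:
        sel = (label_map == rid) & np.isfinite(t1_map)
        if not sel.any():
            raise ValueError(f"region {rid} is empty")
        vals = t1_map[sel]
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        reports.append(
            RegionReport(
                region_id=rid,
                n_pixels=int(sel.sum()),
                mean_t1=mean,
                precision=sd,
                cov=sd / mean if mean != 0 else math.nan,
                extras=dict(extras or {}),
            )
        )
    return reports
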
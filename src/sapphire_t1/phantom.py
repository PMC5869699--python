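"""Numerical phantoms: mid-ventricular short-axis heart and static vial grid.

The cardiac phantom is a 650 x 650 pixel short-axis section with three
compartments — LV myocardium, LV + RV blood and an epicardial fat rim —
with T1 = 1578 / 2048 / 382 ms respectively.  The systolic geometry scales
the LV cavity diameter to 70% and the wall thickness to 140% of their
diastolic values about the LV center.  The default radii (cavity 130 px,
wall 30 px at 650 px grid) are chosen so that both phases quantize exactly
onto the pixel grid; all radii scale linearly with the grid size.

Series synthesis assigns each pixel the closed-form signal of its
compartment for the frame's realized (TS, TI), uses the systolic geometry
for frames labeled systole (mis-triggered frames), embeds the signed
magnetization in the real axis of a complex image (times any background
phase), and adds i.i.d. complex Gaussian noise whose per-channel SD is the
unprepared myocardial signal divided by the configured SNR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .cardiac_timing import (
    FrameTiming,
    apply_mistrigger,
    generate_rr_series,
    schedule_diastolic,
    schedule_systolic,
)
from .signal_model import TissueParams, mz_saturation, mz_sapphire

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomSeries",
    "DEFAULT_COMPARTMENTS",
    "CARDIAC_LABELS",
    "build_cardiac_phantom",
    "build_vial_phantom",
    "default_vial_t1s",
    "synthesize_series",
    "simulate_experiment",
    "condition_seed",
]

#: compartment T1/M0 defaults of the numerical heart phantom (T1 in ms)
DEFAULT_COMPARTMENTS = {
    "myocardium": TissueParams(t1=1578.0, m0=1.0),
    "blood": TissueParams(t1=2048.0, m0=1.0),
    "fat": TissueParams(t1=382.0, m0=1.0),
}

CARDIAC_LABELS = {"background": 0, "myocardium": 1, "blood": 2, "fat": 3}

_REFERENCE_GRID = 650  # grid at which the default radii are defined


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue assignment of the cardiac phantom.

    Lengths are in pixels at grid size ``grid``; defaults scale linearly from
    the 650-pixel reference (cavity radius 130, wall 30, fat rim 8, RV disc
    radius 130 offset 110 px toward the septum).
    """

    grid: int = 650
    pixel_mm: float = 1.0
    lv_center: tuple[float, float] | None = None  # (row, col)
    rv_center: tuple[float, float] | None = None
    lv_outer_radius: float | None = None  # epicardial radius (diastole)
    wall_thickness: float | None = None
    fat_rim_thickness: float | None = None
    rv_radius: float | None = None
    compartments: dict = field(default_factory=lambda: dict(DEFAULT_COMPARTMENTS))
    systolic_scale: tuple[float, float] = (0.70, 1.40)

    def resolved(self) -> "PhantomSpec":
        """Fill unset geometry fields with grid-scaled defaults and validate."""
        s = self.grid / _REFERENCE_GRID
        cy = cx = (self.grid - 1) / 2.0
        lv_center = self.lv_center or (cy, cx)
        lv_outer = self.lv_outer_radius if self.lv_outer_radius is not None else 160.0 * s
        wall = self.wall_thickness if self.wall_thickness is not None else 30.0 * s
        fat = self.fat_rim_thickness if self.fat_rim_thickness is not None else 8.0 * s
        rv_r = self.rv_radius if self.rv_radius is not None else 130.0 * s
        rv_center = self.rv_center or (lv_center[0], lv_center[1] - 110.0 * s)
        spec = PhantomSpec(
            grid=self.grid,
            pixel_mm=self.pixel_mm,
            lv_center=lv_center,
            rv_center=rv_center,
            lv_outer_radius=lv_outer,
            wall_thickness=wall,
            fat_rim_thickness=fat,
            rv_radius=rv_r,
            compartments=self.compartments,
            systolic_scale=self.systolic_scale,
        )
        if not wall < lv_outer:
            raise ValueError("wall_thickness must be smaller than lv_outer_radius")
        if min(self.systolic_scale) <= 0:
            raise ValueError("systolic scale factors must be > 0")
        if lv_center[1] + lv_outer + fat >= self.grid or lv_center[1] - lv_outer - fat < 0:
            raise ValueError("LV geometry overflows the grid")
        if rv_center[1] - rv_r < -1:
            raise ValueError("RV geometry overflows the grid")
        return spec


@dataclass
class PhantomTruth:
    """Ground-truth maps of one phantom geometry (one cardiac phase)."""

    label_map: np.ndarray
    t1_map: np.ndarray
    m0_map: np.ndarray
    phase0_map: np.ndarray
    names: dict
    pixel_mm: float = 1.0


@dataclass
class PhantomSeries:
    """A synthesized stack of complex base-images with per-frame timing."""

    frames: np.ndarray  # complex, shape (n_frames, ny, nx)
    timings: list
    truth_t1_map: np.ndarray | None = None
    truth_m0_map: np.ndarray | None = None
    label_map: np.ndarray | None = None
    snr: float = math.inf
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.timings):
            raise ValueError("number of frames and timing entries differ")


def _disc_mask(grid: int, center: tuple[float, float], radius: float) -> np.ndarray:
    rows, cols = np.ogrid[:grid, :grid]
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2


def _truth_from_labels(
    label_map: np.ndarray,
    assignment: dict[str, int],
    compartments: dict[str, TissueParams],
    pixel_mm: float,
) -> PhantomTruth:
    t1 = np.zeros(label_map.shape, dtype=float)
    m0 = np.zeros(label_map.shape, dtype=float)
    ph = np.zeros(label_map.shape, dtype=float)
    for name, lbl in assignment.items():
        if name == "background":
            continue
        tp = compartments[name]
        sel = label_map == lbl
        t1[sel] = tp.t1
        m0[sel] = tp.m0
        ph[sel] = tp.phase0
    return PhantomTruth(label_map, t1, m0, ph, dict(assignment), pixel_mm)


def build_cardiac_phantom(spec: PhantomSpec | None = None, phase: str = "diastole") -> PhantomTruth:
    """Label + truth maps of the short-axis cardiac phantom for one phase.

    Diastole: LV blood disc of radius ``lv_outer_radius - wall_thickness``,
    myocardial annulus out to ``lv_outer_radius``, RV blood crescent (RV disc
    minus the LV epicardium) abutting the septum, thin epicardial fat rim
    elsewhere.  Systole scales the cavity diameter by ``systolic_scale[0]``
    and the wall thickness by ``systolic_scale[1]`` about the LV center.
    """
    spec = (spec or PhantomSpec()).resolved()
    if phase not in ("diastole", "systole"):
        raise ValueError(f"unknown phase {phase!r}")
    r_cav = spec.lv_outer_radius - spec.wall_thickness
    wall = spec.wall_thickness
    if phase == "systole":
        r_cav *= spec.systolic_scale[0]
        wall *= spec.systolic_scale[1]
    r_epi = r_cav + wall

    grid = spec.grid
    label = np.zeros((grid, grid), dtype=np.int16)
    lv_cavity = _disc_mask(grid, spec.lv_center, r_cav)
    lv_epi = _disc_mask(grid, spec.lv_center, r_epi)
    rv_disc = _disc_mask(grid, spec.rv_center, spec.rv_radius)
    fat_ring = _disc_mask(grid, spec.lv_center, r_epi + spec.fat_rim_thickness) & ~lv_epi

    label[lv_epi & ~lv_cavity] = CARDIAC_LABELS["myocardium"]
    label[lv_cavity] = CARDIAC_LABELS["blood"]
    rv_blood = rv_disc & ~lv_epi
    label[rv_blood] = CARDIAC_LABELS["blood"]
    label[fat_ring & ~rv_blood] = CARDIAC_LABELS["fat"]
    return _truth_from_labels(label, CARDIAC_LABELS, spec.compartments, spec.pixel_mm)


def default_vial_t1s(n: int = 7, lo: float = 200.0, hi: float = 2000.0) -> np.ndarray:
    """Log-spaced vial T1 grid (ms) spanning the native/post-contrast range."""
    return np.geomspace(lo, hi, n)


def build_vial_phantom(
    t1_list: Sequence[float] | None = None,
    grid: int = 192,
    vial_radius: float | None = None,
    ring_radius: float | None = None,
    m0: float = 1.0,
    pixel_mm: float = 1.0,
) -> PhantomTruth:
    """Static vial phantom: disjoint circular ROIs, one per T1 (labels 1..n).

    Default layout: one central vial plus the rest on a ring; raises if the
    requested vials overlap or leave the grid.
    """
    t1_list = np.asarray(default_vial_t1s() if t1_list is None else t1_list, dtype=float)
    n = len(t1_list)
    if n < 1:
        raise ValueError("need at least one vial")
    if np.any(t1_list <= 0):
        raise ValueError("vial T1s must be > 0")
    c = (grid - 1) / 2.0
    vial_radius = vial_radius if vial_radius is not None else 0.11 * grid
    ring_radius = ring_radius if ring_radius is not None else 0.33 * grid

    centers = [(c, c)]
    for k in range(n - 1):
        ang = 2 * math.pi * k / max(n - 1, 1)
        centers.append((c + ring_radius * math.sin(ang), c + ring_radius * math.cos(ang)))
    centers = centers[:n]

    for i in range(n):
        for j in range(i + 1, n):
            d = math.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
            if d <= 2 * vial_radius:
                raise ValueError("vials overlap; reduce vial_radius or count")
        if (
            centers[i][0] - vial_radius < 0
            or centers[i][0] + vial_radius >= grid
            or centers[i][1] - vial_radius < 0
            or centers[i][1] + vial_radius >= grid
        ):
            raise ValueError("vial leaves the grid")

    label = np.zeros((grid, grid), dtype=np.int16)
    compartments = {}
    names = {"background": 0}
    for i, (ctr, t1) in enumerate(zip(centers, t1_list), start=1):
        label[_disc_mask(grid, ctr, vial_radius)] = i
        name = f"vial{i}"
        compartments[name] = TissueParams(t1=float(t1), m0=m0)
        names[name] = i
    return _truth_from_labels(label, names, compartments, pixel_mm)


def _frame_signal(truth: PhantomTruth, fr: FrameTiming) -> np.ndarray:
    """Signed per-pixel magnetization of one frame (vectorized closed forms)."""
    t1 = truth.t1_map
    m0 = truth.m0_map
    fg = t1 > 0
    out = np.zeros(t1.shape, dtype=float)
    if fr.prep == "none":
        out[fg] = m0[fg]
    elif fr.prep == "sat":
        out[fg] = mz_saturation(t1[fg], fr.ts, m0[fg])
    elif fr.prep == "sat_inv":
        out[fg] = mz_sapphire(t1[fg], fr.ts, fr.ti, m0[fg])
    else:  # pragma: no cover - FrameTiming validates prep
        raise ValueError(fr.prep)
    return out


def synthesize_series(
    truth: PhantomTruth,
    timings: Sequence[FrameTiming],
    snr: float = math.inf,
    phase_map: np.ndarray | None = None,
    seed: int | None = None,
    truth_systole: PhantomTruth | None = None,
    ref_m0: float | None = None,
) -> PhantomSeries:
    """Complex base-image series from truth maps and a timing schedule.

    Frames labeled ``systole`` use ``truth_systole`` (required if any such
    frame exists).  The per-channel noise SD is ``ref_m0 / snr`` where
    ``ref_m0`` defaults to the unprepared myocardial signal (myocardium M0)
    when a myocardium compartment exists, else the median non-zero M0.
    """
    timings = list(timings)
    if any(fr.phase_label == "systole" for fr in timings) and truth_systole is None:
        if truth.names.get("myocardium") is not None and "vial1" not in truth.names:
            raise ValueError("systolic frames present but no systolic truth maps given")
        truth_systole = truth  # static phantom: both phases identical
    if not (snr > 0):
        raise ValueError("snr must be > 0 (use inf for noiseless)")

    if ref_m0 is None:
        if "myocardium" in truth.names:
            myo = truth.label_map == truth.names["myocardium"]
            ref_m0 = float(np.median(truth.m0_map[myo]))
        else:
            nz = truth.m0_map[truth.m0_map > 0]
            ref_m0 = float(np.median(nz)) if nz.size else 1.0

    shape = truth.t1_map.shape
    if phase_map is None:
        phase_map = np.zeros(shape, dtype=float)
    rng = np.random.default_rng(seed)
    noise_sd = 0.0 if math.isinf(snr) else ref_m0 / snr

    frames = np.empty((len(timings),) + shape, dtype=complex)
    for i, fr in enumerate(timings):
        tr = truth_systole if fr.phase_label == "systole" and truth_systole is not None else truth
        mz = _frame_signal(tr, fr)
        img = mz * np.exp(1j * (tr.phase0_map + phase_map))
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, shape) + 1j * rng.normal(0.0, noise_sd, shape)
        frames[i] = img
    return PhantomSeries(
        frames=frames,
        timings=timings,
        truth_t1_map=truth.t1_map,
        truth_m0_map=truth.m0_map,
        label_map=truth.label_map,
        snr=snr,
        seed=seed,
    )


def condition_seed(base_seed: int, condition_index: int, rep: int) -> int:
    """Stable per-(condition, repetition) seed derived from the base seed."""
    ss = np.random.SeedSequence([int(base_seed), int(condition_index), int(rep)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SimRecord:
    """One simulated repetition of one condition."""

    condition_index: int
    condition_sd_ms: float
    rep: int
    seed: int
    series: PhantomSeries


def simulate_experiment(cfg) -> Iterator[SimRecord]:
    """Yield one :class:`PhantomSeries` per (condition, repetition) of a run config.

    ``cfg`` is a :class:`sapphire_t1.config.RunConfig` (duck-typed).  Each
    repetition ``r`` of condition ``c`` uses a seed derived deterministically
    from ``(base_seed, c, r)``.  Series are yielded lazily; at the 650-pixel
    reference scale one series is ~65 MB, so callers should write or reduce
    each record before drawing the next.
    """
    sds = cfg.condition_sds_ms()
    if cfg.phantom.kind == "cardiac":
        spec = cfg.phantom.to_spec()
        truth_dia = build_cardiac_phantom(spec, "diastole")
        truth_sys = build_cardiac_phantom(spec, "systole")
    else:
        truth_dia = build_vial_phantom(
            t1_list=cfg.phantom.vial_t1_ms, grid=cfg.phantom.grid, pixel_mm=cfg.phantom.pixel_mm
        )
        truth_sys = truth_dia  # vials do not move

    snr = cfg.noise.snr if cfg.noise.snr is not None else math.inf
    for ci, sd in enumerate(sds):
        for r in range(cfg.repetitions):
            seed = condition_seed(cfg.base_seed, ci, r)
            rr = generate_rr_series(
                cfg.rr.mean_ms, sd, cfg.schedule.n_frames + 1, seed=seed, floor=cfg.rr.floor_ms
            )
            if cfg.schedule.variant == "diastolic":
                timings = schedule_diastolic(rr, cfg.schedule.td_ms, cfg.schedule.ti_list)
                if cfg.mistrigger.mode != "none":
                    timings = apply_mistrigger(
                        timings, rr, cfg.schedule.td_ms, mode=cfg.mistrigger.mode, seed=seed + 1
                    )
            else:
                timings = schedule_systolic(
                    rr,
                    td_sys=cfg.schedule.td_ms,
                    n_frames=cfg.schedule.n_frames,
                    n_sat=cfg.schedule.n_sat,
                    n_inv=cfg.schedule.n_inv,
                    ti_spread=tuple(cfg.schedule.ti_spread),
                )
            series = synthesize_series(
                truth_dia, timings, snr=snr, seed=seed, truth_systole=truth_sys
            )
            yield SimRecord(ci, float(sd), r, seed, series)
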
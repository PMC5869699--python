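"""Pixel-wise and ROI-wise T1 estimation.

The estimator is a 3-parameter nonlinear least-squares fit of
(M0, T1, inversion efficiency) to the signed recovery signal, with the
per-frame model selected by the frame's preparation type:

    none:     s = M0
    sat:      s = M0 * (1 - exp(-TS/T1))
    sat_inv:  s = M0 * (1 - (1 + eta) exp(-TI/T1) + eta exp(-TS/T1))

Because the model is linear in (M0, M0*eta) at fixed T1, initialization uses
a variable-projection scan over a log-spaced T1 grid (closed-form linear
solve per node) before the bounded trust-region refinement with an analytic
Jacobian.  Magnitude data lose the sign of the magnetization; two polarity
strategies restore it:

* magnitude restoration — sort the inversion-prepared points by TI and flip
  the first k for every k, keeping the candidate with the smallest SSR
  (fewest flips on ties); appropriate when TS is fixed (diastolic variant);
* phase-sensitive mapping — subtract the phase of the unprepared reference
  image, unwrap the 2-D phase difference, and assign negative polarity where
  |dphi| > pi/2; required in systole where TS varies between frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from skimage.restoration import unwrap_phase

from .cardiac_timing import FrameTiming

__all__ = [
    "FitResult",
    "T1MapResult",
    "fit_three_param",
    "restore_polarity_magnitude",
    "polarity_from_phase",
    "fit_t1_map",
    "fit_region",
]

#: default parameter bounds: T1 (ms), inversion efficiency
T1_BOUNDS = (1.0, 5000.0)
INV_EFF_BOUNDS = (0.0, 1.0)
#: background threshold: fraction of the unprepared frame's 99th percentile
BACKGROUND_FRACTION = 0.05

_T1_INIT_GRID = np.geomspace(50.0, 4000.0, 12)


@dataclass(frozen=True)
class FitResult:
    """Result of one 3-parameter recovery-curve fit."""

    t1: float
    m0: float
    inv_eff: float
    ssr: float
    converged: bool
    n_flips: int = 0  # magnitude polarity restoration only


@dataclass
class T1MapResult:
    """Fitted parameter maps plus polarity and diagnostics.

    ``polarity_map`` holds the per-frame, per-pixel sign (+1/-1) applied to
    the magnitudes before fitting; background pixels are NaN in the parameter
    maps and excluded from ``converged_mask``.
    """

    t1_map: np.ndarray
    m0_map: np.ndarray
    inv_eff_map: np.ndarray
    residual_map: np.ndarray
    polarity_map: np.ndarray
    converged_mask: np.ndarray
    method: str
    mask: np.ndarray | None = None


def _frame_arrays(timings: Sequence[FrameTiming]):
    prep = np.array(
        [{"none": 0, "sat": 1, "sat_inv": 2}[fr.prep] for fr in timings], dtype=int
    )
    ts = np.array([fr.ts for fr in timings], dtype=float)
    ti = np.array([fr.ti if fr.ti is not None else 0.0 for fr in timings], dtype=float)
    return prep, ts, ti


def _basis(t1: float, prep, ts, ti):
    """Per-frame basis (g, h) with model s = m0*g + (m0*eta)*h at fixed T1."""
    with np.errstate(over="ignore"):
        e_ts = np.where(np.isfinite(ts), np.exp(-ts / t1), 0.0)
        e_ti = np.exp(-ti / t1)
    g = np.where(prep == 0, 1.0, np.where(prep == 1, 1.0 - e_ts, 1.0 - e_ti))
    h = np.where(prep == 2, e_ts - e_ti, 0.0)
    return g, h, e_ts, e_ti


def _model(params, prep, ts, ti):
    m0, t1, eta = params[0], params[1], params[2]
    g, h, _, _ = _basis(t1, prep, ts, ti)
    return m0 * g + m0 * eta * h


def _jacobian(params, prep, ts, ti):
    m0, t1, eta = params[0], params[1], params[2]
    g, h, e_ts, e_ti = _basis(t1, prep, ts, ti)
    # d e_ts / d t1 = e_ts * ts / t1^2 (0 for unprepared frames where ts=inf)
    ts_finite = np.where(np.isfinite(ts), ts, 0.0)
    dts = e_ts * ts_finite / t1**2
    dti = e_ti * ti / t1**2
    dg = np.where(prep == 0, 0.0, np.where(prep == 1, -dts, -dti))
    dh = np.where(prep == 2, dts - dti, 0.0)
    jac = np.empty((len(g), 3))
    jac[:, 0] = g + eta * h
    jac[:, 1] = m0 * (dg + eta * dh)
    jac[:, 2] = m0 * h
    return jac


def _varpro_init(signals, prep, ts, ti, m0_hi):
    """Best (m0, t1, eta) over the T1 grid by linear solve at each node."""
    best = None
    for t1 in _T1_INIT_GRID:
        g, h, _, _ = _basis(t1, prep, ts, ti)
        # 2x2 normal equations for s = a*g + b*h
        gg, gh, hh = float(g @ g), float(g @ h), float(h @ h)
        gs, hs = float(g @ signals), float(h @ signals)
        det = gg * hh - gh * gh
        if det > 1e-12 * max(gg * hh, 1e-30):
            a = (gs * hh - hs * gh) / det
            b = (gg * hs - gh * gs) / det
        else:  # no (or degenerate) inversion frames: eta unidentifiable
            a = gs / gg if gg > 0 else 1e-12
            b = a
        a_cl = min(max(a, 1e-12), m0_hi)
        eta = min(max(b / a_cl, 0.0), 1.0)
        if abs(b - a_cl * eta) > 1e-12 * (abs(b) + 1e-30):
            # constraint active: re-solve the amplitude at fixed eta
            f = g + eta * h
            denom = float(f @ f)
            if denom > 0:
                a_cl = min(max(float(f @ signals) / denom, 1e-12), m0_hi)
        r = signals - (a_cl * g + a_cl * eta * h)
        ssr = float(r @ r)
        if best is None or ssr < best[0]:
            best = (ssr, a_cl, t1, eta)
    return best[1], best[2], best[3]


def fit_three_param(
    signals,
    timings: Sequence[FrameTiming],
    init: tuple[float, float, float] | None = None,
    bounds: tuple | None = None,
) -> FitResult:
    """Fit (M0, T1, inversion efficiency) to signed recovery signals.

    ``signals`` are polarity-restored (signed) amplitudes, one per frame.
    Requires at least 4 frames (3 parameters + 1 dof).  Non-convergence is
    reported through ``converged``, never raised.
    """
    signals = np.asarray(signals, dtype=float)
    timings = list(timings)
    if len(signals) != len(timings):
        raise ValueError("signals and timings differ in length")
    if len(signals) < 4:
        raise ValueError("need at least 4 frames for a 3-parameter fit")
    prep, ts, ti = _frame_arrays(timings)

    m0_hi = 10.0 * max(float(np.max(np.abs(signals))), 1e-9)
    if bounds is None:
        lo = np.array([0.0, T1_BOUNDS[0], INV_EFF_BOUNDS[0]])
        hi = np.array([m0_hi, T1_BOUNDS[1], INV_EFF_BOUNDS[1]])
    else:
        lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)

    if init is None:
        a, t1_0, eta_0 = _varpro_init(signals, prep, ts, ti, m0_hi)
        x0 = np.array([a, t1_0, eta_0])
    else:
        x0 = np.array([init[0], init[1], init[2]], dtype=float)
    x0 = np.minimum(np.maximum(x0, lo + 1e-12), hi - 1e-12)

    try:
        res = least_squares(
            lambda x: _model(x, prep, ts, ti) - signals,
            x0,
            jac=lambda x: _jacobian(x, prep, ts, ti),
            bounds=(lo, hi),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=400,
        )
        m0, t1, eta = res.x
        ssr = float(2.0 * res.cost)
        converged = bool(res.status > 0)
    except Exception:
        m0, t1, eta = x0
        r = _model(x0, prep, ts, ti) - signals
        ssr = float(r @ r)
        converged = False
    return FitResult(float(t1), float(m0), float(eta), ssr, converged)


def restore_polarity_magnitude(
    magnitudes, timings: Sequence[FrameTiming]
) -> tuple[np.ndarray, FitResult]:
    """Sign restoration for magnitude data by successive polarity flipping.

    The inversion-prepared points are sorted by TI; for every k the first k of
    them are negated and refitted, and the candidate with the smallest SSR
    wins (ties favor fewer flips).  Returns the signed signals and the best
    fit.
    """
    magnitudes = np.asarray(magnitudes, dtype=float)
    if np.any(magnitudes < 0):
        raise ValueError("magnitude input must be non-negative")
    timings = list(timings)
    inv_idx = [i for i, fr in enumerate(timings) if fr.prep == "sat_inv"]
    inv_idx.sort(key=lambda i: timings[i].ti)

    best_signed = magnitudes.copy()
    best_fit = None
    best_k = 0
    for k in range(len(inv_idx) + 1):
        signed = magnitudes.copy()
        signed[inv_idx[:k]] *= -1.0
        fit = fit_three_param(signed, timings)
        if best_fit is None or fit.ssr < best_fit.ssr - 1e-15:
            best_fit, best_signed, best_k = fit, signed, k
    best_fit = FitResult(
        best_fit.t1, best_fit.m0, best_fit.inv_eff, best_fit.ssr, best_fit.converged, best_k
    )
    return best_signed, best_fit


def _wrap_to_pi(phi):
    return np.angle(np.exp(1j * phi))


def polarity_from_phase(
    frames: np.ndarray,
    reference_index: int,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame, per-pixel polarity from phase differences to the reference.

    ``frames`` is a complex stack (n_frames, ny, nx) — or (n_frames, n) for
    ROI-level vectors, in which case no spatial unwrapping is applied.  The
    phase of the unprepared reference frame is subtracted, the difference is
    spatially unwrapped, a global 2*pi offset (median over the foreground) is
    removed, and pixels with |dphi| > pi/2 get polarity -1, others +1.
    """
    frames = np.asarray(frames)
    if not np.iscomplexobj(frames):
        raise ValueError("phase-sensitive polarity requires complex data")
    ref = frames[reference_index]
    pol = np.ones(frames.shape, dtype=np.int8)
    spatial = frames.ndim == 3
    for i in range(len(frames)):
        if i == reference_index:
            continue
        dphi = np.angle(frames[i] * np.conj(ref))
        if spatial:
            dphi = np.asarray(unwrap_phase(dphi), dtype=float)
            sel = mask if mask is not None else np.ones(dphi.shape, bool)
            anchor = 2 * np.pi * np.round(np.median(dphi[sel]) / (2 * np.pi))
            dphi = dphi - anchor
            # unwrap offsets are global multiples of 2*pi; fold any residual
            # local multiple back before the sign decision
            dphi = _wrap_to_pi(dphi)
        pol[i] = np.where(np.abs(dphi) > np.pi / 2, -1, 1)
    return pol


def _unprepared_index(timings: Sequence[FrameTiming]) -> int:
    for i, fr in enumerate(timings):
        if fr.prep == "none":
            return i
    raise ValueError("schedule contains no unprepared reference frame")


def _background_mask(ref_magnitude: np.ndarray) -> np.ndarray:
    thr = BACKGROUND_FRACTION * np.percentile(ref_magnitude, 99)
    return ref_magnitude >= thr


def _fit_stack(signed: np.ndarray, timings) -> np.ndarray:
    """Fit every column of a (n_frames, n_pix) signed-signal matrix.

    Identical columns (exact float match, e.g. noiseless compartments) are
    fitted once and broadcast.
    """
    uniq, inverse = np.unique(signed.T, axis=0, return_inverse=True)
    results = np.empty((len(uniq), 5))
    for j, sig in enumerate(uniq):
        fit = fit_three_param(sig, timings)
        results[j] = (fit.t1, fit.m0, fit.inv_eff, fit.ssr, float(fit.converged))
    return results[inverse]


def fit_t1_map(series, method: str = "phase_sensitive", mask: np.ndarray | None = None) -> T1MapResult:
    """Pixel-wise T1 map from a series with timing metadata.

    ``series`` is a :class:`sapphire_t1.phantom.PhantomSeries` or any object
    with ``frames`` (n_frames, ny, nx) and ``timings``.  Background pixels
    (unprepared-frame magnitude below 5% of its 99th percentile) are masked
    out.  ``method='magnitude'`` uses flip-and-refit polarity restoration;
    ``method='phase_sensitive'`` uses the phase-difference polarity map and
    requires complex input.
    """
    frames = np.asarray(series.frames)
    timings = list(series.timings)
    if len(frames) != len(timings):
        raise ValueError("frames and timing entries differ in count")
    if method not in ("magnitude", "phase_sensitive"):
        raise ValueError(f"unknown method {method!r}")
    ref_idx = _unprepared_index(timings)
    mag = np.abs(frames)
    fg = _background_mask(mag[ref_idx])
    if mask is not None:
        fg = fg & mask

    shape = frames.shape[1:]
    nan_map = np.full(shape, np.nan)
    out = T1MapResult(
        t1_map=nan_map.copy(),
        m0_map=nan_map.copy(),
        inv_eff_map=nan_map.copy(),
        residual_map=nan_map.copy(),
        polarity_map=np.ones(frames.shape, dtype=np.int8),
        converged_mask=np.zeros(shape, dtype=bool),
        method=method,
        mask=fg,
    )
    npx = int(fg.sum())
    if npx == 0:
        return out

    if method == "phase_sensitive":
        pol = polarity_from_phase(frames, ref_idx, mask=fg)
        out.polarity_map = pol
        signed = (pol * mag)[:, fg]
        res = _fit_stack(signed, timings)
    else:
        cols = mag[:, fg]
        res = np.empty((npx, 5))
        pol_cols = np.ones((len(frames), npx), dtype=np.int8)
        # dedup identical magnitude columns (noiseless compartments)
        uniq, inverse = np.unique(cols.T, axis=0, return_inverse=True)
        ures = np.empty((len(uniq), 5))
        upol = np.ones((len(uniq), len(frames)), dtype=np.int8)
        for j, sig in enumerate(uniq):
            signed, fit = restore_polarity_magnitude(sig, timings)
            ures[j] = (fit.t1, fit.m0, fit.inv_eff, fit.ssr, float(fit.converged))
            upol[j] = np.where(np.abs(sig) > 0, np.sign(signed + (sig == 0)), 1).astype(np.int8)
        res = ures[inverse]
        pol_cols = upol[inverse].T
        out.polarity_map[:, fg] = pol_cols

    out.t1_map[fg] = res[:, 0]
    out.m0_map[fg] = res[:, 1]
    out.inv_eff_map[fg] = res[:, 2]
    out.residual_map[fg] = res[:, 3]
    out.converged_mask[fg] = res[:, 4] > 0
    return out


def fit_region(series, region_mask: np.ndarray, method: str = "phase_sensitive") -> FitResult:
    """ROI-level fit: average the complex (or magnitude) signal over a region,
    restore polarity, and fit the mean recovery curve."""
    frames = np.asarray(series.frames)
    timings = list(series.timings)
    if region_mask.dtype != bool:
        region_mask = region_mask.astype(bool)
    sig = frames[:, region_mask].mean(axis=1)
    if method == "phase_sensitive":
        if not np.iscomplexobj(frames):
            raise ValueError("phase-sensitive fitting requires complex data")
        ref_idx = _unprepared_index(timings)
        pol = polarity_from_phase(sig[:, None], ref_idx)[:, 0]
        signed = pol * np.abs(sig)
        return fit_three_param(signed, timings)
    if method == "magnitude":
        _, fit = restore_polarity_magnitude(np.abs(sig), timings)
        return fit
    raise ValueError(f"unknown method {method!r}")
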
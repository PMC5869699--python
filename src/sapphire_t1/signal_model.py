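"""Longitudinal-magnetization signal models for saturation/inversion-prepared imaging.

The hybrid saturation + inversion preparation (SAPPHIRE) resets the
longitudinal magnetization with a saturation pulse at time TS before the
readout, applies an inversion pulse at time TI before the readout
(0 <= TI <= TS), and lets the magnetization relax mono-exponentially with
time constant T1 in between.  At the readout

    Mz(TS, TI) = M0 * [1 - (1 + eta) * exp(-TI/T1) + eta * exp(-TS/T1)]

where ``eta`` is the inversion completeness (1 = perfect inversion).  With
TI = TS, or eta = 0, this reduces to plain saturation recovery
``M0 * (1 - exp(-TS/T1))``; with TS -> infinity and eta = 1 it reduces to
ideal inversion recovery ``M0 * (1 - 2 exp(-TI/T1))``.

All closed forms are cross-checked against :func:`bloch_piecewise`, an
event-by-event propagation of Mz that serves as the brute-force oracle.
Times are in milliseconds, signals in arbitrary units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TissueParams",
    "PrepEvent",
    "saturation_signal",
    "sapphire_signal",
    "bloch_piecewise",
    "signal_series",
    "mz_saturation",
    "mz_sapphire",
]


@dataclass(frozen=True)
class TissueParams:
    """Per-compartment relaxometry parameters.

    Parameters
    ----------
    t1 : float
        Longitudinal relaxation time in ms, strictly positive.
    m0 : float
        Equilibrium signal amplitude (arbitrary units), non-negative.
    phase0 : float
        Intrinsic signal phase in radians, in (-pi, pi].
    """

    t1: float
    m0: float = 1.0
    phase0: float = 0.0

    def __post_init__(self) -> None:
        if not self.t1 > 0:
            raise ValueError(f"t1 must be > 0, got {self.t1}")
        if self.m0 < 0:
            raise ValueError(f"m0 must be >= 0, got {self.m0}")
        if not (-math.pi < self.phase0 <= math.pi):
            raise ValueError(f"phase0 must lie in (-pi, pi], got {self.phase0}")


#: preparation kinds understood by :func:`bloch_piecewise`
_EVENT_KINDS = ("saturation", "inversion", "readout")


@dataclass(frozen=True)
class PrepEvent:
    """One instantaneous preparation or readout event on the sequence timeline.

    ``efficiency`` means the *residual* longitudinal fraction for a
    saturation pulse (0 is ideal) and the inversion *completeness* for an
    inversion pulse (1 is ideal).  ``None`` selects the ideal value for the
    event kind.
    """

    kind: str
    time: float
    efficiency: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.efficiency is not None and not (0.0 <= self.efficiency <= 1.0):
            raise ValueError("efficiency must lie in [0, 1]")

    @property
    def resolved_efficiency(self) -> float:
        if self.efficiency is not None:
            return self.efficiency
        return 0.0 if self.kind == "saturation" else 1.0


# ---------------------------------------------------------------------------
# array-level cores (used pixel-wise by the phantom generator and the fitter)
# ---------------------------------------------------------------------------

def mz_saturation(t1, ts, m0=1.0):
    """Saturation-recovery magnetization ``m0 * (1 - exp(-ts/t1))``, array-aware."""
    t1 = np.asarray(t1, dtype=float)
    return np.asarray(m0, dtype=float) * (1.0 - np.exp(-np.divide(ts, t1)))


def mz_sapphire(t1, ts, ti, m0=1.0, inv_eff=1.0):
    """Saturation + inversion recovery magnetization, array-aware.

    ``m0 * (1 - (1 + inv_eff) exp(-ti/t1) + inv_eff exp(-ts/t1))``.
    """
    t1 = np.asarray(t1, dtype=float)
    e_ts = np.exp(-np.divide(ts, t1))
    e_ti = np.exp(-np.divide(ti, t1))
    return np.asarray(m0, dtype=float) * (
        1.0 - (1.0 + inv_eff) * e_ti + inv_eff * e_ts
    )


# ---------------------------------------------------------------------------
# scalar public operations
# ---------------------------------------------------------------------------

def saturation_signal(tissue: TissueParams, ts: float) -> float:
    """Signal of a saturation-prepared acquisition at saturation delay ``ts``.

    Monotonically increasing in ``ts``; tends to ``m0`` as ``ts -> inf``.
    """
    if ts < 0:
        raise ValueError(f"ts must be >= 0, got {ts}")
    return float(mz_saturation(tissue.t1, ts, tissue.m0))


def sapphire_signal(
    tissue: TissueParams, ts: float, ti: float, inv_eff: float = 1.0
) -> float:
    """Signal of a saturation + inversion prepared acquisition.

    Saturation at ``ts`` and inversion (completeness ``inv_eff``) at ``ti``
    before the readout, with ``0 <= ti <= ts``.
    """
    if ti < 0:
        raise ValueError(f"ti must be >= 0, got {ti}")
    if ti > ts:
        raise ValueError(f"timing order violated: ti={ti} > ts={ts}")
    if not (0.0 <= inv_eff <= 1.0):
        raise ValueError(f"inv_eff must lie in [0, 1], got {inv_eff}")
    return float(mz_sapphire(tissue.t1, ts, ti, tissue.m0, inv_eff))


def bloch_piecewise(tissue: TissueParams, events: Sequence[PrepEvent]) -> float:
    """Propagate Mz through an ordered event list; oracle for the closed forms.

    Starts from equilibrium (``Mz = m0``) at the series origin.  Between
    events Mz relaxes mono-exponentially,
    ``Mz(t + dt) = m0 + (Mz(t) - m0) * exp(-dt/t1)``; a saturation maps
    ``Mz -> eff * Mz`` (eff = 0 ideal) and an inversion maps
    ``Mz -> -eff * Mz`` (eff = 1 ideal).  Returns Mz at the single,
    terminal readout event.
    """
    events = list(events)
    if not events:
        raise ValueError("event list is empty")
    times = [ev.time for ev in events]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("events must be strictly ordered in time")
    n_readout = sum(ev.kind == "readout" for ev in events)
    if n_readout != 1 or events[-1].kind != "readout":
        raise ValueError("exactly one readout must terminate the event list")

    mz = tissue.m0
    t = 0.0
    for ev in events:
        mz = tissue.m0 + (mz - tissue.m0) * math.exp(-(ev.time - t) / tissue.t1)
        t = ev.time
        if ev.kind == "saturation":
            mz = ev.resolved_efficiency * mz
        elif ev.kind == "inversion":
            mz = -ev.resolved_efficiency * mz
        else:  # readout
            return mz
    raise AssertionError("unreachable")


def signal_series(tissue: TissueParams, timings: Iterable) -> np.ndarray:
    """Evaluate the signal of every frame of a timing schedule.

    Dispatches on each frame's preparation type: ``none`` (full recovery,
    signal m0), ``sat`` (saturation recovery at the frame's TS) or
    ``sat_inv`` (hybrid preparation at the frame's TS/TI).  ``timings`` is
    any iterable of objects exposing ``prep``, ``ts`` and ``ti`` attributes
    (see :class:`sapphire_t1.cardiac_timing.FrameTiming`).
    """
    out = []
    for fr in timings:
        if fr.prep == "none":
            out.append(tissue.m0)
        elif fr.prep == "sat":
            out.append(saturation_signal(tissue, fr.ts))
        elif fr.prep == "sat_inv":
            out.append(sapphire_signal(tissue, fr.ts, fr.ti))
        else:
            raise ValueError(f"unknown preparation {fr.prep!r}")
    return np.asarray(out, dtype=float)
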
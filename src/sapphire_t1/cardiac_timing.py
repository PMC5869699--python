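"""ECG-derived timing: RR-interval series, trigger logic and frame schedules.

Two SAPPHIRE schedule variants are modelled.

*Diastolic* (conventional): saturation and inversion are both played in the
same heartbeat as the readout, so every prepared frame has a fixed
saturation delay TS equal to the trigger delay TD; the inversion delay TI
varies per frame.

*Systolic*: the short interval between the R-wave and systolic readout
leaves no room for recovery, so the saturation pulse is played in the
*preceding* heartbeat, directly after the previous readout.  The realized
TS then equals the RR interval between consecutive readouts and varies
beat-by-beat with the heart rate; the fit must therefore consume the
realized per-frame (TS, TI), which this module records exactly.

Arrhythmia is modelled as Gaussian RR-interval variability (clipped below
at a physiological floor).  Mis-triggering — the programmed trigger delay
extending beyond a shortened RR interval so that the readout lands in the
wrong cardiac phase — is applied either by the deterministic threshold rule
(RR < TD) or by relabeling a randomized share of frames.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RRSeries",
    "FrameTiming",
    "DEFAULT_TI_DIASTOLIC_MS",
    "DEFAULT_TD_DIASTOLIC_MS",
    "generate_rr_series",
    "schedule_diastolic",
    "schedule_systolic",
    "apply_mistrigger",
    "mistrigger_share",
    "arrhythmia_factor_to_sd",
    "timings_to_dataframe",
    "timings_from_dataframe",
    "save_timing_sidecar",
    "load_timing_sidecar",
]

#: the 10-frame diastolic TI schedule (ms); the first entry is a full-recovery
#: sentinel, i.e. an unprepared frame
DEFAULT_TI_DIASTOLIC_MS = (10000.0, 805.0, 113.0, 211.0, 309.0, 407.0, 505.0, 603.0, 701.0, 799.0)
DEFAULT_TD_DIASTOLIC_MS = 805.0

#: physiological refractory floor for RR intervals (ms)
DEFAULT_RR_FLOOR_MS = 300.0


@dataclass(frozen=True)
class RRSeries:
    """A realized series of RR intervals (ms) with its generating statistics."""

    mean_rr: float
    sd_rr: float
    values: np.ndarray
    seed: int | None = None
    floor: float = DEFAULT_RR_FLOOR_MS

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values < self.floor - 1e-9):
            raise ValueError("RR values below the configured floor")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FrameTiming:
    """Realized preparation timing of one frame.

    ``prep`` is one of ``none`` (unprepared, full recovery), ``sat``
    (saturation only) or ``sat_inv`` (saturation + inversion).  ``ts`` is the
    saturation-to-readout delay (``inf`` for unprepared frames), ``ti`` the
    inversion-to-readout delay (``None`` unless ``sat_inv``).
    """

    index: int
    prep: str
    ts: float = math.inf
    ti: float | None = None
    phase_label: str = "diastole"
    beat_rr: float | None = None

    def __post_init__(self) -> None:
        if self.prep not in ("none", "sat", "sat_inv"):
            raise ValueError(f"unknown preparation {self.prep!r}")
        if self.prep == "sat_inv":
            if self.ti is None:
                raise ValueError("sat_inv frame requires ti")
            if not (0.0 <= self.ti <= self.ts):
                raise ValueError(
                    f"frame {self.index}: need 0 <= ti <= ts, got ti={self.ti}, ts={self.ts}"
                )
        if self.phase_label not in ("diastole", "systole"):
            raise ValueError(f"unknown phase label {self.phase_label!r}")


def arrhythmia_factor_to_sd(factor: float, mean_rr: float) -> float:
    """Convert an arrhythmia factor (SD as a fraction of mean RR) to an SD in ms."""
    if factor < 0:
        raise ValueError("factor must be >= 0")
    return factor * mean_rr


def generate_rr_series(
    mean_rr: float,
    sd_rr: float,
    n: int,
    seed: int | None = None,
    floor: float = DEFAULT_RR_FLOOR_MS,
) -> RRSeries:
    """Draw ``n`` Gaussian RR intervals (ms), clipped below at ``floor``.

    Deterministic under a fixed seed.
    """
    if mean_rr <= 0:
        raise ValueError("mean_rr must be > 0")
    if sd_rr < 0:
        raise ValueError("sd_rr must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.normal(mean_rr, sd_rr, size=n)
    return RRSeries(mean_rr=mean_rr, sd_rr=sd_rr, values=np.maximum(draws, floor), seed=seed, floor=floor)


def schedule_diastolic(
    rr: RRSeries,
    td: float = DEFAULT_TD_DIASTOLIC_MS,
    ti_list: Sequence[float] | None = None,
) -> list[FrameTiming]:
    """Per-frame timing for the conventional (diastolic) variant.

    Every prepared frame has ``ts = td`` (saturation at the R-wave, readout
    at the trigger delay).  A TI larger than TD is a full-recovery sentinel
    and yields an unprepared frame; TI equal to TD degenerates to a
    saturation-only preparation.
    """
    if ti_list is None:
        ti_list = DEFAULT_TI_DIASTOLIC_MS
    if len(rr) < len(ti_list):
        raise ValueError("RR series shorter than the number of frames")
    frames: list[FrameTiming] = []
    for i, ti in enumerate(ti_list):
        beat_rr = float(rr.values[i])
        if ti > td:  # full recovery sentinel (e.g. 10000 ms)
            frames.append(FrameTiming(i, "none", math.inf, None, "diastole", beat_rr))
        elif ti == td:
            frames.append(FrameTiming(i, "sat", float(td), None, "diastole", beat_rr))
        elif ti < 0:
            raise ValueError(f"negative TI {ti}")
        else:
            frames.append(FrameTiming(i, "sat_inv", float(td), float(ti), "diastole", beat_rr))
    return frames


def schedule_systolic(
    rr: RRSeries,
    td_sys: float = 300.0,
    n_frames: int = 10,
    n_sat: int = 4,
    n_inv: int = 5,
    ti_spread: tuple[float, float] = (100.0, 300.0),
) -> list[FrameTiming]:
    """Per-frame timing for the systolic variant.

    Frame 0 is unprepared; the next ``n_sat`` frames are saturation-only and
    the last ``n_inv`` frames additionally carry an inversion with TIs
    linearly spread over ``ti_spread``.  The saturation of frame ``k`` is
    played directly after readout ``k-1``, so its realized
    ``ts = (R_k + TD) - (R_{k-1} + TD)`` equals the RR interval preceding the
    frame's R-wave and varies with the realized heart rate.  A frame whose
    realized TS falls below its TI is dropped (and the drop logged).
    """
    if 1 + n_sat + n_inv != n_frames:
        raise ValueError("layout must satisfy 1 + n_sat + n_inv == n_frames")
    if ti_spread[1] > td_sys:
        raise ValueError("max TI must not exceed the systolic trigger delay")
    if ti_spread[0] < 0 or ti_spread[0] > ti_spread[1]:
        raise ValueError("invalid ti_spread")
    if len(rr) < n_frames:
        raise ValueError("RR series shorter than the number of frames")

    ti_values = list(np.linspace(ti_spread[0], ti_spread[1], n_inv)) if n_inv else []
    frames: list[FrameTiming] = []
    dropped = 0
    for k in range(n_frames):
        beat_rr = float(rr.values[k])
        if k == 0:
            frames.append(FrameTiming(0, "none", math.inf, None, "systole", beat_rr))
            continue
        ts = beat_rr  # saturation directly after the previous readout
        if k <= n_sat:
            frames.append(FrameTiming(k, "sat", ts, None, "systole", beat_rr))
        else:
            ti = float(ti_values[k - n_sat - 1])
            if ts < ti:
                logging.getLogger(__name__).warning(
                    "dropping frame %d: realized ts=%.1f ms < ti=%.1f ms", k, ts, ti
                )
                dropped += 1
                continue
            frames.append(FrameTiming(k, "sat_inv", ts, ti, "systole", beat_rr))
    return frames


def mistrigger_share(mean_rr: float, sd_rr: float, td: float) -> float:
    """Expected fraction of mis-triggered frames, P(RR < TD).

    With the RR floor below TD, clipping does not change this probability, so
    it equals the Gaussian CDF at ``(td - mean_rr) / sd_rr``.
    """
    if sd_rr == 0:
        return float(td > mean_rr)
    return float(stats.norm.cdf((td - mean_rr) / sd_rr))


def apply_mistrigger(
    timings: Sequence[FrameTiming],
    rr: RRSeries | None = None,
    td: float = DEFAULT_TD_DIASTOLIC_MS,
    mode: str = "threshold",
    seed: int | None = None,
) -> list[FrameTiming]:
    """Relabel diastolic frames whose readout lands in systole.

    ``mode='threshold'``: a frame is relabeled when its beat's RR interval is
    shorter than the trigger delay (the readout overruns the next R-wave).

    ``mode='share'``: the target systolic share is computed from the RR
    statistics (truncated-Gaussian P(RR < TD)) and that many frames, chosen
    uniformly at random (seeded), are relabeled — the randomized-replacement
    protocol of the numerical experiment.
    """
    timings = list(timings)
    if mode == "threshold":
        out = []
        for fr in timings:
            if fr.beat_rr is not None and fr.beat_rr < td:
                out.append(replace(fr, phase_label="systole"))
            else:
                out.append(fr)
        return out
    if mode == "share":
        if rr is None:
            raise ValueError("mode='share' requires the RR series statistics")
        p = mistrigger_share(rr.mean_rr, rr.sd_rr, td)
        n_re = int(round(p * len(timings)))
        rng = np.random.default_rng(seed)
        idx = set(rng.choice(len(timings), size=n_re, replace=False).tolist()) if n_re else set()
        return [
            replace(fr, phase_label="systole") if i in idx else fr
            for i, fr in enumerate(timings)
        ]
    raise ValueError(f"unknown mis-trigger mode {mode!r}")


# ---------------------------------------------------------------------------
# timing sidecar serialization (CSV with a JSON twin)
# ---------------------------------------------------------------------------

_SIDECAR_COLUMNS = ["index", "prep", "ts_ms", "ti_ms", "phase", "rr_ms"]


def timings_to_dataframe(timings: Sequence[FrameTiming]) -> pd.DataFrame:
    rows = [
        {
            "index": fr.index,
            "prep": fr.prep,
            "ts_ms": fr.ts if math.isfinite(fr.ts) else np.nan,
            "ti_ms": fr.ti if fr.ti is not None else np.nan,
            "phase": fr.phase_label,
            "rr_ms": fr.beat_rr if fr.beat_rr is not None else np.nan,
        }
        for fr in timings
    ]
    return pd.DataFrame(rows, columns=_SIDECAR_COLUMNS)


def timings_from_dataframe(df: pd.DataFrame) -> list[FrameTiming]:
    out = []
    for _, row in df.iterrows():
        ts = float(row["ts_ms"]) if pd.notna(row["ts_ms"]) else math.inf
        ti = float(row["ti_ms"]) if pd.notna(row["ti_ms"]) else None
        rr = float(row["rr_ms"]) if pd.notna(row["rr_ms"]) else None
        out.append(
            FrameTiming(int(row["index"]), str(row["prep"]), ts, ti, str(row["phase"]), rr)
        )
    return out


def save_timing_sidecar(timings: Sequence[FrameTiming], csv_path, json_path=None) -> None:
    df = timings_to_dataframe(timings)
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        records = df.where(pd.notna(df), None).to_dict(orient="records")
        with open(json_path, "w") as fh:
            json.dump(records, fh, indent=1)


def load_timing_sidecar(path) -> list[FrameTiming]:
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            df = pd.DataFrame(json.load(fh))
    else:
        df = pd.read_csv(path)
    return timings_from_dataframe(df)
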
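"""Doppler inflow indices: E/A ratio and the myocardial performance index.

Pulsed-wave Doppler of ventricular inflow in adult zebrafish shows two
diastolic lobes per beat: the early passive filling peak (E wave) and the
late atrial-contraction peak (A wave).  Global function is summarised by the
myocardial performance (Tei) index

    MPI = (IVCT + IVRT) / ET,

where IVCT/IVRT are the isovolumic contraction/relaxation times and ET the
ejection time across the ventriculobulbar valve; higher MPI indicates worse
combined systolic and diastolic function.  IVCT, IVRT and ET come from valve
event annotations; an inflow trace alone cannot localise them, so without
annotations the intervals (and MPI) are reported as unavailable rather than
guessed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .exceptions import InvalidParameterError, LobeDetectionError, ZeroDivisionInputError

__all__ = [
    "DopplerWaveform",
    "DopplerIndices",
    "detect_ea_peaks",
    "compute_mpi",
    "intervals_from_events",
    "analyze_doppler",
]

EVENT_COLUMNS = ("av_close", "vb_open", "vb_close", "av_open")


@dataclass
class DopplerWaveform:
    """Inflow-velocity time series with optional valve event annotations.

    ``events``: one row per cycle with columns ``av_close``, ``vb_open``,
    ``vb_close``, ``av_open`` (times in seconds), bounding IVCT, ET and IVRT.
    """

    time: np.ndarray  # s
    velocity: np.ndarray  # mm/s
    events: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.time.shape != self.velocity.shape or self.time.ndim != 1:
            raise InvalidParameterError("time and velocity must be equal-length 1-D")
        if len(self.time) > 1 and np.any(np.diff(self.time) <= 0):
            raise InvalidParameterError("time must be strictly increasing")


@dataclass
class DopplerIndices:
    """Cycle-averaged Doppler indices; interval fields are None when
    annotations were absent."""

    e: float  # mm/s
    a: float  # mm/s
    e_over_a: float
    ivct: float | None = None  # s
    ivrt: float | None = None  # s
    et: float | None = None  # s
    mpi: float | None = None

    def summary(self) -> str:
        fmt = lambda v, u: "n/a" if v is None else f"{v:.4g} {u}"  # noqa: E731
        return "\n".join(
            [
                f"E velocity      {self.e:.4g} mm/s",
                f"A velocity      {self.a:.4g} mm/s",
                f"E/A             {self.e_over_a:.4g}",
                f"IVCT            {fmt(self.ivct, 's')}",
                f"IVRT            {fmt(self.ivrt, 's')}",
                f"ET              {fmt(self.et, 's')}",
                f"MPI             {fmt(self.mpi, '')}",
            ]
        )


def detect_ea_peaks(
    waveform: DopplerWaveform, min_prominence_frac: float = 0.1
) -> tuple[float, float, float, pd.DataFrame]:
    """Detect per-cycle E and A inflow peaks and average them.

    Lobes are velocity peaks with prominence above ``min_prominence_frac``
    of the global maximum; they are paired in temporal order (E first, A
    second within each diastole).  Returns (E, A, E/A, per-cycle table) with
    E/A formed from the cycle-averaged peaks.

    Raises
    ------
    LobeDetectionError
        If fewer than two lobes are present or lobes cannot be paired.
    """
    v = waveform.velocity
    if np.ptp(v) == 0:
        raise LobeDetectionError("flat velocity trace")
    prom = min_prominence_frac * float(v.max())
    peaks, _ = find_peaks(v, prominence=prom)
    if len(peaks) < 2:
        raise LobeDetectionError(f"found {len(peaks)} inflow lobes; need two per cycle")
    if len(peaks) % 2 != 0:
        raise LobeDetectionError(
            f"found {len(peaks)} inflow lobes; expected an even count (E/A pairs)"
        )
    e_peaks = peaks[0::2]
    a_peaks = peaks[1::2]
    table = pd.DataFrame(
        {
            "cycle": np.arange(len(e_peaks)),
            "e_time": waveform.time[e_peaks],
            "e": v[e_peaks],
            "a_time": waveform.time[a_peaks],
            "a": v[a_peaks],
        }
    )
    e_mean = float(table["e"].mean())
    a_mean = float(table["a"].mean())
    if a_mean <= 0:
        raise LobeDetectionError("non-positive A peak; cannot form E/A")
    return e_mean, a_mean, e_mean / a_mean, table


def compute_mpi(ivct: float, ivrt: float, et: float) -> float:
    """Myocardial performance index, MPI = (IVCT + IVRT) / ET."""
    if ivct < 0 or ivrt < 0:
        raise InvalidParameterError("IVCT and IVRT must be non-negative")
    if et <= 0:
        raise ZeroDivisionInputError("ET must be positive")
    return (ivct + ivrt) / et


def intervals_from_events(events: pd.DataFrame) -> tuple[float, float, float]:
    """Cycle-averaged (IVCT, IVRT, ET) from valve event annotations."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise InvalidParameterError(f"event table missing columns: {missing}")
    ivct = (events["vb_open"] - events["av_close"]).to_numpy()
    et = (events["vb_close"] - events["vb_open"]).to_numpy()
    ivrt = (events["av_open"] - events["vb_close"]).to_numpy()
    if np.any(ivct < 0) or np.any(et <= 0) or np.any(ivrt < 0):
        raise InvalidParameterError("event times imply negative or zero intervals")
    return float(ivct.mean()), float(ivrt.mean()), float(et.mean())


def analyze_doppler(waveform: DopplerWaveform) -> DopplerIndices:
    """E/A from the inflow trace plus MPI when valve annotations are present."""
    e, a, ea, _ = detect_ea_peaks(waveform)
    ivct = ivrt = et = mpi = None
    if waveform.events is not None and len(waveform.events) > 0:
        ivct, ivrt, et = intervals_from_events(waveform.events)
        mpi = compute_mpi(ivct, ivrt, et)
    return DopplerIndices(e=e, a=a, e_over_a=ea, ivct=ivct, ivrt=ivrt, et=et, mpi=mpi)
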
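"""Transit-time pulse-wave velocity from paired aortic flow waveforms.

PWV = aortic path length / transit time, where the transit time is the
difference between the times at which the ascending and descending
waveforms first reach half of their peak value on the upstroke. The
half-max crossing is linearly interpolated between samples, which matters
at the ~40 ms temporal resolution typical of cine phase contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import Centreline


@dataclass
class WaveformPair:
    """Time-aligned ascending/descending aorta waveforms (velocity or flow)."""

    time: np.ndarray  # ms
    ascending: np.ndarray
    descending: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ascending = np.asarray(self.ascending, dtype=float)
        self.descending = np.asarray(self.descending, dtype=float)
        n = len(self.time)
        if n < 8:
            raise ValueError(f"waveforms need >= 8 samples; got {n}")
        if len(self.ascending) != n or len(self.descending) != n:
            raise ValueError("time, ascending, descending must have equal length")
        for name, w in (("ascending", self.ascending), ("descending", self.descending)):
            if w.max() <= 0:
                raise ValueError(f"{name} waveform has no positive peak")

    @property
    def sampling_interval(self) -> float:
        return float(self.time[1] - self.time[0])


def arc_length(centreline: Centreline) -> float:
    """Polyline arc length, mm (sum of Euclidean segment lengths)."""
    seg = np.diff(centreline.points, axis=0)
    return float(np.linalg.norm(seg, axis=1).sum())


def half_max_crossing(waveform: np.ndarray, time: np.ndarray) -> float:
    """Time (ms) of the first upstroke crossing of half the peak value.

    Scans from the start of the cycle to the global peak and linearly
    interpolates the first sample interval that rises through 0.5*peak.
    A waveform already at or above half-max at its first sample has no
    upstroke and is rejected.
    """
    w = np.asarray(waveform, dtype=float)
    t = np.asarray(time, dtype=float)
    peak_idx = int(np.argmax(w))
    half = 0.5 * w[peak_idx]
    if w[peak_idx] <= 0:
        raise ValueError("waveform has no positive peak")
    if w[0] >= half:
        raise ValueError("waveform starts at or above half-max; no upstroke to cross")
    for i in range(peak_idx):
        if w[i] < half <= w[i + 1]:
            frac = (half - w[i]) / (w[i + 1] - w[i])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    raise ValueError("no upstroke crossing of half-max before the peak")


def transit_time(pair: WaveformPair) -> float:
    """Descending minus ascending half-max crossing time, ms.

    Non-positive transit times are physiologically invalid and reported
    as NaN with a warning.
    """
    tt = half_max_crossing(pair.descending, pair.time) - half_max_crossing(
        pair.ascending, pair.time
    )
    if tt <= 0:
        warnings.warn(f"non-positive transit time ({tt:.2f} ms); reported missing", stacklevel=2)
        return np.nan
    return tt


def pwv(length_mm: float, transit_time_ms: float) -> float:
    """Pulse-wave velocity in m/s from path length (mm) and transit time (ms)."""
    if not np.isfinite(transit_time_ms) or transit_time_ms <= 0:
        return np.nan
    return (length_mm / 1000.0) / (transit_time_ms / 1000.0)


def pwv_from_pair(pair: WaveformPair, centreline: Centreline) -> dict:
    """Convenience wrapper: full PWV computation with intermediates."""
    asc = half_max_crossing(pair.ascending, pair.time)
    desc = half_max_crossing(pair.descending, pair.time)
    tt = desc - asc
    if tt <= 0:
        warnings.warn(f"non-positive transit time ({tt:.2f} ms); reported missing", stacklevel=2)
        tt = np.nan
    length = arc_length(centreline)
    return {
        "ascending_crossing_ms": asc,
        "descending_crossing_ms": desc,
        "transit_time_ms": tt,
        "arc_length_mm": length,
        "pwv_m_s": pwv(length, tt),
    }
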
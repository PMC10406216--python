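"""End-tidal CO2 (PETCO2) extraction from a normalized capnogram.

The capnogram's breath-wise exhalation peaks are detected with a minimum
inter-peak distance (breaths are at least ~2 s apart) and an amplitude
floor on the normalized scale; the continuous PETCO2 trace is the linear
interpolation between those peak values on the source grid, held constant
before the first and after the last peak.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import WaveformSeries

logger = logging.getLogger(__name__)

DEFAULT_MIN_DISTANCE_S = 2.0   # at least 2 s between exhalations
DEFAULT_AMP_FLOOR = 0.3        # normalized-CO2 units; negative peaks rejected


@dataclass
class PeakSeries:
    """Detected exhalation peaks: strictly increasing times plus values."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("peak times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.times.size


@dataclass
class EndTidalTrace:
    """Continuous PETCO2 trace on the same grid as the source CO2."""

    series: WaveformSeries
    peaks: PeakSeries | None = None


def detect_peaks(co2: WaveformSeries,
                 min_distance_s: float = DEFAULT_MIN_DISTANCE_S,
                 amp_floor: float = DEFAULT_AMP_FLOOR) -> PeakSeries:
    """Detect exhalation peaks in a normalized CO2 waveform.

    Local maxima separated by at least ``min_distance_s`` whose value is
    >= ``amp_floor`` and strictly positive. Returns an empty
    :class:`PeakSeries` (with a warning) if nothing qualifies.
    """
    distance = max(1, int(round(min_distance_s * co2.fs)))
    floor = max(amp_floor, np.finfo(float).tiny)  # negative peaks always rejected
    idx, _ = signal.find_peaks(co2.values, height=floor, distance=distance)
    if idx.size == 0:
        msg = "no CO2 exhalation peaks found; downstream PETCO2 metrics are undefined"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return PeakSeries(co2.t0 + idx / co2.fs, co2.values[idx])


def peaks_to_trace(peaks: PeakSeries, template: WaveformSeries) -> EndTidalTrace:
    """Interpolate peak values into a continuous trace on ``template``'s grid.

    Linear between peaks, constant extrapolation outside the peak span.
    Requires at least two peaks.
    """
    if peaks.n < 2:
        raise ValueError(f"need >= 2 peaks to form a PETCO2 trace, got {peaks.n}")
    vals = np.interp(template.times, peaks.times, peaks.values)
    return EndTidalTrace(WaveformSeries(vals, template.fs, template.t0), peaks)


def extract_petco2(co2: WaveformSeries,
                   min_distance_s: float = DEFAULT_MIN_DISTANCE_S,
                   amp_floor: float = DEFAULT_AMP_FLOOR) -> EndTidalTrace:
    """Detect peaks and interpolate them into the PETCO2 trace."""
    peaks = detect_peaks(co2, min_distance_s=min_distance_s, amp_floor=amp_floor)
    return peaks_to_trace(peaks, co2)
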
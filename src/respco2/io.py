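"""Containers and on-disk formats for paired respiration/CO2 recordings.

Two dialects are supported:

* plain two-column CSV ``time,value`` with a header row (one file per
  channel), sampling rate inferred from the time column;
* BIDS-physio-style TSV (headerless, tab-separated, columns named in the
  JSON sidecar) with a sidecar carrying ``SamplingFrequency``,
  ``StartTime`` and ``Columns``.

All writers emit UTF-8 with LF line endings and a fixed float format so
that output is byte-stable for a given recording.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

#: fraction of non-finite samples tolerated (and repaired) by the loaders
DEFAULT_MAX_NAN_FRAC = 0.001

_FLOAT_FMT = "%.9g"


@dataclass
class WaveformSeries:
    """A uniformly sampled scalar time series.

    Parameters
    ----------
    values : ndarray
        Samples (arbitrary units before normalization; unitless after).
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("WaveformSeries requires a 1-D array with >= 1 sample")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Duration in seconds (n samples at fs)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def copy(self) -> "WaveformSeries":
        return WaveformSeries(self.values.copy(), self.fs, self.t0)


@dataclass
class PhysioRecording:
    """A paired respiration-belt / %CO2 recording.

    ``delay_applied_s`` records how far the CO2 channel has been shifted
    backwards in time to compensate the measurement delay; ``normalized``
    flags whether both channels have been z-scored.
    """

    subject_id: str
    recording_id: str
    resp: WaveformSeries
    co2: WaveformSeries
    normalized: bool = False
    delay_applied_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty (needed for subject-level folds)")

    def copy(self) -> "PhysioRecording":
        return replace(self, resp=self.resp.copy(), co2=self.co2.copy(),
                       meta=dict(self.meta))


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _repair_nonfinite(values: np.ndarray, max_nan_frac: float, label: str) -> np.ndarray:
    bad = ~np.isfinite(values)
    if not bad.any():
        return values
    frac = bad.mean()
    if frac > max_nan_frac:
        raise ValueError(
            f"{label}: {bad.sum()} non-finite samples ({frac:.2%}) exceed the "
            f"allowed fraction {max_nan_frac:.2%}"
        )
    idx = np.arange(values.size)
    values = values.copy()
    values[bad] = np.interp(idx[bad], idx[~bad], values[~bad])
    msg = f"{label}: interpolated {bad.sum()} non-finite sample(s)"
    logger.warning(msg)
    warnings.warn(msg, RuntimeWarning, stacklevel=3)
    return values


def read_waveform_csv(path, max_nan_frac: float = DEFAULT_MAX_NAN_FRAC) -> WaveformSeries:
    """Read a two-column ``time,value`` CSV; fs inferred from the time axis."""
    arr = np.genfromtxt(path, delimiter=",", names=True)
    t = np.asarray(arr[arr.dtype.names[0]], dtype=float)
    v = np.asarray(arr[arr.dtype.names[1]], dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need >= 2 samples to infer the sampling rate")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: time axis is not uniformly sampled")
    v = _repair_nonfinite(v, max_nan_frac, str(path))
    return WaveformSeries(v, fs=1.0 / dt[0], t0=float(t[0]))


def read_recording(path_resp, path_co2, *, subject_id: str = "unknown",
                   recording_id: str | None = None,
                   max_nan_frac: float = DEFAULT_MAX_NAN_FRAC) -> PhysioRecording:
    """Read a raw recording from two ``time,value`` CSV files."""
    resp = read_waveform_csv(path_resp, max_nan_frac)
    co2 = read_waveform_csv(path_co2, max_nan_frac)
    rid = recording_id or Path(path_resp).stem.replace("_resp", "")
    return PhysioRecording(subject_id=subject_id, recording_id=rid, resp=resp, co2=co2)


def read_recording_bids(path_tsv, path_json, *, subject_id: str = "unknown",
                        recording_id: str | None = None,
                        max_nan_frac: float = DEFAULT_MAX_NAN_FRAC) -> PhysioRecording:
    """Read a BIDS-physio-style TSV with JSON sidecar.

    The sidecar must provide ``SamplingFrequency`` and ``Columns``
    (containing ``respiratory`` and ``co2``); ``StartTime`` defaults to 0.
    """
    with open(path_json, encoding="utf-8") as fh:
        side = json.load(fh)
    if "SamplingFrequency" not in side:
        raise ValueError(f"{path_json}: sidecar lacks SamplingFrequency")
    fs = float(side["SamplingFrequency"])
    t0 = float(side.get("StartTime", 0.0))
    cols = side.get("Columns", ["respiratory", "co2"])
    data = np.genfromtxt(path_tsv, delimiter="\t")
    data = np.atleast_2d(data)
    try:
        i_resp, i_co2 = cols.index("respiratory"), cols.index("co2")
    except ValueError as exc:
        raise ValueError(f"{path_json}: Columns must name 'respiratory' and 'co2'") from exc
    resp = _repair_nonfinite(data[:, i_resp].astype(float), max_nan_frac, f"{path_tsv}[respiratory]")
    co2 = _repair_nonfinite(data[:, i_co2].astype(float), max_nan_frac, f"{path_tsv}[co2]")
    rid = recording_id or Path(path_tsv).stem
    meta = {k: v for k, v in side.items() if k not in ("SamplingFrequency", "StartTime", "Columns")}
    return PhysioRecording(
        subject_id=str(side.get("SubjectId", subject_id)),
        recording_id=str(side.get("RecordingId", rid)),
        resp=WaveformSeries(resp, fs, t0),
        co2=WaveformSeries(co2, fs, t0),
        normalized=bool(side.get("Normalized", False)),
        delay_applied_s=float(side.get("DelayAppliedSeconds", 0.0)),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_waveform_csv(series: WaveformSeries, path) -> Path:
    path = Path(path)
    t = series.times
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("time,value\n")
        for ti, vi in zip(t, series.values):
            fh.write(f"{_FLOAT_FMT % ti},{_FLOAT_FMT % vi}\n")
    return path


def write_recording(rec: PhysioRecording, directory) -> dict:
    """Write a recording as two CSVs plus a JSON sidecar; returns the paths.

    Round-tripping through :func:`read_recording_dir` reproduces values to
    within the float format precision and metadata exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    p_resp = write_waveform_csv(rec.resp, directory / f"{rec.recording_id}_resp.csv")
    p_co2 = write_waveform_csv(rec.co2, directory / f"{rec.recording_id}_co2.csv")
    side = {
        "SubjectId": rec.subject_id,
        "RecordingId": rec.recording_id,
        "SamplingFrequency": rec.resp.fs,
        "StartTime": rec.resp.t0,
        "Normalized": rec.normalized,
        "DelayAppliedSeconds": rec.delay_applied_s,
    }
    side.update(rec.meta)
    p_json = directory / f"{rec.recording_id}.json"
    with open(p_json, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(side, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"resp": p_resp, "co2": p_co2, "sidecar": p_json}


def read_recording_dir(directory, recording_id: str) -> PhysioRecording:
    """Read back a recording written by :func:`write_recording`."""
    directory = Path(directory)
    with open(directory / f"{recording_id}.json", encoding="utf-8") as fh:
        side = json.load(fh)
    rec = read_recording(
        directory / f"{recording_id}_resp.csv",
        directory / f"{recording_id}_co2.csv",
        subject_id=side["SubjectId"],
        recording_id=side["RecordingId"],
    )
    rec.normalized = bool(side.get("Normalized", False))
    rec.delay_applied_s = float(side.get("DelayAppliedSeconds", 0.0))
    rec.meta = {k: v for k, v in side.items()
                if k not in ("SubjectId", "RecordingId", "SamplingFrequency",
                             "StartTime", "Normalized", "DelayAppliedSeconds")}
    return rec


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample(series: WaveformSeries, target_fs: float) -> WaveformSeries:
    """Resample to ``target_fs`` via polyphase filtering.

    Duration is preserved within one sample period. The caller is expected
    to have low-pass filtered below the new Nyquist when downsampling;
    upsampling without that is allowed but logged.
    """
    if not target_fs > 0:
        raise ValueError("target_fs must be > 0")
    if np.isclose(target_fs, series.fs):
        return series.copy()
    if target_fs > series.fs:
        logger.info("upsampling %g Hz -> %g Hz", series.fs, target_fs)
    ratio = Fraction(target_fs / series.fs).limit_denominator(10000)
    out = signal.resample_poly(series.values, ratio.numerator, ratio.denominator,
                               padtype="smooth")
    return WaveformSeries(out, fs=series.fs * ratio.numerator / ratio.denominator,
                          t0=series.t0)
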
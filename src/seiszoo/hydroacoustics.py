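"""Calibrated hydrophone pressure series and windowed broadband sound metrics.

The two metrics reported for impulsive airgun noise are the broadband sound
exposure level (SEL, dB re 1 µPa²s) over fixed 10 s intervals in the
10 Hz – 20 kHz band, and the maximum peak-to-peak pressure (Pa) in each
interval.  SEL is an energy metric::

    SEL = 10 log10( ∫ p(t)² dt / (p_ref² · t_ref) ),   p_ref = 1 µPa, t_ref = 1 s

Pressure is held in Pa internally; the +120 dB term converts Pa² to µPa².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "PressureRecording",
    "calibrate",
    "bandlimit",
    "window_sel",
    "window_p2p",
    "metrics_vs_distance",
]

#: conversion between the Pa domain used internally and the µPa reference
_DB_PA_TO_UPA = 120.0


@dataclass
class PressureRecording:
    """A uniformly sampled sound-pressure time series in pascal.

    Parameters
    ----------
    samples : ndarray
        Instantaneous pressure, Pa.
    sample_rate : float
        Sampling frequency, Hz. Must be positive.
    start_time : float
        Time of the first sample, s (relative or epoch).
    """

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sample_rate

    def to_wav(self, path) -> None:
        """Write as 32-bit float WAV; sample values are pressure in Pa."""
        wavfile.write(path, int(round(self.sample_rate)), self.samples.astype(np.float32))

    @classmethod
    def from_wav(cls, path, sensitivity_db: float | None = None, start_time: float = 0.0):
        """Read a mono WAV.  Integer PCM is scaled to [-1, 1) first; if
        ``sensitivity_db`` is given the raw amplitudes are calibrated to Pa,
        otherwise they are taken to already be Pa (our own float WAVs)."""
        rate, data = wavfile.read(path)
        if data.ndim > 1:
            warnings.warn("multichannel WAV: using first channel only")
            data = data[:, 0]
        if np.issubdtype(data.dtype, np.integer):
            data = data / float(np.iinfo(data.dtype).max)
        data = np.asarray(data, dtype=float)
        if sensitivity_db is not None:
            return calibrate(data, sensitivity_db, rate, start_time=start_time)
        return cls(data, float(rate), start_time)


def calibrate(raw, sensitivity_db: float, sample_rate: float,
              start_time: float = 0.0) -> PressureRecording:
    """Convert raw hydrophone amplitudes to pressure in Pa.

    ``sensitivity_db`` is the magnitude of the hydrophone sensitivity in
    dB re 1 µPa (e.g. 205 for a -205 dB re 1 V/µPa element): one raw unit
    maps to ``10^(|s|/20)`` µPa.
    """
    if not sample_rate > 0:
        raise ValueError("sample_rate must be positive")
    scale_upa = 10.0 ** (abs(sensitivity_db) / 20.0)
    samples_pa = np.asarray(raw, dtype=float) * scale_upa * 1e-6
    return PressureRecording(samples_pa, sample_rate, start_time)


def bandlimit(rec: PressureRecording, f_lo: float = 10.0, f_hi: float = 20_000.0,
              order: int = 4) -> PressureRecording:
    """Zero-phase Butterworth band-pass (default 10 Hz – 20 kHz).

    Forward-backward filtering keeps the waveform phase intact so subsequent
    peak-to-peak readings are not distorted; the effective order is doubled.
    """
    nyq = rec.sample_rate / 2.0
    if not 0 < f_lo < f_hi:
        raise ValueError("need 0 < f_lo < f_hi")
    if f_hi >= nyq:
        raise ValueError(f"f_hi={f_hi} Hz must be below Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [f_lo, f_hi], btype="bandpass", fs=rec.sample_rate,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return PressureRecording(filtered, rec.sample_rate, rec.start_time)


def _window_slice(rec: PressureRecording, window_start: float, window_length: float):
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    i0 = int(round((window_start - rec.start_time) * rec.sample_rate))
    i1 = i0 + int(round(window_length * rec.sample_rate))
    if i0 < 0 or i1 > rec.samples.size:
        raise ValueError(
            f"window [{window_start}, {window_start + window_length}) s not fully "
            f"inside recording [{rec.start_time}, {rec.start_time + rec.duration}) s")
    return rec.samples[i0:i1]


def window_sel(rec: PressureRecording, window_start: float,
               window_length: float = 10.0) -> float:
    """Sound exposure level of one window, dB re 1 µPa²s.

    An all-zero (silent) window returns ``-inf`` rather than raising, so
    recording gaps survive batch processing.
    """
    p = _window_slice(rec, window_start, window_length)
    energy_pa2s = float(np.sum(p * p)) / rec.sample_rate
    if energy_pa2s == 0.0:
        return -np.inf
    return 10.0 * np.log10(energy_pa2s) + _DB_PA_TO_UPA


def window_p2p(rec: PressureRecording, window_start: float,
               window_length: float = 10.0) -> float:
    """Maximum peak-to-peak pressure (max - min) in the window, Pa."""
    p = _window_slice(rec, window_start, window_length)
    if p.size == 0:
        raise ValueError("empty window")
    return float(p.max() - p.min())


def metrics_vs_distance(rec: PressureRecording, track: pd.DataFrame,
                        window_length: float = 10.0,
                        f_lo: float = 10.0, f_hi: float = 20_000.0,
                        p2p_on_filtered: bool = True) -> pd.DataFrame:
    """Per-window SEL and peak-to-peak pressure joined to source distance.

    The recording is split into contiguous, non-overlapping windows starting
    at the recording start; trailing partial windows are dropped.  Each window
    is annotated with the track distance interpolated at the window midpoint.
    Windows that fall between airgun shots simply carry the background level —
    no shot detection is attempted.

    ``track`` needs columns ``time_s`` and ``distance_m`` and must cover the
    recording's time span.
    """
    t_lo = float(track["time_s"].min())
    t_hi = float(track["time_s"].max())
    n_win = int(np.floor(rec.duration / window_length))
    if n_win < 1:
        raise ValueError("recording shorter than one window")
    starts = rec.start_time + window_length * np.arange(n_win)
    mids = starts + window_length / 2.0
    if mids.min() < t_lo or mids.max() > t_hi:
        raise ValueError(
            f"track [{t_lo}, {t_hi}] s does not cover window midpoints "
            f"[{mids.min()}, {mids.max()}] s")

    filtered = bandlimit(rec, f_lo, f_hi)
    sel_rec = filtered
    p2p_rec = filtered if p2p_on_filtered else rec
    dist = np.interp(mids, track["time_s"].to_numpy(), track["distance_m"].to_numpy())
    rows = []
    for start, mid, d in zip(starts, mids, dist):
        rows.append({
            "window_start_s": start,
            "distance_m": d,
            "sel_db": window_sel(sel_rec, start, window_length),
            "p2p_pa": window_p2p(p2p_rec, start, window_length),
        })
    return pd.DataFrame(rows)
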
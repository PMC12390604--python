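"""Windowing, periodogram PSD, mean power frequency and the peak envelope.

The trial is split into 120 equal, contiguous windows.  Each window's power
spectral density is the raw periodogram PSD(f_k) = |X(k)|^2 / T (T the window
duration), and its mean power frequency is the power-weighted mean
MPF = sum(f * PSD) / sum(PSD) on the discrete one-sided grid.  Per-channel MPF
series are min-max normalized to [0, 1] so the two modalities become
commensurable, and a piecewise-linear envelope through the local maxima
anchors the fatigue staging at its global peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.fft import rfft, rfftfreq

__all__ = [
    "Window",
    "PSDEstimate",
    "MPFSeries",
    "PeakEnvelope",
    "DegenerateWindowError",
    "segment_signal",
    "periodogram_psd",
    "mean_power_frequency",
    "normalize_minmax",
    "peak_envelope",
    "mpf_series",
]


class DegenerateWindowError(ValueError):
    """A window carries no power (or a series is constant): MPF undefined."""


@dataclass(frozen=True)
class Window:
    index: int
    samples: np.ndarray
    fs: float

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class PSDEstimate:
    frequencies: np.ndarray
    densities: np.ndarray


@dataclass
class MPFSeries:
    """Per-window MPF of one channel, raw (Hz) and min-max normalized."""

    subject_id: int
    muscle_id: str
    modality: str
    raw: np.ndarray
    normalized: np.ndarray
    x_min: float
    x_max: float


@dataclass
class PeakEnvelope:
    """Piecewise-linear envelope through the local maxima of an MPF series."""

    anchors: np.ndarray  # indices of the anchor windows
    values: np.ndarray  # envelope evaluated at every window
    peak_index: int  # global peak window p*
    peak_value: float
    series: np.ndarray  # the underlying (normalized) series


def segment_signal(samples: np.ndarray, fs: float, n_windows: int = 120) -> list[Window]:
    """Split a signal into ``n_windows`` equal contiguous windows.

    Trailing remainder samples (length mod n_windows) are dropped from the end.
    """
    samples = np.asarray(samples, dtype=float)
    n = len(samples)
    if n < n_windows:
        raise ValueError(f"signal of length {n} cannot form {n_windows} windows")
    wlen = n // n_windows
    return [
        Window(index=i, samples=samples[i * wlen : (i + 1) * wlen], fs=fs)
        for i in range(n_windows)
    ]


def periodogram_psd(window: Window, taper: str = "none") -> PSDEstimate:
    """Raw periodogram PSD(f_k) = |X(f_k)|^2 / T on the one-sided DFT grid.

    ``X`` is the finite-time Fourier transform of the window (DFT scaled by the
    sample interval) and ``T`` the window duration, so the one-sided density
    (interior bins doubled) integrates to the window's mean power.
    ``taper='hann'`` applies a Hann window first (robustness option; the
    default is the plain periodogram).
    """
    x = window.samples
    n = len(x)
    if n == 0:
        raise ValueError("empty window")
    if taper == "hann":
        x = x * np.hanning(n)
    elif taper != "none":
        raise ValueError(f"unknown taper {taper!r}")
    T = n / window.fs
    dt = 1.0 / window.fs
    spec = np.abs(rfft(x) * dt) ** 2 / T
    spec[1:] *= 2.0
    if n % 2 == 0:
        spec[-1] /= 2.0  # Nyquist bin is not mirrored
    freqs = rfftfreq(n, dt)
    return PSDEstimate(frequencies=freqs, densities=spec)


def mean_power_frequency(psd: PSDEstimate) -> float:
    """Power-weighted mean frequency sum(f*PSD) / sum(PSD) of one window."""
    total = float(np.sum(psd.densities))
    if total <= 0:
        raise DegenerateWindowError("window has zero total power; MPF undefined")
    return float(np.sum(psd.frequencies * psd.densities) / total)


def normalize_minmax(series: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Min-max normalization y_i = (x_i - x_min) / (x_max - x_min).

    Returns the normalized series together with the extrema used.  A constant
    series is rejected (the normalization is undefined).
    """
    x = np.asarray(series, dtype=float)
    x_min, x_max = float(np.min(x)), float(np.max(x))
    if x_max == x_min:
        raise DegenerateWindowError("constant series cannot be min-max normalized")
    return (x - x_min) / (x_max - x_min), x_min, x_max


def peak_envelope(series: np.ndarray) -> PeakEnvelope:
    """Envelope through the strict local maxima of a series plus both endpoints.

    The global peak is the anchor of maximum value; on plateaus the first
    index wins.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 windows for an envelope")
    interior = np.where((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:]))[0] + 1
    anchors = np.concatenate(([0], interior, [n - 1]))
    values = np.interp(np.arange(n), anchors, y[anchors])
    peak_pos = int(np.argmax(y[anchors]))  # argmax -> first among equals
    peak_index = int(anchors[peak_pos])
    return PeakEnvelope(
        anchors=anchors,
        values=values,
        peak_index=peak_index,
        peak_value=float(y[peak_index]),
        series=y,
    )


def mpf_series(
    samples: np.ndarray,
    fs: float,
    subject_id: int = 0,
    muscle_id: str = "",
    modality: str = "semg",
    n_windows: int = 120,
    taper: str = "none",
) -> MPFSeries:
    """Per-window MPF (raw and normalized) of one preprocessed channel."""
    windows = segment_signal(samples, fs, n_windows)
    raw = np.array([mean_power_frequency(periodogram_psd(w, taper=taper)) for w in windows])
    normalized, x_min, x_max = normalize_minmax(raw)
    return MPFSeries(
        subject_id=subject_id,
        muscle_id=muscle_id,
        modality=modality,
        raw=raw,
        normalized=normalized,
        x_min=x_min,
        x_max=x_max,
    )
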
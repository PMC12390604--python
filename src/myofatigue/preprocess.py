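"""Per-modality noise reduction: Butterworth band-pass and rectification.

Filtering is fourth-order Butterworth (20-500 Hz for sEMG, 10-50 Hz for MMG),
designed in second-order sections for numerical stability and applied
forward-backward so the output is zero-phase: window boundaries stay aligned
with the events that produced them.  Rectification (full-wave) is available as
the post-filter correction step but is not applied before spectral features by
default, because taking absolute values distorts the spectrum the MPF is
computed from.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .config import MMG_BAND, SEMG_BAND
from .simulate import RawRecording

__all__ = ["FilterSpec", "SEMG_FILTER", "MMG_FILTER", "bandpass_filter", "rectify", "default_filter"]


@dataclass(frozen=True)
class FilterSpec:
    order: int
    low_cut: float
    high_cut: float
    modality: str

    def __post_init__(self) -> None:
        if not (0 < self.low_cut < self.high_cut):
            raise ValueError("need 0 < low_cut < high_cut")
        if self.order < 1:
            raise ValueError("order must be >= 1")


SEMG_FILTER = FilterSpec(4, *SEMG_BAND, "semg")
MMG_FILTER = FilterSpec(4, *MMG_BAND, "mmg")


def default_filter(modality: str, order: int = 4) -> FilterSpec:
    band = SEMG_BAND if modality == "semg" else MMG_BAND
    return FilterSpec(order, *band, modality)


def bandpass_filter(recording: RawRecording, spec: FilterSpec | None = None) -> RawRecording:
    """Zero-phase Butterworth band-pass of one recording.

    Reflective padding of at least three low-frequency filter lengths
    suppresses startup transients in the first analysis window.
    """
    if spec is None:
        spec = default_filter(recording.modality)
    if spec.modality != recording.modality:
        raise ValueError(
            f"filter for {spec.modality!r} applied to a {recording.modality!r} channel"
        )
    if spec.high_cut >= recording.fs / 2:
        raise ValueError(
            f"high_cut {spec.high_cut} Hz >= Nyquist {recording.fs / 2} Hz "
            f"for channel {recording.channel_key}"
        )
    sos = butter(
        spec.order, [spec.low_cut, spec.high_cut], btype="bandpass", fs=recording.fs, output="sos"
    )
    padlen = min(len(recording.samples) - 1, int(3 * recording.fs / spec.low_cut))
    y = sosfiltfilt(sos, recording.samples, padlen=padlen)
    return replace(recording, samples=y)


def rectify(recording: RawRecording) -> RawRecording:
    """Full-wave rectification (pointwise absolute value); idempotent."""
    return replace(recording, samples=np.abs(recording.samples))
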
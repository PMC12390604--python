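"""Fatigue staging of MPF peak envelopes and whole-body state fusion.

Each muscle channel's envelope is converted to an ordinal stage series:

======  =====================================================
stage   meaning
======  =====================================================
0       before the ascent of the MPF begins (not fatigued)
1       MPF growing to its peak (transition)
2..5    envelope has dropped 5 / 10 / 15 / 20 % below its peak
======  =====================================================

Stage series are made non-decreasing by carrying the running maximum forward
(fatigue does not regress within a trial).  The 12 per-muscle series (6 sEMG +
6 MMG) are then fused into one whole-body state per window by two rules applied
in order: (1) if at least four muscles currently share a stage, the body takes
the highest such stage; (2) if afterwards any muscle is at least two stages
above the body state, the body state is promoted by one level.  The result is
carried forward so the body state never decreases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import N_STAGES
from .spectral import PeakEnvelope

__all__ = [
    "StagingSpec",
    "StageLabelSeries",
    "BodyStateSeries",
    "stage_muscle",
    "fuse_body_state",
    "fuse_stage_matrix",
    "fuse_window",
]

#: Number of muscle channels the body-state fusion expects.
N_FUSED_CHANNELS = 12


@dataclass(frozen=True)
class StagingSpec:
    """Fractional envelope drops mapping to stages 2..5."""

    drop_thresholds: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20)

    def __post_init__(self) -> None:
        t = self.drop_thresholds
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("drop thresholds must be strictly increasing")


@dataclass
class StageLabelSeries:
    muscle_id: str
    modality: str
    labels: np.ndarray  # int, in {0..5}, non-decreasing


@dataclass
class BodyStateSeries:
    labels: np.ndarray  # int, in {0..5}, non-decreasing
    provenance: np.ndarray  # str per window: condition1 | condition2 | carry-forward


def stage_muscle(
    envelope: PeakEnvelope,
    spec: StagingSpec = StagingSpec(),
    muscle_id: str = "",
    modality: str = "",
) -> StageLabelSeries:
    """Stage one muscle channel from its MPF peak envelope.

    The ascent start is the last window before the global peak at which the
    underlying series attains its pre-peak minimum; drops after the peak are
    fractions (peak - envelope) / peak of the envelope value.  Labels carry
    their running maximum forward.
    """
    env = envelope.values
    n = len(env)
    peak = envelope.peak_index
    pv = envelope.peak_value
    labels = np.zeros(n, dtype=int)
    if pv - float(np.min(env)) <= 1e-12:
        warnings.warn("flat envelope: staging degenerate, all labels 0", stacklevel=2)
        return StageLabelSeries(muscle_id, modality, labels)

    pre = envelope.series[: peak + 1]
    ascent_start = len(pre) - 1 - int(np.argmin(pre[::-1]))
    labels[ascent_start : peak + 1] = 1
    current = 1
    for w in range(peak + 1, n):
        drop = (pv - env[w]) / pv
        level = 1
        for k, thr in enumerate(spec.drop_thresholds):
            if drop >= thr:
                level = 2 + k
        current = max(current, level)
        labels[w] = current
    return StageLabelSeries(muscle_id, modality, labels)


def fuse_window(muscle_labels: np.ndarray, prev_body: int) -> tuple[int, str]:
    """Apply the two fusion conditions at a single window.

    Condition 1: if >= 4 muscles share a stage, the candidate body state is the
    highest such stage (else the previous state carries forward).  Condition 2:
    if any muscle is >= candidate + 2, promote the candidate by one.  The
    returned state is never below ``prev_body``.
    """
    counts = np.bincount(muscle_labels, minlength=N_STAGES)
    eligible = np.where(counts >= 4)[0]
    if eligible.size:
        body = int(eligible.max())
        how = "condition1"
    else:
        body = prev_body
        how = "carry-forward"
    if np.any(muscle_labels >= body + 2):
        body += 1
        how = "condition2"
    if body < prev_body:
        body = prev_body
        how = "carry-forward"
    return body, how


def fuse_stage_matrix(stage_matrix: np.ndarray) -> np.ndarray:
    """Fuse a (12, n_windows) matrix of muscle stages into a body-state series."""
    stage_matrix = np.asarray(stage_matrix, dtype=int)
    if stage_matrix.shape[0] != N_FUSED_CHANNELS:
        raise ValueError(
            f"body-state fusion needs {N_FUSED_CHANNELS} muscle series, "
            f"got {stage_matrix.shape[0]}"
        )
    body = np.zeros(stage_matrix.shape[1], dtype=int)
    prev = 0
    for w in range(stage_matrix.shape[1]):
        prev, _ = fuse_window(stage_matrix[:, w], prev)
        body[w] = prev
    return body


def fuse_body_state(series: list[StageLabelSeries]) -> BodyStateSeries:
    """Fuse 12 per-muscle stage series into the whole-body fatigue state."""
    if len(series) != N_FUSED_CHANNELS:
        raise ValueError(
            f"body-state fusion needs {N_FUSED_CHANNELS} muscle series, got {len(series)}"
        )
    lengths = {len(s.labels) for s in series}
    if len(lengths) != 1:
        raise ValueError("all stage series must share the same window count")
    matrix = np.stack([s.labels for s in series]).astype(int)
    n = matrix.shape[1]
    labels = np.zeros(n, dtype=int)
    provenance = np.empty(n, dtype=object)
    prev = 0
    for w in range(n):
        prev, how = fuse_window(matrix[:, w], prev)
        labels[w] = prev
        provenance[w] = how
    return BodyStateSeries(labels=labels, provenance=provenance)
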
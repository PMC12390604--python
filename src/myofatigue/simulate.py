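"""Synthetic multi-channel sEMG/MMG cohort with a known fatigue process.

Each channel is band-limited Gaussian noise whose spectral centroid follows a
parameterized mean-power-frequency (MPF) trajectory: a shallow warm-up dip,
a rise to a peak, then a linear decline as fatigue deepens.  Signals are
amplitude-modulated by one raised-cosine burst per lifting movement and can be
contaminated by complementary artifacts (sweat on sEMG, vibration bursts on
MMG).  Ground-truth per-window fatigue stages are derived from the noiseless
trajectory so every downstream stage is testable without real recordings.

Synthesis is short-time: square-root-Hann blocks with 50% overlap are shaped
in the frequency domain around the instantaneous center and overlap-added,
which keeps the sample variance stationary while the centroid drifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.fft import irfft, rfft, rfftfreq

from .config import (
    BAND,
    MODALITIES,
    MuscleFatigueParams,
    SimulationConfig,
)

__all__ = [
    "RawRecording",
    "GroundTruth",
    "TrajectoryClampWarning",
    "mpf_trajectory",
    "ground_truth_stages",
    "simulate_subject",
    "simulate_cohort",
]

#: Fractional envelope drops bounding fatigue stages 2..5.
STAGE_DROPS: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20)


class TrajectoryClampWarning(UserWarning):
    """A declining trajectory would have left the pass band and was clamped."""


@dataclass
class RawRecording:
    """One muscle channel: a real-valued time series with its provenance.

    Units are arbitrary (mV-like for sEMG, acceleration-like for MMG); all
    analysis downstream is scale-invariant.
    """

    subject_id: int
    muscle_id: str
    modality: str
    fs: float
    samples: np.ndarray
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(
                f"non-finite samples in {self.channel_key} of subject {self.subject_id}"
            )
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def channel_key(self) -> str:
        return f"{self.muscle_id}:{self.modality}"


@dataclass
class GroundTruth:
    """Noiseless trajectories, peak windows, stages and fused body state."""

    trajectories: dict[tuple[str, str], np.ndarray]  # (muscle, modality) -> Hz/window
    peak_windows: dict[tuple[str, str], int]
    stages: dict[tuple[str, str], np.ndarray]
    body: np.ndarray = field(default=None)  # type: ignore[assignment]


def _piecewise_trajectory(
    params: MuscleFatigueParams,
    t: np.ndarray,
    duration_s: float,
    band: tuple[float, float],
    width: float,
) -> np.ndarray:
    """Evaluate the noiseless MPF center trajectory at times ``t`` (seconds)."""
    t_rise = params.rise_start_fraction * duration_s
    t_peak = params.ascent_end_fraction * duration_s
    valley = params.baseline_center * (1.0 - params.dip_fraction)
    out = np.empty_like(t, dtype=float)

    pre = t <= t_rise
    out[pre] = params.baseline_center + (valley - params.baseline_center) * t[pre] / t_rise
    asc = (t > t_rise) & (t <= t_peak)
    out[asc] = valley + (params.peak_center - valley) * (t[asc] - t_rise) / (t_peak - t_rise)
    dec = t > t_peak
    out[dec] = params.peak_center * (1.0 - params.decline_rate * (t[dec] - t_peak))

    floor = band[0] + 2.0 * width
    if np.any(out < floor):
        warnings.warn(
            f"trajectory clamped at {floor:.1f} Hz to stay inside the {band} Hz band",
            TrajectoryClampWarning,
            stacklevel=3,
        )
        out = np.maximum(out, floor)
    return out


def _window_midpoints(duration_s: float, n_windows: int) -> np.ndarray:
    return (np.arange(n_windows) + 0.5) * duration_s / n_windows


def mpf_trajectory(
    config: SimulationConfig,
    muscle_id: str,
    modality: str = "semg",
    params: MuscleFatigueParams | None = None,
) -> np.ndarray:
    """Noiseless per-window MPF center curve (Hz) for one channel.

    Evaluated at the midpoints of the ``config.n_windows`` analysis windows.
    """
    if params is None:
        params = config.params_for(muscle_id, modality)
    t = _window_midpoints(config.duration_s, config.n_windows)
    return _piecewise_trajectory(
        params, t, config.duration_s, BAND[modality], config.spectral_width(modality)
    )


def stage_scan(trajectory: np.ndarray, thresholds: tuple[float, ...] = STAGE_DROPS) -> np.ndarray:
    """Threshold scan of a (noiseless) trajectory into fatigue stages 0..5.

    Applies the staging definition directly, with its own plain-loop
    implementation: min-max normalize, draw the upper envelope through the
    strict local maxima (plus endpoints), take the first global maximum as the
    peak window and the last pre-peak minimum of the series as the ascent
    start; windows before the ascent are stage 0, ascent through peak stage 1,
    and after the peak the stage is the highest Table-style drop threshold the
    envelope has reached, carried forward so the series never decreases.
    """
    x = np.asarray(trajectory, dtype=float)
    n = len(x)
    rng_ = x.max() - x.min()
    if rng_ <= 0:
        return np.zeros(n, dtype=int)
    y = (x - x.min()) / rng_
    # upper envelope through strict local maxima + endpoints, linear pieces
    anchors = [0]
    anchors += [i for i in range(1, n - 1) if y[i] > y[i - 1] and y[i] > y[i + 1]]
    anchors += [n - 1]
    env = np.empty(n)
    for a, b in zip(anchors, anchors[1:]):
        for w in range(a, b + 1):
            frac = 0.0 if b == a else (w - a) / (b - a)
            env[w] = y[a] + frac * (y[b] - y[a])
    peak = anchors[int(np.argmax([y[a] for a in anchors]))]
    peak_value = y[peak]
    pre = y[: peak + 1]
    ascent_start = len(pre) - 1 - int(np.argmin(pre[::-1]))  # last index of the minimum
    stages = np.zeros(n, dtype=int)
    stages[ascent_start : peak + 1] = 1
    current = 1
    for w in range(peak + 1, n):
        drop = (peak_value - env[w]) / peak_value
        level = 1
        for k, thr in enumerate(thresholds):
            if drop >= thr:
                level = 2 + k
        current = max(current, level)
        stages[w] = current
    return stages


def ground_truth_stages(
    config: SimulationConfig,
    muscle_id: str,
    modality: str = "semg",
    trajectory: np.ndarray | None = None,
) -> np.ndarray:
    """Per-window true stage series from the noiseless trajectory."""
    if trajectory is None:
        trajectory = mpf_trajectory(config, muscle_id, modality)
    return stage_scan(trajectory)


# ---------------------------------------------------------------------------
# signal synthesis


def _synthesize_channel(
    rng: np.random.Generator,
    centers_hz: np.ndarray,
    width: float,
    band: tuple[float, float],
    fs: float,
    duration_s: float,
    n_windows: int,
    movement_period_s: float,
    envelope_floor: float,
    noise_floor: float,
) -> np.ndarray:
    """Band-limited noise whose spectral centroid tracks ``centers_hz``."""
    n = int(round(fs * duration_s))
    block = int(round(n / n_windows))
    block -= block % 2
    hop = block // 2
    amp_win = np.sqrt(np.hanning(block))  # sqrt-Hann at 50% overlap: stationary variance
    freqs = rfftfreq(block, 1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    t_mid = _window_midpoints(duration_s, n_windows)

    sig = np.zeros(n)
    for start in range(-hop, n, hop):
        t_c = (start + block / 2) / fs
        c = float(np.interp(t_c, t_mid, centers_hz))
        gain = np.exp(-((freqs - c) ** 2) / (4.0 * width**2))
        gain[~in_band] = 0.0
        y = irfft(rfft(rng.standard_normal(block)) * gain, n=block) * amp_win
        lo = max(start, 0)
        hi = min(start + block, n)
        sig[lo:hi] += y[lo - start : hi - start]

    t = np.arange(n) / fs
    env = envelope_floor + (1.0 - envelope_floor) * 0.5 * (
        1.0 - np.cos(2.0 * np.pi * t / movement_period_s)
    )
    sig *= env
    rms = float(np.sqrt(np.mean(sig**2)))
    if rms > 0:
        sig /= rms
    if noise_floor > 0:
        sig += noise_floor * rng.standard_normal(n)
    return sig


def _apply_sweat(rng: np.random.Generator, x: np.ndarray, fs: float, art) -> None:
    """Attenuate random sEMG segments and overlay broadband sweat noise."""
    n = len(x)
    rms = float(np.std(x))
    seg = int(round(art.semg_sweat_segment_s * fs))
    n_segs = max(1, int(round(art.semg_sweat_coverage * n / seg)))
    for _ in range(n_segs):
        start = int(rng.integers(0, max(1, n - seg)))
        sl = slice(start, min(start + seg, n))
        x[sl] = x[sl] * art.semg_sweat_attenuation + (
            art.semg_sweat_gain * rms * rng.standard_normal(sl.stop - sl.start)
        )


def _apply_vibration(rng: np.random.Generator, x: np.ndarray, fs: float, art) -> None:
    """Inject short high-amplitude vibration transients into an MMG channel."""
    n = len(x)
    rms = float(np.std(x))
    dur = max(2, int(round(art.mmg_vibration_duration_s * fs)))
    n_events = int(rng.poisson(art.mmg_vibration_rate * n / fs))
    for _ in range(n_events):
        start = int(rng.integers(0, max(1, n - dur)))
        burst = art.mmg_vibration_amplitude * rms * rng.standard_normal(dur) * np.hanning(dur)
        x[start : start + dur] += burst


def _jittered_params(
    config: SimulationConfig, subject_id: int
) -> dict[str, list[MuscleFatigueParams]]:
    """Per-subject perturbation of the cohort fatigue parameters.

    Timing jitter is shared between the two modalities of a muscle (one muscle,
    one fatigue process); center jitter is drawn per channel.
    """
    rng = np.random.default_rng([config.seed, 900_000 + subject_id])
    j = config.subject_jitter
    out: dict[str, list[MuscleFatigueParams]] = {m: [] for m in MODALITIES}
    for i in range(len(config.muscles)):
        d_rise, d_peak = rng.uniform(-j, j, size=2)
        rate_mult = 1.0 + rng.uniform(-2.0 * j, 2.0 * j)
        for mod in MODALITIES:
            p = config.fatigue[mod][i]
            c_mult = 1.0 + rng.uniform(-j, j)
            out[mod].append(
                MuscleFatigueParams(
                    baseline_center=p.baseline_center * c_mult,
                    peak_center=p.peak_center * c_mult,
                    rise_start_fraction=float(np.clip(p.rise_start_fraction + d_rise, 0.05, 0.9)),
                    ascent_end_fraction=float(
                        np.clip(p.ascent_end_fraction + d_peak, p.rise_start_fraction + d_rise + 0.05, 0.95)
                    ),
                    decline_rate=p.decline_rate * rate_mult,
                    dip_fraction=p.dip_fraction,
                )
            )
    return out


def simulate_subject(
    config: SimulationConfig, subject_id: int
) -> tuple[list[RawRecording], GroundTruth]:
    """Generate all 12 channels (6 muscles x 2 modalities) for one subject.

    Returns the raw recordings and the ground truth (noiseless trajectories,
    true peak windows, per-muscle stages and the fused body state).  Identical
    ``(config, subject_id)`` give bit-identical output.
    """
    from .labeling import fuse_stage_matrix  # local import avoids a cycle at module load

    params = _jittered_params(config, subject_id)
    t_mid = _window_midpoints(config.duration_s, config.n_windows)
    recordings: list[RawRecording] = []
    trajectories: dict[tuple[str, str], np.ndarray] = {}
    peaks: dict[tuple[str, str], int] = {}
    stages: dict[tuple[str, str], np.ndarray] = {}

    for m_idx, modality in enumerate(MODALITIES):
        fs = config.fs(modality)
        width = config.spectral_width(modality)
        band = BAND[modality]
        for i, muscle in enumerate(config.muscles):
            p = params[modality][i]
            traj = _piecewise_trajectory(p, t_mid, config.duration_s, band, width)
            rng = np.random.default_rng([config.seed, subject_id, m_idx, i, 0])
            x = _synthesize_channel(
                rng,
                traj,
                width,
                band,
                fs,
                config.duration_s,
                config.n_windows,
                config.movement_period_s,
                config.envelope_floor,
                config.noise_floor,
            )
            if config.artifacts.enabled:
                art_rng = np.random.default_rng([config.seed, subject_id, m_idx, i, 1])
                if modality == "semg":
                    _apply_sweat(art_rng, x, fs, config.artifacts)
                else:
                    _apply_vibration(art_rng, x, fs, config.artifacts)
            recordings.append(
                RawRecording(
                    subject_id=subject_id, muscle_id=muscle, modality=modality, fs=fs, samples=x
                )
            )
            key = (muscle, modality)
            trajectories[key] = traj
            peaks[key] = int(np.argmax(traj))
            stages[key] = stage_scan(traj)

    stage_matrix = np.stack([stages[(m, mod)] for mod in MODALITIES for m in config.muscles])
    body = fuse_stage_matrix(stage_matrix)
    return recordings, GroundTruth(trajectories, peaks, stages, body)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[RawRecording], dict[int, GroundTruth]]:
    """Simulate every subject of the cohort."""
    recordings: list[RawRecording] = []
    truths: dict[int, GroundTruth] = {}
    for s in range(config.n_subjects):
        recs, gt = simulate_subject(config, s)
        recordings.extend(recs)
        truths[s] = gt
    return recordings, truths
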
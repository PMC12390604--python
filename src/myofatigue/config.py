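"""Configuration models for the fatigue-analysis pipeline.

Every tunable parameter of the simulation and analysis stages lives in a
pydantic model so that YAML configs are validated strictly (unknown keys are
rejected) and each run can emit its fully resolved configuration next to its
results.

Units: frequencies in Hz, durations in seconds, cadence in beats per minute.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

Modality = Literal["semg", "mmg"]

#: Pass bands of the two modalities.  Surface EMG carries its power roughly in
#: 20-500 Hz; accelerometer-based mechanomyography in 10-50 Hz.
SEMG_BAND: tuple[float, float] = (20.0, 500.0)
MMG_BAND: tuple[float, float] = (10.0, 50.0)
BAND: dict[str, tuple[float, float]] = {"semg": SEMG_BAND, "mmg": MMG_BAND}

MODALITIES: tuple[str, str] = ("semg", "mmg")

#: The six muscles instrumented during the lifting protocol.
DEFAULT_MUSCLES: tuple[str, ...] = (
    "vastus_medialis",
    "quadriceps_femoris",
    "latissimus_dorsi",
    "trapezius",
    "deltoid",
    "biceps_brachii",
)

N_STAGES = 6


class StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MuscleFatigueParams(StrictModel):
    """Parameters of one channel's noiseless mean-power-frequency trajectory.

    The trajectory is piecewise linear: a shallow warm-up dip from
    ``baseline_center`` down to ``baseline_center * (1 - dip_fraction)`` at
    ``rise_start_fraction`` of the trial, a rise to ``peak_center`` at
    ``ascent_end_fraction``, then a linear decline losing ``decline_rate``
    (fraction of the peak) per second.  The dip makes the onset of the rise a
    unique minimum, so the ascent start is identifiable from data.
    """

    baseline_center: float = Field(gt=0)
    peak_center: float = Field(gt=0)
    rise_start_fraction: float = Field(gt=0.0, lt=1.0)
    ascent_end_fraction: float = Field(gt=0.0, lt=1.0)
    decline_rate: float = Field(ge=0.0, description="fraction of peak lost per second")
    dip_fraction: float = Field(default=0.05, ge=0.0, lt=0.5)

    @model_validator(mode="after")
    def _ordered(self) -> "MuscleFatigueParams":
        if self.ascent_end_fraction <= self.rise_start_fraction:
            raise ValueError("ascent_end_fraction must exceed rise_start_fraction")
        if self.peak_center <= self.baseline_center:
            raise ValueError("peak_center must exceed baseline_center")
        return self


class ArtifactParams(StrictModel):
    """Complementary contamination models.

    Sweat degrades surface EMG: contiguous segments are attenuated and overlaid
    with broadband noise.  External vibration degrades MMG: short high-amplitude
    transient bursts arrive at a Poisson rate.  The two never touch the other
    modality, which is what makes the fused feature set informative when either
    single modality is compromised.
    """

    enabled: bool = False
    semg_sweat_gain: float = Field(default=1.5, ge=0.0)
    semg_sweat_attenuation: float = Field(default=0.35, gt=0.0, le=1.0)
    semg_sweat_coverage: float = Field(default=0.30, ge=0.0, le=0.9)
    semg_sweat_segment_s: float = Field(default=15.0, gt=0.0)
    mmg_vibration_rate: float = Field(default=0.12, ge=0.0, description="bursts per second")
    mmg_vibration_amplitude: float = Field(default=8.0, ge=0.0)
    mmg_vibration_duration_s: float = Field(default=0.12, gt=0.0)


def default_fatigue_params(
    duration_s: float, muscles: tuple[str, ...] = DEFAULT_MUSCLES
) -> dict[str, list[MuscleFatigueParams]]:
    """Per-muscle defaults with staggered fatigue onset.

    Timing is shared between the two modalities of the same muscle (it is the
    same muscle fatiguing); the spectral centers differ per modality.  The
    stagger across muscles gives the heterogeneous per-muscle onsets that the
    body-state fusion rule is designed to reconcile.
    """
    semg: list[MuscleFatigueParams] = []
    mmg: list[MuscleFatigueParams] = []
    for i in range(len(muscles)):
        rise = 0.26 + 0.015 * i
        ascent_end = 0.56 + 0.018 * i
        total_drop = 0.30 + 0.012 * i  # fraction of peak lost by trial end
        rate = total_drop / ((1.0 - ascent_end) * duration_s)
        timing = dict(
            rise_start_fraction=rise,
            ascent_end_fraction=ascent_end,
            decline_rate=rate,
            dip_fraction=0.05,
        )
        semg.append(
            MuscleFatigueParams(
                baseline_center=94.0 + 1.2 * i, peak_center=116.0 + 1.5 * i, **timing
            )
        )
        mmg.append(
            MuscleFatigueParams(
                baseline_center=32.0 + 0.5 * i, peak_center=44.0 + 0.6 * i, **timing
            )
        )
    return {"semg": semg, "mmg": mmg}


class SimulationConfig(StrictModel):
    """Conditions of the synthetic lifting-to-fatigue cohort.

    Defaults mirror the acquisition protocol being emulated: 16 subjects,
    cyclic lifting at 180 BPM with one movement per 4 beats, six muscles with
    surface EMG sampled at 2000 Hz on one body side and MMG at 400 Hz on the
    other, and 120 analysis windows per trial.
    """

    n_subjects: int = Field(default=16, ge=1)
    cadence_bpm: float = Field(default=180.0, gt=0)
    beats_per_movement: int = Field(default=4, ge=1)
    duration_s: float = Field(default=300.0, gt=0)
    fs_semg: float = Field(default=2000.0, gt=0)
    fs_mmg: float = Field(default=400.0, gt=0)
    n_windows: int = Field(default=120, ge=3)
    muscles: tuple[str, ...] = DEFAULT_MUSCLES
    fatigue: Optional[dict[Modality, list[MuscleFatigueParams]]] = None
    semg_spectral_width: float = Field(default=4.0, gt=0, description="PSD sigma, Hz")
    mmg_spectral_width: float = Field(default=1.2, gt=0, description="PSD sigma, Hz")
    envelope_floor: float = Field(default=0.3, ge=0.0, lt=1.0)
    noise_floor: float = Field(default=0.08, ge=0.0, description="relative amplitude")
    subject_jitter: float = Field(default=0.02, ge=0.0)
    artifacts: ArtifactParams = Field(default_factory=ArtifactParams)
    seed: int = Field(default=0, ge=0)

    @property
    def movement_period_s(self) -> float:
        """Seconds per lifting movement: beats_per_movement / (cadence / 60)."""
        return self.beats_per_movement / (self.cadence_bpm / 60.0)

    @property
    def window_duration_s(self) -> float:
        return self.duration_s / self.n_windows

    @model_validator(mode="after")
    def _validate(self) -> "SimulationConfig":
        if self.fs_semg <= 2 * SEMG_BAND[1]:
            raise ValueError(
                f"fs_semg={self.fs_semg} violates Nyquist for the {SEMG_BAND} Hz band"
            )
        if self.fs_mmg <= 2 * MMG_BAND[1]:
            raise ValueError(
                f"fs_mmg={self.fs_mmg} violates Nyquist for the {MMG_BAND} Hz band"
            )
        # every window must hold >= 2 cycles of the lowest in-band frequency
        for mod in MODALITIES:
            low = BAND[mod][0]
            if self.window_duration_s < 2.0 / low:
                raise ValueError(
                    f"duration {self.duration_s}s is too short for {self.n_windows} "
                    f"windows holding 2 cycles of {low} Hz ({mod})"
                )
        if self.fatigue is None:
            object.__setattr__(
                self, "fatigue", default_fatigue_params(self.duration_s, self.muscles)
            )
        for mod in MODALITIES:
            params = self.fatigue.get(mod)
            if params is None or len(params) != len(self.muscles):
                raise ValueError(f"fatigue[{mod!r}] must list one entry per muscle")
            lo, hi = BAND[mod]
            width = self.spectral_width(mod)
            for p in params:
                for c in (p.baseline_center, p.peak_center):
                    if not (lo + 2 * width < c < hi - 2 * width):
                        raise ValueError(
                            f"{mod} center {c} Hz not inside pass band {lo}-{hi} Hz "
                            f"with 2*sigma={2 * width} margin"
                        )
        # stage 5 must be reachable: >= 20% decline for at least one muscle
        reachable = any(
            p.decline_rate * (1.0 - p.ascent_end_fraction) * self.duration_s >= 0.20
            for mod in MODALITIES
            for p in self.fatigue[mod]
        )
        if not reachable:
            raise ValueError("no channel declines >= 20% of peak; stage 5 unreachable")
        return self

    def spectral_width(self, modality: str) -> float:
        return self.semg_spectral_width if modality == "semg" else self.mmg_spectral_width

    def fs(self, modality: str) -> float:
        return self.fs_semg if modality == "semg" else self.fs_mmg

    def params_for(self, muscle_id: str, modality: str) -> MuscleFatigueParams:
        try:
            idx = self.muscles.index(muscle_id)
        except ValueError as exc:
            raise KeyError(f"unknown muscle {muscle_id!r}") from exc
        return self.fatigue[modality][idx]


class PreprocessConfig(StrictModel):
    order: int = Field(default=4, ge=1)
    semg_band: tuple[float, float] = SEMG_BAND
    mmg_band: tuple[float, float] = MMG_BAND
    rectify_before_features: bool = False


class FeatureConfig(StrictModel):
    n_windows: int = Field(default=120, ge=3)
    taper: Literal["none", "hann"] = "none"


class LabelingConfig(StrictModel):
    drop_thresholds: tuple[float, float, float, float] = (0.05, 0.10, 0.15, 0.20)

    @model_validator(mode="after")
    def _increasing(self) -> "LabelingConfig":
        t = self.drop_thresholds
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("drop thresholds must be strictly increasing")
        return self


class ClassifyConfig(StrictModel):
    variants: tuple[str, ...] = ("semg", "mmg", "fused")
    families: tuple[str, ...] = ("svm_rbf", "svm_att", "mlp", "mlp_att")
    test_fraction: float = Field(default=0.2, gt=0.0, lt=1.0)
    stratified: bool = False
    svm_c: float = 10.0
    mlp_hidden: tuple[int, ...] = (180, 180, 180)
    mlp_max_iter: int = 200
    encoder_layers: int = 2
    encoder_heads: int = 4
    encoder_dim: int = 8
    encoder_ff_dim: int = 16
    encoder_head_hidden: int = 32
    encoder_epochs: int = 120
    encoder_batch: int = 256
    encoder_lr: float = 5e-3


class EvaluateConfig(StrictModel):
    n_repeats: int = Field(default=10, ge=2)
    alpha: float = Field(default=0.02, gt=0, lt=1)
    equal_var: bool = False  # Welch by default


class PipelineConfig(StrictModel):
    """Top-level configuration tying all stages together."""

    seed: int = Field(default=0, ge=0)
    simulate: SimulationConfig = Field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    features: FeatureConfig = Field(default_factory=FeatureConfig)
    labeling: LabelingConfig = Field(default_factory=LabelingConfig)
    classify: ClassifyConfig = Field(default_factory=ClassifyConfig)
    evaluate: EvaluateConfig = Field(default_factory=EvaluateConfig)

    @model_validator(mode="after")
    def _propagate_seed(self) -> "PipelineConfig":
        # the global seed also seeds the simulator unless set explicitly
        if "simulate" not in self.model_fields_set or "seed" not in self.simulate.model_fields_set:
            object.__setattr__(self.simulate, "seed", self.seed)
        return self

    def resolved_dict(self) -> dict:
        return json.loads(self.model_dump_json())

    def config_hash(self) -> str:
        payload = json.dumps(self.resolved_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load and strictly validate a YAML pipeline configuration."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)
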
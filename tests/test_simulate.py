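"""Generator: trajectory shape, determinism, spectral confinement, staging truth."""

import numpy as np
import pytest

from myofatigue.config import BAND, MuscleFatigueParams, SimulationConfig
from myofatigue.simulate import (
    TrajectoryClampWarning,
    _piecewise_trajectory,
    _window_midpoints,
    ground_truth_stages,
    mpf_trajectory,
    simulate_subject,
    stage_scan,
)
from myofatigue.spectral import Window, mean_power_frequency, periodogram_psd


def test_movement_period_from_cadence():
    cfg = SimulationConfig()
    assert cfg.movement_period_s == pytest.approx(4 / (180 / 60))  # 1.333 s


class TestTrajectory:
    def test_starts_at_baseline_and_peaks_at_peak_center(self):
        cfg = SimulationConfig()
        muscle = cfg.muscles[0]
        p = cfg.params_for(muscle, "semg")
        traj = mpf_trajectory(cfg, muscle, "semg")
        # window 0 midpoint sits a half-window into the shallow dip
        assert traj[0] == pytest.approx(p.baseline_center, rel=0.01)
        assert traj.max() == pytest.approx(p.peak_center, rel=0.01)
        peak_w = int(np.argmax(traj))
        assert peak_w == pytest.approx(p.ascent_end_fraction * cfg.n_windows, abs=1)

    def test_decline_rate_sets_fractional_drop(self):
        # drop of 10% of peak must be reached where rate * elapsed = 0.10
        cfg = SimulationConfig()
        duration = cfg.duration_s
        t = _window_midpoints(duration, 120)
        t_peak = 0.5 * duration
        p = MuscleFatigueParams(
            baseline_center=90,
            peak_center=110,
            rise_start_fraction=0.2,
            ascent_end_fraction=0.5,
            decline_rate=0.10 / (t[90] - t_peak),
        )
        traj = _piecewise_trajectory(p, t, duration, BAND["semg"], 4.0)
        assert traj[90] == pytest.approx(0.9 * p.peak_center, rel=1e-9)

    def test_decline_clamped_at_band_edge_with_warning(self):
        p = MuscleFatigueParams(
            baseline_center=30,
            peak_center=40,
            rise_start_fraction=0.2,
            ascent_end_fraction=0.4,
            decline_rate=0.02,  # would dive far below 10 Hz
        )
        with pytest.warns(TrajectoryClampWarning):
            traj = _piecewise_trajectory(
                p, _window_midpoints(300, 120), 300, BAND["mmg"], 1.2
            )
        assert traj.min() >= BAND["mmg"][0]


class TestConfigValidation:
    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            SimulationConfig(fs_semg=800)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            SimulationConfig(duration_s=20)

    def test_center_outside_band_rejected(self):
        from myofatigue.config import default_fatigue_params

        fat = default_fatigue_params(300.0)
        fat["mmg"][0] = MuscleFatigueParams(
            baseline_center=48,
            peak_center=49.9,
            rise_start_fraction=0.3,
            ascent_end_fraction=0.6,
            decline_rate=0.001,
        )
        with pytest.raises(ValueError, match="pass band"):
            SimulationConfig(fatigue=fat)


class TestGroundTruthStages:
    def test_never_declining_trajectory_stays_below_stage_2(self):
        traj = np.concatenate([np.linspace(90, 89, 10), np.linspace(89, 110, 110)])
        stages = stage_scan(traj)
        assert stages.max() <= 1

    def test_five_percent_drop_reaches_stage_2(self):
        # drop crosses 5% of the normalized range at a known window
        traj = np.concatenate(
            [np.linspace(100, 98, 30), np.linspace(98, 120, 40), np.linspace(120, 90, 51)[1:]]
        )
        stages = stage_scan(traj)
        y = (traj - traj.min()) / (traj.max() - traj.min())
        first2 = int(np.argmax(stages >= 2))
        assert (1 - y[first2]) >= 0.05
        assert (1 - y[first2 - 1]) < 0.05 or stages[first2 - 1] >= 2

    def test_intermediate_drop_maps_between_thresholds(self):
        # 12% drop (normalized) must be stage 3: past 10%, short of 15%
        base = np.concatenate(
            [np.linspace(50, 49, 10), np.linspace(49, 100, 50), np.linspace(100, 88, 61)[1:]]
        )
        # normalized drop at the end: (100-88)/(100-49) = 23.5% -> stage 5 at end
        stages = stage_scan(base)
        y = (base - base.min()) / (base.max() - base.min())
        drops = 1 - y
        in_band = (drops >= 0.10) & (drops < 0.15) & (np.arange(len(y)) > np.argmax(y))
        assert np.all(stages[in_band] >= 3)

    def test_stages_non_decreasing_and_ordered(self):
        cfg = SimulationConfig()
        for muscle in cfg.muscles:
            for mod in ("semg", "mmg"):
                st = ground_truth_stages(cfg, muscle, mod)
                assert np.all(np.diff(st) >= 0)
                assert st[0] == 0 and st.max() == 5
                # stage 0 precedes 1 precedes the peak
                peak = int(np.argmax(mpf_trajectory(cfg, muscle, mod)))
                assert np.all(st[:1] == 0) and st[peak] == 1


class TestSimulateSubject:
    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(n_subjects=1, seed=11)
        recs_a, _ = simulate_subject(cfg, 0)
        recs_b, _ = simulate_subject(cfg, 0)
        for a, b in zip(recs_a, recs_b):
            assert np.array_equal(a.samples, b.samples)

    def test_channel_count_lengths_and_finiteness(self, one_subject):
        cfg, recs, _ = one_subject
        assert len(recs) == 12
        for rec in recs:
            assert len(rec.samples) == round(rec.fs * cfg.duration_s)
            assert np.all(np.isfinite(rec.samples))

    def test_spectral_confinement(self, one_subject):
        """>= 95% of channel power inside the modality band (artifacts off)."""
        _, recs, _ = one_subject
        for rec in recs[:3] + recs[6:9]:  # subset of each modality
            w = Window(0, rec.samples, rec.fs)
            psd = periodogram_psd(w)
            lo, hi = BAND[rec.modality]
            mask = (psd.frequencies >= lo) & (psd.frequencies <= hi)
            frac = psd.densities[mask].sum() / psd.densities.sum()
            assert frac >= 0.95

    def test_stationary_center_recovered(self):
        """Noise-free stationary synthesis at 100 Hz: window MPF within 3 Hz."""
        from myofatigue.simulate import _synthesize_channel

        rng = np.random.default_rng(0)
        x = _synthesize_channel(
            rng,
            centers_hz=np.full(120, 100.0),
            width=4.0,
            band=BAND["semg"],
            fs=2000.0,
            duration_s=300.0,
            n_windows=120,
            movement_period_s=4 / 3,
            envelope_floor=0.3,
            noise_floor=0.0,
        )
        from myofatigue.spectral import segment_signal

        mpfs = [
            mean_power_frequency(periodogram_psd(w)) for w in segment_signal(x, 2000.0, 120)
        ]
        assert np.mean(np.abs(np.array(mpfs) - 100.0) <= 3.0) >= 0.95

    def test_ground_truth_fused_body_monotone(self, one_subject):
        _, _, gt = one_subject
        assert np.all(np.diff(gt.body) >= 0)
        assert gt.body.min() >= 0 and gt.body.max() <= 5
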
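"""Shared fixtures: small simulated cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from myofatigue.config import PipelineConfig, SimulationConfig
from myofatigue.pipeline import extract_features, label_cohort
from myofatigue.simulate import simulate_subject


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig(seed=7, simulate={"n_subjects": 2})


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Two simulated subjects with features and fused labels."""
    recordings = []
    truths = {}
    for s in range(small_config.simulate.n_subjects):
        recs, gt = simulate_subject(small_config.simulate, s)
        recordings.extend(recs)
        truths[s] = gt
    mpf_df = extract_features(recordings, small_config)
    labels_df, body_states = label_cohort(mpf_df, small_config)
    return {
        "recordings": recordings,
        "truths": truths,
        "mpf": mpf_df,
        "labels": labels_df,
        "body_states": body_states,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def one_subject():
    """One default-condition subject with ground truth (moderate noise)."""
    cfg = SimulationConfig(seed=3)
    recs, gt = simulate_subject(cfg, 0)
    return cfg, recs, gt
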
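"""End-to-end orchestration: simulate -> preprocess -> features -> labels ->
datasets -> classifiers -> metrics, plus the repeated-seed experiments built
on top (stage recovery, fusion benefit).

Every run writes its fully resolved configuration, a config hash and a run
log (seeds, row counts -- no wall-clock values, so outputs are byte-for-byte
reproducible), per-channel MPF tables, label tables, dataset CSVs and metric
JSONs into the output directory.  A stage failure aborts with the stage name;
artifacts of completed stages remain on disk.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import evaluate as ev
from .config import MODALITIES, PipelineConfig
from .labeling import StagingSpec, fuse_body_state, stage_muscle
from .preprocess import bandpass_filter, default_filter, rectify
from .simulate import GroundTruth, RawRecording, simulate_subject
from .spectral import mpf_series, peak_envelope

logger = logging.getLogger(__name__)

__all__ = [
    "StageError",
    "extract_features",
    "label_cohort",
    "build_datasets",
    "evaluate_combination",
    "run_pipeline",
    "recovery_experiment",
    "fusion_experiment",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _timed(stage: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s failed after %.1fs", stage, dt)
                raise StageError(stage, exc) from exc
            logger.info("stage %s done in %.1fs", stage, dt)
            return False

    return _Ctx()


def extract_features(recordings: list[RawRecording], config: PipelineConfig) -> pd.DataFrame:
    """Band-pass (optionally rectify) each channel and compute its MPF series.

    Returns a long table: subject, muscle, modality, window, mpf_hz, mpf_norm.
    """
    rows = []
    for rec in recordings:
        filt = bandpass_filter(rec, default_filter(rec.modality, config.preprocess.order))
        if config.preprocess.rectify_before_features:
            filt = rectify(filt)
        s = mpf_series(
            filt.samples,
            filt.fs,
            subject_id=rec.subject_id,
            muscle_id=rec.muscle_id,
            modality=rec.modality,
            n_windows=config.features.n_windows,
            taper=config.features.taper,
        )
        rows.append(
            pd.DataFrame(
                {
                    "subject": rec.subject_id,
                    "muscle": rec.muscle_id,
                    "modality": rec.modality,
                    "window": np.arange(len(s.raw)),
                    "mpf_hz": s.raw,
                    "mpf_norm": s.normalized,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def label_cohort(
    mpf_df: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, dict[int, np.ndarray]]:
    """Stage every channel and fuse per-subject body states.

    Returns a wide label table (subject, window, one column per channel, body,
    provenance) and the per-subject body-state arrays.
    """
    spec = StagingSpec(config.labeling.drop_thresholds)
    label_rows = []
    body_states: dict[int, np.ndarray] = {}
    for subject, group in mpf_df.groupby("subject"):
        series_list = []
        cols: dict[str, np.ndarray] = {}
        for modality in MODALITIES:
            for muscle in sorted(group["muscle"].unique()):
                chan = group[(group["muscle"] == muscle) & (group["modality"] == modality)]
                chan = chan.sort_values("window")
                env = peak_envelope(chan["mpf_norm"].to_numpy())
                st = stage_muscle(env, spec, muscle_id=muscle, modality=modality)
                series_list.append(st)
                cols[f"{modality}:{muscle}"] = st.labels
        body = fuse_body_state(series_list)
        body_states[int(subject)] = body.labels
        df = pd.DataFrame({"subject": subject, "window": np.arange(len(body.labels))})
        for name, labels in cols.items():
            df[name] = labels
        df["body"] = body.labels
        df["provenance"] = body.provenance
        label_rows.append(df)
    return pd.concat(label_rows, ignore_index=True), body_states


def build_datasets(
    mpf_df: pd.DataFrame, body_states: dict[int, np.ndarray], variants: tuple[str, ...]
) -> dict[str, clf.FatigueDataset]:
    return {v: clf.assemble_dataset(mpf_df, body_states, v) for v in variants}


def evaluate_combination(
    dataset: clf.FatigueDataset,
    family: str,
    config: PipelineConfig,
    seed: int,
    encoder_cache: dict | None = None,
) -> ev.MetricsReport:
    """One train/test cycle of one (variant, family) combination.

    The ``mlp_att`` and ``svm_att`` families pre-train the identical attention
    encoder (same data, same seed); when ``encoder_cache`` is supplied the
    fitted encoder is shared between them instead of trained twice.
    """
    c = config.classify
    split = clf.SplitSpec(test_fraction=c.test_fraction, seed=seed, stratified=c.stratified)
    train_idx, test_idx = clf.train_test_split(dataset, split)
    spec = clf.ClassifierSpec(
        family=family,
        svm_c=c.svm_c,
        mlp_hidden=c.mlp_hidden,
        mlp_max_iter=c.mlp_max_iter,
        encoder=dict(
            n_layers=c.encoder_layers,
            n_heads=c.encoder_heads,
            d_model=c.encoder_dim,
            d_ff=c.encoder_ff_dim,
            head_hidden=c.encoder_head_hidden,
            epochs=c.encoder_epochs,
            batch_size=c.encoder_batch,
            lr=c.encoder_lr,
        ),
        seed=seed,
    )
    prefit = None
    if encoder_cache is not None and family in ("mlp_att", "svm_att"):
        prefit = encoder_cache.get((dataset.variant, seed))
    model = clf.train_classifier(
        dataset.features[train_idx], dataset.labels[train_idx], spec, prefit_encoder=prefit
    )
    if encoder_cache is not None and family in ("mlp_att", "svm_att") and prefit is None:
        encoder_cache[(dataset.variant, seed)] = (
            model.encoder if family == "svm_att" else model
        )
    pred = clf.predict_labels(model, dataset.features[test_idx])
    cm = ev.confusion_matrix(dataset.labels[test_idx], pred)
    return ev.classification_metrics(
        cm,
        meta={
            "variant": dataset.variant,
            "family": family,
            "seed": seed,
            "n_train": len(train_idx),
            "n_test": len(test_idx),
        },
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and write all artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    (outdir / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.resolved_dict(), sort_keys=True)
    )
    log: dict = {"config_hash": cfg_hash, "seed": config.seed, "stages": {}}

    with _timed("simulate"):
        recordings: list[RawRecording] = []
        truths: dict[int, GroundTruth] = {}
        for s in range(config.simulate.n_subjects):
            recs, gt = simulate_subject(config.simulate, s)
            recordings.extend(recs)
            truths[s] = gt
        log["stages"]["simulate"] = {"n_channels": len(recordings)}

    with _timed("features"):
        mpf_df = extract_features(recordings, config)
        mpf_df.to_csv(outdir / "mpf.csv", index=False)
        log["stages"]["features"] = {"n_rows": len(mpf_df)}

    with _timed("labeling"):
        labels_df, body_states = label_cohort(mpf_df, config)
        labels_df.to_csv(outdir / "labels.csv", index=False)
        truth_rows = []
        for s, gt in truths.items():
            df = pd.DataFrame({"subject": s, "window": np.arange(len(gt.body))})
            for (muscle, modality), stages in gt.stages.items():
                df[f"{modality}:{muscle}"] = stages
            df["body"] = gt.body
            truth_rows.append(df)
        pd.concat(truth_rows, ignore_index=True).to_csv(outdir / "ground_truth.csv", index=False)
        log["stages"]["labeling"] = {"n_subjects": len(body_states)}

    with _timed("datasets"):
        datasets = build_datasets(mpf_df, body_states, config.classify.variants)
        (outdir / "datasets").mkdir(exist_ok=True)
        for v, ds in datasets.items():
            ds.to_frame().to_csv(outdir / "datasets" / f"{v}.csv", index=False)
        log["stages"]["datasets"] = {v: ds.n_rows for v, ds in datasets.items()}

    reports: dict[tuple[str, str], ev.MetricsReport] = {}
    with _timed("classify"):
        (outdir / "metrics").mkdir(exist_ok=True)
        cache: dict = {}
        for v in config.classify.variants:
            for fam in config.classify.families:
                rep = evaluate_combination(datasets[v], fam, config, config.seed, cache)
                reports[(v, fam)] = rep
                (outdir / "metrics" / f"{v}_{fam}.json").write_text(
                    json.dumps(rep.to_dict(), sort_keys=True, indent=2)
                )
        summary = pd.DataFrame(
            [
                {"variant": v, "family": f, "test_accuracy": r.overall_accuracy}
                for (v, f), r in sorted(reports.items())
            ]
        )
        summary.to_csv(outdir / "summary.csv", index=False)
        log["stages"]["classify"] = {"n_reports": len(reports)}

    (outdir / "run.json").write_text(json.dumps(log, sort_keys=True, indent=2))
    return {
        "config_hash": cfg_hash,
        "mpf": mpf_df,
        "labels": labels_df,
        "body_states": body_states,
        "truths": truths,
        "datasets": datasets,
        "reports": reports,
    }


# ---------------------------------------------------------------------------
# repeated-seed experiments


def recovery_experiment(
    config: PipelineConfig, n_seeds: int = 10, base_seed: int = 0
) -> pd.DataFrame:
    """Per-seed staging recovery of one simulated subject against ground truth.

    For each seed: simulate subject 0, run the feature/staging path, and
    compare the estimated peak window and per-window stages of all 12 channels
    with the noiseless truth.
    """
    rows = []
    for i in range(n_seeds):
        sim = config.simulate.model_copy(update={"seed": base_seed + i})
        recs, gt = simulate_subject(sim, 0)
        peak_errs, agreements = [], []
        spec = StagingSpec(config.labeling.drop_thresholds)
        for rec in recs:
            filt = bandpass_filter(rec, default_filter(rec.modality, config.preprocess.order))
            s = mpf_series(filt.samples, filt.fs, n_windows=config.features.n_windows)
            env = peak_envelope(s.normalized)
            st = stage_muscle(env, spec)
            key = (rec.muscle_id, rec.modality)
            peak_errs.append(abs(env.peak_index - gt.peak_windows[key]))
            agreements.append(float(np.mean(st.labels == gt.stages[key])))
        rows.append(
            {
                "seed": base_seed + i,
                "median_peak_error": float(np.median(peak_errs)),
                "max_peak_error": float(np.max(peak_errs)),
                "mean_stage_agreement": float(np.mean(agreements)),
                "min_stage_agreement": float(np.min(agreements)),
            }
        )
    return pd.DataFrame(rows)


def fusion_experiment(
    config: PipelineConfig, n_seeds: int = 10, base_seed: int = 0, with_artifacts: bool = True
) -> pd.DataFrame:
    """Test accuracy of every (variant, family) combination over several seeds.

    Each seed re-simulates the cohort (with complementary artifacts enabled by
    default), re-derives features and labels, re-splits and re-trains.  The
    returned long table has one row per (seed, variant, family).
    """
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        cfg = config.model_copy(deep=True)
        object.__setattr__(cfg, "seed", seed)
        sim = cfg.simulate.model_copy(deep=True, update={"seed": seed})
        sim.artifacts.enabled = with_artifacts
        object.__setattr__(cfg, "simulate", sim)

        recordings = []
        body_states = {}
        for s in range(cfg.simulate.n_subjects):
            recs, _ = simulate_subject(cfg.simulate, s)
            recordings.extend(recs)
        mpf_df = extract_features(recordings, cfg)
        _, body_states = label_cohort(mpf_df, cfg)
        datasets = build_datasets(mpf_df, body_states, cfg.classify.variants)
        cache: dict = {}
        for v in cfg.classify.variants:
            for fam in cfg.classify.families:
                rep = evaluate_combination(datasets[v], fam, cfg, seed, cache)
                rows.append(
                    {
                        "seed": seed,
                        "variant": v,
                        "family": fam,
                        "test_accuracy": rep.overall_accuracy,
                    }
                )
        logger.info("fusion experiment seed %d done", seed)
    return pd.DataFrame(rows)
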
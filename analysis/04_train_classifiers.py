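"""Train the four classifier families on the three dataset variants.

Builds the 6-dim sEMG, 6-dim MMG and 12-dim fused datasets from the MPF
features and fused body-state labels, splits 80/20, and evaluates
SVM+RBF, SVM+attention, the 3x180 BP network and attention+MLP on each.
Writes the per-combination metric reports and a summary grid.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from myofatigue.config import PipelineConfig
from myofatigue.pipeline import build_datasets, evaluate_combination

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--mpf", type=Path, default=Path("results/mpf.csv"))
parser.add_argument("--labels", type=Path, default=Path("results/labels.csv"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

cfg = PipelineConfig(seed=args.seed)
mpf_df = pd.read_csv(args.mpf)
labels_df = pd.read_csv(args.labels)
body = {
    int(s): g.sort_values("window")["body"].to_numpy() for s, g in labels_df.groupby("subject")
}
datasets = build_datasets(mpf_df, body, cfg.classify.variants)

(args.out / "metrics").mkdir(parents=True, exist_ok=True)
rows = []
cache: dict = {}
for variant in cfg.classify.variants:
    for family in cfg.classify.families:
        rep = evaluate_combination(datasets[variant], family, cfg, cfg.seed, cache)
        (args.out / "metrics" / f"{variant}_{family}.json").write_text(
            json.dumps(rep.to_dict(), sort_keys=True, indent=2)
        )
        rows.append(
            {
                "variant": variant,
                "family": family,
                "accuracy": rep.overall_accuracy,
                "precision": rep.macro["precision"],
                "recall": rep.macro["recall"],
                "specificity": rep.macro["specificity"],
                "f1": rep.macro["f1"],
            }
        )

summary = pd.DataFrame(rows)
summary.to_csv(args.out / "classification_summary.csv", index=False)
print("single-split classification results (macro metrics):")
print(summary.round(4).to_string(index=False))
best = summary.loc[summary.accuracy.idxmax()]
print(f"\nbest combination: {best.variant}/{best.family} at accuracy {best.accuracy:.4f}")
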
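"""Confusion matrices, multi-class metrics, repeated runs and the t-test.

The five metrics are computed from one-vs-rest tallies of the 6x6 confusion
matrix:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * recall / (precision + recall)

Overall accuracy is trace / total.  Per-class metrics with a zero denominator
are reported as undefined (None) and excluded from the macro average; micro
averages are emitted alongside for transparency.  Repeated-run comparison uses
a two-sample Welch t-test (pooled variance available via ``equal_var=True``)
at significance level alpha = 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .config import N_STAGES

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "TTestResult",
    "RepeatResult",
    "confusion_matrix",
    "classification_metrics",
    "repeat_runs",
    "two_sample_ttest",
    "mean_sd_table",
    "ttest_table",
]


@dataclass
class ConfusionMatrix:
    """6x6 count matrix; rows are true classes, columns predicted."""

    matrix: np.ndarray
    n_classes: int = N_STAGES

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        if self.matrix.shape != (self.n_classes, self.n_classes):
            raise ValueError(f"expected {(self.n_classes,) * 2} matrix")
        if np.any(self.matrix < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def tallies(self, cls: int) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, TN, FP, FN) for one class."""
        tp = int(self.matrix[cls, cls])
        fn = int(self.matrix[cls].sum() - tp)
        fp = int(self.matrix[:, cls].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = N_STAGES
) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label series differ in length")
    m = _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))
    return ConfusionMatrix(m, n_classes)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


@dataclass
class MetricsReport:
    """Overall accuracy plus per-class / macro / micro metrics for one run."""

    overall_accuracy: float
    per_class: dict[int, dict[str, Optional[float]]]
    macro: dict[str, Optional[float]]
    micro: dict[str, float]
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "macro": self.macro,
            "micro": self.micro,
            "meta": self.meta,
        }


def classification_metrics(cm: ConfusionMatrix, meta: dict | None = None) -> MetricsReport:
    """The five metrics from one-vs-rest tallies, macro- and micro-averaged."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class: dict[int, dict[str, Optional[float]]] = {}
    sums = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for c in range(cm.n_classes):
        tp, tn, fp, fn = cm.tallies(c)
        sums["tp"] += tp
        sums["tn"] += tn
        sums["fp"] += fp
        sums["fn"] += fn
        precision = _ratio(tp, tp + fp)
        recall = _ratio(tp, tp + fn)
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision is not None and recall is not None and (precision + recall) > 0
            else None
        )
        per_class[c] = {
            "accuracy": _ratio(tp + tn, tp + tn + fp + fn),
            "precision": precision,
            "recall": recall,
            "specificity": _ratio(tn, tn + fp),
            "f1": f1,
        }
    macro: dict[str, Optional[float]] = {}
    for name in ("accuracy", "precision", "recall", "specificity", "f1"):
        defined = [v[name] for v in per_class.values() if v[name] is not None]
        macro[name] = float(np.mean(defined)) if defined else None
    micro = {
        "precision": sums["tp"] / (sums["tp"] + sums["fp"]),
        "recall": sums["tp"] / (sums["tp"] + sums["fn"]),
        "specificity": sums["tn"] / (sums["tn"] + sums["fp"]),
    }
    micro["f1"] = (
        2 * micro["precision"] * micro["recall"] / (micro["precision"] + micro["recall"])
        if micro["precision"] + micro["recall"] > 0
        else 0.0
    )
    return MetricsReport(
        overall_accuracy=float(np.trace(cm.matrix) / cm.total),
        per_class=per_class,
        macro=macro,
        micro=micro,
        meta=meta or {},
    )


@dataclass
class RepeatResult:
    accuracies: list[float]
    meta: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1))

    def format_mean_sd(self, percent: bool = True) -> str:
        if percent:
            return f"{100 * self.mean:.2f} ± {100 * self.sd:.2f}%"
        return f"{self.mean:.4f} ± {self.sd:.4f}"


def repeat_runs(
    run: Callable[[int], float], n_repeats: int = 10, base_seed: int = 0, meta: dict | None = None
) -> RepeatResult:
    """Run ``run(seed)`` for ``n_repeats`` distinct derived seeds.

    Each repetition re-draws everything the seed controls (split and model
    initialization).  Any failure aborts with the run index.
    """
    if n_repeats < 2:
        raise ValueError("need at least 2 repeats")
    accs: list[float] = []
    for i in range(n_repeats):
        try:
            accs.append(float(run(base_seed + i)))
        except Exception as exc:  # noqa: BLE001 - re-raise with run index
            raise RuntimeError(f"repeat run {i} failed") from exc
    return RepeatResult(accuracies=accs, meta=meta or {})


@dataclass
class TTestResult:
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int
    alpha: float = 0.02

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def two_sample_ttest(
    acc_a, acc_b, alpha: float = 0.02, equal_var: bool = False
) -> TTestResult:
    """Two-sample t-test on two accuracy samples (Welch by default).

    Two zero-variance samples with equal means give t = 0, p = 1 by
    convention.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return TTestResult(0.0, 1.0, len(a), len(b), alpha)
        return TTestResult(np.inf if np.mean(a) > np.mean(b) else -np.inf, 0.0, len(a), len(b), alpha)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(t), float(p), len(a), len(b), alpha)


def mean_sd_table(results: dict[tuple[str, str], RepeatResult]) -> pd.DataFrame:
    """Accuracy mean +/- s.d. per (variant, family) combination."""
    rows = [
        {
            "variant": variant,
            "family": family,
            "mean_accuracy": r.mean,
            "sd_accuracy": r.sd,
            "mean_sd": r.format_mean_sd(),
        }
        for (variant, family), r in sorted(results.items())
    ]
    return pd.DataFrame(rows)


def ttest_table(
    results: dict[str, RepeatResult], reference: str, alpha: float = 0.02, equal_var: bool = False
) -> pd.DataFrame:
    """Pairwise t-tests of each family against a reference family."""
    ref = results[reference]
    rows = [{"family": reference, "t_statistic": np.nan, "p_value": np.nan, "significant": ""}]
    for family, r in results.items():
        if family == reference:
            continue
        tt = two_sample_ttest(ref.accuracies, r.accuracies, alpha=alpha, equal_var=equal_var)
        rows.append(
            {
                "family": family,
                "t_statistic": tt.t_statistic,
                "p_value": tt.p_value,
                "significant": bool(tt.significant),
            }
        )
    return pd.DataFrame(rows)
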
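"""Dataset assembly, train/test split and the four classifier families.

The three dataset variants are the 6-dimensional sEMG feature set, the
6-dimensional MMG set and the 12-dimensional fused set; each row is one
(subject, window) with normalized MPF features and the fused body-state label.
Classifier families:

``svm_rbf``
    support vector machine with an RBF kernel;
``mlp``
    back-propagation multilayer perceptron, three hidden layers of 180 units;
``mlp_att``
    the scaled dot-product attention encoder trained jointly with an MLP head;
``svm_att``
    the attention encoder pre-trained with its MLP head, then frozen, its
    pooled encodings fed to an RBF SVM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split as _sk_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .attention import AttentionEncoderClassifier
from .config import MODALITIES, N_STAGES

logger = logging.getLogger(__name__)

__all__ = [
    "VARIANTS",
    "FAMILIES",
    "FatigueDataset",
    "SplitSpec",
    "ClassifierSpec",
    "assemble_dataset",
    "train_test_split",
    "train_classifier",
    "predict_labels",
    "attention_encode",
]

VARIANTS: tuple[str, ...] = ("semg", "mmg", "fused")
FAMILIES: tuple[str, ...] = ("svm_rbf", "svm_att", "mlp", "mlp_att")


@dataclass
class FatigueDataset:
    """Feature matrix + body-state labels for one variant."""

    variant: str
    features: np.ndarray  # (n_rows, 6 or 12), values in [0, 1]
    labels: np.ndarray  # (n_rows,), body state in {0..5}
    provenance: pd.DataFrame  # columns: subject, window
    feature_names: list[str]

    def __post_init__(self) -> None:
        expected = 12 if self.variant == "fused" else 6
        if self.features.shape[1] != expected:
            raise ValueError(
                f"variant {self.variant!r} needs {expected} feature columns, "
                f"got {self.features.shape[1]}"
            )
        if not np.all((self.labels >= 0) & (self.labels < N_STAGES)):
            raise ValueError("labels must lie in {0..5}")

    @property
    def n_rows(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        df = self.provenance.copy()
        for j, name in enumerate(self.feature_names):
            df[name] = self.features[:, j]
        df["label"] = self.labels
        return df


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.2
    seed: int = 0
    stratified: bool = False


@dataclass
class ClassifierSpec:
    family: str = "svm_rbf"
    svm_c: float = 10.0
    svm_gamma: str | float = "scale"
    mlp_hidden: tuple[int, ...] = (180, 180, 180)
    mlp_max_iter: int = 200
    encoder: dict = field(default_factory=dict)  # AttentionEncoderClassifier kwargs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")


def _variant_columns(variant: str, muscles: list[str]) -> list[tuple[str, str]]:
    if variant == "semg":
        return [("semg", m) for m in muscles]
    if variant == "mmg":
        return [("mmg", m) for m in muscles]
    if variant == "fused":
        return [(mod, m) for mod in MODALITIES for m in muscles]
    raise ValueError(f"unknown variant {variant!r}")


def assemble_dataset(
    mpf_norm: pd.DataFrame,
    body_states: dict[int, np.ndarray],
    variant: str,
) -> FatigueDataset:
    """Build one dataset variant from normalized MPF features and body states.

    ``mpf_norm`` is a long table with columns subject, muscle, modality,
    window, mpf_norm.  Subjects missing any channel of the variant are dropped
    with a logged warning.
    """
    muscles = sorted(mpf_norm["muscle"].unique())
    cols = _variant_columns(variant, muscles)
    wide = mpf_norm.pivot_table(
        index=["subject", "window"], columns=["modality", "muscle"], values="mpf_norm"
    )
    rows, labels, prov = [], [], []
    for subject, body in sorted(body_states.items()):
        try:
            block = wide.loc[subject].loc[:, cols]
        except KeyError:
            logger.warning("subject %s lacks channels for variant %s; dropped", subject, variant)
            continue
        if block.isna().any().any() or len(block) != len(body):
            logger.warning("subject %s has incomplete features; dropped", subject)
            continue
        rows.append(block.to_numpy())
        labels.append(np.asarray(body, dtype=int))
        prov.append(pd.DataFrame({"subject": subject, "window": block.index.to_numpy()}))
    if not rows:
        raise ValueError("no complete subjects for dataset assembly")
    return FatigueDataset(
        variant=variant,
        features=np.vstack(rows),
        labels=np.concatenate(labels),
        provenance=pd.concat(prov, ignore_index=True),
        feature_names=[f"{mod}:{m}" for mod, m in cols],
    )


def train_test_split(
    dataset: FatigueDataset, spec: SplitSpec = SplitSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Row indices of the train and test sets (80/20 by default).

    The draw is plain random; if some class present in the full dataset is
    absent from the training rows, the split is re-drawn stratified (and
    logged) so every classifier sees all classes.
    """
    idx = np.arange(dataset.n_rows)
    strat = dataset.labels if spec.stratified else None
    train, test = _sk_split(
        idx, test_size=spec.test_fraction, random_state=spec.seed, stratify=strat
    )
    missing = set(np.unique(dataset.labels)) - set(np.unique(dataset.labels[train]))
    if missing:
        logger.warning("classes %s missing from train rows; re-drawing stratified", missing)
        try:
            train, test = _sk_split(
                idx, test_size=spec.test_fraction, random_state=spec.seed, stratify=dataset.labels
            )
        except ValueError:
            # singleton classes cannot be stratified: move one row of each
            # train-absent class from test to train (deterministic)
            train, test = list(train), list(test)
            for cls in sorted(missing):
                j = next(i for i in test if dataset.labels[i] == cls)
                test.remove(j)
                train.append(j)
    return np.sort(train), np.sort(test)


class _AttentionSVM:
    """Attention encoder pre-trained with an MLP head, frozen, feeding an SVM."""

    def __init__(self, encoder: AttentionEncoderClassifier, svm: SVC) -> None:
        self.encoder = encoder
        self.svm = svm

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_AttentionSVM":
        if self.encoder.weights_ is None:
            self.encoder.fit(X, y)
        self.svm.fit(self.encoder.encode(X), y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svm.predict(self.encoder.encode(X))


def _build(spec: ClassifierSpec):
    if spec.family == "svm_rbf":
        return SVC(kernel="rbf", C=spec.svm_c, gamma=spec.svm_gamma, random_state=spec.seed)
    if spec.family == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=spec.mlp_hidden,
            max_iter=spec.mlp_max_iter,
            random_state=spec.seed,
        )
    enc_kwargs = dict(seed=spec.seed)
    enc_kwargs.update(spec.encoder)
    if spec.family == "mlp_att":
        return AttentionEncoderClassifier(**enc_kwargs)
    if spec.family == "svm_att":
        return _AttentionSVM(
            AttentionEncoderClassifier(**enc_kwargs),
            SVC(kernel="rbf", C=spec.svm_c, gamma=spec.svm_gamma, random_state=spec.seed),
        )
    raise ValueError(spec.family)


def train_classifier(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec, prefit_encoder=None):
    """Fit one classifier family on training rows; rejects single-class input.

    ``prefit_encoder`` lets the attention families reuse an encoder already
    trained on the same rows with the same seed instead of training it again.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training rows cover fewer than 2 classes")
    model = _build(spec)
    if prefit_encoder is not None:
        if spec.family == "mlp_att":
            return prefit_encoder
        if spec.family == "svm_att":
            model.encoder = prefit_encoder
    import warnings as _warnings

    with _warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        _warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def predict_labels(model, X: np.ndarray) -> np.ndarray:
    """Predict one stage label in {0..5} per row."""
    X = np.asarray(X, dtype=float)
    pred = np.asarray(model.predict(X), dtype=int)
    if pred.shape != (len(X),):
        raise ValueError("prediction shape mismatch")
    return pred


def attention_encode(X: np.ndarray, encoder: AttentionEncoderClassifier) -> np.ndarray:
    """Pooled encoder representation of feature rows (requires a fitted encoder)."""
    return encoder.encode(X)
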
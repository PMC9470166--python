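"""Session classification: dataset assembly, normalization, stratified CV.

The question the classifier answers: can the 18 microstructure features of
a single drinking session predict which experimental condition (fluid ×
virus, four classes) the animal belongs to?  The pipeline one-hot encodes
the labels, rescales every feature to [0, 1], splits with stratified k-fold
(k = 6) so the unequal class proportions are preserved in every fold, and
trains a fresh feedforward network per fold, reporting held-out accuracy
against a chance baseline.

Normalization is fit on the full table before cross-validation by default,
mirroring the analysed protocol; ``fold_safe=True`` instead fits the scaler
on each training fold only, avoiding the (mild) information leakage of the
default at the cost of comparability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError
from .features import FEATURE_NAMES
from .lickometer import CLASS_ORDER
from .mlp import MLP

__all__ = [
    "CVSplit",
    "NetworkSpec",
    "CVResult",
    "assemble_dataset",
    "minmax_normalize",
    "stratified_kfold",
    "train_evaluate",
    "cross_validate_features",
]


@dataclass(frozen=True)
class CVSplit:
    fold_index: int  # 1-based
    train_rows: np.ndarray
    test_rows: np.ndarray


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and training settings for one cross-validation run."""

    layer_widths: tuple[int, ...] = (2048, 512, 64, 4)
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0

    def small(self) -> "NetworkSpec":  # convenience for desk-scale runs
        return NetworkSpec((64, 32, 16, self.layer_widths[-1]),
                           self.learning_rate, self.epochs, self.batch_size, self.seed)


@dataclass
class CVResult:
    per_fold_accuracy: list[float]
    chance_accuracy: float
    uniform_chance_accuracy: float
    loss_curves: list[dict[str, list[float]]] = field(repr=False, default_factory=list)
    fold_sizes: list[tuple[int, int]] = field(default_factory=list)  # (train, test)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_fold_accuracy))

    @property
    def max_accuracy(self) -> float:
        return float(np.max(self.per_fold_accuracy))

    @property
    def accuracy_over_chance(self) -> float:
        return self.mean_accuracy / self.chance_accuracy

    def to_dict(self) -> dict:
        return {
            "per_fold_accuracy": self.per_fold_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "max_accuracy": self.max_accuracy,
            "chance_accuracy": self.chance_accuracy,
            "uniform_chance_accuracy": self.uniform_chance_accuracy,
            "accuracy_over_chance": self.accuracy_over_chance,
            "fold_sizes": self.fold_sizes,
            "loss_curves": self.loss_curves,
        }


def assemble_dataset(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Feature table → (n × 18 matrix, n × 4 one-hot labels).

    Row order follows the table (no dedup).  Classes are ordered
    water-ChR2, water-eGFP, alcohol-ChR2, alcohol-eGFP.
    """
    missing = [c for c in (*FEATURE_NAMES, "fluid", "virus") if c not in table.columns]
    if missing:
        raise ValidationError(f"feature table missing columns {missing}")
    if table[["fluid", "virus"]].isna().any().any():
        raise ValidationError("every row must carry fluid and virus labels")
    X = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    class_of = {fv: i for i, fv in enumerate(CLASS_ORDER)}
    try:
        idx = np.array(
            [class_of[(f, v)] for f, v in zip(table["fluid"], table["virus"])]
        )
    except KeyError as exc:
        raise ValidationError(f"unknown class label {exc.args[0]}") from exc
    Y = np.zeros((len(table), len(CLASS_ORDER)))
    Y[np.arange(len(table)), idx] = 1.0
    return X, Y


def minmax_normalize(
    X: np.ndarray, bounds: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Affinely map each column to [0, 1]; constant columns map to 0.

    Pass ``bounds`` (mins, maxes) to reuse a previously fitted scaling,
    e.g. training-fold bounds applied to a test fold.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValidationError("matrix contains non-finite entries")
    if bounds is None:
        lo, hi = X.min(axis=0), X.max(axis=0)
    else:
        lo, hi = bounds
    width = hi - lo
    safe = np.where(width > 0, width, 1.0)
    Z = (X - lo) / safe
    Z[:, width == 0] = 0.0
    if bounds is not None:  # reused bounds can leave values outside [0, 1]
        Z = np.clip(Z, 0.0, 1.0)
    return Z, (lo, hi)


def stratified_kfold(labels: np.ndarray, k: int = 6, seed: int = 0) -> list[CVSplit]:
    """Deterministic shuffled stratified k-fold over class-index labels.

    Every test fold's class proportions are within one sample of the global
    proportions; every class must have at least ``k`` members.
    """
    labels = np.asarray(labels)
    if labels.ndim == 2:  # accept one-hot
        labels = np.argmax(labels, axis=1)
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    counts = np.bincount(labels)
    small = np.nonzero((counts > 0) & (counts < k))[0]
    if small.size:
        raise ValidationError(f"classes {small.tolist()} have fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = []
    for i, (train, test) in enumerate(skf.split(np.zeros_like(labels), labels), start=1):
        splits.append(CVSplit(fold_index=i, train_rows=train, test_rows=test))
    return splits


def _chance_from_labels(Y: np.ndarray) -> tuple[float, float]:
    freq = Y.mean(axis=0)
    present = freq[freq > 0]
    return float(freq.max()), float(1.0 / len(present))


def train_evaluate(
    X: np.ndarray,
    Y: np.ndarray,
    splits: list[CVSplit],
    spec: NetworkSpec = NetworkSpec(),
    fold_safe: bool = False,
) -> CVResult:
    """Train one fresh network per fold; report held-out accuracies.

    ``X`` should already be [0, 1]-normalized unless ``fold_safe`` is set,
    in which case normalization is fit on each training fold here.  The
    chance baseline is the frequency of the modal class (the best constant
    guesser); the uniform 1/n_classes alternative is reported alongside.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    chance, uniform = _chance_from_labels(Y)
    accs: list[float] = []
    curves: list[dict[str, list[float]]] = []
    sizes: list[tuple[int, int]] = []
    for split in splits:
        overlap = np.intersect1d(split.train_rows, split.test_rows)
        if overlap.size:
            raise ValidationError(f"fold {split.fold_index} leaks rows {overlap[:5]}")
        Xtr, Xte = X[split.train_rows], X[split.test_rows]
        if fold_safe:
            Xtr, bounds = minmax_normalize(Xtr)
            Xte, _ = minmax_normalize(Xte, bounds=bounds)
        net = MLP(layer_widths=spec.layer_widths, learning_rate=spec.learning_rate)
        hist = net.fit(
            Xtr,
            Y[split.train_rows],
            epochs=spec.epochs,
            batch_size=spec.batch_size,
            seed=spec.seed + split.fold_index,
            eval_set=(Xte, Y[split.test_rows]),
        )
        accs.append(hist["test_accuracy"][-1])
        curves.append(hist)
        sizes.append((len(split.train_rows), len(split.test_rows)))
    return CVResult(
        per_fold_accuracy=accs,
        chance_accuracy=chance,
        uniform_chance_accuracy=uniform,
        loss_curves=curves,
        fold_sizes=sizes,
    )


def cross_validate_features(
    table: pd.DataFrame,
    k: int = 6,
    spec: NetworkSpec = NetworkSpec(),
    fold_safe: bool = False,
) -> CVResult:
    """Full pipeline on a labeled feature table: assemble → scale → CV → train."""
    X, Y = assemble_dataset(table)
    if not fold_safe:
        X, _ = minmax_normalize(X)
    splits = stratified_kfold(np.argmax(Y, axis=1), k=k, seed=spec.seed)
    return train_evaluate(X, Y, splits, spec, fold_safe=fold_safe)
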
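"""Linear SVM decoding of the two workload states and transfer-rate metrics.

Per subject and chromophore, the labeled window features are split 70:30
(stratified), z-scored with train-set statistics only, and classified with
a linear soft-margin SVM (hinge loss, decision f(x) = r.x + b).  Accuracy
is reported in percent; the Wolpaw information transfer rate converts it to
bits per trial and bits per minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix, extract_features
from .optics import HemodynamicSeries
from .paradigm import ParadigmSchedule

__all__ = [
    "SvmModel",
    "EvaluationResult",
    "split_70_30",
    "train_svm",
    "evaluate_subject",
    "itr_bits_per_trial",
    "dtr_bits_per_minute",
]

CHROMOPHORES = ("hbo", "hbr", "hbt")


@dataclass
class SvmModel:
    """Fitted linear SVM with its training-set standardization."""

    weights: np.ndarray  # r, in standardized feature space
    bias: float  # b
    C: float
    classes: tuple[str, ...]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    _svc: SVC = field(repr=False, default=None)

    def decision_function(self, X) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_scale
        return Xs @ self.weights + self.bias

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        return np.where(d >= 0, self.classes[1], self.classes[0])


@dataclass
class EvaluationResult:
    """Test accuracies (percent) per chromophore plus per-window predictions."""

    accuracy: dict  # chromophore -> percent
    itr: dict  # chromophore -> bits/trial at the achieved accuracy
    predictions: dict  # chromophore -> (test labels, predicted labels)
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        for v in self.accuracy.values():
            if not 0 <= v <= 100:
                raise ValueError("accuracy must lie in [0, 100]")
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test rows overlap")

    def to_frame(self, subject: str = "S1") -> pd.DataFrame:
        row = {"subject": subject}
        for c in CHROMOPHORES:
            row[f"accuracy_{c}"] = round(self.accuracy[c], 2)
        for c in ("hbo", "hbr"):
            row[f"itr_{c}"] = round(self.itr[c], 2)
        return pd.DataFrame([row])


def split_70_30(
    matrix: "FeatureMatrix | tuple", seed: int = 0, test_fraction: float = 0.3,
    by_epoch: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified 70:30 split of feature rows, reproducible for a seed.

    Within each class the test share is ``floor(test_fraction * n)`` rows
    (rounding toward the training set).  With ``by_epoch`` the split is at
    the level of whole task epochs instead of windows, which prevents
    windows of one epoch from landing in both sets (the window-level
    default mirrors the common practice for this kind of data but is
    optimistic in that respect).
    """
    if isinstance(matrix, FeatureMatrix):
        y, groups = matrix.y, matrix.epoch_id
    else:
        y, groups = np.asarray(matrix[0]), None
        if len(matrix) > 1 and matrix[1] is not None:
            groups = np.asarray(matrix[1])
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if by_epoch:
            if groups is None:
                raise ValueError("by_epoch split requires epoch ids")
            eps = np.unique(groups[idx])
            if eps.size < 2:
                raise ValueError(f"class {cls!r} has fewer than 2 epochs")
            eps = rng.permutation(eps)
            n_test = int(np.floor(test_fraction * eps.size))
            test_eps = set(eps[:n_test].tolist())
            test.extend(i for i in idx if groups[i] in test_eps)
            train.extend(i for i in idx if groups[i] not in test_eps)
        else:
            if idx.size < 2:
                raise ValueError(f"class {cls!r} has fewer than 2 rows")
            idx = rng.permutation(idx)
            n_test = int(np.floor(test_fraction * idx.size))
            test.extend(idx[:n_test].tolist())
            train.extend(idx[n_test:].tolist())
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(test, dtype=int))


def train_svm(X, y, C: float = 1.0) -> SvmModel:
    """Fit a linear soft-margin SVM on standardized features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"exactly two classes required, got {classes.size}")
    if C <= 0:
        raise ValueError("C must be > 0")
    scaler = StandardScaler().fit(X)
    svc = SVC(kernel="linear", C=C).fit(scaler.transform(X), y)
    return SvmModel(
        weights=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        C=C,
        classes=tuple(svc.classes_),
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        _svc=svc,
    )


def evaluate_subject(
    series: HemodynamicSeries,
    schedule: ParadigmSchedule,
    channels=None,
    window_s: float = 2.0,
    step_s: float = 1.0,
    feature_set: tuple[str, ...] = ("mean", "slope"),
    C: float = 1.0,
    seed: int = 0,
    by_epoch: bool = False,
) -> EvaluationResult:
    """Run features -> split -> train -> test for HbO, HbR and HbT.

    The same row split is reused across chromophores so the three
    accuracies are directly comparable.
    """
    accuracy, itr, predictions = {}, {}, {}
    train_idx = test_idx = None
    for chrom in CHROMOPHORES:
        fm = extract_features(
            series,
            schedule,
            window_s=window_s,
            step_s=step_s,
            feature_set=feature_set,
            channels=channels,
            chromophore=chrom,
        )
        if train_idx is None:
            train_idx, test_idx = split_70_30(fm, seed=seed, by_epoch=by_epoch)
        model = train_svm(fm.X.values[train_idx], fm.y[train_idx], C=C)
        pred = model.predict(fm.X.values[test_idx])
        truth = fm.y[test_idx]
        acc = float(np.mean(pred == truth)) * 100.0
        accuracy[chrom] = acc
        itr[chrom] = itr_bits_per_trial(acc / 100.0, 2)
        predictions[chrom] = (truth, pred)
    return EvaluationResult(
        accuracy=accuracy,
        itr=itr,
        predictions=predictions,
        train_idx=train_idx,
        test_idx=test_idx,
        seed=seed,
    )


def itr_bits_per_trial(P: float, N: int) -> float:
    """Wolpaw information transfer rate in bits per trial.

    Bt = log2 N + P log2 P + (1 - P) log2((1 - P) / (N - 1)), with the
    convention 0 * log2 0 = 0.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if not 0 <= P <= 1:
        raise ValueError("P must lie in [0, 1]")

    def plog(p: float) -> float:
        return p * np.log2(p) if p > 0 else 0.0

    return float(
        np.log2(N) + plog(P) + ((1 - P) * np.log2((1 - P) / (N - 1)) if P < 1 else 0.0)
    )


def dtr_bits_per_minute(bt: float, T: float, Cn: int = 1) -> float:
    """Data transfer rate in bits per minute: (60 / T) * Cn * Bt."""
    if T <= 0:
        raise ValueError("T must be > 0")
    if Cn < 1:
        raise ValueError("Cn must be >= 1")
    return 60.0 / T * Cn * bt
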
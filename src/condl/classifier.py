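"""Kernel SVM over dependency paths: positive decision values = interactions.

`EditDistancePathSVC` is a scikit-learn-style estimator (fit / predict /
decision_function, ``get_params``/``set_params``); it trains a soft-margin
SVM on the eigenvalue-repaired Gram matrix of the edit-distance kernel and
scores new paths with the raw kernel against its support paths.  The
module-level :func:`train` / :func:`score` helpers and a portable JSON model
format wrap the estimator for pipeline use.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .deppath import CandidatePair, DependencyPath
from .kernel import cross_kernel, gram_matrix

__all__ = [
    "LabeledPath",
    "KernelModel",
    "ScoredInteraction",
    "EditDistancePathSVC",
    "train",
    "score",
    "read_labeled_paths",
    "write_labeled_paths",
    "save_model",
    "load_model",
    "cross_validated_f1",
]


@dataclass(frozen=True)
class LabeledPath:
    sequence: tuple[str, ...]
    label: int  # +1 interaction, -1 not

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("labeled path sequence must be nonempty")
        if self.label not in (1, -1):
            raise ValueError(f"label must be +1 or -1, got {self.label}")


@dataclass(frozen=True)
class KernelModel:
    support_sequences: tuple[tuple[str, ...], ...]
    dual_coef: tuple[float, ...]  # alpha_i * y_i per support sequence
    bias: float
    gamma: float
    C: float
    psd_repaired: bool

    def decision_value(self, sequence: Sequence[str]) -> float:
        k = cross_kernel([tuple(sequence)], self.support_sequences, self.gamma)[0]
        return float(np.dot(k, self.dual_coef) + self.bias)


@dataclass(frozen=True)
class ScoredInteraction:
    pair: CandidatePair
    path: DependencyPath
    score: float

    @property
    def is_positive(self) -> bool:
        return self.score > 0


class EditDistancePathSVC(BaseEstimator, ClassifierMixin):
    """SVM classifier over token sequences with the edit-distance kernel.

    Parameters
    ----------
    C : float
        Soft-margin penalty; must be positive.
    gamma : float
        Kernel decay rate; must be positive.
    threshold : float
        Decision threshold for :meth:`predict` (default 0).
    random_state : int or None
        Accepted for sklearn API compatibility; the dual solver is
        deterministic for fixed data order.

    Attributes
    ----------
    support_sequences_ : tuple of token tuples
    dual_coef_ : ndarray, signed dual coefficients (alpha_i * y_i)
    intercept_ : float
    psd_repaired_ : bool, whether the training Gram matrix needed repair
    """

    def __init__(
        self,
        C: float = 1.0,
        gamma: float = 0.25,
        threshold: float = 0.0,
        random_state: int | None = None,
    ):
        self.C = C
        self.gamma = gamma
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X: Sequence[Sequence[str]], y: Sequence[int]) -> "EditDistancePathSVC":
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        X = [tuple(x) for x in X]
        y = np.asarray(y, dtype=int)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        classes = set(y.tolist())
        if classes != {1, -1}:
            if len(classes) < 2:
                raise ValueError("training data must contain both classes (+1 and -1)")
            raise ValueError(f"labels must be +1/-1, got {sorted(classes)}")
        gram, repaired = gram_matrix(X, gamma=self.gamma)
        svc = SVC(C=self.C, kernel="precomputed")
        svc.fit(gram, y)
        self.psd_repaired_ = repaired
        self.support_sequences_ = tuple(X[i] for i in svc.support_)
        self.dual_coef_ = svc.dual_coef_[0].copy()
        self.intercept_ = float(svc.intercept_[0])
        self.classes_ = np.array([-1, 1])
        return self

    def decision_function(self, X: Sequence[Sequence[str]]) -> np.ndarray:
        k = cross_kernel([tuple(x) for x in X], self.support_sequences_, self.gamma)
        return k @ self.dual_coef_ + self.intercept_

    def predict(self, X: Sequence[Sequence[str]]) -> np.ndarray:
        return np.where(self.decision_function(X) > self.threshold, 1, -1)

    def to_model(self) -> KernelModel:
        return KernelModel(
            support_sequences=self.support_sequences_,
            dual_coef=tuple(float(c) for c in self.dual_coef_),
            bias=self.intercept_,
            gamma=self.gamma,
            C=self.C,
            psd_repaired=self.psd_repaired_,
        )


def train(
    labeled: Sequence[LabeledPath],
    C: float = 1.0,
    gamma: float = 0.25,
    seed: int = 0,
) -> KernelModel:
    """Fit the path SVM on labeled sequences (deterministic for fixed order)."""
    est = EditDistancePathSVC(C=C, gamma=gamma, random_state=seed)
    est.fit([lp.sequence for lp in labeled], [lp.label for lp in labeled])
    return est.to_model()


def score(
    model: KernelModel, pair: CandidatePair, path: DependencyPath
) -> ScoredInteraction:
    return ScoredInteraction(pair, path, model.decision_value(path.sequence))


def read_labeled_paths(path: str | Path) -> list[LabeledPath]:
    """TSV with columns path (space-joined tokens) and label (+1/-1)."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(LabeledPath(tuple(row["path"].split()), int(row["label"])))
    return out


def write_labeled_paths(labeled: Iterable[LabeledPath], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["path", "label"])
        for lp in labeled:
            writer.writerow([" ".join(lp.sequence), lp.label])


def save_model(model: KernelModel, path: str | Path) -> None:
    """Serialize a trained model to a single portable JSON file."""
    payload = {
        "gamma": model.gamma,
        "C": model.C,
        "bias": model.bias,
        "psd_repaired": model.psd_repaired,
        "supports": [
            {"coef": c, "sequence": list(s)}
            for c, s in zip(model.dual_coef, model.support_sequences)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> KernelModel:
    payload = json.loads(Path(path).read_text())
    return KernelModel(
        support_sequences=tuple(tuple(s["sequence"]) for s in payload["supports"]),
        dual_coef=tuple(s["coef"] for s in payload["supports"]),
        bias=payload["bias"],
        gamma=payload["gamma"],
        C=payload["C"],
        psd_repaired=payload["psd_repaired"],
    )


def cross_validated_f1(
    labeled: Sequence[LabeledPath],
    n_folds: int = 10,
    C: float = 1.0,
    gamma: float = 0.25,
    seed: int = 42,
) -> float:
    """Stratified k-fold cross-validated F1 of the path SVM (positive class)."""
    from sklearn.model_selection import StratifiedKFold

    X = [lp.sequence for lp in labeled]
    y = np.array([lp.label for lp in labeled])
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    tp = fp = fn = 0
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        est = EditDistancePathSVC(C=C, gamma=gamma)
        est.fit([X[i] for i in train_idx], y[train_idx])
        pred = est.predict([X[i] for i in test_idx])
        truth = y[test_idx]
        tp += int(np.sum((pred == 1) & (truth == 1)))
        fp += int(np.sum((pred == 1) & (truth == -1)))
        fn += int(np.sum((pred == -1) & (truth == 1)))
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)
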
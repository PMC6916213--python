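"""Held-out evaluation of death-date prediction.

Samples are split 70:30 by *patient* (never by sample, so no patient leaks
across the split).  The LSTM classifier is scored by window accuracy: a
sample is correct when the predicted B-day death window equals the true one.
The linear-regression and support-vector baselines predict a continuous
days-before-death value from bag-of-words counts and are scored by the
within-window rule: correct when |predicted - actual| <= B days (boundary
inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import LinearRegression
from sklearn.svm import LinearSVR

from .errors import ConfigurationError, ValidationError
from .preprocess import DailySample, Vocabulary, sample_matrix
from .progression_model import TrainedModel

BASELINE_KINDS = ("lr", "svm")


@dataclass(frozen=True)
class EvalResult:
    """Accuracy plus per-sample correctness for one model on one test set."""

    model_tag: str
    accuracy: float
    correct: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.correct and abs(self.accuracy - float(np.mean(self.correct))) > 1e-12:
            raise ValidationError("accuracy must equal the mean of the indicators")


def split(
    samples: Sequence[DailySample], ratio: float = 0.7, seed: int = 0
) -> tuple[list[DailySample], list[DailySample]]:
    """Patient-level train/test split at the given ratio, seeded shuffle."""
    if not 0.0 < ratio < 1.0:
        raise ConfigurationError("split ratio must be in (0, 1)")
    patients = sorted({s.patient_id for s in samples})
    if len(patients) < 2:
        raise ValidationError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_train = int(round(ratio * len(patients)))
    n_train = min(max(n_train, 1), len(patients) - 1)
    train_ids = {patients[i] for i in order[:n_train]}
    train = [s for s in samples if s.patient_id in train_ids]
    test = [s for s in samples if s.patient_id not in train_ids]
    return train, test


def accuracy_within_window(
    predicted_death_day: float, actual_death_day: float, window_days: int
) -> int:
    """1 iff the prediction is within the window of the truth (inclusive)."""
    return int(abs(predicted_death_day - actual_death_day) <= window_days)


def lstm_accuracy(model: TrainedModel, test: Sequence[DailySample]) -> EvalResult:
    """Window-classification accuracy of the trained four-layer model."""
    if model.config.n_classes < 2:
        raise ValidationError("window accuracy is undefined for a single-class head")
    if not test:
        raise ValidationError("empty test set")
    ids, labels = sample_matrix(test)
    pred = np.argmax(model.predict_proba(ids), axis=1)
    correct = tuple(int(p == t) for p, t in zip(pred, labels))
    return EvalResult("lstm", float(np.mean(correct)), correct)


def bag_of_words(samples: Sequence[DailySample], vocab_size: int) -> sp.csr_matrix:
    """Sparse token-count features over the shared vocabulary (padding dropped)."""
    rows, cols, vals = [], [], []
    for r, s in enumerate(samples):
        ids, counts = np.unique(s.token_ids, return_counts=True)
        keep = ids != 0
        rows.extend([r] * int(keep.sum()))
        cols.extend(ids[keep].tolist())
        vals.extend(counts[keep].tolist())
    return sp.csr_matrix((vals, (rows, cols)), shape=(len(samples), vocab_size), dtype=float)


@dataclass
class BaselineModel:
    """A fitted LR or SVM regressor over bag-of-words counts."""

    kind: str
    estimator: object
    vocab_size: int

    def predict_days(self, samples: Sequence[DailySample]) -> np.ndarray:
        X = bag_of_words(samples, self.vocab_size)
        return np.asarray(self.estimator.predict(X), dtype=float)


def fit_baseline(
    kind: str, train_samples: Sequence[DailySample], vocab_size: int, seed: int = 0
) -> BaselineModel:
    """Fit a baseline regressor of days-before-death on token counts."""
    if kind not in BASELINE_KINDS:
        raise ConfigurationError(f"unknown baseline kind {kind!r}; expected one of {BASELINE_KINDS}")
    if not train_samples:
        raise ValidationError("empty training set")
    X = bag_of_words(train_samples, vocab_size)
    y = np.array([s.days_before_death for s in train_samples], dtype=float)
    if kind == "lr":
        est = LinearRegression()
    else:
        est = LinearSVR(random_state=seed, max_iter=5000)
    est.fit(X, y)
    return BaselineModel(kind=kind, estimator=est, vocab_size=vocab_size)


def baseline_accuracy(
    model: BaselineModel, test: Sequence[DailySample], window_days: int
) -> EvalResult:
    """Mean within-window correctness of a baseline's death-day predictions."""
    if not test:
        raise ValidationError("empty test set")
    pred = model.predict_days(test)
    correct = tuple(
        accuracy_within_window(p, s.days_before_death, window_days)
        for p, s in zip(pred, test)
    )
    return EvalResult(model.kind, float(np.mean(correct)), correct)
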
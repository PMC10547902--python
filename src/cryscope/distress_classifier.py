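"""Two-class cry vs distress classification of cry units.

Two models mirror the study design: a random forest on 26-dimensional
MFCC summaries and a small convolutional network on fixed-size log-mel
spectrograms.  Units are split 80/20 into training and validation by a
plain random split (training size = ceil(0.8 n), remainder to
validation), and performance is reported as a confusion matrix with
distress as the positive class plus accuracy, sensitivity and
specificity.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .config import ClassifierConfig
from ._nn import SmallCNN

LABELS = ("cry", "distress")
POSITIVE = "distress"


@dataclass
class Split:
    train: np.ndarray
    validation: np.ndarray


@dataclass
class LabeledDataset:
    """Per-unit features with labels and a train/validation split."""

    features: np.ndarray          # (n, d) MFCC summaries or (n, H, W) images
    labels: np.ndarray            # strings from LABELS
    split: Split | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {bad}")
        if len(self.features) != len(self.labels):
            raise ValueError("features/labels length mismatch")

    @property
    def y(self) -> np.ndarray:
        return (self.labels == POSITIVE).astype(int)


@dataclass
class ClassifierReport:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else np.nan

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else np.nan

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else np.nan

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def make_split(n_items: int, frac_train: float = 0.8, seed: int = 0) -> Split:
    """Plain random split: ceil(frac * n) training items, rest validation."""
    if not (0.0 < frac_train < 1.0):
        raise ValueError("frac_train must be in (0, 1)")
    n_train = int(np.ceil(frac_train * n_items))
    perm = np.random.default_rng(seed).permutation(n_items)
    return Split(train=np.sort(perm[:n_train]), validation=np.sort(perm[n_train:]))


def train_rf(dataset: LabeledDataset, seed: int = 0,
             cfg: ClassifierConfig | None = None) -> RandomForestClassifier:
    """Random forest on MFCC summary vectors."""
    cfg = cfg or ClassifierConfig()
    if dataset.split is None:
        raise ValueError("dataset needs a split")
    x = dataset.features[dataset.split.train]
    y = dataset.y[dataset.split.train]
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    model = RandomForestClassifier(
        n_estimators=cfg.rf_n_estimators, random_state=seed, n_jobs=1,
    )
    model.fit(x.reshape(len(x), -1), y)
    return model


def train_cnn(dataset: LabeledDataset, seed: int = 0, epochs: int | None = None,
              cfg: ClassifierConfig | None = None, verbose: bool = False) -> SmallCNN:
    """Convolutional network on spectrogram images with early stopping."""
    cfg = cfg or ClassifierConfig()
    if dataset.split is None:
        raise ValueError("dataset needs a split")
    xtr = dataset.features[dataset.split.train]
    ytr = dataset.y[dataset.split.train]
    xva = dataset.features[dataset.split.validation]
    yva = dataset.y[dataset.split.validation]
    if len(np.unique(ytr)) < 2:
        raise ValueError("training set contains a single class")
    model = SmallCNN(
        input_shape=xtr.shape[1:], filters=cfg.cnn_filters,
        dense_units=cfg.cnn_dense_units, seed=seed,
    )
    model.fit(
        xtr, ytr, xva, yva,
        epochs=epochs if epochs is not None else cfg.cnn_epochs,
        batch_size=cfg.cnn_batch_size, lr=cfg.cnn_learning_rate,
        patience=cfg.cnn_patience, seed=seed, verbose=verbose,
    )
    return model


def evaluate(model, dataset: LabeledDataset) -> ClassifierReport:
    """Confusion-matrix report on the validation split (distress = positive)."""
    if dataset.split is None:
        raise ValueError("dataset needs a split")
    idx = dataset.split.validation
    x = dataset.features[idx]
    y = dataset.y[idx]
    if isinstance(model, RandomForestClassifier):
        pred = model.predict(x.reshape(len(x), -1))
    else:
        pred = model.predict(x)
    return report_from_predictions(y, pred)


def report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ClassifierReport:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ClassifierReport(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )
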
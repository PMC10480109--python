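"""Decoder training and stimulus-grouped cross-validated evaluation.

Features are z-scored with statistics from the training split only, then
fed to an RBF-kernel SVM (C=1, gamma=0.01) with calibrated probability
outputs.  Cross-validation folds are assigned at the level of stimulus
events, never individual windows, so overlapping windows cut from the
same stimulus can never straddle the train/test split.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .features import FeatureTable
from .signal_io import DecoderArtifact, ValidationError

logger = logging.getLogger(__name__)

_CONST_SD_EPS = 1e-12


@dataclass(frozen=True)
class SvmConfig:
    C: float = 1.0
    gamma: float = 0.01
    kernel: str = "rbf"
    probability_outputs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValidationError("C and gamma must be > 0")


@dataclass(frozen=True)
class CvPlan:
    k: int = 4
    seed: int = 0
    class_set: tuple = ("P", "R")


@dataclass
class MetricsReport:
    """Confusion matrix plus the derived accuracy/recall/precision."""

    classes: list[str]
    confusion: np.ndarray       # rows = true, cols = predicted

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=float)
        if self.confusion.shape != (len(self.classes), len(self.classes)):
            raise ValidationError("confusion shape does not match classes")
        if (self.confusion < 0).any():
            raise ValidationError("confusion counts must be >= 0")

    @property
    def total(self) -> float:
        return float(self.confusion.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.total) if self.total else 0.0

    def recall(self, cls: str) -> float:
        i = self.classes.index(cls)
        row = self.confusion[i].sum()
        return float(self.confusion[i, i] / row) if row else 0.0

    def precision(self, cls: str) -> float:
        i = self.classes.index(cls)
        col = self.confusion[:, i].sum()
        return float(self.confusion[i, i] / col) if col else 0.0

    @property
    def row_normalized(self) -> np.ndarray:
        rows = self.confusion.sum(axis=1, keepdims=True)
        return self.confusion / np.where(rows > 0, rows, 1.0)

    @property
    def col_normalized(self) -> np.ndarray:
        cols = self.confusion.sum(axis=0, keepdims=True)
        return self.confusion / np.where(cols > 0, cols, 1.0)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "recall": {c: self.recall(c) for c in self.classes},
            "precision": {c: self.precision(c) for c in self.classes},
            "row_normalized": self.row_normalized.tolist(),
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def confusion_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.confusion, index=self.classes,
                     columns=self.classes).to_csv(path)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class ZScaler:
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) / self.sd


def fit_zscaler(X: np.ndarray) -> ZScaler:
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        raise ValidationError("cannot standardize an empty table")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    const = sd < _CONST_SD_EPS
    if const.any():
        logger.warning("%d constant feature column(s); SD clamped to 1",
                       int(const.sum()))
        sd = np.where(const, 1.0, sd)
    return ZScaler(mean, sd)


def zscore_fit_apply(train: FeatureTable, apply_to: FeatureTable):
    """Fit per-column standardization on ``train``; apply to both tables."""
    if train.feature_names != apply_to.feature_names:
        raise ValidationError("feature column sets differ between tables")
    scaler = fit_zscaler(train.X)

    def _std(ft: FeatureTable) -> FeatureTable:
        df = ft.df.copy()
        df[ft.feature_names] = scaler.transform(ft.X)
        return FeatureTable(df, list(ft.feature_names))

    return scaler, _std(train), _std(apply_to)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_svm(table: FeatureTable, cfg: SvmConfig | None = None,
              modality: str = "EEG", standardized: bool = True,
              scaler: ZScaler | None = None) -> DecoderArtifact:
    """Fit the probabilistic RBF-SVM on a (standardized) feature table.

    When ``standardized`` is False the scaler is fitted here and stored in
    the artifact; otherwise pass the scaler used upstream so the artifact
    can reproduce the full window -> probability mapping.
    """
    cfg = cfg or SvmConfig()
    classes = sorted(set(table.y))
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes to train")
    if not standardized:
        scaler = fit_zscaler(table.X)
        X = scaler.transform(table.X)
    else:
        X = table.X
        if scaler is None:
            scaler = ZScaler(np.zeros(X.shape[1]), np.ones(X.shape[1]))
    svm = SVC(C=cfg.C, gamma=cfg.gamma, kernel=cfg.kernel,
              probability=cfg.probability_outputs,
              random_state=cfg.seed)
    with warnings.catch_warnings():
        # sklearn >= 1.9 deprecates probability=True; the built-in Platt
        # calibration is exactly what the decoder contract wants
        warnings.simplefilter("ignore", FutureWarning)
        svm.fit(X, table.y)
    return DecoderArtifact(
        scaler_mean=scaler.mean, scaler_sd=scaler.sd, svm=svm,
        classes=list(svm.classes_), modality=modality,
        feature_names=list(table.feature_names),
        meta={"C": cfg.C, "gamma": cfg.gamma, "seed": cfg.seed,
              "n_train": len(table)},
    )


def predict_proba(artifact: DecoderArtifact, X: np.ndarray) -> np.ndarray:
    """Class probabilities for raw (unstandardized) feature rows."""
    Xs = (np.asarray(X, float) - artifact.scaler_mean) / artifact.scaler_sd
    return artifact.svm.predict_proba(Xs)


def p_pain(artifact: DecoderArtifact, X: np.ndarray) -> np.ndarray:
    proba = predict_proba(artifact, X)
    return proba[:, artifact.classes.index("P")]


# ---------------------------------------------------------------------------
# Grouped cross-validation
# ---------------------------------------------------------------------------

def grouped_kfold(groups, k: int, seed: int = 0) -> dict:
    """Map each group id to a fold index (0..k-1).

    Groups are shuffled with ``seed`` and dealt round-robin, so all
    windows of one stimulus land in the same fold.
    """
    uniq = list(dict.fromkeys(groups))  # first-appearance order
    if len(uniq) < k:
        raise ValidationError(f"{len(uniq)} groups is fewer than k={k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    return {uniq[g]: int(i % k) for i, g in enumerate(order)}


def cross_validate(table: FeatureTable, plan: CvPlan | None = None,
                   cfg: SvmConfig | None = None, grouped: bool = True):
    """Stimulus-grouped k-fold CV; returns (overall report, per-fold reports).

    ``grouped=False`` assigns folds to individual windows instead — only
    useful to demonstrate the leakage that grouping prevents.
    """
    plan = plan or CvPlan()
    cfg = cfg or SvmConfig(seed=plan.seed)
    table = table.select_labels(plan.class_set)
    if len(table) == 0:
        raise ValidationError("no rows for requested class set")
    classes = [c for c in plan.class_set if c in set(table.y)]
    if grouped:
        fold_of = grouped_kfold(table.groups, plan.k, plan.seed)
        folds = np.array([fold_of[g] for g in table.groups])
    else:
        fold_of = grouped_kfold(range(len(table)), plan.k, plan.seed)
        folds = np.array([fold_of[i] for i in range(len(table))])

    conf = np.zeros((len(classes), len(classes)))
    fold_reports = []
    idx = {c: i for i, c in enumerate(classes)}
    for f in range(plan.k):
        test_mask = folds == f
        tr = FeatureTable(table.df[~test_mask].copy(), list(table.feature_names))
        te = FeatureTable(table.df[test_mask].copy(), list(table.feature_names))
        scaler, tr_s, te_s = zscore_fit_apply(tr, te)
        art = train_svm(tr_s, cfg, standardized=True, scaler=scaler)
        pred = art.svm.predict(te_s.X)
        fc = np.zeros((len(classes), len(classes)))
        for yt, yp in zip(te.y, pred):
            fc[idx[yt], idx[yp]] += 1
        conf += fc
        fold_reports.append(MetricsReport(classes, fc))
        logger.debug("fold %d: n_test=%d acc=%.3f", f, int(test_mask.sum()),
                     fold_reports[-1].accuracy)
    return MetricsReport(classes, conf), fold_reports


def classification_metrics(y_true, y_pred, class_set) -> MetricsReport:
    classes = list(class_set)
    idx = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)))
    for yt, yp in zip(y_true, y_pred):
        conf[idx[yt], idx[yp]] += 1
    return MetricsReport(classes, conf)
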
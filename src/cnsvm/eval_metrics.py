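"""Performance indices and pixel-wise cube segmentation.

Six indices are reported for every experiment: overall accuracy,
sensitivity (true-positive rate, BCC = positive class), specificity
(true-negative rate), ROC-AUC, Cohen's kappa and the mean squared error of
the probability-like scores against the binary labels.  A model is flagged
as clinically adequate when sensitivity and specificity are balanced and
AUC and kappa both reach 0.8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from cnsvm.errors import ShapeError, UndefinedMetricError, WindowError
from cnsvm.model_core import ModelHandle, forward_proba
from cnsvm.spectra_io import (
    HyperCube,
    SignatureSet,
    SpectralWindow,
    crop_cube_to_window,
    cube_to_signatures,
)
from cnsvm.svm_head import CNSVMModel, predict

#: Quality thresholds: AUC and kappa at or above 0.8, and a sensitivity /
#: specificity gap no larger than this, mark an adequate model.
QUALITY_THRESHOLD = 0.8
BALANCE_TOLERANCE = 0.1


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with BCC = 1 as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ShapeError("confusion counts must be non-negative")
        if self.total < 1:
            raise ShapeError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_binary(v, name: str) -> np.ndarray:
    arr = np.asarray(v)
    if arr.ndim != 1:
        raise ShapeError(f"{name} must be 1-D")
    if not np.isin(arr, (0, 1)).all():
        raise ShapeError(f"{name} must contain only 0/1")
    return arr.astype(np.int64)


def confusion(labels_true, labels_pred) -> ConfusionMatrix:
    """Count tp/fp/tn/fn for binary label vectors of equal length."""
    yt = _as_binary(labels_true, "labels_true")
    yp = _as_binary(labels_pred, "labels_pred")
    if yt.shape != yp.shape or yt.size < 1:
        raise ShapeError("label vectors must share a positive length")
    return ConfusionMatrix(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def basic_rates(c: ConfusionMatrix) -> tuple[float, float | None, float | None]:
    """(accuracy, sensitivity, specificity); a rate with a zero denominator
    is reported as None (absent), never as 0."""
    accuracy = (c.tp + c.tn) / c.total
    sensitivity = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    specificity = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return accuracy, sensitivity, specificity


def roc_auc(labels_true, scores) -> tuple[np.ndarray, float]:
    """ROC curve and AUC.

    The curve sweeps thresholds over the distinct scores (prediction
    positive when score >= threshold) with sentinels so it starts at (0, 0)
    and ends at (1, 1).  The AUC is the Mann-Whitney statistic
    P(score_pos > score_neg) + 0.5 P(tie), computed by midranks, so ties are
    handled exactly.
    """
    yt = _as_binary(labels_true, "labels_true")
    scores = np.asarray(scores, dtype=float)
    if scores.shape != yt.shape:
        raise ShapeError("labels and scores must share one length")
    n_pos = int(np.sum(yt == 1))
    n_neg = yt.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC/AUC needs both classes present")

    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1], [-np.inf]))
    points = []
    for t in thresholds:
        pred = scores >= t
        tpr = np.sum(pred & (yt == 1)) / n_pos
        fpr = np.sum(pred & (yt == 0)) / n_neg
        points.append((fpr, tpr))
    roc = np.array(points)

    ranks = rankdata(scores)  # midranks handle ties
    auc = (ranks[yt == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return roc, float(auc)


def cohen_kappa(c: ConfusionMatrix) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    p_o is the observed accuracy and p_e the agreement expected from the
    marginals.  The degenerate case p_e = 1 is defined as 0.
    """
    total = c.total
    p_o = (c.tp + c.tn) / total
    p_yes = ((c.tp + c.fn) / total) * ((c.tp + c.fp) / total)
    p_no = ((c.tn + c.fp) / total) * ((c.tn + c.fn) / total)
    p_e = p_yes + p_no
    if p_e == 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def mse(labels_true, scores) -> float:
    """Mean squared error of probability-like scores against binary labels."""
    yt = _as_binary(labels_true, "labels_true")
    scores = np.asarray(scores, dtype=float)
    if scores.shape != yt.shape:
        raise ShapeError("labels and scores must share one length")
    return float(np.mean((scores - yt) ** 2))


@dataclass
class MetricsReport:
    """The six performance indices plus the confusion matrix and ROC curve
    they derive from, and the model-quality flags."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    auc: float
    kappa: float
    mse: float
    roc: np.ndarray = field(repr=False)
    confusion: ConfusionMatrix = field(repr=False)

    @property
    def quality_flags(self) -> dict[str, bool]:
        balanced = (
            self.sensitivity is not None
            and self.specificity is not None
            and abs(self.sensitivity - self.specificity) <= BALANCE_TOLERANCE
        )
        return {
            "auc_ok": self.auc >= QUALITY_THRESHOLD,
            "kappa_ok": self.kappa >= QUALITY_THRESHOLD,
            "balanced": bool(balanced),
        }

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "kappa": self.kappa,
            "mse": self.mse,
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "tn": self.confusion.tn,
                "fn": self.confusion.fn,
            },
            "quality_flags": self.quality_flags,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def __str__(self) -> str:
        fmt = lambda v: "absent" if v is None else f"{v:.4f}"
        flags = self.quality_flags
        return (
            f"accuracy    {fmt(self.accuracy)}\n"
            f"sensitivity {fmt(self.sensitivity)}\n"
            f"specificity {fmt(self.specificity)}\n"
            f"AUC         {fmt(self.auc)}  (>=0.8: {flags['auc_ok']})\n"
            f"kappa       {fmt(self.kappa)}  (>=0.8: {flags['kappa_ok']})\n"
            f"MSE         {fmt(self.mse)}\n"
            f"balanced sens/spec: {flags['balanced']}"
        )


def _scores_and_labels(model, s: SignatureSet) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(model, CNSVMModel):
        return predict(model, s)
    if isinstance(model, ModelHandle):
        scores = forward_proba(model, s)
        return (scores >= 0.5).astype(np.int64), scores
    raise TypeError(f"cannot evaluate object of type {type(model).__name__}")


def evaluate(model, s: SignatureSet) -> MetricsReport:
    """Full report for a hybrid model or a sigmoid-output backbone on a
    labelled signature set."""
    if not s.is_labelled:
        raise UndefinedMetricError("evaluate requires labelled signatures")
    pred, scores = _scores_and_labels(model, s)
    c = confusion(s.labels, pred)
    accuracy, sensitivity, specificity = basic_rates(c)
    roc, auc = roc_auc(s.labels, scores)
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        auc=auc,
        kappa=cohen_kappa(c),
        mse=mse(s.labels, scores),
        roc=roc,
        confusion=c,
    )


@dataclass
class SegmentationMask:
    """Per-pixel predicted labels and scores for one cube."""

    labels: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.labels.shape != self.scores.shape or self.labels.ndim != 2:
            raise ShapeError("labels and scores must be 2-D arrays of one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def pixel_accuracy(self, truth: np.ndarray) -> float:
        truth = np.asarray(truth)
        if truth.shape != self.labels.shape:
            raise ShapeError("truth mask shape must match the segmentation")
        return float(np.mean(self.labels == (truth != 0)))


def segment_cube(
    m: CNSVMModel, c: HyperCube, window: SpectralWindow | None = None
) -> SegmentationMask:
    """Classify every pixel of a cube.

    Each pixel spectrum is cropped to the window, standardised with the
    backbone's stored training statistics, scored by the hybrid model, and
    the predictions are reassembled into a (rows, cols) mask.
    """
    if window is None:
        window = SpectralWindow.default()
    cropped = crop_cube_to_window(c, window)
    if cropped.grid.n_channels != m.backbone.config.input_len:
        raise WindowError(
            f"window keeps {cropped.grid.n_channels} channels; backbone "
            f"expects {m.backbone.config.input_len}"
        )
    rows, cols, _ = cropped.shape
    pixels = cube_to_signatures(cropped)
    labels, scores = predict(m, pixels)
    return SegmentationMask(
        labels=labels.reshape(rows, cols), scores=scores.reshape(rows, cols)
    )
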
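"""SVM activation layer replacing the backbone's sigmoid output.

After the convolutional network is trained, every signature is passed
through it and the activations of the last dense layer become the feature
vector for a kernel SVM (linear, polynomial or radial), tuned by stratified
10-fold cross-validation.  The backbone stays frozen; only the head is
(re)trained.  A Platt-style logistic calibration of the SVM decision values
provides probability-like scores in [0, 1] so ROC/AUC and MSE remain
computable for the hybrid model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from cnsvm.errors import ConfigError, CVError, ShapeError, TrainingError
from cnsvm.model_core import ModelHandle, extract_features
from cnsvm.spectra_io import SignatureSet

_SKLEARN_KERNELS = {"linear": "linear", "polynomial": "poly", "radial": "rbf"}


@dataclass(frozen=True)
class SVMHeadConfig:
    """Kernel family and coefficients of the SVM activation layer."""

    kernel: str = "radial"
    C: float = 1.0
    gamma: float = 0.1
    degree: int = 3
    coef0: float = 0.0
    k_folds: int = 10

    def __post_init__(self) -> None:
        if self.kernel not in _SKLEARN_KERNELS:
            raise ConfigError(
                f"kernel must be one of {sorted(_SKLEARN_KERNELS)}, got {self.kernel!r}"
            )
        if self.C <= 0:
            raise ConfigError("C must be positive")
        if self.gamma <= 0:
            raise ConfigError("gamma must be positive")
        if self.degree < 1 or int(self.degree) != self.degree:
            raise ConfigError("degree must be a positive integer")
        if self.k_folds < 2:
            raise ConfigError("k_folds must be >= 2")


def kernel_eval(cfg: SVMHeadConfig, x: np.ndarray, y: np.ndarray) -> float:
    """Evaluate the configured kernel on two feature vectors.

    linear: <x, y>; polynomial: (gamma <x, y> + coef0)**degree;
    radial: exp(-gamma ||x - y||^2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeError(f"feature vectors must share one shape, got {x.shape} vs {y.shape}")
    if cfg.kernel == "linear":
        return float(x @ y)
    if cfg.kernel == "polynomial":
        return float((cfg.gamma * (x @ y) + cfg.coef0) ** cfg.degree)
    return float(np.exp(-cfg.gamma * np.sum((x - y) ** 2)))


def _make_svc(cfg: SVMHeadConfig) -> SVC:
    return SVC(
        kernel=_SKLEARN_KERNELS[cfg.kernel],
        C=cfg.C,
        gamma=cfg.gamma,
        degree=cfg.degree,
        coef0=cfg.coef0,
    )


def cross_val_accuracy(
    features: np.ndarray, labels: np.ndarray, cfg: SVMHeadConfig, seed: int = 0
) -> float:
    """Mean accuracy over seeded stratified k folds (fit on k-1, score on
    the held-out fold)."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    counts = np.bincount(labels.astype(int), minlength=2)
    if counts.min() < cfg.k_folds:
        raise CVError(
            f"k_folds={cfg.k_folds} exceeds the smallest class count ({counts.min()})"
        )
    folds = StratifiedKFold(n_splits=cfg.k_folds, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in folds.split(features, labels):
        svc = _make_svc(cfg).fit(features[train_idx], labels[train_idx])
        scores.append(svc.score(features[test_idx], labels[test_idx]))
    return float(np.mean(scores))


@dataclass
class CNSVMModel:
    """Frozen backbone + fitted SVM head + decision-value calibration."""

    backbone: ModelHandle
    head: SVC = field(repr=False)
    head_config: SVMHeadConfig
    calibration: LogisticRegression = field(repr=False)
    cv_accuracy: float

    @property
    def feature_dim(self) -> int:
        return self.backbone.feature_dim


def fit_head(
    backbone: ModelHandle,
    s: SignatureSet,
    cfg: SVMHeadConfig | None = None,
    seed: int = 0,
) -> CNSVMModel:
    """Fit the SVM activation layer on features extracted by the backbone.

    The reported ``cv_accuracy`` is the mean over seeded stratified k-fold
    cross-validation; the returned head is refitted on all features.  The
    calibration map is a logistic fit of decision values against labels on
    the training features.
    """
    if cfg is None:
        cfg = SVMHeadConfig()
    if not s.is_labelled:
        raise TrainingError("fit_head requires labelled signatures")
    features = extract_features(backbone, s)
    labels = s.labels
    cv = cross_val_accuracy(features, labels, cfg, seed=seed)
    head = _make_svc(cfg).fit(features, labels)
    decisions = head.decision_function(features)
    calibration = LogisticRegression(max_iter=1000)
    calibration.fit(decisions[:, None], labels)
    return CNSVMModel(
        backbone=backbone,
        head=head,
        head_config=cfg,
        calibration=calibration,
        cv_accuracy=cv,
    )


def decision_values(m: CNSVMModel, s) -> np.ndarray:
    """Raw SVM decision values for signatures or a reflectance matrix."""
    features = extract_features(m.backbone, s)
    return m.head.decision_function(features)


def predict(m: CNSVMModel, s) -> tuple[np.ndarray, np.ndarray]:
    """Labels and calibrated scores for a signature set.

    Label 1 iff the decision value is strictly positive (a tie at exactly
    zero yields the healthy label 0); scores are the calibrated
    probability of class 1, clipped to [0, 1].
    """
    d = decision_values(m, s)
    labels = (d > 0).astype(np.int64)
    scores = np.clip(m.calibration.predict_proba(d[:, None])[:, 1], 0.0, 1.0)
    return labels, scores
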
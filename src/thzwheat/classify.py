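"""Kernel-SVM sub-classifiers with calibrated probability outputs.

Multiclass handling is one-vs-one with pairwise coupling of Platt-calibrated
decision values, which yields the per-class probabilities the decision-layer
fusion consumes as basic probability assignments.  Features are z-scored on
the training set before the kernel is applied so that one gamma value is
comparable across modalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DegenerateLabelsError, DegenerateSplitError, InvalidGridError
from .synthetic import CLASS_ORDER

#: default logarithmic grid for gamma and C
DEFAULT_GRID = [float(2.0**k) for k in range(-6, 7)]


@dataclass
class SvmConfig:
    """Kernel and hyper-parameter settings for one SVM sub-classifier."""

    kernel: str = "rbf"  # rbf | linear | poly
    C: float = 1.0
    gamma: float = 1.0
    degree: int = 3
    C_grid: Sequence[float] = field(default_factory=lambda: list(DEFAULT_GRID))
    gamma_grid: Sequence[float] = field(default_factory=lambda: list(DEFAULT_GRID))
    cv_folds: int = 5
    seed: int = 0
    #: "zscore": per-feature standardization fit on training data;
    #: "none": features arrive pre-scaled (e.g. modality-block normalized
    #: PCA scores, whose variance decay the z-score would destroy)
    scale: str = "zscore"
    #: score the CV grid by argmax of the calibrated probabilities instead of
    #: the raw decision rule.  For a sub-classifier whose *output* is the
    #: probability vector (decision-layer fusion), hyper-parameters must be
    #: chosen for probability quality: at very small C the hard predictions
    #: can stay accurate while the Platt-coupled probabilities go flat
    probability_scoring: bool = False

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear", "poly"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.scale not in ("zscore", "none"):
            raise ValueError(f"unknown scale mode {self.scale!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def split_dataset(
    labels: Sequence[str],
    ratio: tuple[int, int] = (2, 1),
    seed: int = 0,
    stratify: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test index split at an integer ratio (default 2:1).

    Stratification by class is on by default; turn it off to emulate a plain
    random draw with uneven per-class test counts.
    """
    labels = np.asarray(labels)
    tr, te = ratio
    if tr <= 0 or te < 0:
        raise ValueError("ratio parts must be positive (test may be zero)")
    idx = np.arange(labels.size)
    if te == 0:
        return idx, np.array([], dtype=int)
    test_frac = te / (tr + te)
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_frac,
        random_state=seed,
        stratify=labels if stratify else None,
    )
    for part, name in ((train_idx, "train"),):
        present = set(labels[part])
        if present != set(np.unique(labels)):
            raise DegenerateSplitError(f"{name} split lost a class")
    return np.sort(train_idx), np.sort(test_idx)


def _make_pipeline(
    config: SvmConfig, gamma: float, C: float, probability: bool = True
) -> Pipeline:
    # probability=False during grid search: CV accuracy does not need the
    # Platt calibration, which dominates the fit cost
    # coef0=1 gives the inhomogeneous polynomial kernel; the homogeneous
    # default degenerates on centered (z-scored) features
    svc = SVC(
        kernel=config.kernel,
        C=C,
        gamma=gamma if config.kernel != "linear" else "scale",
        degree=config.degree,
        coef0=1.0 if config.kernel == "poly" else 0.0,
        probability=probability,
        random_state=config.seed,
        decision_function_shape="ovo",
    )
    steps = [("svm", svc)]
    if config.scale == "zscore":
        steps.insert(0, ("scale", StandardScaler()))
    return Pipeline(steps)


def grid_search(
    X: np.ndarray, y: Sequence[str], config: SvmConfig
) -> tuple[SvmConfig, float]:
    """Cross-validated grid search over (gamma, C).

    Returns the best configuration and its CV accuracy.  Ties are broken
    toward smaller C, then smaller gamma, favouring the smoother model.
    For the linear kernel only C is searched.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise DegenerateLabelsError("grid search needs at least two classes")
    if not config.C_grid or (config.kernel != "linear" and not config.gamma_grid):
        raise InvalidGridError("empty hyper-parameter grid")
    cv = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed
    )
    gamma_candidates = (
        [config.gamma] if config.kernel == "linear" else sorted(config.gamma_grid)
    )

    def _proba_accuracy(est, Xv, yv):
        proba = est.predict_proba(Xv)
        pred = est.named_steps["svm"].classes_[np.argmax(proba, axis=1)]
        return float(np.mean(pred == yv))

    scoring = _proba_accuracy if config.probability_scoring else None
    best: tuple[float, float, float] | None = None  # (score, -C, -gamma) ordering
    best_params = (config.gamma, config.C)
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*probability.*", category=FutureWarning
        )
        for C in sorted(config.C_grid):
            for gamma in gamma_candidates:
                score = cross_val_score(
                    _make_pipeline(
                        config, gamma, C,
                        probability=config.probability_scoring,
                    ),
                    X, y, cv=cv, scoring=scoring, n_jobs=None,
                ).mean()
                key = (score, -C, -gamma)
                if best is None or key > best:
                    best = key
                    best_params = (gamma, C)
    out = SvmConfig(
        kernel=config.kernel,
        C=best_params[1],
        gamma=best_params[0],
        degree=config.degree,
        C_grid=list(config.C_grid),
        gamma_grid=list(config.gamma_grid),
        cv_folds=config.cv_folds,
        seed=config.seed,
        scale=config.scale,
        probability_scoring=config.probability_scoring,
    )
    return out, float(best[0])


@dataclass
class TrainedClassifier:
    """Fitted scaler+SVM with a fixed class order for probability columns."""

    config: SvmConfig
    pipeline: Pipeline
    classes: tuple[str, ...] = CLASS_ORDER
    cv_accuracy: float | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-class probabilities in :data:`CLASS_ORDER` columns."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.pipeline.n_features_in_:
            raise ValueError("feature dimension does not match the trained model")
        with warnings.catch_warnings():
            warnings.filterwarnings(
                "ignore", message=".*probability.*", category=FutureWarning
            )
            raw = self.pipeline.predict_proba(X)
        fitted = list(self.pipeline.named_steps["svm"].classes_)
        out = np.zeros((X.shape[0], len(self.classes)))
        for j, c in enumerate(self.classes):
            if c in fitted:
                out[:, j] = raw[:, fitted.index(c)]
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.pipeline.predict(np.asarray(X, dtype=float))


def train(
    X: np.ndarray,
    y: Sequence[str],
    config: SvmConfig,
    cv_accuracy: float | None = None,
) -> TrainedClassifier:
    """Fit the standardizer and SVM on training data only."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise DegenerateLabelsError("training needs at least two classes")
    pipe = _make_pipeline(config, config.gamma, config.C)
    with warnings.catch_warnings():
        # pairwise-coupled Platt probabilities via SVC(probability=True) are
        # exactly what the decision-layer fusion needs; silence the pending
        # deprecation until the replacement offers the same coupling
        warnings.filterwarnings(
            "ignore", message=".*probability.*", category=FutureWarning
        )
        pipe.fit(np.asarray(X, dtype=float), y)
    return TrainedClassifier(config=config, pipeline=pipe, cv_accuracy=cv_accuracy)


def fit_with_search(
    X: np.ndarray, y: Sequence[str], config: SvmConfig
) -> TrainedClassifier:
    """Grid search then final fit on the full training set."""
    best, score = grid_search(X, y, config)
    return train(X, y, best, cv_accuracy=score)
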
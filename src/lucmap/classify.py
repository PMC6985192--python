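"""RBF support-vector-machine classification of image time series.

The classifier takes the 92-dimensional feature vectors (four band
series per pixel-year), standardises each feature to zero mean and unit
variance on the training set, and fits a radial-basis-kernel SVM at cost
C = 1 and gamma = 1/92.  gamma equal to the reciprocal of the feature
dimension is the libsvm/e1071 default that accompanies per-feature
standardisation; on the raw index scale the same gamma leaves the kernel
nearly constant and the classifier degenerate, so the scaler is an
integral part of the model.  Multiclass decomposition is the
conventional one-vs-one; per-class probabilities come from Platt scaling
with pairwise coupling, fitted on an internal cross-validation seeded
through the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .consistency_rules import ClassMap
from .data_model import (
    BANDS,
    DEFAULT_VOCABULARY,
    N_FEATURES,
    N_STEPS,
    ClassVocabulary,
    TimeSeriesSample,
    build_feature_matrix,
)
from .validation import AccuracyReport, ConfusionMatrix, accuracies, confusion


@dataclass
class SvmConfig:
    """Hyperparameters of the time-series SVM."""

    C: float = 1.0
    gamma: float = 1.0 / N_FEATURES
    k_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class ProbabilityCube:
    """Per-pixel class probabilities for one mapped year."""

    year: int
    probs: np.ndarray  # (H, W, K)
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3 or self.probs.shape[2] != len(self.class_order):
            raise ValueError("probs must be (H, W, K) matching class_order")

    def validate(self, atol: float = 1e-6) -> None:
        if self.probs.min() < -atol or self.probs.max() > 1 + atol:
            raise ValueError("probabilities outside [0, 1]")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=atol):
            raise ValueError("pixel probabilities do not sum to 1")


@dataclass
class TrainedSvm:
    """A fitted scaler+SVM plus the fixed class order for probability output."""

    model: Pipeline
    class_order: tuple[str, ...]
    vocabulary: ClassVocabulary

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.model.predict(np.atleast_2d(features))

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """(n, K) probabilities in ``class_order`` (ascending class code)."""
        raw = self.model.predict_proba(np.atleast_2d(features))
        order = [list(self.model.classes_).index(c) for c in self.class_order]
        return raw[:, order]


def _svm_pipeline(config: SvmConfig, probability: bool) -> Pipeline:
    return make_pipeline(
        StandardScaler(),
        SVC(
            kernel="rbf",
            C=config.C,
            gamma=config.gamma,
            probability=probability,
            random_state=config.seed,
        ),
    )


def train_svm(
    samples: list[TimeSeriesSample],
    config: SvmConfig = SvmConfig(),
    vocabulary: ClassVocabulary = DEFAULT_VOCABULARY,
) -> TrainedSvm:
    """Fit the RBF SVM (with its feature scaler) on labelled samples."""
    features = build_feature_matrix(samples)
    labels = np.array([s.label for s in samples])
    present = sorted(set(labels), key=vocabulary.code)
    if len(present) < 2:
        raise ValueError("need at least 2 classes to train")
    model = _svm_pipeline(config, probability=True)
    model.fit(features, labels)
    return TrainedSvm(model, tuple(present), vocabulary)


@dataclass
class CrossValidationResult:
    overall: float
    users: dict[str, float]
    producers: dict[str, float]
    confusion: ConfusionMatrix

    @property
    def accuracy_report(self) -> AccuracyReport:
        return accuracies(self.confusion)


def cross_validate(
    samples: list[TimeSeriesSample],
    config: SvmConfig = SvmConfig(),
    vocabulary: ClassVocabulary = DEFAULT_VOCABULARY,
) -> CrossValidationResult:
    """Stratified k-fold cross-validation, pooling held-out predictions.

    If some class has fewer members than there are folds, stratification
    is impossible; a warning is issued and a plain shuffled split is used.
    """
    features = build_feature_matrix(samples)
    labels = np.array([s.label for s in samples])
    if config.k_folds > len(samples):
        raise ValueError("more folds than samples")

    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < config.k_folds:
        warnings.warn(
            "a class has fewer members than folds; falling back to "
            "non-stratified k-fold",
            stacklevel=2,
        )
        splitter = KFold(config.k_folds, shuffle=True, random_state=config.seed)
    else:
        splitter = StratifiedKFold(
            config.k_folds, shuffle=True, random_state=config.seed
        )

    predicted = np.empty(len(samples), dtype=labels.dtype)
    for train_idx, test_idx in splitter.split(features, labels):
        model = _svm_pipeline(config, probability=False)
        model.fit(features[train_idx], labels[train_idx])
        predicted[test_idx] = model.predict(features[test_idx])

    class_order = tuple(sorted(set(labels), key=vocabulary.code))
    cm = confusion(list(predicted), list(labels), class_order)
    report = accuracies(cm)
    return CrossValidationResult(
        overall=report.overall,
        users=report.users,
        producers=report.producers,
        confusion=cm,
    )


def classify_cube(
    model: TrainedSvm, cube: np.ndarray, year: int
) -> tuple[ProbabilityCube, ClassMap]:
    """Classify one year's 4-band raster cube pixel by pixel.

    ``cube`` has shape (4 bands, 23 steps, H, W) in the fixed band order;
    per-pixel features are built exactly as for training samples.  The
    label map is the probability argmax, ties broken by lowest class code.
    """
    cube = np.asarray(cube)
    if cube.ndim != 4 or cube.shape[0] != len(BANDS) or cube.shape[1] != N_STEPS:
        raise ValueError(
            f"expected cube of shape (4, {N_STEPS}, H, W), got {cube.shape}"
        )
    _, _, h, w = cube.shape
    features = cube.transpose(2, 3, 0, 1).reshape(h * w, N_FEATURES)
    probs = model.predict_proba(features)
    prob_cube = ProbabilityCube(year, probs.reshape(h, w, -1), model.class_order)
    # class_order is ascending code, and argmax returns the first maximum.
    codes = np.array([model.vocabulary.code(c) for c in model.class_order])
    label_map = ClassMap(year, codes[np.argmax(prob_cube.probs, axis=2)].astype(np.uint8))
    return prob_cube, label_map
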
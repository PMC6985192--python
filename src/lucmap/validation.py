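"""Accuracy assessment and area-trend diagnostics.

Conventions: confusion-matrix rows are predicted classes and columns are
reference classes.  Overall accuracy is trace/total; user's accuracy for
class c is the diagonal over the row sum (commission view) and producer's
accuracy the diagonal over the column sum (omission view).  Undefined
ratios (empty row or column) are reported as NaN, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .consistency_rules import ClassMap
from .data_model import DEFAULT_VOCABULARY, ClassVocabulary


@dataclass
class ConfusionMatrix:
    """K x K counts; rows = predicted, columns = reference."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square, matching class_order")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.class_order), columns=list(self.class_order)
        )


def confusion(
    predicted, reference, class_order: tuple[str, ...] | None = None
) -> ConfusionMatrix:
    """Tally predictions against reference labels."""
    predicted = list(predicted)
    reference = list(reference)
    if len(predicted) != len(reference):
        raise ValueError("predicted and reference must have equal length")
    if class_order is None:
        class_order = tuple(sorted(set(predicted) | set(reference)))
    if not predicted:
        k = len(class_order)
        return ConfusionMatrix(np.zeros((k, k), dtype=np.int64), class_order)
    # scikit-learn uses rows = true; transpose to rows = predicted.
    counts = _sk_confusion(reference, predicted, labels=list(class_order)).T
    return ConfusionMatrix(counts, class_order)


@dataclass
class AccuracyReport:
    overall: float
    users: dict[str, float]
    producers: dict[str, float]


def accuracies(cm: ConfusionMatrix) -> AccuracyReport:
    """Overall, user's and producer's accuracy from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(cm.counts).astype(float)
    row_sums = cm.counts.sum(axis=1).astype(float)
    col_sums = cm.counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        users = np.where(row_sums > 0, diag / row_sums, np.nan)
        producers = np.where(col_sums > 0, diag / col_sums, np.nan)
    return AccuracyReport(
        overall=float(diag.sum() / cm.total),
        users={c: float(users[i]) for i, c in enumerate(cm.class_order)},
        producers={c: float(producers[i]) for i, c in enumerate(cm.class_order)},
    )


def map_confusion(
    predicted: ClassMap,
    reference: ClassMap,
    vocabulary: ClassVocabulary = DEFAULT_VOCABULARY,
    exclude: np.ndarray | None = None,
) -> ConfusionMatrix:
    """Confusion matrix between two aligned class maps.

    No-data pixels, auxiliary-class pixels and pixels under ``exclude``
    are left out of the tally.
    """
    if predicted.grid.shape != reference.grid.shape:
        raise ValueError("maps are misaligned")
    aux_codes = {vocabulary.code(c) for c in vocabulary.auxiliary_classes}
    skip = (
        (predicted.grid == 0)
        | (reference.grid == 0)
        | np.isin(predicted.grid, sorted(aux_codes))
        | np.isin(reference.grid, sorted(aux_codes))
    )
    if exclude is not None:
        skip |= np.asarray(exclude, dtype=bool)
    keep = ~skip
    pred = [vocabulary.label(int(c)) for c in predicted.grid[keep]]
    ref = [vocabulary.label(int(c)) for c in reference.grid[keep]]
    order = tuple(sorted(set(pred) | set(ref), key=vocabulary.code))
    return confusion(pred, ref, order)


def area_series(
    maps: list[ClassMap],
    pixel_area_ha: float,
    vocabulary: ClassVocabulary = DEFAULT_VOCABULARY,
) -> pd.DataFrame:
    """Class-by-year area table in hectares; total area is conserved."""
    shapes = {m.grid.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError("maps are misaligned")
    records = {}
    all_labels = ["no-data"] + list(
        vocabulary.training_classes + vocabulary.auxiliary_classes
    )
    for m in sorted(maps, key=lambda m: m.year):
        counts = np.bincount(m.grid.ravel(), minlength=len(all_labels))
        records[m.year] = {
            label: counts[code] * pixel_area_ha
            for code, label in enumerate(all_labels)
        }
    frame = pd.DataFrame(records)
    frame.index.name = "class"
    return frame


def pearson(series_a, series_b) -> float:
    """Pearson correlation between two equal-length series."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance series")
    return float(stats.pearsonr(a, b).statistic)
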
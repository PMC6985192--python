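"""Training-sample quality control with self-organizing maps.

Noisy or mislabelled training samples degrade a classifier, so before
training the sample set is screened with repeated SOM clustering: a 2-D
Kohonen lattice is trained on the 92-dimensional feature vectors, each
neuron is labelled by majority vote of the samples it attracts, and a
sample's reliability is the fraction of independent SOM runs in which its
best-matching unit carries the sample's own label.  Samples whose
own-label frequency falls below a threshold (default 80%) are discarded.

Because the lattice is trained on features alone, a sample whose series
was generated by class A but which carries label B will land among class-A
neighbours in (nearly) every run, its BMU will be labelled A by majority
vote, and its own-label (B) frequency will be low — which is exactly the
error model this stage is designed to catch.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    DEFAULT_VOCABULARY,
    ClassVocabulary,
    TimeSeriesSample,
    build_feature_matrix,
)

#: Reserved reliability key for runs in which a sample's BMU had no label.
UNLABELLED = "unlabelled"


@dataclass
class SomGrid:
    """A trained 2-D neuron lattice with optional majority-vote labels."""

    xdim: int
    ydim: int
    weights: np.ndarray  # (xdim*ydim, n_features)
    neuron_labels: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.neuron_labels:
            self.neuron_labels = [None] * (self.xdim * self.ydim)

    @property
    def n_neurons(self) -> int:
        return self.xdim * self.ydim

    def lattice_coords(self) -> np.ndarray:
        """(n_neurons, 2) integer lattice coordinates, row-major."""
        ys, xs = np.divmod(np.arange(self.n_neurons), self.xdim)
        return np.column_stack([xs, ys]).astype(float)

    def bmu(self, features: np.ndarray) -> np.ndarray:
        """Index of the best-matching (nearest) unit for each feature row."""
        features = np.atleast_2d(features)
        # ||w - x||^2 = ||w||^2 - 2 w.x + ||x||^2; the ||x||^2 term is
        # constant per row and does not affect the argmin.
        d2 = (
            np.sum(self.weights**2, axis=1)[None, :]
            - 2.0 * features @ self.weights.T
        )
        return np.argmin(d2, axis=1)


def default_grid_side(n_samples: int) -> int:
    """Kohonen's heuristic of ~5*sqrt(n) neurons, on a square grid."""
    return max(1, math.ceil(math.sqrt(5.0 * math.sqrt(n_samples))))


def train_som(
    features: np.ndarray,
    xdim: int,
    ydim: int,
    epochs: int = 100,
    alpha_start: float = 0.05,
    alpha_end: float = 0.01,
    seed: int = 0,
) -> SomGrid:
    """Train an online Kohonen map on the feature rows.

    Per presented sample, the best-matching unit and its lattice
    neighbours move toward the sample; the learning rate decays linearly
    from ``alpha_start`` to ``alpha_end`` and the neighbourhood radius
    from max(xdim, ydim)/2 to 1, both over the full schedule of
    ``epochs`` passes through a reshuffled sample order.  The lattice
    kernel is Gaussian with the radius as its 3-sigma support, so by the
    end of training essentially only the best-matching unit moves and
    neurons decouple into distinct cluster prototypes.  Deterministic for
    a fixed seed.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    n, dim = features.shape
    if n == 0:
        raise ValueError("no features to train on")
    if xdim < 1 or ydim < 1:
        raise ValueError("grid dimensions must be >= 1")

    rng = np.random.default_rng(seed)
    lo = features.min(axis=0)
    hi = features.max(axis=0)
    weights = rng.uniform(lo, hi, size=(xdim * ydim, dim))
    grid = SomGrid(xdim, ydim, weights)
    coords = grid.lattice_coords()

    total = max(1, epochs * n - 1)
    r0 = max(xdim, ydim) / 2.0
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        for idx in order:
            frac = step / total
            alpha = alpha_start + (alpha_end - alpha_start) * frac
            radius = max(1.0, r0 + (1.0 - r0) * frac)
            x = features[idx]
            b = int(np.argmin(np.sum((weights - x) ** 2, axis=1)))
            d2 = np.sum((coords - coords[b]) ** 2, axis=1)
            sigma = radius / 3.0  # radius = 3-sigma support of the kernel
            h = np.exp(-d2 / (2.0 * sigma * sigma))
            weights += (alpha * h)[:, None] * (x - weights)
            step += 1
    return grid


def label_neurons(
    som: SomGrid,
    samples: list[TimeSeriesSample],
    features: np.ndarray | None = None,
) -> SomGrid:
    """Label each neuron by the modal class of the samples it attracts.

    Ties are broken in favour of the class with the higher global count in
    the sample set, then lexicographically.  Neurons attracting no sample
    stay unlabelled.
    """
    if features is None:
        features = build_feature_matrix(samples)
    bmus = som.bmu(features)
    global_counts: dict[str, int] = {}
    for s in samples:
        global_counts[s.label] = global_counts.get(s.label, 0) + 1

    labels: list[str | None] = [None] * som.n_neurons
    for neuron in np.unique(bmus):
        local: dict[str, int] = {}
        for i in np.flatnonzero(bmus == neuron):
            lab = samples[i].label
            local[lab] = local.get(lab, 0) + 1
        labels[int(neuron)] = min(
            local, key=lambda c: (-local[c], -global_counts.get(c, 0), c)
        )
    return SomGrid(som.xdim, som.ydim, som.weights, labels)


@dataclass
class SampleReliability:
    """Per-sample label frequencies across repeated SOM runs."""

    sample_id: int
    original_label: str
    label_frequency: dict[str, float]

    def own_frequency(self) -> float:
        return self.label_frequency.get(self.original_label, 0.0)


def evaluate_samples(
    samples: list[TimeSeriesSample],
    n_runs: int = 20,
    xdim: int | None = None,
    ydim: int | None = None,
    epochs: int = 100,
    alpha_start: float = 0.05,
    alpha_end: float = 0.01,
    seed: int = 0,
) -> list[SampleReliability]:
    """Estimate per-sample cluster-label frequencies over repeated runs.

    Each run trains a fresh SOM (run r uses seed ``seed + r``), labels its
    neurons by majority vote, and records each sample's BMU label; the
    frequency of class c for a sample is the fraction of runs in which its
    BMU was labelled c.  Frequencies sum to 1 over classes (plus the
    reserved ``unlabelled`` key, which cannot occur for a sample's own
    BMU since that neuron attracts at least the sample itself).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    features = build_feature_matrix(samples)
    n = len(samples)
    side = default_grid_side(n)
    xdim = xdim or side
    ydim = ydim or side

    tallies: list[dict[str, int]] = [dict() for _ in range(n)]
    for run in range(n_runs):
        som = train_som(
            features, xdim, ydim, epochs, alpha_start, alpha_end, seed=seed + run
        )
        som = label_neurons(som, samples, features)
        bmus = som.bmu(features)
        for i in range(n):
            lab = som.neuron_labels[int(bmus[i])] or UNLABELLED
            tallies[i][lab] = tallies[i].get(lab, 0) + 1

    return [
        SampleReliability(
            sample_id=i,
            original_label=samples[i].label,
            label_frequency={c: k / n_runs for c, k in sorted(tallies[i].items())},
        )
        for i in range(n)
    ]


def reduction_percentage(n_in: int, n_out: int) -> float:
    """Percentage reduction of the sample set, to one decimal place."""
    if n_in <= 0:
        raise ValueError("n_in must be positive")
    return round((n_in - n_out) / n_in * 100.0, 1)


@dataclass
class QCReport:
    """Outcome of threshold filtering: counts plus the per-sample table."""

    n_input: int
    n_retained: int
    n_removed: int
    reduction_pct: float
    threshold: float
    rows: list[dict]  # sample id, original label, frequencies, retained flag

    def write_csv(self, path) -> None:
        classes = sorted({c for row in self.rows for c in row["label_frequency"]})
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["sample_id", "original_label", *classes, "retained"])
            for row in self.rows:
                freqs = [row["label_frequency"].get(c, 0.0) for c in classes]
                writer.writerow(
                    [row["sample_id"], row["original_label"], *freqs,
                     int(row["retained"])]
                )


def filter_samples(
    reliabilities: list[SampleReliability],
    threshold: float,
    samples: list[TimeSeriesSample],
) -> tuple[list[TimeSeriesSample], list[TimeSeriesSample], QCReport]:
    """Retain samples whose own-label frequency is at least ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if len(reliabilities) != len(samples):
        raise ValueError("reliabilities and samples must be parallel")
    retained, removed, rows = [], [], []
    for rel, sample in zip(reliabilities, samples):
        keep = rel.own_frequency() >= threshold
        (retained if keep else removed).append(sample)
        rows.append(
            {
                "sample_id": rel.sample_id,
                "original_label": rel.original_label,
                "label_frequency": rel.label_frequency,
                "retained": keep,
            }
        )
    report = QCReport(
        n_input=len(samples),
        n_retained=len(retained),
        n_removed=len(removed),
        reduction_pct=reduction_percentage(len(samples), len(retained)),
        threshold=threshold,
        rows=rows,
    )
    return retained, removed, report
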
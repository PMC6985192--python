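"""Core domain types for satellite image time-series classification.

A labelled sample is one pixel-year of MOD13Q1-like observations: four
vegetation-index / reflectance bands (NDVI, EVI, NIR, MIR), each observed
23 times over one agricultural year (16-day composites).  Values live on
the physical scale, i.e. the MOD13Q1 integers divided by 10^4, so NDVI and
EVI are in [-1, 1].  The feature vector used throughout the pipeline is the
band-major concatenation of the four series: 4 x 23 = 92 numbers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date

import numpy as np

#: Fixed band order for feature construction (band-major concatenation).
BANDS: tuple[str, ...] = ("NDVI", "EVI", "NIR", "MIR")

#: Observations per band per agricultural year (16-day composites).
N_STEPS: int = 23

#: Feature-space dimension: 4 bands x 23 steps.
N_FEATURES: int = len(BANDS) * N_STEPS

#: Bands constrained to the index range [-1, 1].
_INDEX_BANDS = frozenset({"NDVI", "EVI"})


class VocabularyError(ValueError):
    """A label or code is not part of the class vocabulary."""


class SampleParseError(ValueError):
    """A sample CSV row could not be parsed into a valid sample."""


@dataclass(frozen=True)
class ClassVocabulary:
    """The class vocabulary: nine training classes plus auxiliary classes.

    Training classes are the land use/cover types the classifier learns;
    auxiliary classes (water, urban, sugarcane, secondary vegetation) are
    introduced only during post-processing.  Code 0 is reserved for no-data.
    """

    training_classes: tuple[str, ...] = (
        "cerrado",
        "fallow-cotton",
        "forest",
        "pasture",
        "soy-corn",
        "soy-cotton",
        "soy-fallow",
        "soy-millet",
        "soy-sunflower",
    )
    auxiliary_classes: tuple[str, ...] = (
        "water",
        "urban",
        "sugarcane",
        "secondary-vegetation",
    )
    colors: dict[str, str] = field(
        default_factory=lambda: {
            "cerrado": "#b8af4f",
            "fallow-cotton": "#f5e6a1",
            "forest": "#1b7837",
            "pasture": "#ffcc99",
            "soy-corn": "#e6550d",
            "soy-cotton": "#fd8d3c",
            "soy-fallow": "#fdae6b",
            "soy-millet": "#fdd0a2",
            "soy-sunflower": "#feedde",
            "water": "#4575b4",
            "urban": "#969696",
            "sugarcane": "#c994c7",
            "secondary-vegetation": "#a1d99b",
        }
    )

    def __post_init__(self) -> None:
        overlap = set(self.training_classes) & set(self.auxiliary_classes)
        if overlap:
            raise VocabularyError(f"classes in both sets: {sorted(overlap)}")

    @property
    def code_table(self) -> dict[str, int]:
        """Label -> small-integer raster code; 0 is reserved for no-data."""
        labels = self.training_classes + self.auxiliary_classes
        return {label: i + 1 for i, label in enumerate(labels)}

    @property
    def label_table(self) -> dict[int, str]:
        return {code: label for label, code in self.code_table.items()}

    def code(self, label: str) -> int:
        try:
            return self.code_table[label]
        except KeyError:
            raise VocabularyError(f"unknown class label {label!r}") from None

    def label(self, code: int) -> str:
        try:
            return self.label_table[code]
        except KeyError:
            raise VocabularyError(f"unknown class code {code}") from None

    def is_training(self, label: str) -> bool:
        return label in self.training_classes

    def write_code_table(self, path) -> None:
        """Write the label,code,color sidecar that makes rasters self-describing."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["label", "code", "color"])
            writer.writerow(["no-data", 0, "#000000"])
            for label, code in self.code_table.items():
                writer.writerow([label, code, self.colors.get(label, "#ffffff")])


#: Module-level default vocabulary, shared by all stages.
DEFAULT_VOCABULARY = ClassVocabulary()

#: Class census of the published Mato Grosso training set (the deposited,
#: quality-controlled 1,892-sample CSV this pipeline was designed around).
MATO_GROSSO_SAMPLE_COUNTS: dict[str, int] = {
    "cerrado": 379,
    "fallow-cotton": 29,
    "forest": 131,
    "pasture": 344,
    "soy-corn": 364,
    "soy-cotton": 352,
    "soy-fallow": 87,
    "soy-millet": 180,
    "soy-sunflower": 26,
}

#: Size of the Mato Grosso sample set before SOM quality control.
MATO_GROSSO_PRE_QC_COUNT: int = 2115


def class_frequencies_pct(counts: dict[str, int]) -> dict[str, float]:
    """Per-class frequency of a class census, in percent to one decimal."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("empty census")
    return {label: round(n / total * 100.0, 1) for label, n in counts.items()}


@dataclass
class TimeSeriesSample:
    """One labelled pixel-year: location, date span, and the 4 x 23 series."""

    longitude: float
    latitude: float
    start_date: date
    end_date: date
    label: str
    series: dict[str, np.ndarray]

    def validate(self, vocabulary: ClassVocabulary = DEFAULT_VOCABULARY) -> None:
        if not vocabulary.is_training(self.label):
            raise VocabularyError(f"label {self.label!r} is not a training class")
        if set(self.series) != set(BANDS):
            raise ValueError(f"expected bands {BANDS}, got {sorted(self.series)}")
        for band in BANDS:
            values = np.asarray(self.series[band], dtype=float)
            if values.shape != (N_STEPS,):
                raise ValueError(
                    f"band {band} has {values.size} values, expected {N_STEPS}"
                )
            if not np.all(np.isfinite(values)):
                raise ValueError(f"band {band} contains non-finite values")
            if band in _INDEX_BANDS and (values.min() < -1 or values.max() > 1):
                raise ValueError(f"band {band} outside [-1, 1]")


def build_feature_vector(sample: TimeSeriesSample) -> np.ndarray:
    """Concatenate the four band series, band-major, into a 92-vector.

    Order is fixed: NDVI[0..22], EVI[0..22], NIR[0..22], MIR[0..22].
    """
    parts = []
    for band in BANDS:
        if band not in sample.series:
            raise ValueError(f"sample is missing band {band}")
        values = np.asarray(sample.series[band], dtype=float)
        if values.shape != (N_STEPS,):
            raise ValueError(
                f"band {band} has {values.size} values, expected {N_STEPS}"
            )
        parts.append(values)
    vector = np.concatenate(parts)
    if not np.all(np.isfinite(vector)):
        raise ValueError("feature vector contains non-finite values")
    return vector


def build_feature_matrix(samples: list[TimeSeriesSample]) -> np.ndarray:
    """Stack per-sample feature vectors into an (n, 92) matrix."""
    return np.vstack([build_feature_vector(s) for s in samples])


def _csv_header() -> list[str]:
    header = ["longitude", "latitude", "start_date", "end_date", "label"]
    for band in BANDS:
        header.extend(f"{band}_{i}" for i in range(1, N_STEPS + 1))
    return header


def write_samples_csv(samples: list[TimeSeriesSample], path) -> None:
    """Write samples to CSV in the wide, band-major layout."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_csv_header())
        for sample in samples:
            row = [
                f"{sample.longitude:.6f}",
                f"{sample.latitude:.6f}",
                sample.start_date.isoformat(),
                sample.end_date.isoformat(),
                sample.label,
            ]
            for band in BANDS:
                row.extend(f"{v:.6g}" for v in sample.series[band])
            writer.writerow(row)


def read_samples_csv(
    path, vocabulary: ClassVocabulary = DEFAULT_VOCABULARY
) -> list[TimeSeriesSample]:
    """Read samples from CSV, validating every row.

    Raises :class:`SampleParseError` naming the offending row on a missing
    column, non-finite value, unknown label, or wrong series length.
    """
    expected = _csv_header()
    samples: list[TimeSeriesSample] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SampleParseError(f"{path}: empty file, expected a header row")
        missing = set(expected) - set(reader.fieldnames)
        if missing:
            raise SampleParseError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):  # line 1 is the header
            try:
                series = {
                    band: np.array(
                        [float(row[f"{band}_{j}"]) for j in range(1, N_STEPS + 1)]
                    )
                    for band in BANDS
                }
                sample = TimeSeriesSample(
                    longitude=float(row["longitude"]),
                    latitude=float(row["latitude"]),
                    start_date=date.fromisoformat(row["start_date"]),
                    end_date=date.fromisoformat(row["end_date"]),
                    label=row["label"],
                    series=series,
                )
                sample.validate(vocabulary)
            except (ValueError, TypeError, KeyError) as exc:
                raise SampleParseError(f"{path}: row {i}: {exc}") from exc
            samples.append(sample)
    return samples
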
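"""Synthetic vegetation-index time series and multi-year raster scenes.

The generator emulates the statistical structure the pipeline assumes:

* per-class seasonal profiles over the agricultural year (Sep 1 - Aug 31,
  23 sixteen-day composites) — stable high-NDVI forest, mildly seasonal
  cerrado, strongly seasonal pasture, one NDVI peak for single-crop
  classes and two peaks for double-crop classes, with MIR anti-phase to
  NDVI;
* labelled sample sets with optional label noise (a fraction of samples
  relabelled to a random other class, the error model the SOM quality
  control is designed to catch);
* small spatially patchy scenes: per-year 4-band cubes, truth maps,
  water/urban/sugarcane mask rectangles and two reference deforestation
  layers.

Mean curves are hand-designed sums of at most two Gaussian bumps plus a
baseline; they reproduce the qualitative class phenology, not any fitted
spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np

from .consistency_rules import AmazonClass, CerradoClass
from .data_model import (
    BANDS,
    DEFAULT_VOCABULARY,
    N_STEPS,
    ClassVocabulary,
    TimeSeriesSample,
)

#: Default per-band noise standard deviations.
DEFAULT_NOISE_SD = {"NDVI": 0.05, "EVI": 0.05, "NIR": 0.03, "MIR": 0.03}

#: Valid value range per band after noise (index bands are in [-1, 1],
#: reflectance bands in [0, 1]).
_BAND_RANGE = {
    "NDVI": (-1.0, 1.0),
    "EVI": (-1.0, 1.0),
    "NIR": (0.0, 1.0),
    "MIR": (0.0, 1.0),
}


@dataclass
class ClassPattern:
    """A class's mean seasonal curve per band plus per-band noise level."""

    label: str
    mean_curve: dict[str, np.ndarray]
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))

    def __post_init__(self) -> None:
        for band in BANDS:
            curve = np.asarray(self.mean_curve[band], dtype=float)
            if curve.shape != (N_STEPS,) or not np.all(np.isfinite(curve)):
                raise ValueError(f"invalid mean curve for band {band}")
            self.mean_curve[band] = curve
            if self.noise_sd[band] < 0:
                raise ValueError("noise_sd must be nonnegative")


def _bump(center: float, width: float, amplitude: float) -> np.ndarray:
    t = np.arange(N_STEPS, dtype=float)
    return amplitude * np.exp(-0.5 * ((t - center) / width) ** 2)


def _pattern(label: str, ndvi: np.ndarray, mir: np.ndarray) -> ClassPattern:
    """Build the four band curves from an NDVI and a MIR profile.

    EVI tracks NDVI at lower amplitude and NIR rises with green biomass;
    MIR is specified independently because it is driven by soil exposure
    and canopy water rather than greenness alone, and runs anti-phase to
    NDVI for every class.
    """
    ndvi = np.clip(ndvi, -1.0, 1.0)
    curves = {
        "NDVI": ndvi,
        "EVI": np.clip(0.55 * ndvi + 0.05, -1.0, 1.0),
        "NIR": np.clip(0.18 + 0.30 * ndvi, 0.0, 1.0),
        "MIR": np.clip(mir, 0.0, 1.0),
    }
    return ClassPattern(label, curves)


def default_patterns(
    vocabulary: ClassVocabulary = DEFAULT_VOCABULARY,
) -> dict[str, ClassPattern]:
    """One seasonal pattern per training class, keyed by label.

    The crop peaks fall in the wet season (roughly steps 4-16 of the
    September-anchored agricultural year).  Forest is high and nearly
    flat; cerrado's woody phenology gives a mild, lagged seasonal swing
    while pasture grass greens up sharply with the first rains and browns
    in the dry season.  Double-crop classes place a soybean peak early
    and the second crop's peak later; that peak's timing, width and
    amplitude distinguish corn, millet, sunflower and cotton (in order of
    harvest).  Crop MIR sits high over bare off-season soil and dips
    during each green cycle.
    """
    t = np.arange(N_STEPS, dtype=float)
    year = 2 * np.pi * t / N_STEPS

    def soy(second_center, second_width, second_amp, mir_dip_w, mir_dip_a):
        ndvi = (
            0.22
            + _bump(4.5, 1.6, 0.62)
            + _bump(second_center, second_width, second_amp)
        )
        mir = (
            0.42
            - _bump(4.5, 1.9, 0.28)
            - _bump(second_center, mir_dip_w, mir_dip_a)
        )
        return ndvi, mir

    ndvi_mir = {
        "forest": (
            0.85 + 0.02 * np.cos(year - 2 * np.pi * 8 / N_STEPS),
            0.08 - 0.02 * np.cos(year - 2 * np.pi * 8 / N_STEPS),
        ),
        "cerrado": (
            0.56 + 0.08 * np.cos(year - 2 * np.pi * 12 / N_STEPS),
            0.20 + 0.05 * np.cos(year - 2 * np.pi * 22 / N_STEPS),
        ),
        "pasture": (
            0.30 + _bump(8.5, 3.8, 0.45),
            0.36 - _bump(8.5, 4.2, 0.18),
        ),
        "soy-fallow": (
            0.22 + _bump(6.4, 1.9, 0.65),
            0.42 - _bump(6.4, 2.2, 0.30),
        ),
        "fallow-cotton": (
            0.22 + _bump(13.6, 2.6, 0.62),
            0.42 - _bump(13.6, 2.9, 0.30),
        ),
        "soy-corn": soy(10.5, 1.9, 0.60, 2.2, 0.26),
        "soy-cotton": soy(15.0, 2.4, 0.58, 2.7, 0.26),
        "soy-millet": soy(8.8, 1.0, 0.36, 1.3, 0.12),
        "soy-sunflower": soy(12.3, 1.7, 0.46, 2.0, 0.20),
    }
    return {
        label: _pattern(label, *ndvi_mir[label])
        for label in vocabulary.training_classes
    }


def _draw_series(
    pattern: ClassPattern, rng: np.random.Generator, n: int
) -> dict[str, np.ndarray]:
    """Draw n noisy series from a pattern; returns band -> (n, 23) array."""
    out = {}
    for band in BANDS:
        lo, hi = _BAND_RANGE[band]
        noise = rng.normal(0.0, pattern.noise_sd[band], size=(n, N_STEPS))
        out[band] = np.clip(pattern.mean_curve[band] + noise, lo, hi)
    return out


def generate_samples(
    patterns: dict[str, ClassPattern],
    n_per_class: int,
    mislabel_rate: float = 0.0,
    seed: int = 0,
    vocabulary: ClassVocabulary = DEFAULT_VOCABULARY,
    return_truth: bool = False,
):
    """Generate n_per_class noisy samples per training class.

    A fraction ``mislabel_rate`` of samples (independent Bernoulli draws)
    keeps its true-class series but carries a label drawn uniformly from
    the other eight classes.  With ``return_truth`` the list of generating
    (true) labels is returned alongside the samples, so quality-control
    recovery can be measured.
    """
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    if not 0.0 <= mislabel_rate <= 1.0:
        raise ValueError("mislabel_rate must be in [0, 1]")
    missing = set(vocabulary.training_classes) - set(patterns)
    if missing:
        raise ValueError(f"patterns missing for classes {sorted(missing)}")

    rng = np.random.default_rng(seed)
    samples: list[TimeSeriesSample] = []
    truth: list[str] = []
    labels = list(vocabulary.training_classes)
    for label in labels:
        series = _draw_series(patterns[label], rng, n_per_class)
        lon = rng.uniform(-61.0, -50.0, size=n_per_class)
        lat = rng.uniform(-18.0, -7.0, size=n_per_class)
        flip = rng.random(n_per_class) < mislabel_rate
        others = [c for c in labels if c != label]
        wrong = rng.choice(len(others), size=n_per_class)
        for i in range(n_per_class):
            given = others[wrong[i]] if flip[i] else label
            samples.append(
                TimeSeriesSample(
                    longitude=float(lon[i]),
                    latitude=float(lat[i]),
                    start_date=date(2013, 9, 1),
                    end_date=date(2014, 8, 31),
                    label=given,
                    series={b: series[b][i] for b in BANDS},
                )
            )
            truth.append(label)
    if return_truth:
        return samples, truth
    return samples


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle: rows [row0, row1), cols [col0, col1)."""

    row0: int
    col0: int
    row1: int
    col1: int

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)

    def within(self, height: int, width: int) -> bool:
        return (
            0 <= self.row0 < self.row1 <= height
            and 0 <= self.col0 < self.col1 <= width
        )

    def overlaps(self, other: "Rect") -> bool:
        return (
            self.row0 < other.row1
            and other.row0 < self.row1
            and self.col0 < other.col1
            and other.col0 < self.col1
        )


@dataclass
class Patch:
    """A rectangle with a (possibly year-varying) class label."""

    rect: Rect
    labels: dict[int, str]  # year -> label

    @classmethod
    def constant(cls, rect: Rect, label: str, years: list[int]) -> "Patch":
        return cls(rect, {y: label for y in years})


@dataclass
class SceneSpec:
    """Layout of a synthetic scene: patches, masks and reference coverage."""

    width: int
    height: int
    years: tuple[int, ...]
    patches: list[Patch] = field(default_factory=list)
    background: str = "cerrado"
    mislabel_rate: float = 0.0
    seed: int = 0
    water: Rect | None = None
    urban: Rect | None = None
    sugarcane: Rect | None = None
    amazon_rect: Rect | None = None  # reference-layer split; None = top half

    def __post_init__(self) -> None:
        self.years = tuple(self.years)
        if not 0.0 <= self.mislabel_rate <= 1.0:
            raise ValueError("mislabel_rate must be in [0, 1]")
        for patch in self.patches:
            if not patch.rect.within(self.height, self.width):
                raise ValueError(f"patch {patch.rect} outside scene bounds")
        mask_rects = [
            r for r in (self.water, self.urban, self.sugarcane) if r is not None
        ]
        for i, a in enumerate(mask_rects):
            for b in mask_rects[i + 1 :]:
                if a.overlaps(b):
                    raise ValueError(f"overlapping mask rectangles {a} and {b}")


@dataclass
class Scene:
    """A generated scene: data cube, truth, masks and reference layers."""

    spec: SceneSpec
    cube: np.ndarray  # (n_years, 4 bands, 23 steps, H, W) float32
    truth: list  # per-year ClassMap
    masks: dict[str, np.ndarray]  # name -> (H, W) bool
    amazon: np.ndarray  # (H, W) AmazonClass values
    cerrado: np.ndarray  # (H, W) CerradoClass values


#: Classes the reference layers regard as human use.
_ANTHROPIC = frozenset(
    {"pasture", "soy-corn", "soy-cotton", "soy-fallow", "soy-millet",
     "soy-sunflower", "fallow-cotton"}
)


def _truth_grids(
    spec: SceneSpec, vocabulary: ClassVocabulary
) -> tuple[np.ndarray, dict[int, dict[str, np.ndarray]]]:
    """Per-year truth code grids and per-year {label: pixel-mask} index."""
    grids = np.full(
        (len(spec.years), spec.height, spec.width),
        vocabulary.code(spec.background),
        dtype=np.uint8,
    )
    for patch in spec.patches:
        rs, cs = patch.rect.slices()
        for yi, year in enumerate(spec.years):
            if year in patch.labels:
                grids[yi, rs, cs] = vocabulary.code(patch.labels[year])
    by_label: dict[int, dict[str, np.ndarray]] = {}
    for yi in range(len(spec.years)):
        masks = {}
        for code in np.unique(grids[yi]):
            masks[vocabulary.label(int(code))] = grids[yi] == code
        by_label[yi] = masks
    return grids, by_label


def generate_scene(
    spec: SceneSpec,
    patterns: dict[str, ClassPattern] | None = None,
    vocabulary: ClassVocabulary = DEFAULT_VOCABULARY,
) -> Scene:
    """Generate the data cube, truth maps, masks and reference layers.

    Reference layers are derived from the first year's truth: within the
    Amazon rectangle, forest pixels are Forest and anthropic pixels
    Deforestation (everything else Non-Forest); the complement is covered
    by the Cerrado layer, splitting Anthropized from Non-Anthropized.
    """
    if patterns is None:
        patterns = default_patterns(vocabulary)
    from .consistency_rules import ClassMap  # local import avoids cycle at type use

    rng = np.random.default_rng(spec.seed)
    grids, by_label = _truth_grids(spec, vocabulary)
    n_years = len(spec.years)
    cube = np.empty(
        (n_years, len(BANDS), N_STEPS, spec.height, spec.width), dtype=np.float32
    )
    for yi in range(n_years):
        for label in sorted(by_label[yi]):
            mask = by_label[yi][label]
            n_pix = int(mask.sum())
            series = _draw_series(patterns[label], rng, n_pix)
            for bi, band in enumerate(BANDS):
                plane = cube[yi, bi]  # (23, H, W)
                plane[:, mask] = series[band].T

    masks = {}
    for name in ("water", "urban", "sugarcane"):
        grid = np.zeros((spec.height, spec.width), dtype=bool)
        rect = getattr(spec, name)
        if rect is not None:
            if not rect.within(spec.height, spec.width):
                raise ValueError(f"{name} mask {rect} outside scene bounds")
            rs, cs = rect.slices()
            grid[rs, cs] = True
        masks[name] = grid

    amazon_rect = spec.amazon_rect or Rect(0, 0, spec.height // 2, spec.width)
    in_amazon = np.zeros((spec.height, spec.width), dtype=bool)
    rs, cs = amazon_rect.slices()
    in_amazon[rs, cs] = True

    base = grids[0]
    anthropic = np.isin(
        base, [vocabulary.code(c) for c in sorted(_ANTHROPIC)]
    )
    forest = base == vocabulary.code("forest")
    amazon = np.where(
        in_amazon,
        np.where(
            forest,
            AmazonClass.FOREST,
            np.where(anthropic, AmazonClass.DEFORESTATION, AmazonClass.NON_FOREST),
        ),
        AmazonClass.ABSENT,
    ).astype(np.uint8)
    cerrado = np.where(
        ~in_amazon,
        np.where(anthropic, CerradoClass.ANTHROPIZED, CerradoClass.NON_ANTHROPIZED),
        CerradoClass.ABSENT,
    ).astype(np.uint8)

    truth = [ClassMap(year, grids[yi]) for yi, year in enumerate(spec.years)]
    return Scene(spec, cube, truth, masks, amazon, cerrado)
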
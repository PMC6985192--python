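"""Post-classification consistency rules for multi-year class maps.

Three corrections are applied after smoothing, in this order:

1. **Base-map fusion** — the first mapped year is reconciled with two
   reference deforestation-monitoring layers: an Amazon-style layer with
   values {Forest, Non-Forest, Deforestation} and a Cerrado-style layer
   with values {Anthropized, Non-Anthropized}.  Five per-pixel rules,
   first match wins.

2. **Trajectory (LUC) rules** — each pixel's multi-year class sequence is
   rewritten by ten ordered rules that remove implausible transitions
   (e.g. cerrado cannot become pristine forest) and introduce the
   *secondary vegetation* class for forest regrowth on previously cleared
   land.  Rules operate on a four-letter alphabet: F (forest), C
   (cerrado), P (pasture) and S (any soybean class); every other class is
   opaque to the rules.

3. **Auxiliary masks** — water, urban and sugarcane rasters overwrite the
   classification, with precedence water > urban > sugarcane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .data_model import ClassVocabulary, DEFAULT_VOCABULARY


class AmazonClass(IntEnum):
    """Amazon-style deforestation reference layer values (0 = not covered)."""

    ABSENT = 0
    FOREST = 1
    NON_FOREST = 2
    DEFORESTATION = 3


class CerradoClass(IntEnum):
    """Cerrado-style reference layer values (0 = not covered)."""

    ABSENT = 0
    ANTHROPIZED = 1
    NON_ANTHROPIZED = 2


@dataclass
class ClassMap:
    """A per-year categorical raster of class codes."""

    year: int
    grid: np.ndarray  # (H, W) integer class codes

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def copy(self) -> "ClassMap":
        return ClassMap(self.year, self.grid.copy())


@dataclass
class ReferenceLayers:
    """Reference deforestation layers; each pixel is covered by at most one."""

    amazon: np.ndarray  # (H, W) of AmazonClass values
    cerrado: np.ndarray  # (H, W) of CerradoClass values

    def __post_init__(self) -> None:
        self.amazon = np.asarray(self.amazon)
        self.cerrado = np.asarray(self.cerrado)
        if self.amazon.shape != self.cerrado.shape:
            raise ValueError("amazon and cerrado layers must be aligned")
        both = (self.amazon != AmazonClass.ABSENT) & (
            self.cerrado != CerradoClass.ABSENT
        )
        if both.any():
            raise ValueError(
                f"{int(both.sum())} pixels covered by both reference layers"
            )


@dataclass
class TrajectoryStack:
    """Per-pixel class-code sequences over an ordered run of years."""

    years: tuple[int, ...]
    codes: np.ndarray  # (n_years, H, W)
    vocabulary: ClassVocabulary = field(default_factory=lambda: DEFAULT_VOCABULARY)

    def __post_init__(self) -> None:
        self.years = tuple(self.years)
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 3 or self.codes.shape[0] != len(self.years):
            raise ValueError("codes must be (n_years, H, W) matching years")

    @classmethod
    def from_maps(
        cls, maps: list[ClassMap], vocabulary: ClassVocabulary = DEFAULT_VOCABULARY
    ) -> "TrajectoryStack":
        maps = sorted(maps, key=lambda m: m.year)
        years = tuple(m.year for m in maps)
        return cls(years, np.stack([m.grid for m in maps]), vocabulary)

    def to_maps(self) -> list[ClassMap]:
        return [ClassMap(y, self.codes[i].copy()) for i, y in enumerate(self.years)]


# Letters of the rule alphabet.  "O" is opaque: it never matches a rule.
_SOY_CLASSES = ("soy-corn", "soy-cotton", "soy-fallow", "soy-millet", "soy-sunflower")


def to_alphabet(code: int, vocabulary: ClassVocabulary = DEFAULT_VOCABULARY) -> str:
    """Map a class code to the rule alphabet: F, C, P, S or O (other).

    S aggregates exactly the five soybean classes (any class containing a
    soybean cycle); fallow-cotton has no soybean cycle and is opaque, as
    are the auxiliary classes and no-data.
    """
    if code == 0:
        return "O"
    label = vocabulary.label(int(code))  # raises on unknown code
    if label == "forest":
        return "F"
    if label == "cerrado":
        return "C"
    if label == "pasture":
        return "P"
    if label in _SOY_CLASSES:
        return "S"
    return "O"


# The ten trajectory rules, in application order.  Each is a contiguous
# left-hand letter pattern and the rewrites at its starred positions
# ("V" denotes secondary vegetation):
#   1. C,F            -> star 1 := C      (cerrado cannot become forest)
#   2. C,C,P,C        -> star 2 := C      (one-year pasture blip in cerrado)
#   3. C,C,S,C        -> star 2 := C      (one-year soy blip in cerrado)
#   4. P,P,C,C,P      -> stars 2,3 := P   (two-year cerrado blip in pasture)
#   5. F,C,F,F        -> star 1 := F      (one-year cerrado blip in forest)
#   6. F,F,C,F        -> star 2 := F
#   7. F,C,F          -> star 1 := F
#   8. F,C            -> star 1 := F
#   9. F,F,P,F        -> star 3 := V      (regrowth after clearing: SV)
#  10. P,P,F,P        -> star 2 := V
LUC_RULES: tuple[tuple[tuple[str, ...], dict[int, str]], ...] = (
    (("C", "F"), {1: "C"}),
    (("C", "C", "P", "C"), {2: "C"}),
    (("C", "C", "S", "C"), {2: "C"}),
    (("P", "P", "C", "C", "P"), {2: "P", 3: "P"}),
    (("F", "C", "F", "F"), {1: "F"}),
    (("F", "F", "C", "F"), {2: "F"}),
    (("F", "C", "F"), {1: "F"}),
    (("F", "C"), {1: "F"}),
    (("F", "F", "P", "F"), {3: "V"}),
    (("P", "P", "F", "P"), {2: "V"}),
)

_LETTER_TO_LABEL = {
    "F": "forest",
    "C": "cerrado",
    "P": "pasture",
    "V": "secondary-vegetation",
}


def _check_aligned(*grids: np.ndarray) -> None:
    shapes = {g.shape for g in grids}
    if len(shapes) > 1:
        raise ValueError(f"misaligned rasters: shapes {sorted(shapes)}")


def apply_masks(
    class_map: ClassMap,
    water: np.ndarray,
    urban: np.ndarray,
    sugarcane: np.ndarray,
    vocabulary: ClassVocabulary = DEFAULT_VOCABULARY,
) -> ClassMap:
    """Overwrite masked pixels with auxiliary codes; water > urban > sugarcane."""
    water = np.asarray(water, dtype=bool)
    urban = np.asarray(urban, dtype=bool)
    sugarcane = np.asarray(sugarcane, dtype=bool)
    _check_aligned(class_map.grid, water, urban, sugarcane)
    out = class_map.grid.copy()
    out[sugarcane] = vocabulary.code("sugarcane")
    out[urban] = vocabulary.code("urban")
    out[water] = vocabulary.code("water")
    return ClassMap(class_map.year, out)


def apply_basemap_rules(
    base_map: ClassMap,
    refs: ReferenceLayers,
    vocabulary: ClassVocabulary = DEFAULT_VOCABULARY,
) -> ClassMap:
    """Reconcile the base-year map with the reference layers.

    Per pixel, the first matching rule wins; pixels matching no rule are
    unchanged:

    1. Amazon=Forest                          -> forest
    2. Amazon=Non-Forest      and map=forest  -> cerrado
    3. Amazon=Deforestation   and map=forest  -> secondary-vegetation
    4. Cerrado=Non-Anthropized and map=forest -> cerrado
    5. Cerrado=Anthropized    and map=forest  -> secondary-vegetation
    """
    _check_aligned(base_map.grid, refs.amazon)
    m = base_map.grid
    forest = vocabulary.code("forest")
    cerrado = vocabulary.code("cerrado")
    sv = vocabulary.code("secondary-vegetation")
    is_forest = m == forest

    conditions = [
        refs.amazon == AmazonClass.FOREST,
        (refs.amazon == AmazonClass.NON_FOREST) & is_forest,
        (refs.amazon == AmazonClass.DEFORESTATION) & is_forest,
        (refs.cerrado == CerradoClass.NON_ANTHROPIZED) & is_forest,
        (refs.cerrado == CerradoClass.ANTHROPIZED) & is_forest,
    ]
    results = [forest, cerrado, sv, cerrado, sv]
    out = np.select(conditions, results, default=m.astype(np.int64)).astype(m.dtype)
    return ClassMap(base_map.year, out)


def rewrite_trajectory(
    letters: list[str], codes: list[int], vocabulary: ClassVocabulary
) -> list[int]:
    """Apply the ten trajectory rules to one pixel's sequence, in place.

    Scanning is position-major: windows slide left to right over the
    sequence, and at each starting position the rules are tried in
    numbered order, the first matching rule rewriting its starred
    positions immediately before the scan advances.  Per-position rule
    priority is what makes the ten published rewrites exact: a whole-
    trajectory pass of rule 1 (cerrado can never turn into forest) would
    consume the cerrado-blip-in-forest patterns that rules 5-7 repair.
    Returns the list of rule indices (0-based) that fired at least once.
    """
    n = len(letters)
    fired: list[int] = []
    for j in range(n):
        for rule_idx, (lhs, rewrites) in enumerate(LUC_RULES):
            width = len(lhs)
            if j + width > n:
                continue
            if all(letters[j + k] == lhs[k] for k in range(width)):
                for pos, letter in rewrites.items():
                    letters[j + pos] = letter
                    codes[j + pos] = vocabulary.code(_LETTER_TO_LABEL[letter])
                if rule_idx not in fired:
                    fired.append(rule_idx)
                break  # advance to the next window start
    return fired


def apply_luc_rules(
    stack: TrajectoryStack, frozen: np.ndarray | None = None
) -> tuple[TrajectoryStack, dict[int, int]]:
    """Rewrite every pixel trajectory with the ten ordered rules.

    ``frozen`` is an optional boolean raster of pixels (e.g. under
    water/urban/sugarcane masks) that are excluded from rewriting.
    Returns the rewritten stack and a report mapping 1-based rule number
    to the count of pixels that rule changed.
    """
    vocab = stack.vocabulary
    n_years, h, w = stack.codes.shape
    flat = stack.codes.reshape(n_years, h * w)
    out = flat.copy()
    if frozen is not None:
        frozen = np.asarray(frozen, dtype=bool)
        _check_aligned(stack.codes[0], frozen)
    keep = (
        np.ones(h * w, dtype=bool) if frozen is None else ~frozen.reshape(h * w)
    )

    report = {i + 1: 0 for i in range(len(LUC_RULES))}
    active = flat[:, keep]
    # Rewriting is per-trajectory, so run the scan once per distinct
    # trajectory and broadcast the result back to all pixels sharing it.
    uniq, inverse = np.unique(active.T, axis=0, return_inverse=True)
    rewritten = np.empty_like(uniq)
    per_uniq_fired: list[list[int]] = []
    for u in range(uniq.shape[0]):
        codes = [int(c) for c in uniq[u]]
        letters = [to_alphabet(c, vocab) for c in codes]
        fired = rewrite_trajectory(letters, codes, vocab)
        rewritten[u] = codes
        per_uniq_fired.append(fired)

    counts = np.bincount(inverse, minlength=uniq.shape[0])
    for u, fired in enumerate(per_uniq_fired):
        for rule_idx in fired:
            report[rule_idx + 1] += int(counts[u])

    out[:, keep] = rewritten[inverse].T
    return TrajectoryStack(stack.years, out.reshape(n_years, h, w), vocab), report


def run_postprocessing(
    maps: list[ClassMap],
    masks: dict[str, np.ndarray],
    refs: ReferenceLayers,
    vocabulary: ClassVocabulary = DEFAULT_VOCABULARY,
    apply_basemap: bool = True,
) -> tuple[list[ClassMap], dict[int, int]]:
    """Full post-processing: base-map fusion, trajectory rules, then masks.

    ``maps`` must cover consecutive years.  Masked pixels are frozen during
    trajectory rewriting and finally overwritten with their auxiliary code
    on every year.  Returns the final maps and the per-rule change report.
    """
    maps = sorted(maps, key=lambda m: m.year)
    years = [m.year for m in maps]
    if years != list(range(years[0], years[0] + len(years))):
        raise ValueError(f"year gaps in {years}; consecutive years required")
    for name in ("water", "urban", "sugarcane"):
        if name not in masks:
            raise ValueError(f"missing mask {name!r}")

    first = apply_basemap_rules(maps[0], refs, vocabulary) if apply_basemap else maps[0]
    corrected = [first.copy()] + [m.copy() for m in maps[1:]]

    report: dict[int, int] = {i + 1: 0 for i in range(len(LUC_RULES))}
    if len(corrected) >= 2:
        frozen = (
            np.asarray(masks["water"], dtype=bool)
            | np.asarray(masks["urban"], dtype=bool)
            | np.asarray(masks["sugarcane"], dtype=bool)
        )
        stack = TrajectoryStack.from_maps(corrected, vocabulary)
        stack, report = apply_luc_rules(stack, frozen=frozen)
        corrected = stack.to_maps()

    final = [
        apply_masks(m, masks["water"], masks["urban"], masks["sugarcane"], vocabulary)
        for m in corrected
    ]
    return final, report
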
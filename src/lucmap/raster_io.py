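"""Reading and writing the pipeline's raster artifacts as TIFF files.

Class maps are written as uint8 single-band TIFFs with a CSV sidecar code
table (label, code, hex colour) so the rasters are self-describing;
probability cubes as multi-band float32 TIFFs with a class-order sidecar.
Rasters are plain pixel arrays — no map projection metadata is attached.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import tifffile

from .classify import ProbabilityCube
from .consistency_rules import ClassMap
from .data_model import DEFAULT_VOCABULARY, ClassVocabulary


def write_class_map(
    path, class_map: ClassMap, vocabulary: ClassVocabulary = DEFAULT_VOCABULARY
) -> None:
    path = Path(path)
    tifffile.imwrite(path, class_map.grid.astype(np.uint8))
    vocabulary.write_code_table(path.with_suffix(".codes.csv"))


def read_class_map(path, year: int) -> ClassMap:
    return ClassMap(year, tifffile.imread(path))


def write_probability_cube(path, cube: ProbabilityCube) -> None:
    """K-band float32 TIFF plus a sidecar listing the class order."""
    path = Path(path)
    # band-major layout: (K, H, W)
    tifffile.imwrite(path, cube.probs.transpose(2, 0, 1).astype(np.float32))
    with open(path.with_suffix(".classes.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["band", "label"])
        for i, label in enumerate(cube.class_order, start=1):
            writer.writerow([i, label])


def read_probability_cube(path, year: int) -> ProbabilityCube:
    path = Path(path)
    probs = tifffile.imread(path).astype(float)
    with open(path.with_suffix(".classes.csv"), newline="") as fh:
        reader = csv.DictReader(fh)
        class_order = tuple(row["label"] for row in reader)
    return ProbabilityCube(year, probs.transpose(1, 2, 0), class_order)


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), mask.astype(np.uint8))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(bool)


def write_band_cube(path, cube: np.ndarray) -> None:
    """One year's (4 bands, 23 steps, H, W) cube as float32 TIFF."""
    tifffile.imwrite(Path(path), np.asarray(cube, dtype=np.float32))


def read_band_cube(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.float32)


def write_reference_layer(path, layer: np.ndarray) -> None:
    tifffile.imwrite(Path(path), layer.astype(np.uint8))


def read_reference_layer(path) -> np.ndarray:
    return tifffile.imread(Path(path))
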
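"""End-to-end orchestration: samples -> QC -> SVM -> smoothing -> rules -> validation.

The pipeline mirrors the map-production sequence: quality-control the
training samples with repeated SOM clustering, train the RBF SVM,
classify each year's raster cube into class probabilities, smooth the
probabilities with the Bayesian neighbourhood filter, enforce base-map
and trajectory consistency rules, overlay the auxiliary masks, and
finally assess the maps against the reference truth.

A single master seed fans out to per-stage seeds (master * 1000 + a fixed
stage offset, modulo 2^31) so any stage can be re-run in isolation and
the full run is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import bayes_smooth, classify, consistency_rules, raster_io, som_qc, synthetic
from .consistency_rules import ClassMap, ReferenceLayers
from .data_model import DEFAULT_VOCABULARY, ClassVocabulary, write_samples_csv
from .validation import area_series, map_confusion

logger = logging.getLogger("lucmap")

#: Fixed per-stage seed offsets (master*1000 + offset, mod 2^31).
STAGE_OFFSETS = {"simulate": 1, "qc": 2, "svm": 3, "smooth": 4}


def stage_seed(master: int, stage: str) -> int:
    return (master * 1000 + STAGE_OFFSETS[stage]) % (2**31)


@dataclass
class PipelineConfig:
    """All pipeline parameters, serialisable to a flat YAML file."""

    # scene / samples
    width: int = 30
    height: int = 30
    years: tuple[int, ...] = (2001, 2002, 2003, 2004)
    n_per_class: int = 100
    mislabel_rate: float = 0.1
    # SOM quality control
    som_runs: int = 20
    som_epochs: int = 100
    som_xdim: int | None = None
    som_ydim: int | None = None
    som_alpha_start: float = 0.05
    som_alpha_end: float = 0.01
    threshold: float = 0.8
    skip_qc: bool = False
    # SVM
    svm_c: float = 1.0
    svm_gamma: float = 1.0 / 92.0
    k_folds: int = 5
    # smoothing
    sigma2: float = 10.0
    radius: int = 1
    # bookkeeping
    pixel_area_ha: float = 6.25
    seed: int = 0

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["years"] = list(self.years)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "years" in data:
            data["years"] = tuple(data["years"])
        return cls(**data)


@dataclass
class PipelineResult:
    config: PipelineConfig
    samples: list
    retained: list
    qc_report: som_qc.QCReport | None
    cv_result: classify.CrossValidationResult
    prob_cubes: list
    smoothed_cubes: list
    smoothed_maps: list[ClassMap]
    final_maps: list[ClassMap]
    rule_report: dict[int, int]
    truth: list[ClassMap]
    agreement: float
    areas: object  # pandas DataFrame


def _checksum(array: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(array).tobytes()).hexdigest()[:12]


def default_scene_spec(
    width: int = 30, height: int = 30, years: tuple[int, ...] = (2001, 2002, 2003, 2004),
    seed: int = 0,
) -> synthetic.SceneSpec:
    """A small patchy scene exercising every post-processing path.

    Includes stable forest / pasture / double-crop patches on a cerrado
    background, a forest patch cleared to pasture for one year and then
    regrowing (the secondary-vegetation trajectory), the three auxiliary
    mask rectangles, and an Amazon-reference rectangle over the top half.
    """
    if len(years) < 4:
        raise ValueError("default scene needs >= 4 years")
    y = list(years)
    sy = lambda r: {yr: lab for yr, lab in zip(y, r + [r[-1]] * (len(y) - len(r)))}
    fr = height // 2  # amazon/cerrado split row
    patches = [
        synthetic.Patch.constant(
            synthetic.Rect(0, 0, int(fr * 0.85), int(width * 0.42)), "forest", y
        ),
        # cleared in the 3rd year, forest signal back in the 4th
        synthetic.Patch(
            synthetic.Rect(2, int(width * 0.55), 8, int(width * 0.8)),
            sy(["forest", "forest", "pasture", "forest"]),
        ),
        synthetic.Patch.constant(
            synthetic.Rect(int(height * 0.66), 2, int(height * 0.93), int(width * 0.33)),
            "pasture", y,
        ),
        synthetic.Patch.constant(
            synthetic.Rect(int(height * 0.6), int(width * 0.46),
                           int(height * 0.9), int(width * 0.8)),
            "soy-corn", y,
        ),
    ]
    return synthetic.SceneSpec(
        width=width,
        height=height,
        years=tuple(years),
        patches=patches,
        background="cerrado",
        seed=seed,
        water=synthetic.Rect(height - 5, width - 4, height - 1, width),
        urban=synthetic.Rect(0, width - 4, 3, width),
        sugarcane=synthetic.Rect(height // 3, width - 4, height // 3 + 3, width - 1),
        amazon_rect=synthetic.Rect(0, 0, fr, width),
    )


def run_pipeline(
    config: PipelineConfig,
    scene: synthetic.Scene | None = None,
    samples: list | None = None,
    output_dir: str | Path | None = None,
    vocabulary: ClassVocabulary = DEFAULT_VOCABULARY,
) -> PipelineResult:
    """Run the full pipeline; simulate inputs where none are supplied."""
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    patterns = synthetic.default_patterns(vocabulary)
    sim_seed = stage_seed(config.seed, "simulate")
    if samples is None:
        logger.info("simulate: generating %d samples/class, mislabel_rate=%.3f",
                    config.n_per_class, config.mislabel_rate)
        samples = synthetic.generate_samples(
            patterns, config.n_per_class, config.mislabel_rate,
            seed=sim_seed, vocabulary=vocabulary,
        )
    if scene is None:
        spec = default_scene_spec(
            config.width, config.height, config.years, seed=sim_seed + 1
        )
        scene = synthetic.generate_scene(spec, patterns, vocabulary)
    logger.info("simulate: scene cube checksum %s", _checksum(scene.cube))
    if out is not None:
        write_samples_csv(samples, out / "samples.csv")
        for yi, year in enumerate(scene.spec.years):
            raster_io.write_band_cube(out / f"cube_{year}.tif", scene.cube[yi])
            raster_io.write_class_map(out / f"truth_{year}.tif", scene.truth[yi],
                                      vocabulary)

    # --- quality control -------------------------------------------------
    qc_report = None
    if config.skip_qc:
        logger.info("qc: skipped by configuration")
        retained = list(samples)
    else:
        logger.info("qc: %d samples, %d SOM runs, threshold %.2f",
                    len(samples), config.som_runs, config.threshold)
        reliabilities = som_qc.evaluate_samples(
            samples,
            n_runs=config.som_runs,
            xdim=config.som_xdim,
            ydim=config.som_ydim,
            epochs=config.som_epochs,
            alpha_start=config.som_alpha_start,
            alpha_end=config.som_alpha_end,
            seed=stage_seed(config.seed, "qc"),
        )
        retained, _removed, qc_report = som_qc.filter_samples(
            reliabilities, config.threshold, samples
        )
        logger.info("qc: retained %d of %d (%.1f%% reduction)",
                    qc_report.n_retained, qc_report.n_input, qc_report.reduction_pct)
        if out is not None:
            qc_report.write_csv(out / "qc_report.csv")
            write_samples_csv(retained, out / "samples_retained.csv")

    # --- SVM training and cross-validation -------------------------------
    svm_config = classify.SvmConfig(
        C=config.svm_c, gamma=config.svm_gamma, k_folds=config.k_folds,
        seed=stage_seed(config.seed, "svm"),
    )
    logger.info("train: SVM C=%g gamma=%g on %d samples",
                svm_config.C, svm_config.gamma, len(retained))
    model = classify.train_svm(retained, svm_config, vocabulary)
    cv_result = classify.cross_validate(retained, svm_config, vocabulary)
    logger.info("cv: overall accuracy %.3f", cv_result.overall)
    if out is not None:
        cv_result.confusion.to_frame().to_csv(out / "cv_confusion.csv")

    # --- per-year classification and smoothing ---------------------------
    smoothing = bayes_smooth.SmoothingConfig(sigma2=config.sigma2, radius=config.radius)
    prob_cubes, smoothed_cubes, smoothed_maps = [], [], []
    for yi, year in enumerate(scene.spec.years):
        cube, _raw_map = classify.classify_cube(model, scene.cube[yi], year)
        smoothed, label_map = bayes_smooth.smooth(cube, smoothing, vocabulary)
        logger.info("classify+smooth %d: labels checksum %s",
                    year, _checksum(label_map.grid))
        prob_cubes.append(cube)
        smoothed_cubes.append(smoothed)
        smoothed_maps.append(label_map)
        if out is not None:
            raster_io.write_probability_cube(out / f"probs_{year}.tif", cube)
            raster_io.write_probability_cube(out / f"probs_smoothed_{year}.tif",
                                             smoothed)

    # --- consistency rules and masks -------------------------------------
    refs = ReferenceLayers(scene.amazon, scene.cerrado)
    final_maps, rule_report = consistency_rules.run_postprocessing(
        smoothed_maps, scene.masks, refs, vocabulary
    )
    logger.info("rules: per-rule changed pixels %s",
                {k: v for k, v in rule_report.items() if v})
    if out is not None:
        for m in final_maps:
            raster_io.write_class_map(out / f"final_{m.year}.tif", m, vocabulary)

    # --- validation -------------------------------------------------------
    agreement_num = agreement_den = 0
    for final, truth in zip(final_maps, scene.truth):
        cm = map_confusion(final, truth, vocabulary)
        agreement_num += int(np.trace(cm.counts))
        agreement_den += cm.total
    agreement = agreement_num / agreement_den if agreement_den else float("nan")
    areas = area_series(final_maps, config.pixel_area_ha, vocabulary)
    logger.info("validate: pooled map agreement %.3f over %d pixel-years",
                agreement, agreement_den)
    if out is not None:
        areas.to_csv(out / "area_series.csv")
        config.to_yaml(out / "config.yaml")

    return PipelineResult(
        config=config,
        samples=samples,
        retained=retained,
        qc_report=qc_report,
        cv_result=cv_result,
        prob_cubes=prob_cubes,
        smoothed_cubes=smoothed_cubes,
        smoothed_maps=smoothed_maps,
        final_maps=final_maps,
        rule_report=rule_report,
        truth=scene.truth,
        agreement=agreement,
        areas=areas,
    )
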
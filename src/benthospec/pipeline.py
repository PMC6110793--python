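"""End-to-end survey pipeline.

Orchestrates the full workflow in the order it is applied to a real
track: preprocess the raw cube, build a reference library from
video-identified ROIs, angle-match the remaining annotated anomalies
and fold them into an expanded training library, train the per-pixel
SVM, classify the cube, detect objects and summarize counts and
densities. Every stage logs its parameters; a run is a pure function
of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import (
    ClassificationMap,
    TrainingMode,
    assemble_training,
    classify_cube,
    train_classifier,
)
from .cube import HyperCube, read_cube
from .detect import OOIRecord, SurveySummary, detect_oois, oois_to_dataframe, summarize_survey
from .library import (
    ROI,
    ROISource,
    SpectralLibrary,
    extract_roi_spectrum,
    rois_from_polygons,
)
from .matching import MatchResult, match_to_library
from .preprocess import PreprocessConfig, preprocess_cube

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "run_pipeline_in_memory",
    "compute_surveyed_area",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (see also the YAML front end)."""

    cube_path: str
    video_rois_path: str  # polygon JSON, categories known
    anomaly_rois_path: str | None = None  # polygon JSON, categories ignored
    out_dir: str = "pipeline_out"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    training_mode: TrainingMode = TrainingMode.ROI_PIXELS
    max_pixels_per_roi: int | None = 400
    svm_C: float = 100.0
    min_size_px: int = 20
    connectivity: int = 8
    surveyed_area_m2: float | None = None  # None: from cube dims x pixel size
    seed: int = 0


@dataclass
class PipelineResult:
    """Everything a run produces, in memory."""

    processed: HyperCube
    library: SpectralLibrary
    matches: list[MatchResult]
    classification: ClassificationMap
    oois: list[OOIRecord]
    summary: SurveySummary
    warnings: list[str] = field(default_factory=list)


def compute_surveyed_area(cubes: list[HyperCube]) -> float:
    """Total imaged seafloor area in m² across tracks."""
    return float(
        sum(c.lines * c.samples * (c.pixel_size_mm / 1000.0) ** 2 for c in cubes)
    )


def run_pipeline_in_memory(
    cube: HyperCube,
    video_rois: list[ROI],
    anomaly_rois: list[ROI] | None = None,
    background_rois: list[ROI] | None = None,
    preprocess: PreprocessConfig | None = None,
    training_mode: TrainingMode | str = TrainingMode.ROI_PIXELS,
    max_pixels_per_roi: int | None = 400,
    svm_C: float = 100.0,
    min_size_px: int = 20,
    connectivity: int = 8,
    surveyed_area_m2: float | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the full stage chain on in-memory inputs.

    ``video_rois`` carry trusted categories (the reference group);
    ``anomaly_rois`` are unidentified and get their category from the
    smallest spectral contrast angle against the reference library
    before both groups train the classifier. ``background_rois``
    (sediment/nodule patches) let the classifier label non-object
    pixels.
    """
    if not video_rois:
        raise ValueError("library stage: no video-identified ROIs supplied")
    collected: list[str] = []

    logger.info("stage preprocess: %s", preprocess or PreprocessConfig())
    processed = preprocess_cube(cube, preprocess)

    logger.info("stage library: %d video-identified ROIs", len(video_rois))
    library = SpectralLibrary(wavelengths=processed.wavelengths)
    for roi in video_rois:
        library.add(extract_roi_spectrum(processed, roi))

    matches: list[MatchResult] = []
    matched_rois: list[ROI] = []
    if anomaly_rois:
        logger.info("stage match: %d anomaly ROIs against %d entries", len(anomaly_rois), len(library))
        # all anomalies are matched against the fixed reference library;
        # only then is the library expanded for classifier training
        matched_specs = []
        for roi in anomaly_rois:
            spec = extract_roi_spectrum(processed, roi)
            m = match_to_library(spec.values, library, query_id=roi.ooi_id)
            matches.append(m)
            matched_rois.append(
                ROI(
                    ooi_id=roi.ooi_id,
                    category=m.best_category,
                    pixels=roi.pixels,
                    source=ROISource.SPECTRAL_ANOMALY,
                )
            )
            spec.category = m.best_category
            spec.source = ROISource.SPECTRAL_ANOMALY
            matched_specs.append(spec)
        for spec in matched_specs:  # expand-library stage
            library.add(spec)

    training_rois = video_rois + matched_rois + list(background_rois or [])
    logger.info(
        "stage train: %d ROIs (%d video, %d matched, %d background)",
        len(training_rois),
        len(video_rois),
        len(matched_rois),
        len(background_rois or []),
    )
    ts = assemble_training(
        processed,
        training_rois,
        mode=training_mode,
        max_pixels_per_roi=max_pixels_per_roi,
        rng=seed,
    )
    model = train_classifier(ts, C=svm_C)

    logger.info("stage classify: %d x %d pixels", processed.lines, processed.samples)
    cmap = classify_cube(processed, model)

    logger.info("stage detect: min_size=%d, connectivity=%d", min_size_px, connectivity)
    no_background = not (background_rois or [])
    oois = detect_oois(
        cmap, min_size_px=min_size_px, connectivity=connectivity, no_background_ok=no_background
    )

    area = (
        surveyed_area_m2
        if surveyed_area_m2 is not None
        else compute_surveyed_area([cube])
    )
    summary = summarize_survey(oois, area)
    logger.info("stage summarize: %d OOIs over %.3f m2", summary.total_ooi_count, area)
    return PipelineResult(
        processed=processed,
        library=library,
        matches=matches,
        classification=cmap,
        oois=oois,
        summary=summary,
        warnings=collected,
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """File-based entry point: load inputs, run the chain, write artifacts.

    Writes to ``cfg.out_dir``: the expanded library JSON, the angle-match
    CSV, the classification raster (PNG, 32-bit integer) with a JSON
    legend sidecar, the OOI table CSV and the survey summary CSV/JSON.
    """
    cube = read_cube(cfg.cube_path)
    video = rois_from_polygons(cfg.video_rois_path, (cube.lines, cube.samples))
    anomalies = (
        rois_from_polygons(
            cfg.anomaly_rois_path, (cube.lines, cube.samples), source=ROISource.SPECTRAL_ANOMALY
        )
        if cfg.anomaly_rois_path
        else None
    )
    background = [r for r in video if r.category in ("sediment", "nodule")]
    video = [r for r in video if r.category not in ("sediment", "nodule")]

    result = run_pipeline_in_memory(
        cube,
        video,
        anomalies,
        background_rois=background,
        preprocess=cfg.preprocess,
        training_mode=cfg.training_mode,
        max_pixels_per_roi=cfg.max_pixels_per_roi,
        svm_C=cfg.svm_C,
        min_size_px=cfg.min_size_px,
        connectivity=cfg.connectivity,
        surveyed_area_m2=cfg.surveyed_area_m2,
        seed=cfg.seed,
    )

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.library.save(out / "library.json")
    if result.matches:
        pd.DataFrame(
            [
                {
                    "query_id": m.query_id,
                    "best_category": m.best_category,
                    "theta_min_deg": m.theta_min,
                    **{f"theta_{k}": v for k, v in m.angles.items()},
                }
                for m in result.matches
            ]
        ).to_csv(out / "matches.csv", index=False)
    _save_classmap(result.classification, out / "classmap.png")
    oois_to_dataframe(result.oois).to_csv(out / "oois.csv", index=False)
    result.summary.to_frame().to_csv(out / "summary.csv", index=False)
    (out / "summary.json").write_text(
        json.dumps(
            {
                "total_ooi_count": result.summary.total_ooi_count,
                "surveyed_area_m2": result.summary.surveyed_area_m2,
                "counts": result.summary.counts,
                "densities_per_m2": result.summary.densities,
            },
            indent=1,
        )
    )
    return result


def _save_classmap(cmap: ClassificationMap, path: Path) -> None:
    from PIL import Image

    Image.fromarray(cmap.labels.astype(np.int32), mode="I").save(path)
    Path(str(path) + ".legend.json").write_text(json.dumps(cmap.legend, indent=1))
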
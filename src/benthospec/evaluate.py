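"""Ground-truth evaluation of pipeline runs on synthetic scenes.

Turns a simulated scene's truth into annotation ROIs (a stratified half
of the planted objects plays the role of the video-identified reference
group, the other half the unidentified anomalies), runs the full
pipeline, and scores pixel-wise classification accuracy and per-object
recovery against the truth rasters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .library import ROI, ROISource
from .pipeline import PipelineResult, run_pipeline_in_memory
from .simulate import SceneConfig, SceneTruth, generate_scene

__all__ = [
    "truth_rois",
    "split_objects",
    "background_rois_from_truth",
    "SceneEvaluation",
    "evaluate_scene",
    "pixel_accuracy",
    "object_recovery",
]


def truth_rois(truth: SceneTruth, object_ids: list[int] | None = None) -> list[ROI]:
    """One ROI per planted object, from the truth object-id raster."""
    table = truth.objects
    ids = object_ids if object_ids is not None else table["object_id"].tolist()
    rois = []
    for oid in ids:
        row = table.loc[table["object_id"] == oid].iloc[0]
        coords = np.argwhere(truth.object_ids == oid)
        rois.append(
            ROI(ooi_id=f"obj_{oid:03d}", category=str(row["category"]), pixels=coords)
        )
    return rois


def split_objects(truth: SceneTruth, rng: np.random.Generator | int | None = 0) -> tuple[list[int], list[int]]:
    """Stratified half-split of planted objects by category.

    The first half stands in for the video-identified reference group
    (every category keeps at least one exemplar there); the second half
    for the anomalies to be angle-identified.
    """
    rng = np.random.default_rng(rng)
    first: list[int] = []
    second: list[int] = []
    for cat, group in truth.objects.groupby("category"):
        ids = group["object_id"].to_numpy()
        ids = ids[rng.permutation(len(ids))]
        k = max(1, len(ids) // 2)
        first.extend(int(i) for i in ids[:k])
        second.extend(int(i) for i in ids[k:])
    return sorted(first), sorted(second)


def background_rois_from_truth(
    truth: SceneTruth,
    rng: np.random.Generator | int | None = 0,
    patch: int = 12,
    n_sediment: int = 6,
    n_nodule_px: int = 400,
) -> list[ROI]:
    """Sediment patches and nodule pixel samples from the truth raster.

    Emulates the manual annotation of background training regions on a
    real track.
    """
    rng = np.random.default_rng(rng)
    code = {v: k for k, v in truth.legend.items()}
    lines, samples = truth.labels.shape
    rois: list[ROI] = []
    placed = 0
    for _ in range(200):
        if placed >= n_sediment:
            break
        l0 = int(rng.integers(0, lines - patch))
        s0 = int(rng.integers(0, samples - patch))
        block = truth.labels[l0 : l0 + patch, s0 : s0 + patch]
        if (block == code["sediment"]).all():
            ll, ss = np.mgrid[l0 : l0 + patch, s0 : s0 + patch]
            coords = np.column_stack([ll.ravel(), ss.ravel()])
            rois.append(
                ROI(ooi_id=f"bg_sed_{placed}", category="sediment", pixels=coords)
            )
            placed += 1
    if placed == 0:
        raise RuntimeError("could not find a clean sediment patch for background training")
    nodule_px = np.argwhere(truth.labels == code.get("nodule", -1))
    if nodule_px.shape[0] > 0:
        take = min(n_nodule_px, nodule_px.shape[0])
        sel = rng.choice(nodule_px.shape[0], size=take, replace=False)
        rois.append(ROI(ooi_id="bg_nodule", category="nodule", pixels=nodule_px[np.sort(sel)]))
    return rois


def pixel_accuracy(truth: SceneTruth, result: PipelineResult) -> float:
    """Fraction of pixels whose predicted category equals the truth."""
    pred_names = np.array([result.classification.legend[i] for i in
                           range(max(result.classification.legend) + 1)], dtype=object)
    true_names = np.array([truth.legend[i] for i in range(max(truth.legend) + 1)], dtype=object)
    pred = pred_names[result.classification.labels]
    true = true_names[truth.labels]
    return float(np.mean(pred == true))


def object_recovery(truth: SceneTruth, result: PipelineResult, min_size_px: int = 20) -> float:
    """Fraction of planted objects (at or above the detection size)
    recovered as a detected OOI with the correct majority category.

    An object counts as recovered when some detected OOI overlaps more
    than half of its planted pixels and carries its true category.
    """
    # rasterize detected OOIs (their stored component coordinates)
    det = np.zeros_like(truth.object_ids)
    for idx, o in enumerate(result.oois, start=1):
        if o.coords is not None:
            det[o.coords[:, 0], o.coords[:, 1]] = idx

    recovered = 0
    eligible = 0
    for _, row in truth.objects.iterrows():
        mask = truth.object_ids == row["object_id"]
        if mask.sum() < min_size_px:
            continue
        eligible += 1
        overlap = det[mask]
        overlap = overlap[overlap > 0]
        if overlap.size == 0 or overlap.size <= mask.sum() / 2:
            continue
        best = int(np.bincount(overlap).argmax())
        if result.oois[best - 1].category == row["category"]:
            recovered += 1
    return recovered / eligible if eligible else float("nan")


@dataclass
class SceneEvaluation:
    """Scores of one synthetic end-to-end run."""

    pixel_accuracy: float
    object_recovery: float
    result: PipelineResult
    truth: SceneTruth


def evaluate_scene(
    cfg: SceneConfig,
    split_seed: int | None = None,
    **pipeline_kwargs,
) -> SceneEvaluation:
    """Generate a scene, run the full pipeline, score against truth."""
    cube, truth = generate_scene(cfg)
    seed = cfg.seed if split_seed is None else split_seed
    video_ids, anomaly_ids = split_objects(truth, rng=seed)
    video = truth_rois(truth, video_ids)
    anomalies = [
        ROI(ooi_id=r.ooi_id, category="unknown", pixels=r.pixels, source=ROISource.SPECTRAL_ANOMALY)
        for r in truth_rois(truth, anomaly_ids)
    ]
    background = background_rois_from_truth(truth, rng=seed)
    pipeline_kwargs.setdefault("seed", seed)
    result = run_pipeline_in_memory(cube, video, anomalies, background_rois=background, **pipeline_kwargs)
    min_size = pipeline_kwargs.get("min_size_px", 20)
    return SceneEvaluation(
        pixel_accuracy=pixel_accuracy(truth, result),
        object_recovery=object_recovery(truth, result, min_size_px=min_size),
        result=result,
        truth=truth,
    )
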
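"""Supervised per-pixel classification of pseudo-reflectance cubes.

A multi-class support vector machine (RBF kernel, one-vs-one) is trained
on labeled ROI spectra — either one mean spectrum per object
(``avg_spectra``) or every ROI pixel (``roi_pixels``) — and applied to
every pixel of a cube. Background materials (sediment, manganese
nodules) are first-class categories so that non-object pixels get a
meaningful label.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .cube import HyperCube, Stage
from .library import BACKGROUND_CATEGORIES, ROI

__all__ = [
    "TrainingMode",
    "TrainingSet",
    "ClassificationMap",
    "assemble_training",
    "PixelSVMClassifier",
    "train_classifier",
    "classify_cube",
]

logger = logging.getLogger(__name__)


class TrainingMode(str, enum.Enum):
    AVG_SPECTRA = "avg_spectra"
    ROI_PIXELS = "roi_pixels"


@dataclass
class TrainingSet:
    """Labeled spectra ready for classifier fitting."""

    X: np.ndarray  # (n_samples, n_bands)
    y: np.ndarray  # category labels
    ooi_ids: np.ndarray
    mode: TrainingMode
    wavelengths: np.ndarray

    @property
    def categories(self) -> list[str]:
        return sorted(set(self.y.tolist()))


@dataclass
class ClassificationMap:
    """Per-pixel integer labels with a legend mapping to category names."""

    labels: np.ndarray  # (lines, samples) int raster
    legend: dict[int, str]
    pixel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"legend does not cover label(s) {sorted(missing)}")

    @property
    def category_of(self) -> dict[int, str]:
        return self.legend

    def pixel_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {self.legend[int(v)]: int(c) for v, c in zip(vals, counts)}


def assemble_training(
    cube: HyperCube,
    rois: list[ROI],
    mode: TrainingMode | str = TrainingMode.ROI_PIXELS,
    max_pixels_per_roi: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> TrainingSet:
    """Build a training set from labeled ROIs on a processed cube.

    ``avg_spectra`` yields one sample per ROI (its mean spectrum),
    mirroring training on per-object average fingerprints;
    ``roi_pixels`` yields one sample per ROI pixel. Optionally each
    ROI's pixels are subsampled (seeded) to ``max_pixels_per_roi`` to
    bound training cost on large objects.

    Warns when no background (sediment/nodule) ROI is present: the
    classifier then runs in a degraded OOI-only mode that cannot label
    background pixels as such.
    """
    mode = TrainingMode(mode)
    if cube.stage not in (Stage.SMOOTHED, Stage.PSEUDO_REFLECTANCE):
        raise ValueError("training spectra come from processed (pseudo-reflectance) cubes")
    if not rois:
        raise ValueError("no ROIs supplied")
    categories = {r.category for r in rois}
    if len(categories) < 2:
        raise ValueError(f"need >=2 distinct categories, got {sorted(categories)}")
    if not categories & set(BACKGROUND_CATEGORIES):
        warnings.warn(
            "no background (sediment/nodule) ROI in the training set; "
            "classification will run in degraded OOI-only mode",
            stacklevel=2,
        )
    rng = np.random.default_rng(rng)
    X_parts, y_parts, id_parts = [], [], []
    for roi in rois:
        px = roi.pixels
        if mode is TrainingMode.AVG_SPECTRA:
            spec = cube.data[px[:, 0], px[:, 1], :].mean(axis=0)
            X_parts.append(spec[np.newaxis, :])
            y_parts.append([roi.category])
            id_parts.append([roi.ooi_id])
        else:
            if max_pixels_per_roi is not None and px.shape[0] > max_pixels_per_roi:
                sel = rng.choice(px.shape[0], size=max_pixels_per_roi, replace=False)
                px = px[np.sort(sel)]
            X_parts.append(cube.data[px[:, 0], px[:, 1], :])
            y_parts.append([roi.category] * px.shape[0])
            id_parts.append([roi.ooi_id] * px.shape[0])
    X = np.vstack(X_parts).astype(np.float64)
    return TrainingSet(
        X=X,
        y=np.concatenate([np.asarray(p, dtype=object) for p in y_parts]),
        ooi_ids=np.concatenate([np.asarray(p, dtype=object) for p in id_parts]),
        mode=mode,
        wavelengths=cube.wavelengths.copy(),
    )


class PixelSVMClassifier(ClassifierMixin, BaseEstimator):
    """RBF-kernel SVM for per-pixel spectral classification.

    Thin scikit-learn estimator around a one-vs-one ``SVC`` with the
    defaults used for hyperspectral pixel classification: ``gamma = 1 /
    n_bands`` and penalty ``C = 100``. Fitting is deterministic and
    insensitive to training-sample order (samples are lexicographically
    sorted before the fit).
    """

    def __init__(self, C: float = 100.0, gamma: str | float = "bands", kernel: str = "rbf"):
        self.C = C
        self.gamma = gamma
        self.kernel = kernel

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self._check_degenerate(X, y)
        # canonical ordering -> order-insensitive, reproducible fit
        order = np.lexsort(np.vstack([X.T, np.asarray(y, dtype=str)[np.newaxis, :]]))
        Xs, ys = X[order], y[order]
        gamma = 1.0 / X.shape[1] if self.gamma == "bands" else self.gamma
        self.svc_ = SVC(C=self.C, kernel=self.kernel, gamma=gamma, decision_function_shape="ovo")
        self.svc_.fit(Xs, ys.astype(str))
        self.classes_ = self.svc_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _check_degenerate(X: np.ndarray, y: np.ndarray) -> None:
        """Reject identical spectra carrying different category labels."""
        _, inv = np.unique(X.round(12), axis=0, return_inverse=True)
        collisions = []
        for g in np.unique(inv):
            labels = set(np.asarray(y)[inv == g].tolist())
            if len(labels) > 1:
                collisions.append(sorted(labels))
        if collisions:
            raise ValueError(
                f"identical training spectra carry conflicting labels: {collisions}"
            )

    def predict(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.predict(np.asarray(X, dtype=np.float64))


def train_classifier(ts: TrainingSet, **params) -> PixelSVMClassifier:
    """Fit the pixel SVM on an assembled training set."""
    clf = PixelSVMClassifier(**params)
    clf.fit(ts.X, ts.y)
    logger.info(
        "trained SVM on %d samples, %d categories (%s mode)",
        len(ts.y),
        len(ts.categories),
        ts.mode.value,
    )
    return clf


def classify_cube(
    cube: HyperCube,
    model: PixelSVMClassifier,
    chunk_lines: int = 64,
) -> ClassificationMap:
    """Assign every pixel of a processed cube to a category.

    Prediction runs in along-track chunks to bound memory; per-category
    pixel counts go to the run log.
    """
    check_is_fitted(model, "svc_")
    if cube.n_bands != model.n_features_in_:
        raise ValueError(
            f"cube has {cube.n_bands} bands but the model was trained on "
            f"{model.n_features_in_}"
        )
    categories = list(model.classes_)
    code = {c: i for i, c in enumerate(categories)}
    labels = np.empty((cube.lines, cube.samples), dtype=np.int32)
    for start in range(0, cube.lines, chunk_lines):
        stop = min(start + chunk_lines, cube.lines)
        flat = cube.data[start:stop].reshape(-1, cube.n_bands)
        pred = model.predict(flat)
        labels[start:stop] = np.array([code[c] for c in pred], dtype=np.int32).reshape(
            stop - start, cube.samples
        )
    cmap = ClassificationMap(
        labels=labels,
        legend={i: c for c, i in code.items()},
        pixel_size_mm=cube.pixel_size_mm,
    )
    logger.info("per-category pixel counts: %s", cmap.pixel_counts())
    return cmap
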
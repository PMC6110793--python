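"""Reference spectral library of optical fingerprints.

Each entry is the mean pseudo-reflectance spectrum of one annotated
object of interest (OOI) — an identified megafauna individual or a
sediment anomaly — max-normalized so that entries of different
brightness are comparable in shape. The library is the training source
for both angle matching and supervised classification.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cube import HyperCube, Stage

__all__ = [
    "DEFAULT_CATEGORIES",
    "BACKGROUND_CATEGORIES",
    "ROISource",
    "ROI",
    "ReferenceSpectrum",
    "SpectralLibrary",
    "extract_roi_spectrum",
    "normalize_max",
    "rois_from_label_mask",
    "rois_from_polygons",
]

# Default survey vocabulary: 16 megafauna morphotypes + 3 sediment anomalies.
DEFAULT_CATEGORIES: tuple[str, ...] = (
    "sponge_round",
    "sponge_disc",
    "glass_sponge",
    "coral_white",
    "coral_yellow",
    "coral_green",
    "holothurian_synallactidae",
    "holothurian_paelopatides",
    "ophiuroid_white",
    "ophiuroid_red",
    "crustacean",
    "salp_dead",
    "polychaete",
    "crinoid",
    "isopod",
    "bony_fish",
    "white_exposed_sediment",
    "green_spot",
    "white_spot",
)

# Optical background classes: not OOIs, but first-class classifier labels.
BACKGROUND_CATEGORIES: tuple[str, ...] = ("sediment", "nodule")

# Expected annotation sizes (pixels); outside this range a warning is issued.
ROI_SIZE_RANGE = (20, 600)


class ROISource(str, enum.Enum):
    VIDEO_IDENTIFIED = "video_identified"
    SPECTRAL_ANOMALY = "spectral_anomaly"


@dataclass
class ROI:
    """An annotated region of interest: one object's pixel mask."""

    ooi_id: str
    category: str
    pixels: np.ndarray  # (n, 2) int array of (line, sample) coordinates
    source: ROISource = ROISource.VIDEO_IDENTIFIED

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.intp).reshape(-1, 2)
        self.source = ROISource(self.source)
        if self.pixels.shape[0] == 0:
            raise ValueError(f"ROI {self.ooi_id}: empty pixel mask")

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]


@dataclass
class ReferenceSpectrum:
    """One library entry: a named, taxonomy-annotated mean spectrum."""

    ooi_id: str
    category: str
    values: np.ndarray  # max-normalized pseudo-reflectance
    wavelengths: np.ndarray
    n_pixels: int = 1
    taxonomy: str = ""
    source: ROISource = ROISource.VIDEO_IDENTIFIED
    raw_mean: np.ndarray | None = None  # unnormalized mean, for diagnostics

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.source = ROISource(self.source)
        if self.values.shape != self.wavelengths.shape:
            raise ValueError("values and wavelengths differ in length")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")


def normalize_max(values: np.ndarray) -> np.ndarray:
    """Divide a spectrum by its maximum so the output peaks at exactly 1."""
    values = np.asarray(values, dtype=np.float64)
    peak = values.max() if values.size else 0.0
    if peak <= 0:
        raise ValueError("cannot max-normalize a spectrum without a positive value")
    return values / peak


def extract_roi_spectrum(cube: HyperCube, roi: ROI, normalize: bool = False) -> ReferenceSpectrum:
    """Per-band arithmetic mean over an ROI's pixel mask.

    Warns (does not fail) when the mask size falls outside the 20–600 px
    range used for well-averaged fingerprints.
    """
    if cube.stage not in (Stage.PSEUDO_REFLECTANCE, Stage.SMOOTHED):
        raise ValueError(
            f"ROI spectra are extracted from pseudo-reflectance data, got stage {cube.stage.value}"
        )
    lines, samples = roi.pixels[:, 0], roi.pixels[:, 1]
    if (lines < 0).any() or (lines >= cube.lines).any() or (samples < 0).any() or (
        samples >= cube.samples
    ).any():
        raise ValueError(f"ROI {roi.ooi_id}: pixels outside cube bounds")
    lo, hi = ROI_SIZE_RANGE
    if not lo <= roi.n_pixels <= hi:
        warnings.warn(
            f"ROI {roi.ooi_id}: {roi.n_pixels} pixels outside the expected "
            f"{lo}-{hi} px averaging range",
            stacklevel=2,
        )
    mean = cube.data[lines, samples, :].mean(axis=0).astype(np.float64)
    values = normalize_max(mean) if normalize else mean
    return ReferenceSpectrum(
        ooi_id=roi.ooi_id,
        category=roi.category,
        values=values,
        wavelengths=cube.wavelengths.copy(),
        n_pixels=roi.n_pixels,
        source=roi.source,
        raw_mean=mean,
    )


@dataclass
class SpectralLibrary:
    """Collection of reference spectra on one common wavelength grid."""

    wavelengths: np.ndarray
    entries: list[ReferenceSpectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def categories(self) -> list[str]:
        return sorted({e.category for e in self.entries})

    def add(self, spec: ReferenceSpectrum, normalize: bool = True) -> None:
        """Append an entry (max-normalizing by default); rejects duplicate
        ids and grid mismatches."""
        if any(e.ooi_id == spec.ooi_id for e in self.entries):
            raise ValueError(f"duplicate ooi_id '{spec.ooi_id}' in library")
        if spec.wavelengths.shape != self.wavelengths.shape or not np.allclose(
            spec.wavelengths, self.wavelengths
        ):
            raise ValueError(
                f"entry '{spec.ooi_id}' is on a {spec.wavelengths.size}-band grid; "
                f"library grid has {self.wavelengths.size} bands"
            )
        if normalize:
            spec.values = normalize_max(spec.values)
        self.entries.append(spec)

    def matrix(self) -> np.ndarray:
        """Entries stacked as an ``(n_entries, n_bands)`` array."""
        return np.vstack([e.values for e in self.entries])

    def save(self, path: str | Path) -> None:
        payload = {
            "wavelengths_nm": self.wavelengths.tolist(),
            "entries": [
                {
                    "ooi_id": e.ooi_id,
                    "category": e.category,
                    "taxonomy": e.taxonomy,
                    "n_pixels": e.n_pixels,
                    "source": e.source.value,
                    "values": e.values.tolist(),
                    "raw_mean": None if e.raw_mean is None else e.raw_mean.tolist(),
                }
                for e in self.entries
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SpectralLibrary":
        payload = json.loads(Path(path).read_text())
        lib = cls(wavelengths=np.array(payload["wavelengths_nm"]))
        for d in payload["entries"]:
            lib.add(
                ReferenceSpectrum(
                    ooi_id=d["ooi_id"],
                    category=d["category"],
                    taxonomy=d.get("taxonomy", ""),
                    n_pixels=d["n_pixels"],
                    source=d["source"],
                    values=np.array(d["values"]),
                    wavelengths=lib.wavelengths.copy(),
                    raw_mean=None if d.get("raw_mean") is None else np.array(d["raw_mean"]),
                ),
                normalize=False,
            )
        return lib


def rois_from_label_mask(
    mask: np.ndarray,
    legend: dict[int, str],
    source: ROISource = ROISource.VIDEO_IDENTIFIED,
    id_prefix: str = "roi",
) -> list[ROI]:
    """Build ROIs from an integer label raster.

    Each positive label in ``legend`` becomes one ROI named
    ``<prefix>_<label>``; label 0 is treated as unannotated.
    """
    mask = np.asarray(mask)
    rois = []
    for label, category in sorted(legend.items()):
        if label == 0:
            continue
        coords = np.argwhere(mask == label)
        if coords.size == 0:
            continue
        rois.append(ROI(ooi_id=f"{id_prefix}_{label}", category=category, pixels=coords, source=source))
    return rois


def rois_from_polygons(
    path_or_obj,
    shape: tuple[int, int],
    source: ROISource = ROISource.VIDEO_IDENTIFIED,
) -> list[ROI]:
    """Rasterize polygon-JSON annotations into ROIs.

    Input is a JSON list of ``{"ooi_id", "category", "polygon": [[line,
    sample], ...]}``; a pixel is included when its center lies inside
    the polygon.
    """
    from skimage.draw import polygon as sk_polygon

    if isinstance(path_or_obj, (str, Path)):
        annots = json.loads(Path(path_or_obj).read_text())
    else:
        annots = path_or_obj
    rois = []
    for a in annots:
        poly = np.asarray(a["polygon"], dtype=float)
        rr, cc = sk_polygon(poly[:, 0], poly[:, 1], shape=shape)
        rois.append(
            ROI(
                ooi_id=a["ooi_id"],
                category=a["category"],
                pixels=np.column_stack([rr, cc]),
                source=a.get("source", source),
            )
        )
    return rois
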
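"""Object-of-interest detection from classification maps.

Non-background pixels are grouped into connected components regardless
of category — an organism whose rim pixels were misclassified as a
spectrally similar category should still count as one object — and each
component takes the majority category of its pixels. Components smaller
than a minimum size are discarded as noise. Counts over the surveyed
area give per-category densities in individuals per m².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .classify import ClassificationMap
from .library import BACKGROUND_CATEGORIES

__all__ = [
    "OOIRecord",
    "SurveySummary",
    "detect_oois",
    "compute_density",
    "summarize_survey",
    "oois_to_dataframe",
]


@dataclass
class OOIRecord:
    """One detected object: a connected non-background component."""

    ooi_id: str
    category: str
    pixel_area: int
    area_cm2: float
    equivalent_diameter_cm: float
    centroid: tuple[float, float]  # (line, sample)
    bbox: tuple[int, int, int, int]  # (min_line, min_sample, max_line, max_sample) half-open
    purity: float  # fraction of pixels carrying the majority label
    coords: np.ndarray | None = None  # (n, 2) component pixel coordinates


@dataclass
class SurveySummary:
    """Table-style survey roll-up: counts and densities per category."""

    counts: dict[str, int]
    total_ooi_count: int
    surveyed_area_m2: float
    densities: dict[str, float]  # individuals per m², full precision

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "category": c,
                "count": n,
                "density_per_m2": self.densities[c],
                "density_per_m2_2dp": round(self.densities[c], 2),
            }
            for c, n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows)


def detect_oois(
    cmap: ClassificationMap,
    min_size_px: int = 20,
    connectivity: int = 8,
    background: tuple[str, ...] = BACKGROUND_CATEGORIES,
    no_background_ok: bool = False,
) -> list[OOIRecord]:
    """Extract discrete objects from a classification map.

    Pixels of ``background`` categories are masked out; the remainder is
    labeled by 4- or 8-connectivity, each component is assigned its
    majority category (alphabetical tie-break, with a warning), and
    components under ``min_size_px`` are dropped.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    legend = cmap.legend
    bg_codes = {code for code, cat in legend.items() if cat in background}
    if not bg_codes and not no_background_ok:
        raise ValueError(
            "legend contains no background class; pass no_background_ok=True "
            "to detect on an OOI-only map"
        )
    fg = ~np.isin(cmap.labels, sorted(bg_codes)) if bg_codes else np.ones_like(cmap.labels, bool)
    comp = measure.label(fg, connectivity=1 if connectivity == 4 else 2)
    px_cm = cmap.pixel_size_mm / 10.0  # pixel edge in cm

    records: list[OOIRecord] = []
    for region in measure.regionprops(comp):
        if region.area < min_size_px:
            continue
        coords = region.coords
        codes = cmap.labels[coords[:, 0], coords[:, 1]]
        vals, counts = np.unique(codes, return_counts=True)
        top = counts.max()
        winners = sorted(legend[int(v)] for v, c in zip(vals, counts) if c == top)
        if len(winners) > 1:
            warnings.warn(
                f"component {region.label}: majority tie between {winners}; "
                "assigning alphabetically first",
                stacklevel=2,
            )
        category = winners[0]
        area_cm2 = float(region.area) * px_cm**2
        records.append(
            OOIRecord(
                ooi_id=f"ooi_{len(records) + 1:04d}",
                category=category,
                pixel_area=int(region.area),
                area_cm2=area_cm2,
                equivalent_diameter_cm=2.0 * float(np.sqrt(area_cm2 / np.pi)),
                centroid=tuple(float(c) for c in region.centroid),
                bbox=tuple(int(b) for b in region.bbox),
                purity=float(top / region.area),
                coords=coords,
            )
        )
    return records


def compute_density(count: int, area_m2: float) -> float:
    """Individuals per m²; rounding to 2 decimals is a report concern."""
    if area_m2 <= 0:
        raise ValueError(f"surveyed area must be positive, got {area_m2}")
    return count / area_m2


def summarize_survey(oois: list[OOIRecord], area_m2: float) -> SurveySummary:
    """Per-category counts and densities over the surveyed area."""
    counts: dict[str, int] = {}
    for o in oois:
        counts[o.category] = counts.get(o.category, 0) + 1
    return SurveySummary(
        counts=counts,
        total_ooi_count=sum(counts.values()),
        surveyed_area_m2=area_m2,
        densities={c: compute_density(n, area_m2) for c, n in counts.items()},
    )


def oois_to_dataframe(oois: list[OOIRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ooi_id": o.ooi_id,
                "category": o.category,
                "pixel_area": o.pixel_area,
                "area_cm2": o.area_cm2,
                "equiv_diam_cm": o.equivalent_diameter_cm,
                "centroid_line": o.centroid[0],
                "centroid_sample": o.centroid[1],
                "purity": o.purity,
            }
            for o in oois
        ]
    )
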
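"""Synthetic seafloor-scene generator.

Forward model of a push-broom underwater hyperspectral survey over
abyssal sediment with manganese nodules: per-pixel

    value(l, s, b) = R_material(lambda_b) * illum(s) * drift(l)
                     * lamp(lambda_b) * gain + noise

where ``R_material`` is the category's reflectance spectrum, ``illum``
a static cross-track lamp-geometry falloff, ``drift`` a small
along-track gain variation, and the noise a per-band Gaussian whose
standard deviation is a fraction of the local signal, inflated outside
the 400–710 nm window (emulating the noisy band edges that motivate
spectral subsetting). Fauna and sediment-anomaly objects are rendered
as discs; the ground truth (label raster, object table, true spectra,
illumination field) is emitted alongside the raw cube.

Material spectra are invented phenomenology: smooth baselines plus
category-specific Gaussian features, with the green/white "spots"
carrying a chlorophyll-a-like reflectance dip at 675 nm. They are
configuration values, not claims about the real organisms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cube import HyperCube, Stage
from .matching import pairwise_contrast_angles

__all__ = [
    "BandGrid",
    "make_band_grid",
    "MaterialSpectrum",
    "material_catalog",
    "ObjectSpec",
    "SceneConfig",
    "SceneTruth",
    "generate_scene",
    "default_scene_config",
    "DEFAULT_SCENE_CATEGORIES",
]

# Standard desk-scale fixture: six fauna/anomaly categories over the two
# background materials.
DEFAULT_SCENE_CATEGORIES: tuple[str, ...] = (
    "coral_white",
    "sponge_round",
    "polychaete",
    "salp_dead",
    "green_spot",
    "white_spot",
)

_SPOT_CATEGORIES = ("green_spot", "white_spot")

# Minimum pairwise spectral contrast angle between catalog spectra,
# checked over the analysis window at build time. Pairs within the
# sediment/spot family are exempt from the floor: the spots ARE the
# sediment baseline carrying a chlorophyll-like dip, so their shape
# separation is governed by the dip parameters (and partly by
# intensity, which the angle ignores by design).
_MIN_PAIRWISE_DEG = 5.0
_FLOOR_EXEMPT = frozenset({"sediment", "green_spot", "white_spot"})
_ANALYSIS_WINDOW_NM = (400.0, 710.0)


@dataclass
class BandGrid:
    """Uniform band-center grid in nm."""

    n_bands: int = 112
    start_nm: float = 378.0
    spacing_nm: float = 3.75

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise ValueError("need at least 2 bands")
        if self.spacing_nm <= 0:
            raise ValueError("band spacing must be positive")

    @property
    def centers(self) -> np.ndarray:
        return self.start_nm + self.spacing_nm * np.arange(self.n_bands)


def make_band_grid(n: int = 112, start_nm: float = 378.0, spacing_nm: float = 3.75) -> BandGrid:
    """Uniform grid; defaults emulate the 112-band 378–805 nm imager
    such that inclusive subsetting at [400, 710] nm keeps 83 bands."""
    return BandGrid(n_bands=n, start_nm=start_nm, spacing_nm=spacing_nm)


@dataclass
class MaterialSpectrum:
    """Reflectance model of one category on a band grid.

    ``baseline`` is linear in normalized wavelength; ``gaussian_features``
    are (center_nm, width_nm, signed_amplitude) bumps; ``dip`` is an
    optional multiplicative absorption feature (center_nm, sigma_nm,
    depth); ``red_boost`` multiplies the spectrum above 650 nm.
    """

    category: str
    base_level: float
    base_slope: float
    gaussian_features: tuple[tuple[float, float, float], ...] = ()
    dip: tuple[float, float, float] | None = None
    red_boost: float = 1.0
    brightness: float = 1.0

    def reflectance(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=np.float64)
        t = (wl - 378.0) / (805.0 - 378.0)
        r = self.base_level + self.base_slope * t
        for center, width, amp in self.gaussian_features:
            r = r + amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
        if self.dip is not None:
            center, sigma, depth = self.dip
            r = r * (1.0 - depth * np.exp(-0.5 * ((wl - center) / sigma) ** 2))
        if self.red_boost != 1.0:
            r = np.where(wl > 650.0, r * self.red_boost, r)
        r = r * self.brightness
        if (r <= 0).any() or (r > 1).any():
            raise ValueError(f"material '{self.category}': reflectance outside (0, 1]")
        return r


# Sediment slope is gentle enough that the spots' 675 nm absorption dip
# stays the global reflectance minimum over 400-710 nm even with the
# white spot's red brightening.
_SEDIMENT = dict(base_level=0.28, base_slope=0.14)

# Category parameter table: baseline level/slope and Gaussian features.
# Centers, widths and amplitudes are chosen so every non-exempt pair of
# categories is >= 5 deg apart in contrast angle over 400-710 nm.
_MATERIAL_PARAMS: dict[str, dict] = {
    "sediment": _SEDIMENT,
    "nodule": dict(base_level=0.085, base_slope=-0.025),
    "sponge_round": dict(base_level=0.40, base_slope=0.02, gaussian_features=((482, 20, 0.22),)),
    "sponge_disc": dict(base_level=0.38, base_slope=0.0, gaussian_features=((530, 20, 0.20),)),
    "glass_sponge": dict(base_level=0.44, base_slope=0.0, gaussian_features=((432, 20, 0.22),)),
    "coral_white": dict(base_level=0.40, base_slope=0.16, gaussian_features=((585, 40, 0.17),)),
    "coral_yellow": dict(base_level=0.22, base_slope=0.04, gaussian_features=((575, 35, 0.32),)),
    "coral_green": dict(base_level=0.17, base_slope=0.02, gaussian_features=((548, 28, 0.28),)),
    "holothurian_synallactidae": dict(
        base_level=0.24, base_slope=0.26, gaussian_features=((655, 40, 0.16),)
    ),
    "holothurian_paelopatides": dict(
        base_level=0.34, base_slope=0.02, gaussian_features=((612, 25, 0.18),)
    ),
    "ophiuroid_white": dict(base_level=0.45, base_slope=0.05, gaussian_features=((508, 40, 0.18),)),
    "ophiuroid_red": dict(base_level=0.13, base_slope=0.28, gaussian_features=((690, 35, 0.22),)),
    "crustacean": dict(base_level=0.26, base_slope=0.12, gaussian_features=((615, 60, 0.22),)),
    "salp_dead": dict(
        base_level=0.36, base_slope=0.0, gaussian_features=((415, 35, 0.16), (705, 35, 0.12))
    ),
    "polychaete": dict(
        base_level=0.28, base_slope=0.06, gaussian_features=((538, 15, 0.26), (455, 15, 0.14))
    ),
    "crinoid": dict(
        base_level=0.24, base_slope=0.04, gaussian_features=((492, 22, 0.20), (645, 22, 0.12))
    ),
    "isopod": dict(base_level=0.24, base_slope=0.0, gaussian_features=((558, 60, 0.22),)),
    "bony_fish": dict(base_level=0.42, base_slope=0.0, gaussian_features=((664, 20, 0.18),)),
    "white_exposed_sediment": dict(
        base_level=0.50, base_slope=0.05, gaussian_features=((565, 75, -0.09),)
    ),
    # chlorophyll-a-like absorption dip at 675 nm; the white spot is
    # shallower and slightly brighter in the red
    "green_spot": dict(**_SEDIMENT, dip=(675.0, 8.0, 0.50)),
    "white_spot": dict(**_SEDIMENT, dip=(675.0, 8.0, 0.35), red_boost=1.15),
}


def material_catalog(
    categories: list[str] | tuple[str, ...] | None = None,
    grid: BandGrid | None = None,
) -> dict[str, MaterialSpectrum]:
    """Build the material catalog and verify pairwise spectral separation.

    Every pair of category spectra must be at least 5 degrees apart in
    spectral contrast angle over the 400–710 nm analysis window, except
    pairs within the sediment/spot family (the spots are the sediment
    baseline with a chlorophyll-like dip; their mutual separation is
    set by the dip parameters and partly by intensity, which the angle
    ignores by design).
    """
    grid = grid or make_band_grid()
    if categories is None:
        categories = list(_MATERIAL_PARAMS)
    unknown = [c for c in categories if c not in _MATERIAL_PARAMS]
    if unknown:
        raise KeyError(f"no material model for categories {unknown}")
    catalog = {c: MaterialSpectrum(category=c, **_MATERIAL_PARAMS[c]) for c in categories}

    wl = grid.centers
    window = (wl >= _ANALYSIS_WINDOW_NM[0]) & (wl <= _ANALYSIS_WINDOW_NM[1])
    names = list(catalog)
    spectra = np.vstack([catalog[c].reflectance(wl)[window] for c in names])
    ang = pairwise_contrast_angles(spectra, spectra)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pair = {names[i], names[j]}
            if pair <= _FLOOR_EXEMPT:
                continue
            if ang[i, j] < _MIN_PAIRWISE_DEG:
                raise ValueError(
                    f"catalog spectra '{names[i]}' and '{names[j]}' are only "
                    f"{ang[i, j]:.2f} deg apart (< {_MIN_PAIRWISE_DEG} deg)"
                )
    return catalog


@dataclass
class ObjectSpec:
    """One object to plant: category, center (line, sample), diameter."""

    category: str
    center: tuple[float, float]
    diameter_cm: float
    aspect: float = 1.0  # along-track/cross-track axis ratio for ellipses


@dataclass
class SceneConfig:
    """Scene layout, optics and noise of one synthetic survey track.

    Defaults emulate the study conditions: 300 x 400 px at 1 mm pixels,
    the 112-band grid, cosine cross-track illumination falling to 0.6 at
    the swath edges, +/-5% along-track gain drift, 1%-of-signal Gaussian
    noise inflated fivefold outside 400–710 nm, fauna objects 0.8–8 cm
    and anomaly spots at most 2 cm across.
    """

    lines: int = 300
    samples: int = 400
    pixel_size_mm: float = 1.0
    grid: BandGrid = field(default_factory=make_band_grid)
    objects: list[ObjectSpec] | None = None  # explicit placement
    categories: tuple[str, ...] = DEFAULT_SCENE_CATEGORIES
    n_objects: int = 18
    fauna_diameter_cm: tuple[float, float] = (1.5, 8.0)
    spot_diameter_cm: tuple[float, float] = (1.0, 2.0)
    n_nodules: int = 60
    nodule_diameter_cm: tuple[float, float] = (1.0, 4.0)
    min_separation_px: float = 12.0  # keeps planted objects disjoint under 8-connectivity
    edge_illumination: float = 0.6
    drift_amplitude: float = 0.05
    noise_frac: float = 0.01
    edge_noise_inflation: float = 5.0
    gain: float = 1000.0
    brightness_jitter: float = 0.05
    seed: int = 0


@dataclass
class SceneTruth:
    """Ground truth emitted with a synthetic cube."""

    labels: np.ndarray  # (lines, samples) int raster
    legend: dict[int, str]
    object_ids: np.ndarray  # (lines, samples) int raster; 0 = background
    objects: pd.DataFrame  # id, category, center, diameter_cm
    materials: dict[str, np.ndarray]  # category -> true reflectance spectrum
    illumination: np.ndarray  # (lines, samples) multiplicative field


def _disc_mask(lines: int, samples: int, center: tuple[float, float], radius_px: float, aspect: float) -> np.ndarray:
    ll, ss = np.ogrid[:lines, :samples]
    return ((ll - center[0]) / aspect) ** 2 + (ss - center[1]) ** 2 <= radius_px**2


def _random_objects(cfg: SceneConfig, rng: np.random.Generator) -> list[ObjectSpec]:
    """Rejection-sample non-overlapping disc placements."""
    placed: list[ObjectSpec] = []
    px_per_cm = 10.0 / cfg.pixel_size_mm
    cats = [cfg.categories[i % len(cfg.categories)] for i in range(cfg.n_objects)]
    sized = []
    for cat in cats:
        lo, hi = cfg.spot_diameter_cm if cat in _SPOT_CATEGORIES else cfg.fauna_diameter_cm
        sized.append((cat, float(rng.uniform(lo, hi))))
    sized.sort(key=lambda cd: -cd[1])  # largest first packs more reliably
    for cat, diameter in sized:
        r = diameter * px_per_cm / 2.0
        if 2 * (r + 1) >= min(cfg.lines, cfg.samples):
            raise ValueError(
                f"a {diameter:.1f} cm '{cat}' does not fit a "
                f"{cfg.lines}x{cfg.samples} px scene at {cfg.pixel_size_mm} mm pixels"
            )
        for _ in range(500):
            center = (
                float(rng.uniform(r + 1, cfg.lines - r - 1)),
                float(rng.uniform(r + 1, cfg.samples - r - 1)),
            )
            margin = cfg.min_separation_px
            ok = all(
                np.hypot(center[0] - o.center[0], center[1] - o.center[1])
                > r + o.diameter_cm * px_per_cm / 2.0 + margin
                for o in placed
            )
            if ok:
                placed.append(ObjectSpec(category=cat, center=center, diameter_cm=diameter))
                break
        else:
            raise RuntimeError(
                f"could not place a {diameter:.1f} cm '{cat}' without overlap; "
                "reduce n_objects or object sizes"
            )
    return placed


def generate_scene(cfg: SceneConfig | None = None) -> tuple[HyperCube, SceneTruth]:
    """Render a raw synthetic cube and its ground truth.

    Fully reproducible from ``cfg.seed``: a single generator drives
    placement, per-object brightness jitter and noise.
    """
    cfg = cfg or SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    wl = cfg.grid.centers
    all_cats = ["sediment", "nodule"] + [
        c for c in _MATERIAL_PARAMS if c not in ("sediment", "nodule")
    ]
    catalog = material_catalog(all_cats, cfg.grid)

    legend = {0: "sediment", 1: "nodule"}
    code_of = {"sediment": 0, "nodule": 1}
    labels = np.zeros((cfg.lines, cfg.samples), dtype=np.int32)
    object_ids = np.zeros((cfg.lines, cfg.samples), dtype=np.int32)

    # nodule background texture (not objects of interest)
    px_per_cm = 10.0 / cfg.pixel_size_mm
    for _ in range(cfg.n_nodules):
        d = rng.uniform(*cfg.nodule_diameter_cm)
        center = (rng.uniform(0, cfg.lines - 1), rng.uniform(0, cfg.samples - 1))
        labels[_disc_mask(cfg.lines, cfg.samples, center, d * px_per_cm / 2.0, 1.0)] = 1

    objects = cfg.objects if cfg.objects is not None else _random_objects(cfg, rng)
    rows = []
    jitter = {}
    for k, obj in enumerate(objects, start=1):
        if obj.category not in catalog:
            raise KeyError(f"object category '{obj.category}' not in material catalog")
        if obj.category not in code_of:
            code_of[obj.category] = len(legend)
            legend[len(legend)] = obj.category
        mask = _disc_mask(
            cfg.lines, cfg.samples, obj.center, obj.diameter_cm * px_per_cm / 2.0, obj.aspect
        )
        labels[mask] = code_of[obj.category]
        object_ids[mask] = k
        jitter[k] = 1.0 + float(rng.uniform(-cfg.brightness_jitter, cfg.brightness_jitter))
        rows.append(
            {
                "object_id": k,
                "category": obj.category,
                "center_line": obj.center[0],
                "center_sample": obj.center[1],
                "diameter_cm": obj.diameter_cm,
            }
        )

    # reflectance cube via catalog lookup
    spectra = np.vstack([catalog[legend[i]].reflectance(wl) for i in sorted(legend)])
    refl = spectra[labels]  # (lines, samples, bands)
    for k, factor in jitter.items():
        if factor != 1.0:
            refl[object_ids == k] = np.clip(refl[object_ids == k] * factor, 1e-6, 1.0)

    # optics: cross-track cosine falloff x along-track drift x lamp spectrum
    x = (np.arange(cfg.samples) - (cfg.samples - 1) / 2) / ((cfg.samples - 1) / 2)
    cross = cfg.edge_illumination + (1 - cfg.edge_illumination) * np.cos(x * np.pi / 2)
    phase = rng.uniform(0, 2 * np.pi)
    drift = 1.0 + cfg.drift_amplitude * np.sin(
        2 * np.pi * np.arange(cfg.lines) / max(cfg.lines, 1) + phase
    )
    illum = np.outer(drift, cross)
    lamp = 0.6 + 0.4 * np.exp(-0.5 * ((wl - 560.0) / 180.0) ** 2)

    signal = refl * illum[:, :, np.newaxis] * lamp[np.newaxis, np.newaxis, :] * cfg.gain
    sd = cfg.noise_frac * signal
    edge_bands = (wl < 400.0) | (wl > 710.0)
    sd[:, :, edge_bands] *= cfg.edge_noise_inflation
    data = signal + rng.standard_normal(signal.shape) * sd
    data = np.maximum(data, 0.0).astype(np.float32)

    cube = HyperCube(
        data=data,
        wavelengths=wl,
        pixel_size_mm=cfg.pixel_size_mm,
        stage=Stage.RAW,
        track_id=f"synthetic_seed{cfg.seed}",
    )
    truth = SceneTruth(
        labels=labels,
        legend=legend,
        object_ids=object_ids,
        objects=pd.DataFrame(rows),
        materials={c: catalog[c].reflectance(wl) for c in {legend[i] for i in legend}},
        illumination=illum,
    )
    return cube, truth


def default_scene_config(seed: int = 0, **overrides) -> SceneConfig:
    """The standard desk-scale fixture used across tests and examples."""
    return SceneConfig(seed=seed, **overrides)
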
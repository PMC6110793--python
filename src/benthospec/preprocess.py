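"""Raw-to-pseudo-reflectance processing chain.

Raw underwater hyperspectral data mix the target reflectance with the
lamp spectrum, illumination geometry and water-column effects. Lacking a
radiometric characterization of those terms, each pixel spectrum is
divided by a reference spectrum estimated from the scene itself; the
result is *pseudo-reflectance* — reflectance-like but with residual
illumination effects — never true reflectance. The chain is fixed as
spectral subsetting, reference division, then moving-average smoothing.

The transformers (`MovingAverageSmoother`) follow the scikit-learn
fit/transform contract on ``(n_spectra, n_bands)`` matrices; the
cube-level functions wrap them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import uniform_filter1d
from sklearn.base import BaseEstimator, TransformerMixin

from .cube import HyperCube, Stage

__all__ = [
    "ReferenceMode",
    "PreprocessConfig",
    "ReferenceField",
    "spectral_subset",
    "compute_reference",
    "pseudo_reflectance",
    "smooth_spectra",
    "MovingAverageSmoother",
    "preprocess_cube",
]


class ReferenceMode(str, enum.Enum):
    COLUMN_MEAN = "column_mean"
    COLUMN_MEDIAN = "column_median"
    GLOBAL_MEAN = "global_mean"


@dataclass
class PreprocessConfig:
    """Parameters of the processing chain.

    Defaults follow the standard deep-sea survey configuration: keep the
    83 bands between 400 and 710 nm (bands outside are noisy), divide by
    a per-cross-track-column reference spectrum, smooth with an 11-band
    (44 nm) moving average. The default reference statistic is the
    column *median*: like the column mean it removes a static
    multiplicative cross-track illumination field exactly, but it stays
    anchored to the background even when sizeable objects occupy a
    large fraction of a column (short tracks), where the mean would be
    pulled toward the object spectra.
    """

    subset_min_nm: float = 400.0
    subset_max_nm: float = 710.0
    reference_mode: ReferenceMode = ReferenceMode.COLUMN_MEDIAN
    smooth_window_bands: int = 11
    edge_mode: str = "reflect"

    def __post_init__(self) -> None:
        self.reference_mode = ReferenceMode(self.reference_mode)
        if self.subset_min_nm >= self.subset_max_nm:
            raise ValueError("subset_min_nm must be < subset_max_nm")
        if self.smooth_window_bands < 1 or self.smooth_window_bands % 2 == 0:
            raise ValueError("smooth_window_bands must be odd and >= 1")
        if self.edge_mode not in ("reflect", "shrink"):
            raise ValueError("edge_mode must be 'reflect' or 'shrink'")


@dataclass
class ReferenceField:
    """Scene-derived reference spectra used for pseudo-reflectance.

    ``spectra`` is ``(samples, bands)`` in column-mean mode or
    ``(bands,)`` in global-mean mode; ``valid_mask`` flags strictly
    positive entries (only those may divide).
    """

    mode: ReferenceMode
    spectra: np.ndarray
    valid_mask: np.ndarray


def spectral_subset(cube: HyperCube, min_nm: float, max_nm: float) -> HyperCube:
    """Keep exactly the bands with ``min_nm <= center <= max_nm`` (inclusive)."""
    keep = (cube.wavelengths >= min_nm) & (cube.wavelengths <= max_nm)
    if not keep.any():
        raise ValueError(
            f"no band centers in [{min_nm}, {max_nm}] nm "
            f"(cube covers {cube.wavelengths[0]}-{cube.wavelengths[-1]} nm)"
        )
    return replace(
        cube,
        data=np.ascontiguousarray(cube.data[:, :, keep]),
        wavelengths=cube.wavelengths[keep],
    )


def compute_reference(cube: HyperCube, mode: ReferenceMode | str = ReferenceMode.COLUMN_MEAN) -> ReferenceField:
    """Estimate the reference spectrum from the track's own data.

    ``column_mean``/``column_median`` reduce each cross-track sample
    position over all along-track lines, correcting the static
    lamp-array geometry (the median variant resists contamination by
    objects within a column); ``global_mean`` averages over all pixels.
    """
    mode = ReferenceMode(mode)
    if cube.stage not in (Stage.RAW, Stage.RADIANCE):
        raise ValueError(f"reference must come from raw/radiance data, got stage {cube.stage.value}")
    if mode in (ReferenceMode.COLUMN_MEAN, ReferenceMode.COLUMN_MEDIAN):
        reducer = np.mean if mode is ReferenceMode.COLUMN_MEAN else np.median
        spectra = reducer(cube.data, axis=0).astype(np.float64)  # (samples, bands)
        band_ok = (spectra > 0).any(axis=0)
    else:
        spectra = cube.data.mean(axis=(0, 1)).astype(np.float64)  # (bands,)
        band_ok = spectra > 0
    if not band_ok.all():
        bad = np.flatnonzero(~band_ok)
        raise ValueError(
            f"reference is nonpositive everywhere in band(s) {bad.tolist()} "
            f"({cube.wavelengths[bad].round(1).tolist()} nm)"
        )
    return ReferenceField(mode=mode, spectra=spectra, valid_mask=spectra > 0)


def pseudo_reflectance(cube: HyperCube, ref: ReferenceField) -> HyperCube:
    """Divide each pixel spectrum elementwise by its reference spectrum."""
    if ref.mode in (ReferenceMode.COLUMN_MEAN, ReferenceMode.COLUMN_MEDIAN):
        if ref.spectra.shape != (cube.samples, cube.n_bands):
            raise ValueError(
                f"reference shape {ref.spectra.shape} incompatible with cube "
                f"({cube.samples} samples x {cube.n_bands} bands)"
            )
        denom = ref.spectra[np.newaxis, :, :]
        used_invalid = ~ref.valid_mask
    else:
        if ref.spectra.shape != (cube.n_bands,):
            raise ValueError(
                f"reference shape {ref.spectra.shape} incompatible with {cube.n_bands} bands"
            )
        denom = ref.spectra[np.newaxis, np.newaxis, :]
        used_invalid = ~ref.valid_mask
    if used_invalid.any():
        raise ValueError("reference contains invalid (nonpositive) entries; cannot divide")
    out = (cube.data.astype(np.float64) / denom).astype(np.float32)
    if not np.all(np.isfinite(out)):
        raise ValueError("pseudo-reflectance produced non-finite values")
    return replace(cube, data=out, stage=Stage.PSEUDO_REFLECTANCE)


class MovingAverageSmoother(TransformerMixin, BaseEstimator):
    """Centered moving-average filter along the band axis.

    scikit-learn-style transformer on ``(n_spectra, n_bands)`` matrices.

    Parameters
    ----------
    window : int
        Odd window length in bands (default 11, i.e. 44 nm at 4 nm
        spacing).
    edge_mode : str
        ``"reflect"`` pads by mirroring so the band count is preserved;
        ``"shrink"`` averages only the in-range part of the window near
        the edges.
    """

    def __init__(self, window: int = 11, edge_mode: str = "reflect"):
        self.window = window
        self.edge_mode = edge_mode

    def fit(self, X, y=None):
        X = np.asarray(X)
        if self.window % 2 == 0 or self.window < 1:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")
        if self.window > X.shape[-1]:
            raise ValueError(f"window {self.window} exceeds band count {X.shape[-1]}")
        if self.edge_mode not in ("reflect", "shrink"):
            raise ValueError("edge_mode must be 'reflect' or 'shrink'")
        self.n_features_in_ = X.shape[-1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        if self.window == 1:
            return X.copy()
        if self.edge_mode == "reflect":
            return uniform_filter1d(X, size=self.window, axis=-1, mode="mirror")
        # shrink: normalize a same-length convolution by the in-window count
        kernel = np.ones(self.window)
        num = np.apply_along_axis(lambda s: np.convolve(s, kernel, mode="same"), -1, X)
        counts = np.convolve(np.ones(X.shape[-1]), kernel, mode="same")
        return num / counts


def smooth_spectra(cube: HyperCube, window: int = 11, edge_mode: str = "reflect") -> HyperCube:
    """Per-pixel moving average along the band axis; preserves band count."""
    sm = MovingAverageSmoother(window=window, edge_mode=edge_mode)
    flat = cube.data.reshape(-1, cube.n_bands)
    out = sm.fit_transform(flat).reshape(cube.data.shape).astype(np.float32)
    return replace(cube, data=out, stage=Stage.SMOOTHED)


def preprocess_cube(cube: HyperCube, config: PreprocessConfig | None = None) -> HyperCube:
    """Full chain: subset -> reference division -> smoothing."""
    cfg = config or PreprocessConfig()
    sub = spectral_subset(cube, cfg.subset_min_nm, cfg.subset_max_nm)
    ref = compute_reference(sub, cfg.reference_mode)
    pr = pseudo_reflectance(sub, ref)
    return smooth_spectra(pr, cfg.smooth_window_bands, cfg.edge_mode)
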
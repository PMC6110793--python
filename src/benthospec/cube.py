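"""Hyperspectral cube container and ENVI-style file I/O.

The cube layout follows push-broom acquisition: axis 0 is the along-track
line, axis 1 the cross-track sample, axis 2 the spectral band. Files are
stored in the de facto remote-sensing container — a ``key = value`` text
header next to a flat binary payload in BSQ, BIL or BIP interleave.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "Stage",
    "HyperCube",
    "read_cube",
    "write_cube",
    "pseudo_rgb",
    "save_pseudo_rgb_png",
]


class Stage(str, enum.Enum):
    """Processing stage of a cube's values."""

    RAW = "raw"
    RADIANCE = "radiance"
    PSEUDO_REFLECTANCE = "pseudo_reflectance"
    SMOOTHED = "smoothed"


# ENVI numeric codes for the dtypes we read and write.
_DTYPE_CODES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_CODE_FOR_DTYPE = {np.dtype(v): k for k, v in _DTYPE_CODES.items()}


@dataclass
class HyperCube:
    """An intensity cube with its wavelength axis.

    Parameters
    ----------
    data
        Array of shape ``(lines, samples, bands)``; nonnegative, finite.
    wavelengths
        Band-center wavelengths in nm, strictly increasing, one per band.
    pixel_size_mm
        Ground pixel size in millimetres (default 1.0).
    stage
        Processing stage tag.
    track_id
        Free-text identifier of the survey track.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    pixel_size_mm: float = 1.0
    stage: Stage = Stage.RAW
    track_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype.kind == "f" and self.data.dtype != np.float32:
            self.data = self.data.astype(np.float32)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.stage = Stage(self.stage)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength count {self.wavelengths.size} != band count {self.data.shape[2]}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def lines(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band whose center is nearest ``wavelength_nm``.

        Ties between two equally near centers resolve to the lower
        wavelength.
        """
        dist = np.abs(self.wavelengths - wavelength_nm)
        return int(np.argmin(dist))  # argmin takes the first (lower-λ) minimum

    def with_data(self, data: np.ndarray, stage: Stage | None = None) -> "HyperCube":
        return replace(self, data=data, stage=self.stage if stage is None else stage)


def _parse_header(text: str) -> dict:
    """Parse an ENVI-style ``key = value`` header into a dict.

    Braced values (``{...}``) may span lines; keys are lower-cased.
    """
    # strip comments
    text = "\n".join(ln for ln in text.splitlines() if not ln.lstrip().startswith(";"))
    fields: dict[str, str] = {}
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.MULTILINE | re.DOTALL)
    for m in pattern.finditer(text):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        fields[key] = val
    return fields


def read_cube(path: str | Path) -> HyperCube:
    """Read a cube from an ENVI-style header + flat binary pair.

    ``path`` may point at the header (``.hdr``) or the binary; the partner
    file is located by extension. Any interleave (BSQ/BIL/BIP) is
    normalized to the band-last in-memory layout.
    """
    path = Path(path)
    if path.suffix.lower() == ".hdr":
        hdr_path = path
        data_path = _find_binary(path)
    else:
        data_path = path
        hdr_path = path.with_suffix(path.suffix + ".hdr")
        if not hdr_path.exists():
            hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(f"header not found for {path}")
    if not data_path.exists():
        raise FileNotFoundError(f"binary payload not found for {path}")

    hdr = _parse_header(hdr_path.read_text())
    for key in ("samples", "lines", "bands", "interleave", "data type"):
        if key not in hdr:
            raise ValueError(f"header missing required field '{key}'")
    samples = int(hdr["samples"])
    lines = int(hdr["lines"])
    bands = int(hdr["bands"])
    interleave = hdr["interleave"].lower()
    code = int(hdr["data type"])
    if code not in _DTYPE_CODES:
        raise ValueError(f"unsupported data type code {code}")
    dtype = np.dtype(_DTYPE_CODES[code])
    byte_order = int(hdr.get("byte order", "0"))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")

    if "wavelength" not in hdr:
        raise ValueError("header missing wavelength list")
    wl_text = hdr["wavelength"].strip().strip("{}")
    wavelengths = np.array([float(x) for x in wl_text.replace("\n", " ").split(",") if x.strip()])
    if wavelengths.size != bands:
        raise ValueError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )

    raw = np.fromfile(data_path, dtype=dtype)
    expected = lines * samples * bands
    if raw.size != expected:
        raise ValueError(
            f"binary payload has {raw.size} values, expected {expected} "
            f"({lines}x{samples}x{bands})"
        )
    if interleave == "bsq":  # band-sequential: (bands, lines, samples)
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":  # band-interleaved-by-line: (lines, bands, samples)
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":  # band-interleaved-by-pixel: (lines, samples, bands)
        data = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unsupported interleave '{interleave}'")

    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    pixel_size = float(hdr.get("pixel size mm", "1.0"))
    stage = hdr.get("stage", "raw")
    track_id = hdr.get("track id", "").strip()
    return HyperCube(
        data=np.ascontiguousarray(data),
        wavelengths=wavelengths,
        pixel_size_mm=pixel_size,
        stage=Stage(stage),
        track_id=track_id,
    )


def _find_binary(hdr_path: Path) -> Path:
    stem = hdr_path.with_suffix("")
    for ext in (".bsq", ".bil", ".bip", ".img", ".dat", ""):
        cand = stem.with_suffix(ext) if ext else stem
        if cand.exists() and cand != hdr_path:
            return cand
    return stem


def write_cube(cube: HyperCube, path: str | Path, interleave: str = "bsq") -> None:
    """Write ``cube`` as an ENVI-style header + flat binary pair.

    ``path`` names the binary payload; a sibling ``<path>.hdr`` header is
    written next to it. Wavelengths are serialized at 4 decimal places.
    """
    path = Path(path)
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unsupported interleave '{interleave}'")
    data = cube.data
    if data.dtype not in _CODE_FOR_DTYPE:
        data = data.astype(np.float32)
    if interleave == "bsq":
        out = data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:
        out = data
    path.parent.mkdir(parents=True, exist_ok=True)
    np.ascontiguousarray(out).tofile(path)

    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {cube.samples}\n"
        f"lines = {cube.lines}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        f"data type = {_CODE_FOR_DTYPE[np.dtype(data.dtype)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"pixel size mm = {cube.pixel_size_mm}\n"
        f"stage = {cube.stage.value}\n"
        f"track id = {cube.track_id}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    path.with_suffix(path.suffix + ".hdr").write_text(hdr)


def pseudo_rgb(
    cube: HyperCube,
    r_nm: float = 645.0,
    g_nm: float = 571.0,
    b_nm: float = 473.0,
    stretch: tuple[float, float] = (2.0, 98.0),
) -> np.ndarray:
    """Render a cube as a 3-channel image from three chosen bands.

    Default wavelengths give the red/green/blue rendering used for visual
    inspection of seafloor tracks (645, 571, 473 nm). Each channel is the
    band nearest the requested wavelength, independently rescaled to
    [0, 1] by a percentile stretch.
    """
    if cube.n_bands < 3:
        raise ValueError("pseudo-RGB rendering needs at least 3 bands")
    spacing = float(np.median(np.diff(cube.wavelengths))) if cube.n_bands > 1 else 0.0
    lo = cube.wavelengths[0] - spacing
    hi = cube.wavelengths[-1] + spacing
    channels = []
    for nm in (r_nm, g_nm, b_nm):
        if not (lo <= nm <= hi):
            raise ValueError(
                f"requested wavelength {nm} nm outside covered range "
                f"[{cube.wavelengths[0]}, {cube.wavelengths[-1]}] nm"
            )
        band = cube.data[:, :, cube.band_index(nm)].astype(np.float64)
        p_lo, p_hi = np.percentile(band, stretch)
        if p_hi > p_lo:
            band = np.clip((band - p_lo) / (p_hi - p_lo), 0.0, 1.0)
        else:  # constant channel -> mid-gray
            band = np.full_like(band, 0.5)
        channels.append(band)
    return np.stack(channels, axis=-1)


def save_pseudo_rgb_png(cube: HyperCube, path: str | Path, **kwargs) -> None:
    """Write the pseudo-RGB rendering of ``cube`` to a PNG file."""
    rgb = pseudo_rgb(cube, **kwargs)
    img = Image.fromarray((rgb * 255).round().astype(np.uint8))
    img.save(Path(path))
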
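"""Core raster containers: grayscale micrographs and binary spheroid masks.

Both carry a physical pixel size in micrometres per pixel; every downstream
measurement (area, perimeter, volume) is reported in physical units.
Conventions used throughout the package:

* coordinates are 0-based ``(row, col)`` with pixel centers at integer
  coordinates;
* foreground connectivity is 4-connected, boundary tracing 8-connected;
* the spheroid is assumed darker than the background (brightfield).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image as _PILImage

__all__ = [
    "SpheromorphError",
    "DegenerateInputError",
    "GrayImage",
    "BinaryMask",
]


class SpheromorphError(Exception):
    """Base class for all errors raised by this package."""


class DegenerateInputError(SpheromorphError):
    """Raised when an input is structurally valid but unmeasurable."""


def _read_raster(path: Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        arr = np.asarray(_PILImage.open(path))
    if arr.ndim == 3:  # RGB(A) -> luminance, conservative for gray-saved PNGs
        arr = arr[..., :3].mean(axis=-1)
    return np.asarray(arr)


def _write_raster(path: Path, arr: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        _PILImage.fromarray(arr).save(path)


@dataclass
class GrayImage:
    """A 2D intensity raster with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        Rectangular 2D array of finite intensities (any numeric dtype).
    pixel_size : float
        Side length of a (square) pixel in μm; must be finite and positive.
    source : str
        Free-form provenance identifier (file path, phantom spec, ...).
    """

    pixels: np.ndarray
    pixel_size: float
    source: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise DegenerateInputError("image must be a nonempty 2D raster")
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise DegenerateInputError("pixel_size must be finite and positive")
        if not np.all(np.isfinite(np.asarray(self.pixels, dtype=float))):
            raise DegenerateInputError("image intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def to_uint8(self) -> np.ndarray:
        """Clip to [0, 255] and quantize; no rescaling is applied."""
        return np.clip(np.rint(np.asarray(self.pixels, dtype=float)), 0, 255).astype(np.uint8)

    @classmethod
    def from_file(cls, path: str | Path, pixel_size: float) -> "GrayImage":
        return cls(_read_raster(Path(path)), pixel_size, source=str(path))

    def save(self, path: str | Path) -> None:
        """Write as 8-bit grayscale TIFF or PNG (by extension)."""
        _write_raster(Path(path), self.to_uint8())


@dataclass
class BinaryMask:
    """A 2D boolean raster marking spheroid pixels, plus QC flags."""

    pixels: np.ndarray
    pixel_size: float
    qc_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise DegenerateInputError("mask must be a nonempty 2D raster")
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise DegenerateInputError("pixel_size must be finite and positive")
        self.qc_flags = set(self.qc_flags)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    def save(self, path: str | Path) -> None:
        """Write as a 0/255 PNG (or TIFF) with a JSON sidecar.

        The sidecar ``<path>.json`` records ``pixel_size_um`` and the QC
        flags so a reloaded mask is measurement-equivalent.
        """
        path = Path(path)
        _write_raster(path, (self.pixels.astype(np.uint8) * 255))
        sidecar = {"pixel_size_um": self.pixel_size, "qc_flags": sorted(self.qc_flags)}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path, pixel_size: float | None = None) -> "BinaryMask":
        path = Path(path)
        arr = _read_raster(path) > 127
        flags: set[str] = set()
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
            flags = set(meta.get("qc_flags", []))
        if pixel_size is None:
            raise SpheromorphError("pixel_size required (no sidecar found)")
        return cls(arr, float(pixel_size), flags)
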
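"""Brightfield spheroid segmentation and mask quality control.

The segmentation recipe is deliberately simple and fully documented:
min–max intensity normalization, a global Otsu threshold (the spheroid is
assumed *darker* than the background; a polarity switch inverts), a
morphological closing with a small disk to bridge noise speckle, hole
filling, removal of components below a minimum area fraction, and finally
the largest 4-connected dark component. One spheroid per image is assumed
throughout — multiple comparable objects are a QC flag, not a scene to
parse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

from .images import BinaryMask, DegenerateInputError, GrayImage, SpheromorphError

__all__ = [
    "SegmentationError",
    "SegmentationOptions",
    "QCReport",
    "segment_spheroid",
    "mask_qc",
]


class SegmentationError(SpheromorphError):
    pass


@dataclass(frozen=True)
class SegmentationOptions:
    """Tunable knobs of the segmentation recipe.

    ``dark_object`` selects brightfield polarity (object darker than
    background). ``closing_radius`` is the disk radius (px) of the closing;
    ``min_area_fraction`` drops components smaller than this fraction of
    the image; ``threshold`` overrides Otsu with a fixed normalized value.
    """

    dark_object: bool = True
    closing_radius: int = 3
    min_area_fraction: float = 0.01
    threshold: float | None = None
    #: minimum Otsu class separation (fraction of the normalized range)
    #: required to accept that an object is present at all; pure-noise
    #: blanks split at ~0.2, real body/background contrast at ~0.6
    min_contrast: float = 0.3


def segment_spheroid(
    image: GrayImage, options: SegmentationOptions | None = None
) -> BinaryMask:
    """Segment the single spheroid in a brightfield image.

    Returns the largest dark 4-connected component after cleaning, with QC
    flags recorded on the mask (``multi_object`` from the pre-cleaning
    component structure, ``touches_border`` from the final mask).

    Raises
    ------
    SegmentationError
        ``"degenerate image"`` for a constant image, ``"no object found"``
        when no component exceeds the minimum area.
    """
    opts = options or SegmentationOptions()
    px = np.asarray(image.pixels, dtype=float)
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        raise SegmentationError("degenerate image")
    norm = (px - lo) / (hi - lo)
    if not opts.dark_object:
        norm = 1.0 - norm
    thr = float(filters.threshold_otsu(norm)) if opts.threshold is None else opts.threshold
    raw = norm < thr  # dark foreground
    if raw.any() and (~raw).any():
        if float(norm[~raw].mean() - norm[raw].mean()) < opts.min_contrast:
            raise SegmentationError("no object found")

    flags: set[str] = set()
    raw_labels, n_raw = ndimage.label(raw, structure=_FOUR_CONN)
    if n_raw >= 2:
        sizes = np.sort(ndimage.sum_labels(raw, raw_labels, index=np.arange(1, n_raw + 1)))[::-1]
        if sizes[1] >= 0.25 * sizes[0]:
            flags.add("multi_object")

    fg = raw
    if opts.closing_radius > 0:
        fg = ndimage.binary_closing(fg, structure=morphology.disk(opts.closing_radius))
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg, structure=_FOUR_CONN)
    if n == 0:
        raise SegmentationError("no object found")
    sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
    min_area = opts.min_area_fraction * fg.size
    keep = int(np.argmax(sizes)) + 1
    if sizes[keep - 1] < min_area:
        raise SegmentationError("no object found")
    mask = labels == keep

    if _touches_border(mask):
        flags.add("touches_border")
    return BinaryMask(mask, image.pixel_size, qc_flags=flags)


_FOUR_CONN = ndimage.generate_binary_structure(2, 1)


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any())


@dataclass
class QCReport:
    """Pass/fail verdict plus the individual flags that fired."""

    passed: bool
    flags: set[str] = field(default_factory=set)


def mask_qc(mask: BinaryMask, min_diameter_um: float = 100.0) -> QCReport:
    """Automatic checks on a binary mask before measurement.

    Flags raised:

    * ``touches_border`` — foreground on the image frame (silhouette may be
      clipped);
    * ``multi_object`` — a second 4-connected component at least 25% the
      size of the largest (either present in the given raster or inherited
      from segmentation's pre-cleaning flags);
    * ``too_small`` — equivalent diameter below ``min_diameter_um``.
    """
    flags = set(mask.qc_flags)
    px = mask.pixels
    if px.sum() == 0:
        raise DegenerateInputError("empty mask")
    labels, n = ndimage.label(px, structure=_FOUR_CONN)
    if n >= 2:
        sizes = np.sort(ndimage.sum_labels(px, labels, index=np.arange(1, n + 1)))[::-1]
        if sizes[1] >= 0.25 * sizes[0]:
            flags.add("multi_object")
    if _touches_border(px):
        flags.add("touches_border")
    area_um2 = px.sum() * mask.pixel_size**2
    d_eq = 2.0 * np.sqrt(area_um2 / np.pi)
    if d_eq < min_diameter_um:
        flags.add("too_small")
    return QCReport(passed=not flags, flags=flags)
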
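"""Micrograph → binary mask → labelled cell instances.

Front end of every analysis here: threshold the grayscale image to
suppress background, clean the binary mask, then split the foreground
into connected components, each one cell silhouette.  Otsu's method is
the default threshold because it is parameter-free and reproducible; a
manual threshold is available for low-contrast material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError, ValidationError
from .io import Micrograph

__all__ = ["BinaryMask", "CellInstance", "binarize", "clean_mask", "label_instances"]


@dataclass
class BinaryMask:
    """Boolean raster plus the record of how it was produced."""

    pixels: np.ndarray
    pixel_size_um: float
    method_record: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("mask must be 2-D and non-empty")
        if not (self.pixel_size_um > 0):
            raise ValidationError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def foreground_count(self) -> int:
        return int(self.pixels.sum())


@dataclass
class CellInstance:
    """One connected foreground component.

    ``coords`` are global (row, col) pixel coordinates; ``outline`` is the
    ordered outer boundary contour (sub-pixel, from marching squares) in
    the same frame.
    """

    cell_id: int
    coords: np.ndarray
    outline: np.ndarray
    touches_border: bool
    image_shape: tuple[int, int]
    pixel_size_um: float

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    def bbox(self) -> tuple[int, int, int, int]:
        """(rmin, cmin, rmax, cmax), half-open on the max side."""
        rmin, cmin = self.coords.min(axis=0)
        rmax, cmax = self.coords.max(axis=0) + 1
        return int(rmin), int(cmin), int(rmax), int(cmax)

    def local_mask(self, pad: int = 1) -> tuple[np.ndarray, tuple[int, int]]:
        """Boolean raster of this cell alone, padded; returns (mask, origin)."""
        rmin, cmin, rmax, cmax = self.bbox()
        mask = np.zeros((rmax - rmin + 2 * pad, cmax - cmin + 2 * pad), dtype=bool)
        mask[self.coords[:, 0] - rmin + pad, self.coords[:, 1] - cmin + pad] = True
        return mask, (rmin - pad, cmin - pad)


def binarize(
    m: Micrograph,
    method: str = "otsu",
    manual_threshold: float | None = None,
    invert: bool = False,
) -> BinaryMask:
    """Threshold a micrograph.

    Otsu foreground is ``pixels > t``; manual foreground is
    ``pixels >= manual_threshold`` (so threshold 0 selects everything).
    ``invert`` flips the selected side, for dark-on-bright material.
    """
    pix = m.pixels
    if method == "otsu":
        if pix.min() == pix.max():
            raise DegenerateInputError(
                "zero intensity variance: Otsu is undefined; supply a manual threshold"
            )
        t = float(threshold_otsu(pix))
        fg = pix > t
    elif method == "manual":
        if manual_threshold is None:
            raise ValidationError("manual method requires manual_threshold")
        if not (0 <= manual_threshold <= 2**m.bit_depth - 1):
            raise ValidationError(
                f"manual_threshold {manual_threshold} outside {m.bit_depth}-bit range"
            )
        t = float(manual_threshold)
        fg = pix >= t
    else:
        raise ValidationError(f"unknown threshold method {method!r}")
    if invert:
        fg = ~fg
    return BinaryMask(
        pixels=fg,
        pixel_size_um=m.pixel_size_um,
        method_record={"method": method, "threshold": t, "invert": invert},
    )


def clean_mask(mask: BinaryMask, min_object_px: int = 0, fill_holes: bool = False) -> BinaryMask:
    """Drop components below ``min_object_px`` pixels; optionally fill holes."""
    if min_object_px < 0:
        raise ValidationError("min_object_px must be >= 0")
    pix = mask.pixels
    if min_object_px > 1:
        lab, n = ndimage.label(pix, structure=np.ones((3, 3)))
        sizes = np.bincount(lab.ravel(), minlength=n + 1)
        keep = sizes >= min_object_px
        keep[0] = False
        pix = keep[lab]
    if fill_holes:
        pix = ndimage.binary_fill_holes(pix)
    record = dict(mask.method_record)
    record.update({"min_object_px": min_object_px, "fill_holes": fill_holes})
    return BinaryMask(pixels=pix, pixel_size_um=mask.pixel_size_um, method_record=record)


def _outer_contour(local: np.ndarray, origin: tuple[int, int]) -> np.ndarray:
    contours = measure.find_contours(local.astype(float), 0.5)
    if not contours:  # single isolated pixel still yields one; safeguard
        return np.empty((0, 2))
    longest = max(contours, key=len)
    return longest + np.asarray(origin, dtype=float)


def label_instances(
    mask: BinaryMask, connectivity: int = 8, exclude_border: bool = False
) -> list[CellInstance]:
    """Split the mask into connected components, one :class:`CellInstance` each.

    ``connectivity`` is 4 (edge neighbours) or 8 (edges + diagonals,
    default — thin neurites rasterise with diagonal steps that
    4-connectivity would fragment).  Components touching the raster
    border are flagged, and dropped when ``exclude_border`` is set.
    """
    if connectivity not in (4, 8):
        raise ValidationError("connectivity must be 4 or 8")
    lab = measure.label(mask.pixels, connectivity=1 if connectivity == 4 else 2)
    nrows, ncols = mask.shape
    instances: list[CellInstance] = []
    for region in measure.regionprops(lab):
        coords = region.coords
        rmin, cmin, rmax, cmax = region.bbox
        touches = rmin == 0 or cmin == 0 or rmax == nrows or cmax == ncols
        if exclude_border and touches:
            continue
        local = np.zeros((rmax - rmin + 2, cmax - cmin + 2), dtype=bool)
        local[coords[:, 0] - rmin + 1, coords[:, 1] - cmin + 1] = True
        outline = _outer_contour(local, (rmin - 1, cmin - 1))
        instances.append(
            CellInstance(
                cell_id=int(region.label),
                coords=coords.copy(),
                outline=outline,
                touches_border=bool(touches),
                image_shape=(nrows, ncols),
                pixel_size_um=mask.pixel_size_um,
            )
        )
    return instances
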
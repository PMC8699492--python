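"""Box-counting fractal dimension and gliding-box lacunarity.

Both descriptors quantify binary silhouettes of cells or cell networks.
The fractal dimension D is the slope of log N(eps) against log(1/eps),
where N(eps) is the number of eps x eps grid boxes containing foreground;
it indexes structural complexity (a smooth curve scales with D = 1, a
filled region with D = 2, branched structures in between).  To suppress
grid-phase bias, N(eps) is the minimum over several diagonal grid
translations.

Lacunarity Lambda(r) measures gappiness: box masses M are sampled by a
box of side r gliding over every position, and

    Lambda(r) = var(M) / mean(M)**2 + 1

so a translationally uniform mass distribution gives exactly 1 and
clustered, gap-rich patterns give larger values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .errors import DegenerateInputError, ValidationError
from .io import Micrograph
from .segmentation import BinaryMask, binarize, clean_mask

__all__ = [
    "FractalResult",
    "LacunarityResult",
    "box_count",
    "default_box_sizes",
    "fractal_dimension",
    "lacunarity",
    "silhouette_pipeline",
]


@dataclass
class FractalResult:
    box_sizes_px: list[int]
    box_counts: list[int]
    dimension_D: float
    fit_intercept: float
    fit_r2: float
    n_offsets_averaged: int


@dataclass
class LacunarityResult:
    box_sizes_px: list[int]
    lambda_curve: list[float]

    @property
    def mean_lambda(self) -> float:
        return float(np.mean(self.lambda_curve))


def _as_bool(mask) -> np.ndarray:
    pix = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask)
    return pix.astype(bool)


def _count_one(pix: np.ndarray, eps: int, offset: tuple[int, int]) -> int:
    """Boxes of side eps containing >= 1 foreground pixel, grid shifted
    by (row, col) ``offset``; the raster is zero-padded to a full tiling."""
    padded = np.pad(pix, ((offset[0], 0), (offset[1], 0)))
    h = -(-padded.shape[0] // eps) * eps
    w = -(-padded.shape[1] // eps) * eps
    padded = np.pad(padded, ((0, h - padded.shape[0]), (0, w - padded.shape[1])))
    tiles = padded.reshape(h // eps, eps, w // eps, eps)
    return int(tiles.any(axis=(1, 3)).sum())


def box_count(mask, sizes: list[int], n_offsets: int = 4) -> list[int]:
    """Minimum-over-offsets box counts N(eps) for each eps in ``sizes``.

    Candidate grid phases are ``n_offsets`` diagonal translations plus
    one grid anchored at the foreground bounding-box corner; the anchor
    makes the count invariant under translation (and 90° rotation) of
    the pattern, which evenly spaced phases alone cannot guarantee.
    """
    pix = _as_bool(mask)
    if not pix.any():
        raise DegenerateInputError("empty mask: box counts undefined")
    if n_offsets < 1:
        raise ValidationError("n_offsets must be >= 1")
    rmin, cmin = np.argwhere(pix).min(axis=0)
    counts = []
    for eps in sizes:
        eps = int(eps)
        if eps < 1 or eps > min(pix.shape):
            raise ValidationError(f"box size {eps} outside [1, {min(pix.shape)}]")
        offsets = {(o := round(i * eps / n_offsets) % eps, o) for i in range(n_offsets)}
        offsets.add((int(-rmin) % eps, int(-cmin) % eps))
        counts.append(min(_count_one(pix, eps, off) for off in offsets))
    return counts


def default_box_sizes(shape: tuple[int, int], min_box: int = 2, max_box: int | None = None) -> list[int]:
    """Powers of 2 from ``min_box`` up to a quarter of the smaller dimension."""
    if max_box is None:
        max_box = min(shape) // 4
    sizes = []
    eps = min_box
    while eps <= max_box:
        sizes.append(eps)
        eps *= 2
    return sizes


def fractal_dimension(
    mask,
    sizes: list[int] | None = None,
    n_offsets: int = 4,
    r2_warn: float = 0.98,
) -> FractalResult:
    """Least-squares box-counting dimension over the configured size range."""
    pix = _as_bool(mask)
    if sizes is None:
        sizes = default_box_sizes(pix.shape)
    if len(sizes) < 4:
        raise ValidationError(
            f"need >= 4 box sizes for a meaningful log-log fit, got {len(sizes)}"
        )
    counts = box_count(pix, sizes, n_offsets=n_offsets)
    x = np.log(1.0 / np.asarray(sizes, dtype=float))
    y = np.log(np.asarray(counts, dtype=float))
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    if r2 < r2_warn:
        warnings.warn(
            f"poor scaling regime: log-log fit R² = {r2:.4f} < {r2_warn}",
            stacklevel=2,
        )
    return FractalResult(
        box_sizes_px=[int(e) for e in sizes],
        box_counts=counts,
        dimension_D=float(fit.slope),
        fit_intercept=float(fit.intercept),
        fit_r2=r2,
        n_offsets_averaged=n_offsets,
    )


def lacunarity(mask, box_sizes: list[int] | None = None, mode: str = "gliding") -> LacunarityResult:
    """Lambda(r) = var(M)/mean(M)² + 1 over box masses M of side r.

    ``gliding`` samples every box position (overlapping, the standard
    gliding-box estimator); ``grid`` samples the non-overlapping tiling.
    """
    pix = _as_bool(mask)
    if not pix.any():
        raise DegenerateInputError("empty mask: lacunarity undefined")
    if mode not in ("gliding", "grid"):
        raise ValidationError(f"unknown lacunarity mode {mode!r}")
    if box_sizes is None:
        box_sizes = default_box_sizes(pix.shape)
    curve = []
    for r in box_sizes:
        r = int(r)
        if r < 1 or r > min(pix.shape):
            raise ValidationError(f"box size {r} outside [1, {min(pix.shape)}]")
        if mode == "gliding":
            # exact window sums at every position via the integral image
            s = np.zeros((pix.shape[0] + 1, pix.shape[1] + 1), dtype=np.int64)
            np.cumsum(np.cumsum(pix, axis=0), axis=1, out=s[1:, 1:])
            masses = s[r:, r:] - s[:-r, r:] - s[r:, :-r] + s[:-r, :-r]
        else:
            h = (pix.shape[0] // r) * r
            w = (pix.shape[1] // r) * r
            masses = pix[:h, :w].reshape(h // r, r, w // r, r).sum(axis=(1, 3))
        masses = masses.ravel().astype(np.float64)
        mean = masses.mean()
        curve.append(float(masses.var() / mean**2 + 1.0) if mean > 0 else float("nan"))
    return LacunarityResult(box_sizes_px=[int(r) for r in box_sizes], lambda_curve=curve)


def outline_only(mask: BinaryMask) -> BinaryMask:
    """Reduce a silhouette to its 1-px boundary (outline analysis mode)."""
    pix = mask.pixels
    eroded = ndimage.binary_erosion(pix, structure=np.ones((3, 3)))
    record = dict(mask.method_record)
    record["outline_only"] = True
    return BinaryMask(pixels=pix & ~eroded, pixel_size_um=mask.pixel_size_um, method_record=record)


def silhouette_pipeline(
    m: Micrograph,
    threshold_method: str = "otsu",
    manual_threshold: float | None = None,
    invert: bool = False,
    min_object_px: int = 0,
    fill_holes: bool = False,
    mode: str = "silhouette",
    sizes: list[int] | None = None,
    n_offsets: int = 4,
) -> tuple[BinaryMask, FractalResult, LacunarityResult]:
    """Threshold → binary → (optional outline) → D and Lambda.

    ``mode``: ``silhouette`` analyses the filled shapes (default);
    ``outline`` analyses the 1-px boundary, for outline-based protocols.
    The analysis runs on the whole field — single cell or network is a
    question of what the micrograph contains.
    """
    mask = binarize(m, method=threshold_method, manual_threshold=manual_threshold, invert=invert)
    mask = clean_mask(mask, min_object_px=min_object_px, fill_holes=fill_holes)
    if mode == "outline":
        analysed = outline_only(mask)
    elif mode == "silhouette":
        analysed = mask
    else:
        raise ValidationError(f"unknown analysis mode {mode!r}")
    fd = fractal_dimension(analysed, sizes=sizes, n_offsets=n_offsets)
    lac = lacunarity(analysed, box_sizes=sizes)
    return analysed, fd, lac
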
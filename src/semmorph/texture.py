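"""Gray-level co-occurrence matrix (GLCM) texture descriptors.

The GLCM is the joint distribution p(i, j) of quantised intensity pairs
at a fixed pixel displacement; Haralick's classical statistics of that
distribution summarise surface texture.  Five descriptors are computed:

* angular second moment  ASM  = sum p(i,j)^2        (uniformity)
* entropy                     = -sum p log p        (natural log)
* contrast                    = sum (i-j)^2 p       (local variation)
* correlation                 = sum (i-mu_i)(j-mu_j) p / (sigma_i sigma_j)
* inverse difference moment IDM = sum p / (1 + (i-j)^2)  (homogeneity)

Intensities are quantised by uniform binning over the full bit-depth
range (not the observed min-max), so descriptors are comparable across
micrographs from one acquisition session.  The default configuration
accumulates the four distance-1 displacements and symmetrises, a
rotation-tolerant choice for SEM-scale texture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import Micrograph

__all__ = [
    "GLCMConfig",
    "GLCMDescriptors",
    "quantize",
    "glcm",
    "descriptors",
    "image_descriptors",
    "texture_map",
]

DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass(frozen=True)
class GLCMConfig:
    levels: int = 16
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    symmetric: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValidationError("levels must be >= 2")
        for off in self.offsets:
            if off == (0, 0):
                raise ValidationError("offsets must be nonzero")


@dataclass
class GLCMDescriptors:
    asm: float
    entropy: float
    contrast: float
    idm: float
    correlation: float | None  # None when sigma = 0 (single-valued image)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "asm": self.asm,
            "entropy": self.entropy,
            "contrast": self.contrast,
            "correlation": self.correlation,
            "idm": self.idm,
        }


def quantize(m: Micrograph | np.ndarray, levels: int = 16, bit_depth: int | None = None) -> np.ndarray:
    """Map intensities to {0, ..., levels-1} by uniform binning of the
    full bit-depth range: q = floor(v * levels / 2**bit_depth)."""
    if levels < 2:
        raise ValidationError("levels must be >= 2")
    if isinstance(m, Micrograph):
        pix, bit_depth = m.pixels, m.bit_depth
    else:
        pix = np.asarray(m)
        if bit_depth is None:
            bit_depth = 16 if pix.max(initial=0) > 255 else 8
    q = (pix.astype(np.int64) * levels) >> bit_depth
    return np.clip(q, 0, levels - 1).astype(np.int32)


def glcm(quantized: np.ndarray, config: GLCMConfig = GLCMConfig()) -> np.ndarray:
    """Co-occurrence counts of level pairs, accumulated over the
    configured offsets, optionally symmetrised and normalised to sum 1."""
    q = np.asarray(quantized)
    if q.ndim != 2:
        raise ValidationError("quantized raster must be 2-D")
    L = config.levels
    if q.max(initial=0) >= L:
        raise ValidationError("raster contains levels outside the configured range")
    mat = np.zeros((L, L), dtype=np.float64)
    for dr, dc in config.offsets:
        if abs(dr) >= q.shape[0] or abs(dc) >= q.shape[1]:
            raise ValidationError(f"offset {(dr, dc)} exceeds raster size {q.shape}")
        r0, r1 = max(0, -dr), min(q.shape[0], q.shape[0] - dr)
        c0, c1 = max(0, -dc), min(q.shape[1], q.shape[1] - dc)
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        np.add.at(mat, (a, b), 1.0)
    if config.symmetric:
        mat = mat + mat.T
    if config.normalize:
        mat /= mat.sum()
    return mat


def descriptors(p: np.ndarray, log_base: str = "e") -> GLCMDescriptors:
    """The five Haralick descriptors of a normalised GLCM.

    Correlation is reported as None (undefined) for a single-valued
    image, where the marginal standard deviations vanish.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValidationError("GLCM must be square")
    if not math.isclose(p.sum(), 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValidationError("GLCM must be normalised to sum 1")
    L = p.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    asm = float((p**2).sum())
    nz = p[p > 0]
    log = np.log2 if log_base == "2" else np.log
    entropy = float(-(nz * log(nz)).sum()) + 0.0  # avoid -0.0
    contrast = float(((i - j) ** 2 * p).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((np.arange(L) * pi).sum())
    mu_j = float((np.arange(L) * pj).sum())
    var_i = float(((np.arange(L) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(L) - mu_j) ** 2 * pj).sum())
    if var_i <= 0 or var_j <= 0:
        corr: float | None = None
    else:
        corr = float(((i - mu_i) * (j - mu_j) * p).sum() / math.sqrt(var_i * var_j))
    return GLCMDescriptors(asm=asm, entropy=entropy, contrast=contrast, idm=idm, correlation=corr)


def image_descriptors(
    m: Micrograph | np.ndarray,
    config: GLCMConfig = GLCMConfig(),
    bit_depth: int | None = None,
) -> GLCMDescriptors:
    """Quantise → GLCM → descriptors for a whole image."""
    q = quantize(m, config.levels, bit_depth=bit_depth)
    return descriptors(glcm(q, config))


def texture_map(
    m: Micrograph,
    window_px: int,
    stride: int,
    config: GLCMConfig = GLCMConfig(),
) -> dict[str, np.ndarray]:
    """Sliding-window descriptor rasters, one per descriptor.

    The image is quantised once (full bit-depth binning), then each
    window contributes one value per descriptor at its grid position —
    feature maps suitable for downstream texture classification.
    Undefined correlations (flat windows) appear as NaN in the
    correlation map.
    """
    if window_px < 3:
        raise ValidationError("window must be >= 3 px")
    nrows, ncols = m.shape
    if window_px > min(nrows, ncols):
        raise ValidationError("window exceeds image size")
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    q = quantize(m, config.levels)
    r_starts = range(0, nrows - window_px + 1, stride)
    c_starts = range(0, ncols - window_px + 1, stride)
    maps = {
        name: np.full((len(r_starts), len(c_starts)), np.nan)
        for name in ("asm", "entropy", "contrast", "correlation", "idm")
    }
    for wi, r in enumerate(r_starts):
        for wj, c in enumerate(c_starts):
            d = descriptors(glcm(q[r : r + window_px, c : c + window_px], config))
            for name, value in d.as_dict().items():
                maps[name][wi, wj] = np.nan if value is None else value
    return maps
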
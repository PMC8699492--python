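"""Micrograph input/output and pixel-size calibration.

SEM images arrive as 8- or 16-bit grayscale rasters with no standard
embedded scale, so the physical pixel edge length (µm/pixel) is supplied
by the caller and carried on the :class:`Micrograph` through every
downstream measurement.  All physical quantities produced by the package
(lengths in µm, areas in µm², volumes in µm³) derive from this single
calibration value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import InputError, ValidationError

__all__ = [
    "Micrograph",
    "ResultTable",
    "load_micrograph",
    "save_micrograph",
    "write_results",
    "read_results",
    "DESCRIPTOR_UNITS",
]

#: Canonical descriptor vocabulary -> unit. Every row written by
#: :func:`write_results` must use one of these names.
DESCRIPTOR_UNITS: dict[str, str] = {
    "length": "um",
    "width": "um",
    "aspect_ratio": "",
    "projected_area": "um2",
    "volume": "um3",
    "surface": "um2",
    "sv_ratio": "per_um",
    "soma_diameter": "um",
    "neurite_count": "",
    "avg_neurite_length": "um",
    "max_neurite_length": "um",
    "radial_distance": "um",
    "straightness": "um",
    "tortuosity": "",
    "chord_angle": "deg",
    "alignment_class": "",
    "area": "um2",
    "perimeter": "um",
    "circularity": "",
    "is_differentiated": "",
    "n_parallel": "",
    "n_intermediate": "",
    "n_perpendicular": "",
    "fractal_dimension": "",
    "fit_r2": "",
    "box_size": "px",
    "box_count": "",
    "lacunarity": "",
    "mean_lacunarity": "",
    "asm": "",
    "entropy": "",
    "contrast": "",
    "correlation": "",
    "idm": "",
}


@dataclass
class Micrograph:
    """A calibrated single-channel raster.

    Parameters
    ----------
    pixels : ndarray
        Non-negative intensities, shape (rows, cols).
    bit_depth : int
        8 or 16; intensities must lie in [0, 2**bit_depth - 1].
    pixel_size_um : float
        Physical edge length of one pixel in micrometres (> 0).
    source_id : str
        Free-text provenance label.
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_size_um: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("micrograph raster must be 2-D and non-empty")
        if self.bit_depth not in (8, 16):
            raise ValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not (self.pixel_size_um > 0):
            raise ValidationError(
                f"pixel_size_um must be positive, got {self.pixel_size_um}"
            )
        lo, hi = self.pixels.min(), self.pixels.max()
        if lo < 0 or hi > 2**self.bit_depth - 1:
            raise ValidationError(
                f"intensities [{lo}, {hi}] exceed {self.bit_depth}-bit range"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def load_micrograph(path, pixel_size_um: float, source_id: str | None = None) -> Micrograph:
    """Read a TIFF/PNG micrograph and attach a µm/pixel calibration.

    Multi-channel inputs are reduced to grayscale by the unweighted channel
    mean (SEM signal is physically single-channel; colour is incidental) and
    a warning is emitted.
    """
    path = Path(path)
    if not (pixel_size_um > 0):
        raise ValidationError(f"pixel_size_um must be positive, got {pixel_size_um}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # decoder backends raise heterogeneous errors
        raise InputError(f"cannot read micrograph {path}: {exc}") from exc
    if arr.ndim == 3:
        warnings.warn(
            f"{path.name}: multi-channel input reduced by channel mean",
            stacklevel=2,
        )
        arr = arr.astype(np.float64).mean(axis=-1)
        arr = np.round(arr)
    if arr.ndim != 2:
        raise InputError(f"{path}: expected a 2-D raster, got shape {arr.shape}")
    bit_depth = 16 if arr.max(initial=0) > 255 or arr.dtype.itemsize > 1 else 8
    dtype = np.uint16 if bit_depth == 16 else np.uint8
    return Micrograph(
        pixels=arr.astype(dtype),
        bit_depth=bit_depth,
        pixel_size_um=float(pixel_size_um),
        source_id=source_id if source_id is not None else path.name,
    )


def save_micrograph(m: Micrograph, path) -> None:
    """Write the raster to TIFF or PNG (by extension), intensities unmodified."""
    path = Path(path)
    dtype = np.uint16 if m.bit_depth == 16 else np.uint8
    arr = m.pixels.astype(dtype)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


@dataclass
class ResultTable:
    """Long-format measurement records: one row per (cell, descriptor)."""

    rows: list[dict] = field(default_factory=list)

    def add(self, source_id: str, cell_id, descriptor: str, value, unit: str | None = None) -> None:
        if descriptor not in DESCRIPTOR_UNITS:
            raise ValidationError(f"unknown descriptor name {descriptor!r}")
        if unit is None:
            unit = DESCRIPTOR_UNITS[descriptor]
        self.rows.append(
            {
                "source_id": source_id,
                "cell_id": cell_id,
                "descriptor": descriptor,
                "value": value,
                "unit": unit,
            }
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["source_id", "cell_id", "descriptor", "value", "unit"]
        )

    def __len__(self) -> int:
        return len(self.rows)


def write_results(table: ResultTable, path) -> None:
    """Write a ResultTable as UTF-8 CSV, values at 12 significant digits."""
    if len(table) == 0:
        raise ValidationError("refusing to write an empty result table")
    df = table.to_dataframe()
    df.to_csv(path, index=False, float_format="%.12g")


def read_results(path) -> ResultTable:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    return ResultTable(rows=df.to_dict("records"))
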
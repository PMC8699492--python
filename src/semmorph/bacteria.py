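"""Rod-shaped bacterial morphometry.

A rod-shaped bacterium projected in an SEM image is modelled as a
spherocylinder: a cylinder of width W capped by two hemispheres, total
length L (caps included).  From the length and width of a cell the
standard model volume is

    V = (pi * W**2 / 4) * (L - W / 3)

which reduces to the sphere volume pi*d**3/6 when L = W.  The model
surface is S = pi * W * L (cylinder side pi*W*(L - W) plus the two caps
pi*W**2), giving the surface-to-volume ratio S/V that bacteria are known
to regulate.  Aspect ratio is W/L: 1 for cocci, about 0.25 for E. coli.

Length and width are estimated from the silhouette's medial axis: length
as the longest geodesic path through the skeleton extended at each end by
the local medial radius, width as twice the mean distance-transform value
along that path.  This is orientation-independent and follows curved
rods, unlike bounding-box Feret diameters (which are emitted as an
optional cross-check).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.morphology import medial_axis

from . import _skeleton
from .errors import MeasurementError, SemmorphError, ValidationError
from .io import ResultTable
from .segmentation import CellInstance

__all__ = [
    "BacterialMorphometry",
    "measure_rod",
    "aspect_ratio",
    "rod_volume",
    "rod_surface",
    "measure_population",
    "MIN_MEASURABLE_PX",
]

#: Below this pixel count the distance-transform width estimate has more
#: than ~10% quantisation error; smaller instances are rejected.
MIN_MEASURABLE_PX = 25

#: The Euclidean distance transform measures centre-to-centre distances,
#: overestimating the half-width of a rasterised solid by half a pixel on
#: each side; radii sampled from it are corrected by this amount.
_EDT_CENTER_OFFSET_PX = 0.5


@dataclass
class BacterialMorphometry:
    """Per-cell rod metrics, all in physical units."""

    cell_id: int
    length_um: float
    width_um: float
    aspect_ratio: float
    projected_area_um2: float
    volume_um3: float
    surface_um2: float
    sv_ratio_per_um: float
    feret_length_um: float | None = None


def rod_volume(length_um: float, width_um: float) -> float:
    """Spherocylinder volume V = (pi W^2 / 4)(L - W/3), in µm³."""
    _check_rod(length_um, width_um)
    return (math.pi * width_um**2 / 4.0) * (length_um - width_um / 3.0)


def rod_surface(length_um: float, width_um: float) -> float:
    """Spherocylinder surface S = pi W L, in µm²."""
    _check_rod(length_um, width_um)
    return math.pi * width_um * length_um


def _check_rod(length_um: float, width_um: float) -> None:
    if not (width_um > 0 and length_um > 0):
        raise ValidationError("length and width must be positive")
    if width_um > length_um:
        raise ValidationError(
            f"width {width_um} exceeds length {length_um}: spherocylinder model "
            "assumes a rod (W <= L)"
        )


def aspect_ratio(width_um: float, length_um: float) -> float:
    """Width-to-length ratio W/L in (0, 1]; 1 for circular silhouettes.

    Measurement noise can make W marginally exceed L on near-circular
    cells; the ratio is then clipped to 1 with a warning.
    """
    if not (width_um > 0 and length_um > 0):
        raise ValidationError("width and length must be positive")
    ratio = width_um / length_um
    if ratio > 1.0:
        if ratio > 1.1:
            raise ValidationError(
                f"W/L = {ratio:.3f}: width exceeds length by more than "
                "measurement noise can explain"
            )
        warnings.warn(
            f"W/L = {ratio:.3f} > 1 clipped to 1 (measurement noise)", stacklevel=2
        )
        ratio = 1.0
    return ratio


def measure_rod(
    cell: CellInstance,
    pixel_size_um: float | None = None,
    min_pixels: int = MIN_MEASURABLE_PX,
) -> tuple[float, float, float]:
    """Estimate (length_um, width_um, projected_area_um2) of one cell.

    Length is the longest medial-axis geodesic extended at both ends by
    the local medial radius; width is twice the mean medial radius along
    that path; projected area is the pixel count times the pixel area.
    """
    s = pixel_size_um if pixel_size_um is not None else cell.pixel_size_um
    if not (s > 0):
        raise ValidationError("pixel_size_um must be positive")
    if cell.n_pixels < min_pixels:
        raise MeasurementError(
            f"cell {cell.cell_id}: {cell.n_pixels} px < minimum {min_pixels} px "
            "for reliable width estimation"
        )
    mask, _ = cell.local_mask(pad=1)
    # fixed rng: medial_axis breaks thinning ties randomly by default,
    # which would make repeated measurements non-deterministic
    skel, dist = medial_axis(mask, return_distance=True, rng=0)
    if skel.sum() < 2:
        raise MeasurementError(
            f"cell {cell.cell_id}: medial axis degenerate ({int(skel.sum())} px)"
        )
    coords, graph = _skeleton.skeleton_graph(skel)
    path, _chain = _skeleton.longest_geodesic(coords, graph)
    radii = dist[path[:, 0], path[:, 1]] - _EDT_CENTER_OFFSET_PX
    radii = np.clip(radii, 0.5, None)
    body_px = _skeleton.polyline_length(path)
    length_px = body_px + radii[0] + radii[-1]
    # Width = 2 x mean medial radius over the cylindrical trunk of the
    # path.  Pixels closer to either path end than their own radius sit
    # inside the hemispherical end caps, where the medial radius tapers;
    # they are excluded.  A near-circular cell is all cap — then the
    # maximal inscribed radius is the width (and the length).
    steps = np.hypot(*(np.diff(path, axis=0).T)) if len(path) > 1 else np.array([])
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    margin = 2.0  # px; absorbs the ~1 px rasterisation slack of the cap radii
    trunk = (arc >= radii + margin) & (arc[-1] - arc >= radii + margin)
    if trunk.any():
        width_px = 2.0 * float(radii[trunk].mean())
    else:
        width_px = 2.0 * float(dist.max() - _EDT_CENTER_OFFSET_PX)
    length_um = length_px * s
    width_um = width_px * s
    if width_um > length_um:  # near-circular cell: skeleton collapses to a point-ish path
        length_um = width_um
    area_um2 = cell.n_pixels * s * s
    return length_um, width_um, area_um2


def measure_cell(cell: CellInstance, pixel_size_um: float | None = None) -> BacterialMorphometry:
    """Full rod metric set for one cell (length, width, ratio, V, S, S/V)."""
    length_um, width_um, area_um2 = measure_rod(cell, pixel_size_um)
    ar = aspect_ratio(width_um, length_um)
    width_eff = min(width_um, length_um)
    vol = rod_volume(length_um, width_eff)
    surf = rod_surface(length_um, width_eff)
    ext = cell.coords.max(axis=0) - cell.coords.min(axis=0) + 1
    s = pixel_size_um if pixel_size_um is not None else cell.pixel_size_um
    feret = float(np.hypot(*ext)) * s  # bounding-box diagonal, crude upper bound
    return BacterialMorphometry(
        cell_id=cell.cell_id,
        length_um=length_um,
        width_um=width_um,
        aspect_ratio=ar,
        projected_area_um2=area_um2,
        volume_um3=vol,
        surface_um2=surf,
        sv_ratio_per_um=surf / vol,
        feret_length_um=feret,
    )


_FIELDS = [
    ("length", "length_um"),
    ("width", "width_um"),
    ("aspect_ratio", "aspect_ratio"),
    ("projected_area", "projected_area_um2"),
    ("volume", "volume_um3"),
    ("surface", "surface_um2"),
    ("sv_ratio", "sv_ratio_per_um"),
]


def measure_population(
    cells: list[CellInstance],
    pixel_size_um: float | None = None,
    source_id: str = "",
) -> tuple[ResultTable, dict]:
    """Measure every cell; return per-cell rows plus a population summary.

    Cells failing a measurement precondition are reported in
    ``summary['failures']`` with the diagnostic and excluded from the
    mean/sd statistics.
    """
    table = ResultTable()
    measured: list[BacterialMorphometry] = []
    failures: list[tuple[int, str]] = []
    for cell in cells:
        try:
            m = measure_cell(cell, pixel_size_um)
        except SemmorphError as exc:
            failures.append((cell.cell_id, str(exc)))
            continue
        measured.append(m)
        for name, attr in _FIELDS:
            table.add(source_id, m.cell_id, name, getattr(m, attr))
    if not measured:
        raise MeasurementError(
            "no measurable cells in population "
            f"({len(failures)} failed preconditions)"
        )
    summary: dict = {"n": len(measured), "failures": failures}
    for name, attr in _FIELDS:
        vals = np.array([getattr(m, attr) for m in measured], dtype=float)
        summary[name] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        }
    return table, summary
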
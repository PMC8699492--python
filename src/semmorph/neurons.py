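"""Neuron-like cell morphometry: soma, neurites, shape descriptors.

The descriptors quantify neural-cell silhouettes segmented from SEM
micrographs — typically neuroblastoma cells on biomaterial substrates,
where neurite outgrowth and alignment to topographic cues report on the
material's biological performance:

* **soma** — the cell body, operationalised as the maximal inscribed
  disc of the silhouette (centre at the distance-transform argmax).
* **neurites** — processes exiting the cell body; the silhouette is
  skeletonised, the soma disc removed, and each remaining soma-anchored
  skeleton subtree becomes one trace whose path is the longest geodesic
  branch from its anchor to a skeleton endpoint.
* per-trace **length**, **radial distance** (straight-line base-to-tip)
  and **straightness** (length minus radial distance, >= 0 by the
  triangle inequality); a dimensionless tortuosity (length/radial) is
  additionally emitted as an extension.
* **alignment** of the tip-to-base chord relative to a reference axis,
  folded into [0°, 90°] and classified as parallel (< 15°),
  perpendicular (> 75°) or intermediate (the unnamed middle band).
* whole-cell **area** A (pixel count x pixel area), **perimeter** P and
  **circularity** C = 4 pi A / P², which is 1 for a disc and decreases
  with boundary irregularity.
* a cell is **differentiated** when at least one neurite is at least as
  long as the soma diameter.

Angles live in the raster frame: x = column, y = row (downward),
reference axis in degrees from the x-axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure as _skmeasure
from skimage.morphology import skeletonize

from . import _skeleton
from .errors import MeasurementError, ValidationError
from .io import ResultTable
from .segmentation import CellInstance

__all__ = [
    "NeuriteTrace",
    "NeuronMorphometry",
    "identify_soma",
    "extract_neurites",
    "neurite_stats",
    "radial_and_straightness",
    "alignment_angle",
    "classify_alignment",
    "area_perimeter_circularity",
    "count_differentiated",
    "analyze_neuron",
]

#: Discretisation allowance on circularity: rasterised discs may land
#: marginally above 1 with sub-pixel perimeter estimators.
EPSILON_RASTER = 0.05


@dataclass
class NeuriteTrace:
    neurite_id: int
    path: np.ndarray  # (n, 2) pixel coordinates, base -> tip
    length_um: float
    radial_distance_um: float
    straightness_um: float
    chord_angle_deg: float
    alignment_class: str
    tortuosity: float  # length / radial distance; 1 for a straight neurite


@dataclass
class NeuronMorphometry:
    cell_id: int
    soma_center: tuple[float, float]
    soma_diameter_um: float
    neurites: list[NeuriteTrace] = field(default_factory=list)
    cell_area_um2: float = 0.0
    perimeter_um: float = 0.0
    circularity: float = 0.0
    reference_axis_deg: float = 0.0

    @property
    def neurite_count(self) -> int:
        return len(self.neurites)

    @property
    def avg_neurite_length_um(self) -> float | None:
        if not self.neurites:
            return None
        return float(np.mean([t.length_um for t in self.neurites]))

    @property
    def max_neurite_length_um(self) -> float | None:
        if not self.neurites:
            return None
        return float(max(t.length_um for t in self.neurites))

    @property
    def is_differentiated(self) -> bool:
        m = self.max_neurite_length_um
        return m is not None and m >= self.soma_diameter_um

    def alignment_counts(self) -> dict[str, int]:
        counts = {"parallel": 0, "intermediate": 0, "perpendicular": 0}
        for t in self.neurites:
            counts[t.alignment_class] += 1
        return counts


def identify_soma(
    cell: CellInstance, pixel_size_um: float | None = None
) -> tuple[tuple[float, float], float, np.ndarray]:
    """Locate the cell body as the maximal inscribed disc.

    Returns (soma_center in global (row, col), soma_diameter_um,
    soma_mask in the cell's padded local frame).  Ties in the distance
    transform break deterministically to the lowest (row, col).
    """
    s = pixel_size_um if pixel_size_um is not None else cell.pixel_size_um
    mask, origin = cell.local_mask(pad=1)
    dist = ndimage.distance_transform_edt(mask)
    dmax = dist.max()
    if dmax <= 0:
        raise MeasurementError(f"cell {cell.cell_id}: empty silhouette")
    peaks = np.argwhere(dist == dmax)
    if len(peaks) > 1:
        warnings.warn(
            f"cell {cell.cell_id}: {len(peaks)} equal inscribed-disc centres; "
            "using lowest (row, col)",
            stacklevel=2,
        )
    center_local = peaks[0]  # argwhere is row-major sorted: deterministic
    rr, cc = np.ogrid[: mask.shape[0], : mask.shape[1]]
    soma_mask = (rr - center_local[0]) ** 2 + (cc - center_local[1]) ** 2 <= dmax**2
    soma_mask &= mask
    center_global = (
        float(center_local[0] + origin[0]),
        float(center_local[1] + origin[1]),
    )
    return center_global, 2.0 * float(dmax) * s, soma_mask


def extract_neurites(
    cell: CellInstance,
    soma_mask: np.ndarray,
    pixel_size_um: float | None = None,
    min_neurite_um: float | None = None,
    reference_axis_deg: float = 0.0,
) -> list[NeuriteTrace]:
    """Trace neurites as soma-anchored skeleton subtrees.

    The silhouette is skeletonised; skeleton pixels inside the soma disc
    are removed; each remaining connected component adjacent to the soma
    becomes one neurite whose path runs from its anchor (the component
    pixel touching the soma) to the farthest skeleton endpoint.  For a
    round-capped process the medial axis terminates at the cap centre,
    so the geodesic length matches the centreline length of the neurite.
    Traces shorter than ``min_neurite_um`` (default 5 pixels) are
    discarded as skeleton spurs.
    """
    s = pixel_size_um if pixel_size_um is not None else cell.pixel_size_um
    if min_neurite_um is None:
        min_neurite_um = 5.0 * s
    mask, _ = cell.local_mask(pad=1)
    skel = skeletonize(mask)
    dist = ndimage.distance_transform_edt(mask)
    outside = skel & ~soma_mask
    if not outside.any():
        return []
    soma_halo = ndimage.binary_dilation(soma_mask, structure=np.ones((3, 3)))
    lab, n_comp = ndimage.label(outside, structure=np.ones((3, 3)))
    traces: list[NeuriteTrace] = []
    nid = 0
    for comp_id in range(1, n_comp + 1):
        comp = lab == comp_id
        anchors = np.argwhere(comp & soma_halo)
        if len(anchors) == 0:
            continue  # disconnected spur, not exiting the cell body
        coords, graph = _skeleton.skeleton_graph(comp)
        # anchor = touching pixel closest to the soma (lowest distance value),
        # ties broken lexicographically by argwhere order
        key = dist[anchors[:, 0], anchors[:, 1]]
        a = anchors[int(np.argmin(key))]
        a_idx = int(np.flatnonzero((coords == a).all(axis=1))[0])
        path, _chain = _skeleton.longest_geodesic(coords, graph, anchor=a_idx)
        length_um = _skeleton.polyline_length(path) * s
        if length_um < min_neurite_um:
            continue
        nid += 1
        radial_um, straight_um = radial_and_straightness(path, s, length_um=length_um)
        angle = alignment_angle(path, reference_axis_deg)
        traces.append(
            NeuriteTrace(
                neurite_id=nid,
                path=path,
                length_um=length_um,
                radial_distance_um=radial_um,
                straightness_um=straight_um,
                chord_angle_deg=angle,
                alignment_class=classify_alignment(angle),
                tortuosity=length_um / radial_um if radial_um > 0 else math.inf,
            )
        )
    return traces


def neurite_stats(traces: list[NeuriteTrace]) -> tuple[int, float | None, float | None]:
    """(count, average length, maximum length); lengths are None when count is 0."""
    if not traces:
        return 0, None, None
    lengths = [t.length_um for t in traces]
    return len(traces), float(np.mean(lengths)), float(max(lengths))


def radial_and_straightness(
    path: np.ndarray, pixel_size_um: float, length_um: float | None = None
) -> tuple[float, float]:
    """Radial distance (straight base-to-tip line) and straightness
    (path length minus radial distance, clipped at 0)."""
    path = np.asarray(path, dtype=float)
    if len(path) < 2:
        raise ValidationError("trace needs at least 2 points")
    if length_um is None:
        length_um = _skeleton.polyline_length(path) * pixel_size_um
    radial_um = float(np.hypot(*(path[-1] - path[0]))) * pixel_size_um
    return radial_um, max(length_um - radial_um, 0.0)


def alignment_angle(path: np.ndarray, reference_axis_deg: float = 0.0) -> float:
    """Acute angle in [0°, 90°] between the tip-base chord and the
    reference axis (degrees from the image x-axis = column direction)."""
    path = np.asarray(path, dtype=float)
    if len(path) < 2:
        raise ValidationError("trace needs at least 2 points")
    dr = path[-1, 0] - path[0, 0]
    dc = path[-1, 1] - path[0, 1]
    if dr == 0 and dc == 0:
        raise ValidationError("zero-length chord: angle undefined")
    chord_deg = math.degrees(math.atan2(dr, dc))
    rel = chord_deg - reference_axis_deg
    return abs(((rel + 90.0) % 180.0) - 90.0)


def classify_alignment(chord_angle_deg: float) -> str:
    """parallel (< 15°), perpendicular (> 75°), else intermediate.

    The boundary angles 15° and 75° themselves are intermediate: the
    defining inequalities are strict.
    """
    if not (0.0 <= chord_angle_deg <= 90.0):
        raise ValidationError(f"angle {chord_angle_deg} outside [0, 90]")
    if chord_angle_deg < 15.0:
        return "parallel"
    if chord_angle_deg > 75.0:
        return "perpendicular"
    return "intermediate"


def _perimeter_px(mask: np.ndarray, method: str) -> float:
    if method == "crofton":
        return float(_skmeasure.perimeter_crofton(mask, directions=4))
    if method == "chain":
        # ordered marching-squares contours: axis steps 1, diagonal sqrt(2)/2 pairs
        total = 0.0
        for contour in _skmeasure.find_contours(mask.astype(float), 0.5):
            total += float(
                np.sqrt((np.diff(contour, axis=0) ** 2).sum(axis=1)).sum()
            )
        return total
    if method == "pixel_count":
        eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3)))
        return float((mask & ~eroded).sum())
    raise ValidationError(f"unknown perimeter method {method!r}")


def area_perimeter_circularity(
    cell: CellInstance,
    pixel_size_um: float | None = None,
    perimeter_method: str = "crofton",
) -> tuple[float, float, float]:
    """Cell area A, perimeter P and circularity C = 4 pi A / P².

    ``perimeter_method``:

    * ``"crofton"`` (default) — Crofton-formula estimator (4 directions),
      sub-percent bias on smooth shapes, so a rasterised disc calibrates
      to C = 1 as a round cell should;
    * ``"chain"`` — contour-following with sqrt(2)-weighted diagonal
      steps (overestimates smooth perimeters by ~5%, giving discs
      C ≈ 0.9);
    * ``"pixel_count"`` — literal boundary-pixel count.
    """
    s = pixel_size_um if pixel_size_um is not None else cell.pixel_size_um
    mask, _ = cell.local_mask(pad=1)
    area = cell.n_pixels * s * s
    per = _perimeter_px(mask, perimeter_method) * s
    if per <= 0:
        raise MeasurementError(f"cell {cell.cell_id}: degenerate outline")
    return area, per, circularity_from_area_perimeter(area, per)


def circularity_from_area_perimeter(area: float, perimeter: float) -> float:
    """C = 4 pi A / P² — 1 for a disc, lower for irregular outlines."""
    if not (area > 0 and perimeter > 0):
        raise ValidationError("area and perimeter must be positive")
    return 4.0 * math.pi * area / perimeter**2


def count_differentiated(cells: list[NeuronMorphometry]) -> int:
    """Cells with at least one neurite as long as the soma diameter."""
    return sum(1 for c in cells if c.is_differentiated)


def analyze_neuron(
    cell: CellInstance,
    pixel_size_um: float | None = None,
    reference_axis_deg: float = 0.0,
    min_neurite_um: float | None = None,
    perimeter_method: str = "crofton",
) -> NeuronMorphometry:
    """Full descriptor set for one neuron-like silhouette."""
    s = pixel_size_um if pixel_size_um is not None else cell.pixel_size_um
    center, soma_diam, soma_mask = identify_soma(cell, s)
    traces = extract_neurites(
        cell,
        soma_mask,
        pixel_size_um=s,
        min_neurite_um=min_neurite_um,
        reference_axis_deg=reference_axis_deg,
    )
    area, per, circ = area_perimeter_circularity(cell, s, perimeter_method)
    return NeuronMorphometry(
        cell_id=cell.cell_id,
        soma_center=center,
        soma_diameter_um=soma_diam,
        neurites=traces,
        cell_area_um2=area,
        perimeter_um=per,
        circularity=circ,
        reference_axis_deg=reference_axis_deg,
    )


def population_table(
    neurons: list[NeuronMorphometry], source_id: str = ""
) -> ResultTable:
    """Long-format result rows for a field of analysed neurons."""
    table = ResultTable()
    for n in neurons:
        table.add(source_id, n.cell_id, "soma_diameter", n.soma_diameter_um)
        table.add(source_id, n.cell_id, "neurite_count", n.neurite_count)
        if n.neurite_count:
            table.add(source_id, n.cell_id, "avg_neurite_length", n.avg_neurite_length_um)
            table.add(source_id, n.cell_id, "max_neurite_length", n.max_neurite_length_um)
        table.add(source_id, n.cell_id, "area", n.cell_area_um2)
        table.add(source_id, n.cell_id, "perimeter", n.perimeter_um)
        table.add(source_id, n.cell_id, "circularity", n.circularity)
        counts = n.alignment_counts()
        table.add(source_id, n.cell_id, "n_parallel", counts["parallel"])
        table.add(source_id, n.cell_id, "n_intermediate", counts["intermediate"])
        table.add(source_id, n.cell_id, "n_perpendicular", counts["perpendicular"])
        table.add(source_id, n.cell_id, "is_differentiated", int(n.is_differentiated))
    return table
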
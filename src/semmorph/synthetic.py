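"""Seeded synthetic micrographs with exact ground truth.

Every generator returns the image (and/or mask) together with a
:class:`GroundTruth` record of the parameters actually rasterised, so
each measurement module can be validated end-to-end without any external
micrograph.  Generation is a pure function of (parameters, seed): the
same call reproduces the same rasters bit for bit.

The defaults emulate the imaging regimes the measurement modules are
meant for: rod fields use 0.02 µm/px (sub-µm bacterial rods, ≥ 10 px
across the thinnest cell), neuron fields 0.2 µm/px (tens-of-µm somata
and neurites).  Foreground/background intensities (180 on 20, 8-bit)
mimic bright secondary-electron emission of cells on a darker substrate;
optional additive Gaussian noise stands in for detector shot noise.
Charging artefacts and topographic shading are not simulated — the
fixtures test geometry and statistics, not SEM rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import CapacityError, ValidationError
from .io import Micrograph
from .segmentation import BinaryMask

__all__ = [
    "GroundTruth",
    "gen_rod_population",
    "gen_neuron",
    "gen_fractal",
    "gen_texture",
    "ECOLI_PRESET",
]

FOREGROUND = 180
BACKGROUND = 20

#: E. coli-like rod field: lengths uniform on 2–4 µm, constant aspect
#: ratio W/L = 0.25, isotropic orientation, 0.02 µm/px.
ECOLI_PRESET = {
    "length_dist": ("uniform", 2.0, 4.0),
    "aspect": 0.25,
    "orientation": ("uniform", 0.0, 180.0),
    "pixel_size_um": 0.02,
}


@dataclass
class GroundTruth:
    kind: str
    pixel_size_um: float
    seed: int | None
    records: list[dict] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def _sample(dist, rng: np.random.Generator, size: int) -> np.ndarray:
    """Distribution spec: scalar constant, ('uniform', lo, hi) or ('normal', mu, sd)."""
    if np.isscalar(dist):
        return np.full(size, float(dist))
    name, a, b = dist
    if name == "uniform":
        return rng.uniform(a, b, size)
    if name == "normal":
        return rng.normal(a, b, size)
    raise ValidationError(f"unknown distribution {name!r}")


def _rasterize_rod(L_px: float, W_px: float, theta_deg: float) -> np.ndarray:
    """Boolean stamp of a spherocylinder: pixels within W/2 of the axis
    segment; L is the total length, hemispherical caps included."""
    half_axis = max((L_px - W_px) / 2.0, 0.0)
    r = W_px / 2.0
    theta = math.radians(theta_deg)
    ux, uy = math.cos(theta), math.sin(theta)
    half_w = int(math.ceil(half_axis * max(abs(ux), abs(uy)) + r)) + 2
    n = 2 * half_w + 1
    yy, xx = np.mgrid[-half_w : half_w + 1, -half_w : half_w + 1]
    # distance from pixel centre to the axis segment
    t = np.clip(xx * ux + yy * uy, -half_axis, half_axis)
    d2 = (xx - t * ux) ** 2 + (yy - t * uy) ** 2
    stamp = d2 <= r * r
    rows = np.any(stamp, axis=1)
    cols = np.any(stamp, axis=0)
    return stamp[rows][:, cols]


def _render(mask: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    img = np.where(mask, float(FOREGROUND), float(BACKGROUND))
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, mask.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def gen_rod_population(
    n: int,
    length_dist=("uniform", 2.0, 4.0),
    aspect: float = 0.25,
    orientation=("uniform", 0.0, 180.0),
    pixel_size_um: float = 0.02,
    image_size: int | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    max_attempts: int = 300,
) -> tuple[Micrograph, BinaryMask, GroundTruth]:
    """A field of ``n`` non-overlapping spherocylindrical rods.

    Rods are placed by rejection sampling with a 2-px separation margin
    (so 8-connected labelling keeps them distinct) and never touch the
    border.  Raises :class:`CapacityError` when the field cannot fit
    ``n`` rods within ``max_attempts`` tries each.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not (0 < aspect <= 1):
        raise ValidationError("aspect ratio must be in (0, 1]")
    rng = np.random.default_rng(seed)
    lengths = _sample(length_dist, rng, n)
    if (lengths <= 0).any():
        raise ValidationError("sampled lengths must be positive")
    widths = lengths * aspect
    thetas = _sample(orientation, rng, n) % 180.0
    max_l_px = float(lengths.max()) / pixel_size_um
    if image_size is None:
        mean_area = float((lengths * widths).mean()) / pixel_size_um**2
        image_size = int(math.ceil(math.sqrt(8.0 * n * mean_area) + max_l_px))
    canvas = np.zeros((image_size, image_size), dtype=bool)
    margin = 3
    records = []
    for k in range(n):
        stamp = _rasterize_rod(lengths[k] / pixel_size_um, widths[k] / pixel_size_um, thetas[k])
        h, w = stamp.shape
        if h + 2 * margin >= image_size or w + 2 * margin >= image_size:
            raise CapacityError(f"rod {k} ({h}x{w} px) does not fit the field")
        # overlap probe: the stamp grown by the separation margin
        grown = np.zeros((h + 4, w + 4), dtype=bool)
        grown[2:-2, 2:-2] = stamp
        grown = ndimage.binary_dilation(grown, iterations=2)
        placed = False
        for _ in range(max_attempts):
            r0 = int(rng.integers(margin, image_size - h - margin))
            c0 = int(rng.integers(margin, image_size - w - margin))
            window = canvas[r0 - 2 : r0 + h + 2, c0 - 2 : c0 + w + 2]
            if (window & grown).any():
                continue
            canvas[r0 : r0 + h, c0 : c0 + w] |= stamp
            records.append(
                {
                    "object_id": k,
                    "kind": "rod",
                    "length_um": float(lengths[k]),
                    "width_um": float(widths[k]),
                    "aspect_ratio": float(aspect),
                    "orientation_deg": float(thetas[k]),
                    "pixel_count": int(stamp.sum()),
                    "row0": r0,
                    "col0": c0,
                }
            )
            placed = True
            break
        if not placed:
            raise CapacityError(
                f"could not place rod {k} of {n} after {max_attempts} attempts; "
                "enlarge image_size or reduce n"
            )
    truth = GroundTruth(
        kind="rod",
        pixel_size_um=pixel_size_um,
        seed=seed,
        records=records,
        params={
            "n": n,
            "length_dist": length_dist,
            "aspect": aspect,
            "orientation": orientation,
            "noise_sd": noise_sd,
            "image_size": image_size,
        },
    )
    img = Micrograph(
        pixels=_render(canvas, noise_sd, rng),
        bit_depth=8,
        pixel_size_um=pixel_size_um,
        source_id=f"synthetic-rods-seed{seed}",
    )
    mask = BinaryMask(
        pixels=canvas,
        pixel_size_um=pixel_size_um,
        method_record={"method": "synthetic", "seed": seed},
    )
    return img, mask, truth


def _arm_centerline(
    center: np.ndarray,
    soma_r_px: float,
    length_px: float,
    angle_deg: float,
    tortuosity_px: float,
    step: float = 0.25,
) -> np.ndarray:
    """Dense (row, col) polyline from the soma boundary outward.

    A tortuous arm is the straight ray perturbed perpendicularly by a
    sinusoid of amplitude ``tortuosity_px`` (three periods per arm).
    """
    theta = math.radians(angle_deg)
    u = np.array([math.sin(theta), math.cos(theta)])  # (row, col): row = y downward
    v = np.array([-u[1], u[0]])
    t = np.arange(0.0, length_px + step, step)
    t = np.minimum(t, length_px)
    offset = (
        tortuosity_px * np.sin(2.0 * math.pi * 3.0 * t / length_px)
        if tortuosity_px > 0
        else np.zeros_like(t)
    )
    return center + np.outer(soma_r_px + t, u) + np.outer(offset, v)


def _polyline_arclength(points: np.ndarray) -> float:
    return float(np.sqrt((np.diff(points, axis=0) ** 2).sum(axis=1)).sum())


def gen_neuron(
    soma_radius_um: float = 6.0,
    arms: list[tuple[float, float, float]] = (),
    arm_width_um: float = 2.0,
    pixel_size_um: float = 0.2,
    noise_sd: float = 0.0,
    seed: int = 0,
    canvas_px: int | None = None,
    center_px: tuple[int, int] | None = None,
    _canvas: np.ndarray | None = None,
) -> tuple[Micrograph, BinaryMask, GroundTruth]:
    """A neuron-like silhouette: soma disc plus thick-polyline arms.

    ``arms`` lists (length_um, angle_deg, tortuosity_um) per neurite;
    tortuosity 0 draws a straight arm, > 0 a sinusoidal one of that
    perpendicular amplitude.  Ground truth records each arm's drawn
    centreline arc length and its base-to-tip chord angle folded into
    [0°, 90°].  Arms that would overlap one another raise
    :class:`ValidationError`.
    """
    if soma_radius_um <= 0 or arm_width_um <= 0:
        raise ValidationError("soma radius and arm width must be positive")
    rng = np.random.default_rng(seed)
    s = pixel_size_um
    soma_r = soma_radius_um / s
    arm_r = arm_width_um / 2.0 / s
    max_len = max((a[0] for a in arms), default=0.0) / s
    max_tort = max((a[2] for a in arms), default=0.0) / s
    reach = soma_r + max_len + max_tort + arm_r + 4
    if canvas_px is None and _canvas is None:
        canvas_px = int(2 * math.ceil(reach) + 1)
    canvas = _canvas if _canvas is not None else np.zeros((canvas_px, canvas_px), dtype=bool)
    if center_px is None:
        center = np.array([canvas.shape[0] / 2.0, canvas.shape[1] / 2.0])
    else:
        center = np.array(center_px, dtype=float)
    if (
        center[0] - reach < 0
        or center[1] - reach < 0
        or center[0] + reach >= canvas.shape[0]
        or center[1] + reach >= canvas.shape[1]
    ):
        raise ValidationError("canvas too small for the requested neuron")
    yy, xx = np.mgrid[: canvas.shape[0], : canvas.shape[1]]
    cell = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= soma_r**2
    records = []
    arm_masks = []
    for i, (length_um, angle_deg, tort_um) in enumerate(arms):
        if length_um <= 0:
            raise ValidationError(f"arm {i}: length must be positive")
        line = _arm_centerline(center, soma_r, length_um / s, angle_deg, tort_um / s)
        amask = np.zeros_like(cell)
        for p in line:
            rr0 = int(max(p[0] - arm_r - 1, 0))
            rr1 = int(min(p[0] + arm_r + 2, canvas.shape[0]))
            cc0 = int(max(p[1] - arm_r - 1, 0))
            cc1 = int(min(p[1] + arm_r + 2, canvas.shape[1]))
            sub = (yy[rr0:rr1, cc0:cc1] - p[0]) ** 2 + (xx[rr0:rr1, cc0:cc1] - p[1]) ** 2
            amask[rr0:rr1, cc0:cc1] |= sub <= arm_r**2
        for j, other in enumerate(arm_masks):
            if (amask & other & ~cell).any():
                raise ValidationError(f"arm {i} intersects arm {j}")
        arm_masks.append(amask)
        chord = line[-1] - line[0]
        chord_deg = math.degrees(math.atan2(chord[0], chord[1]))
        records.append(
            {
                "object_id": i,
                "kind": "neurite",
                "length_um": _polyline_arclength(line) * s,
                "nominal_length_um": float(length_um),
                "angle_deg": float(angle_deg),
                "chord_angle_deg": abs(((chord_deg + 90.0) % 180.0) - 90.0),
                "tortuosity_um": float(tort_um),
            }
        )
    for amask in arm_masks:
        cell |= amask
    canvas |= cell
    truth = GroundTruth(
        kind="neuron",
        pixel_size_um=s,
        seed=seed,
        records=[
            {
                "object_id": -1,
                "kind": "soma",
                "soma_radius_um": float(soma_radius_um),
                "soma_diameter_um": 2.0 * float(soma_radius_um),
            }
        ]
        + records,
        params={
            "soma_radius_um": soma_radius_um,
            "arms": list(arms),
            "arm_width_um": arm_width_um,
            "noise_sd": noise_sd,
        },
    )
    img = Micrograph(
        pixels=_render(canvas, noise_sd, rng),
        bit_depth=8,
        pixel_size_um=s,
        source_id=f"synthetic-neuron-seed{seed}",
    )
    mask = BinaryMask(
        pixels=canvas, pixel_size_um=s, method_record={"method": "synthetic", "seed": seed}
    )
    return img, mask, truth


def gen_fractal(
    pattern: str, iterations: int = 6, canvas_px: int | None = None
) -> tuple[BinaryMask, GroundTruth]:
    """Deterministic test patterns of known box-counting dimension.

    * ``line`` — single-pixel row, D = 1;
    * ``filled_square`` — all-foreground canvas, D = 2;
    * ``sierpinski`` — right Sierpinski triangle by dyadic substitution:
      canvas 2**iterations, exactly 3**iterations foreground pixels,
      D = log 3 / log 2 ≈ 1.585.
    """
    if pattern == "sierpinski":
        if iterations < 1:
            raise ValidationError("iterations must be >= 1")
        side = 2**iterations
        if canvas_px is None:
            canvas_px = side
        if canvas_px < side:
            raise ValidationError(
                f"canvas {canvas_px} px cannot hold 2^{iterations} = {side} px pattern"
            )
        cell = np.ones((1, 1), dtype=bool)
        unit = np.array([[True, False], [True, True]])
        for _ in range(iterations):
            cell = np.kron(unit, cell)
        pix = np.zeros((canvas_px, canvas_px), dtype=bool)
        pix[:side, :side] = cell
        analytic_d = math.log(3) / math.log(2)
    elif pattern == "line":
        if canvas_px is None:
            canvas_px = 512
        pix = np.zeros((canvas_px, canvas_px), dtype=bool)
        pix[canvas_px // 2, :] = True
        analytic_d = 1.0
    elif pattern == "filled_square":
        if canvas_px is None:
            canvas_px = 512
        pix = np.ones((canvas_px, canvas_px), dtype=bool)
        analytic_d = 2.0
    else:
        raise ValidationError(f"unknown fractal pattern {pattern!r}")
    truth = GroundTruth(
        kind="fractal",
        pixel_size_um=1.0,
        seed=None,
        records=[
            {
                "object_id": 0,
                "kind": pattern,
                "analytic_D": analytic_d,
                "pixel_count": int(pix.sum()),
                "iterations": iterations if pattern == "sierpinski" else None,
            }
        ],
        params={"pattern": pattern, "iterations": iterations, "canvas_px": canvas_px},
    )
    return BinaryMask(pixels=pix, pixel_size_um=1.0, method_record={"method": "synthetic"}), truth


#: Analytic descriptor values for a period-1 checkerboard at offset
#: (0, 1), two levels, symmetric normalised GLCM.
_CHECKERBOARD_TRUTH = {
    "asm": 0.5,
    "entropy": math.log(2.0),
    "contrast": 1.0,
    "idm": 0.5,
    "correlation": -1.0,
}


def gen_texture(
    kind: str,
    canvas_px: int = 128,
    period_px: int = 1,
    value: int = 128,
    noise_sd: float = 20.0,
    seed: int = 0,
    pixel_size_um: float = 0.02,
) -> tuple[Micrograph, GroundTruth]:
    """Texture test patterns, with analytic GLCM truth where closed-form.

    ``constant`` (all ``value``), ``checkerboard`` / ``stripes`` (values
    0 and 255 alternating with ``period_px``), ``gaussian_noise`` (mean
    128, sd ``noise_sd``, clipped to 8 bit).
    """
    rng = np.random.default_rng(seed)
    analytic: dict | None = None
    if kind == "constant":
        pix = np.full((canvas_px, canvas_px), value, dtype=np.uint8)
        analytic = {"asm": 1.0, "entropy": 0.0, "contrast": 0.0, "idm": 1.0, "correlation": None}
    elif kind in ("checkerboard", "stripes"):
        if period_px < 1:
            raise ValidationError("period_px must be >= 1")
        i = np.arange(canvas_px) // period_px
        grid = (i[:, None] + i[None, :]) % 2 if kind == "checkerboard" else np.broadcast_to(
            (i % 2)[:, None], (canvas_px, canvas_px)
        )
        pix = np.where(grid == 1, 255, 0).astype(np.uint8)
        if kind == "checkerboard" and period_px == 1:
            analytic = dict(_CHECKERBOARD_TRUTH)
    elif kind == "gaussian_noise":
        pix = np.clip(
            np.round(rng.normal(128.0, noise_sd, (canvas_px, canvas_px))), 0, 255
        ).astype(np.uint8)
    else:
        raise ValidationError(f"unknown texture kind {kind!r}")
    truth = GroundTruth(
        kind="texture",
        pixel_size_um=pixel_size_um,
        seed=seed,
        records=[
            {
                "object_id": 0,
                "kind": kind,
                **({f"glcm_{k}": v for k, v in analytic.items()} if analytic else {}),
            }
        ],
        params={
            "kind": kind,
            "canvas_px": canvas_px,
            "period_px": period_px,
            "value": value,
            "noise_sd": noise_sd,
        },
    )
    img = Micrograph(
        pixels=pix,
        bit_depth=8,
        pixel_size_um=pixel_size_um,
        source_id=f"synthetic-texture-{kind}-seed{seed}",
    )
    return img, truth
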
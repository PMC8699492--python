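"""Run configuration: every tunable of the analysis commands in one
record, serialisable so any output is reproducible from its sidecar.

Configuration files are flat YAML key–value documents; CLI flags
override file values (flag > file > default).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # calibration
    pixel_size_um: float = 1.0
    # segmentation
    threshold_method: str = "otsu"
    manual_threshold: float | None = None
    invert: bool = False
    min_object_px: int = 25
    fill_holes: bool = True
    connectivity: int = 8
    exclude_border: bool = True
    # bacterial morphometry
    min_cell_px: int = 25
    # neuronal morphometry
    min_neurite_um: float | None = None  # None -> 5 x pixel size
    reference_axis_deg: float | str = 0.0  # or "random" (seeded)
    perimeter_method: str = "crofton"
    # fractal analysis
    min_box: int = 2
    max_box: int | None = None  # None -> min(image)/4
    n_offsets: int = 4
    fractal_mode: str = "silhouette"
    lacunarity_mode: str = "gliding"
    # texture
    glcm_levels: int = 16
    glcm_window: int = 64
    glcm_stride: int = 32
    # randomness
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def replace(self, **overrides) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(self)}
        for key in overrides:
            if key not in known:
                raise ValidationError(f"unknown configuration key {key!r}")
        return dataclasses.replace(self, **overrides)


def load_config(path) -> RunConfig:
    """Read a flat YAML mapping into a RunConfig; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError("config file must be a flat key-value mapping")
    return RunConfig().replace(**raw)
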
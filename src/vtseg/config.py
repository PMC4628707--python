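"""Run configuration: YAML key-value file with validated, namespaced sections.

Defaults follow the source acquisition and segmentation protocol where one is
stated: 1.04 mm spacing between cross-section centers, 0.35 mm cross-section
pixels, s_min = 3 px with s_max = 4 s_min = 12 px, and a 30-iteration cap per
slice.  Unknown keys are rejected so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from typing import Any

import yaml

from .snake import SnakeParams

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config"]


@dataclasses.dataclass
class InputConfig:
    stack_path: str = ""
    format: str | None = None           # nifti | tiff; inferred from extension if None
    spacing_mm: list[float] | None = None  # required for TIFF
    nodes_path: str = ""                # centerline nodes JSON
    overrides_path: str | None = None   # contours JSON replacing computed slices
    mask_path: str | None = None        # forbidden-region stack (nonzero = forbidden)


@dataclasses.dataclass
class PreprocessConfig:
    scale_factor: float = 3.0
    diffusion_iterations: int = 10
    diffusion_kappa: float = 30.0
    diffusion_step: float = 0.15


@dataclasses.dataclass
class CenterlineConfig:
    step_mm: float = 1.04
    pixel_size_mm: float = 0.35
    size_px: int = 129


@dataclasses.dataclass
class SnakeConfig:
    alpha: float = -0.8
    beta: float = 0.8
    gamma: float = 2.0
    delta: float = 0.4
    s_min: float = 3.0
    s_max: float | None = None
    max_iter: int = 30
    window: int = 3
    normalize: bool = True
    resample_each_iter: bool = True
    edge_blur_px: float = 4.0
    refine_iter: int = 15
    dev_to_segments: bool = False
    seed_uv: list[float] | None = None  # start-slice lumen point; image center if None
    start_index: int = 0
    init_radius_px: float | None = None  # None: sized from the image around the seed
    bidirectional: bool = True

    def to_params(self) -> SnakeParams:
        p = SnakeParams(alpha=self.alpha, beta=self.beta, gamma=self.gamma,
                        delta=self.delta, s_min=self.s_min, s_max=self.s_max,
                        max_iter=self.max_iter, window=self.window,
                        normalize=self.normalize,
                        resample_each_iter=self.resample_each_iter,
                        edge_blur_px=self.edge_blur_px,
                        refine_iter=self.refine_iter,
                        dev_to_segments=self.dev_to_segments)
        if abs(p.s_max - 4.0 * p.s_min) > 1e-12:
            log.info("note: s_max = %.3g deviates from the protocol default 4*s_min = %.3g",
                     p.s_max, 4.0 * p.s_min)
        return p


@dataclasses.dataclass
class OutputConfig:
    directory: str = "out"
    mesh_format: str = "ply"  # ply | obj


@dataclasses.dataclass
class RunConfig:
    input: InputConfig = dataclasses.field(default_factory=InputConfig)
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    centerline: CenterlineConfig = dataclasses.field(default_factory=CenterlineConfig)
    snake: SnakeConfig = dataclasses.field(default_factory=SnakeConfig)
    output: OutputConfig = dataclasses.field(default_factory=OutputConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the full configuration for the run manifest."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _build(cls, data: dict[str, Any], path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown configuration key(s) {sorted(unknown)} in {path}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            kwargs[name] = _build(f.type, value or {}, f"{path}.{name}")
        else:
            kwargs[name] = value
    return cls(**kwargs)


_SECTIONS = {
    "input": InputConfig,
    "preprocess": PreprocessConfig,
    "centerline": CenterlineConfig,
    "snake": SnakeConfig,
    "output": OutputConfig,
}


def load_config(path: str | os.PathLike) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown configuration section(s) {sorted(unknown)} in {path}")
    kwargs = {name: _build(cls, data.get(name) or {}, name)
              for name, cls in _SECTIONS.items()}
    return RunConfig(**kwargs)
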
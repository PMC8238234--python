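"""Pipeline configuration: schema, defaults, YAML round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import yaml

from .solver.grid import BoundaryPatch

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs.

    Defaults mirror the reference setup: 1.51 μm isotropic solver spacing,
    Re = 0.1, strong penalization, angiogenic-front breakpoint at 0.7 R_max.
    """

    mask_path: Optional[str] = None
    pixel_size: float = 1.51              # μm per mask pixel
    spacing: float = 1.51                 # μm solver grid spacing (isotropic)
    threshold: float = 0.5
    otsu: bool = False
    Re: float = 0.1
    eta: float = 1.0e5
    smoothing_width: float = 1.08         # cells; calibrated on Poiseuille
    D_in: Optional[float] = None          # μm; inferred from inlet patch if None
    inlet_face: str = "y-"
    inlet_span: Optional[Tuple[int, int]] = None     # cell range on first in-plane axis
    outlet_face: str = "y-"
    outlet_span: Optional[Tuple[int, int]] = None
    origin: Optional[Tuple[float, float]] = None     # μm, analysis frame
    theta_artery: float = 2.0             # radians
    theta_vein: float = 1.0
    fractions: Tuple[float, ...] = (0.7,)
    steady_tol: float = 1.0e-6
    poisson_tol: float = 1.0e-8
    cfl: float = 0.2
    dt: Optional[float] = None
    max_steps: int = 20000
    seed: int = 0
    write_vtk: bool = True
    write_png: bool = False

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.spacing <= 0:
            raise ValueError("pixel_size and spacing must be positive")
        if self.Re <= 0 or self.eta <= 0:
            raise ValueError("Re and eta must be positive")
        for f in self.fractions:
            if not 0.0 < f < 1.0:
                raise ValueError("fractions must lie in (0,1)")
        if self.smoothing_width < 0:
            raise ValueError("smoothing_width must be >= 0")

    def inlet_patch(self) -> BoundaryPatch:
        return BoundaryPatch(face=self.inlet_face,
                             span_a=tuple(self.inlet_span) if self.inlet_span else None)

    def outlet_patch(self) -> BoundaryPatch:
        return BoundaryPatch(face=self.outlet_face,
                             span_a=tuple(self.outlet_span) if self.outlet_span else None)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | os.PathLike, **overrides) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    raw.update(overrides)
    for key in ("inlet_span", "outlet_span", "origin", "fractions"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def dump_config(config: PipelineConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
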
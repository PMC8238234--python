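"""Solver grid, boundary patches and run configuration."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from ..reconstruct import OccupancyGrid3D

__all__ = ["SolverGrid", "BoundaryPatch", "FlowConfig", "make_grid"]

_FACES = ("x-", "x+", "y-", "y+", "z-", "z+")
_FACE_AXIS = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class SolverGrid:
    """Uniform Cartesian grid wrapping the reconstructed lumen.

    ``N`` cell counts, ``L`` physical extents (μm) with ``N_k * Δ_k = L_k``
    exactly, and ``D_in_star`` the inlet artery diameter (μm) used as the
    length scale of the nondimensional problem.
    """

    N: Tuple[int, int, int]
    L: Tuple[float, float, float]
    spacing: Tuple[float, float, float]
    D_in_star: float

    def __post_init__(self) -> None:
        for n, l, d in zip(self.N, self.L, self.spacing):
            if n < 1 or d <= 0:
                raise ValueError("invalid grid dimensions")
            if abs(n * d - l) > 1e-6 * max(l, d):
                raise ValueError(
                    f"N*Δ must equal L exactly (got {n}*{d} vs {l})")
        if self.D_in_star <= 0:
            raise ValueError("D_in_star must be positive")

    @classmethod
    def from_domain(cls, L, spacing, D_in_star) -> "SolverGrid":
        """Grid from physical extents: N = round(L/Δ) per axis; raises if the
        domain is not an integer multiple of the spacing (0.1% tolerance)."""
        if np.isscalar(spacing):
            spacing = (float(spacing),) * 3
        N = []
        for l, d in zip(L, spacing):
            n = int(round(l / d))
            if abs(n * d - l) > 1e-3 * l:
                raise ValueError(f"extent {l} is not a multiple of spacing {d}")
            N.append(n)
        # snap L to N*Δ to satisfy the exact-product invariant
        L_exact = tuple(n * d for n, d in zip(N, spacing))
        return cls(N=tuple(N), L=L_exact, spacing=tuple(spacing),
                   D_in_star=float(D_in_star))

    @property
    def h(self) -> Tuple[float, float, float]:
        """Nondimensional spacing (length scale: inlet diameter)."""
        return tuple(d / self.D_in_star for d in self.spacing)

    @property
    def cell_volume_nd(self) -> float:
        hx, hy, hz = self.h
        return hx * hy * hz


def make_grid(occ: OccupancyGrid3D, D_in_star: float,
              spacing: Optional[Tuple[float, float, float]] = None) -> SolverGrid:
    """Solver grid that wraps an occupancy grid exactly."""
    if spacing is not None:
        if tuple(spacing) != tuple(occ.spacing):
            raise ValueError("requested spacing differs from occupancy spacing")
    sp = tuple(float(s) for s in occ.spacing)
    if max(sp) - min(sp) > 1e-9:
        raise ValueError("spacing must be isotropic")
    N = occ.shape
    L = tuple(n * d for n, d in zip(N, sp))
    return SolverGrid(N=N, L=L, spacing=sp, D_in_star=float(D_in_star))


@dataclass(frozen=True)
class BoundaryPatch:
    """Rectangular opening on one box face.

    ``face`` is one of x-/x+/y-/y+/z-/z+; ``span_a``/``span_b`` are
    half-open cell-index ranges along the two in-plane axes (in axis order
    skipping the face axis), ``None`` meaning the full extent. The open area
    of the patch is its overlap with lumen cells in the adjacent cell layer.
    """

    face: str
    span_a: Optional[Tuple[int, int]] = None
    span_b: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.face not in _FACES:
            raise ValueError(f"face must be one of {_FACES}")

    @property
    def axis(self) -> int:
        return _FACE_AXIS[self.face[0]]

    @property
    def is_plus(self) -> bool:
        return self.face[1] == "+"

    def open_mask(self, lumen: np.ndarray) -> np.ndarray:
        """2D boolean mask (in-plane shape) of lumen cells open to the patch."""
        ax = self.axis
        layer = np.take(lumen, -1 if self.is_plus else 0, axis=ax)
        sel = np.zeros_like(layer, dtype=bool)
        a0, a1 = self.span_a if self.span_a else (0, layer.shape[0])
        b0, b1 = self.span_b if self.span_b else (0, layer.shape[1])
        sel[a0:a1, b0:b1] = True
        return layer.astype(bool) & sel


@dataclass
class FlowConfig:
    """Numerical parameters of one steady-flow solve (nondimensional)."""

    inlet: BoundaryPatch
    outlet: BoundaryPatch
    Re: float = 0.1
    eta: float = 1.0e5
    cfl: float = 0.2
    dt: Optional[float] = None          # override; else cfl * h / u_ref
    steady_tol: float = 1.0e-6
    steady_hold: int = 10               # consecutive steps below tol
    theta: float = 0.5                  # implicit weight: 0.5 = CN, 1 = BE
    project_every_substep: bool = False # tighter pressure coupling
    seepage_projection: bool = True     # mobility-weighted pressure correction
    poisson_tol: float = 1.0e-8         # verified a posteriori (direct solve)
    max_steps: int = 20000
    u_ref: float = 4.0                  # velocity scale for the CFL estimate
    U_in_star: Optional[float] = None   # m/s, for dimensional restore only
    check_connectivity: bool = True
    log_every: int = 50

    def __post_init__(self) -> None:
        if self.Re <= 0:
            raise ValueError("Re must be positive")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.inlet.face == self.outlet.face and \
                self.inlet.span_a == self.outlet.span_a and \
                self.inlet.span_b == self.outlet.span_b:
            raise ValueError("inlet and outlet patches must differ")
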
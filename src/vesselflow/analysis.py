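"""Cylindrical flow decomposition and azimuthal transport quantification.

A cylindrical frame (r, theta) is anchored at the first branching point of
the feeding vessel near the inlet. The velocity field is decomposed into
radial and azimuthal components, the lumen is partitioned into annular
regions by fractions of R_max (the farthest lumen voxel), and the azimuthal
flow rate Q_theta of each region is the volume integral of u_theta over its
lumen voxels. The outermost annulus (default beyond 0.7 R_max) is the
angiogenic front. The azimuthal sign convention makes artery-to-vein
transport positive.

Also provides the Womersley and Peclet helpers used to justify the steady,
convection-relevant regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple  # noqa: F401

import numpy as np

from .reconstruct import OccupancyGrid3D
from .solver.stepper import SteadyFlowField

__all__ = [
    "CylindricalFrame",
    "RegionPartition",
    "AzimuthalFlowReport",
    "womersley",
    "peclet",
    "to_cylindrical",
    "partition_regions",
    "azimuthal_flow_rate",
    "suggest_origin",
]


def womersley(d: float, omega: float, nu: float) -> float:
    """Womersley number alpha = d * sqrt(omega / nu) (SI units)."""
    if d <= 0 or omega <= 0 or nu <= 0:
        raise ValueError("all inputs must be positive")
    return d * math.sqrt(omega / nu)


def peclet(u: float, L: float, D: float) -> float:
    """Peclet number Pe = u * L / D (SI units)."""
    if u < 0 or L <= 0 or D <= 0:
        raise ValueError("L and D must be positive, u non-negative")
    return u * L / D


@dataclass(frozen=True)
class CylindricalFrame:
    """Origin (μm, image coordinates) and artery/vein ray angles (radians).

    ``theta_artery``/``theta_vein`` orient the azimuthal sign: the tangential
    unit vector points from the artery ray toward the vein ray along the
    shorter angular path, so artery->vein transport is positive.
    """

    origin: Tuple[float, float]
    theta_artery: float
    theta_vein: float

    @property
    def orientation(self) -> float:
        """+1 if artery->vein is counter-clockwise, else -1."""
        d = (self.theta_vein - self.theta_artery) % (2.0 * math.pi)
        return 1.0 if d <= math.pi else -1.0


@dataclass
class RegionPartition:
    """Annular lumen regions by fractions of R_max.

    ``labels`` matches the occupancy shape: region index for lumen voxels
    (0 = innermost), -1 outside the lumen. The last region is the
    angiogenic front for the default fractions ``[0.7]``.
    """

    fractions: Tuple[float, ...]
    labels: np.ndarray
    R_max: float
    r_cell: np.ndarray  # 2D (nx, ny) radius of each cell column, μm

    @property
    def n_regions(self) -> int:
        return len(self.fractions) + 1

    def region_cells(self, region: int) -> np.ndarray:
        return self.labels == region


@dataclass
class AzimuthalFlowReport:
    """Per-region azimuthal flow rates.

    ``q_raw`` is the nondimensional volume integral of u_theta; ``q_mean``
    divides by the region's fluid volume; ``q_normalized`` divides by
    (inlet flux x inlet diameter), both nondimensional, giving the
    dimensionless transport fraction used for cross-network comparison.
    """

    regions: List[int]
    fluid_volume: List[float]
    q_raw: List[float]
    q_mean: List[float]
    q_normalized: List[float]
    total_q_raw: float = 0.0

    def as_rows(self) -> List[dict]:
        names = {0: "inner"}
        rows = []
        for i, reg in enumerate(self.regions):
            rows.append({
                "region": reg,
                "fluid_volume": self.fluid_volume[i],
                "Q_theta_raw": self.q_raw[i],
                "Q_theta_per_volume": self.q_mean[i],
                "Q_theta_normalized": self.q_normalized[i],
            })
        return rows

    @property
    def front_normalized(self) -> float:
        """Normalized Q_theta of the outermost region."""
        return self.q_normalized[-1]


def _cell_centers_um(flow: SteadyFlowField):
    """Physical (x, y) of cell centers, μm, image frame (x=column axis)."""
    Nx, Ny, _ = flow.grid.N
    dx, dy, _ = flow.grid.spacing
    x = (np.arange(Nx) + 0.5) * dx
    y = (np.arange(Ny) + 0.5) * dy
    return x, y


def to_cylindrical(flow: SteadyFlowField, frame: CylindricalFrame):
    """Cell-centered (u_r, u_theta) fields; the z component is untouched.

    Cells exactly at r = 0 get u_r = u_theta = 0.
    """
    uc, vc, wc = flow.cell_velocity()
    x, y = _cell_centers_um(flow)
    X = x[:, None] - frame.origin[0]
    Y = y[None, :] - frame.origin[1]
    r = np.hypot(X, Y)
    with np.errstate(invalid="ignore", divide="ignore"):
        cs = np.where(r > 0, X / r, 0.0)
        sn = np.where(r > 0, Y / r, 0.0)
    sgn = frame.orientation
    u_r = uc * cs[:, :, None] + vc * sn[:, :, None]
    u_t = sgn * (-uc * sn[:, :, None] + vc * cs[:, :, None])
    zero = (r == 0.0)
    if zero.any():
        u_r[zero, :] = 0.0
        u_t[zero, :] = 0.0
    return u_r, u_t


def partition_regions(occ_or_lumen, frame: CylindricalFrame,
                      fractions: Sequence[float] = (0.7,),
                      spacing: Optional[Tuple[float, float, float]] = None
                      ) -> RegionPartition:
    """Label lumen voxels by the annulus of r/R_max their column falls in."""
    if isinstance(occ_or_lumen, OccupancyGrid3D):
        lumen = occ_or_lumen.voxels.astype(bool)
        sp = occ_or_lumen.spacing
    else:
        lumen = np.asarray(occ_or_lumen).astype(bool)
        if spacing is None:
            raise ValueError("spacing required when passing a raw lumen array")
        sp = spacing
    if not lumen.any():
        raise ValueError("empty lumen")
    fr = tuple(float(f) for f in fractions)
    if any(not 0.0 < f < 1.0 for f in fr) or list(fr) != sorted(set(fr)):
        raise ValueError("fractions must be strictly increasing in (0,1)")

    Nx, Ny, _ = lumen.shape
    dx, dy = sp[0], sp[1]
    x = (np.arange(Nx) + 0.5) * dx - frame.origin[0]
    y = (np.arange(Ny) + 0.5) * dy - frame.origin[1]
    r = np.hypot(x[:, None], y[None, :])
    r_max = float(r[lumen.any(axis=2)].max())
    edges = np.array([f * r_max for f in fr])
    col_label = np.searchsorted(edges, r, side="right")
    labels = np.where(lumen, col_label[:, :, None], -1)
    return RegionPartition(fractions=fr, labels=labels, R_max=r_max, r_cell=r)


def azimuthal_flow_rate(u_theta: np.ndarray, partition: RegionPartition,
                        flow: SteadyFlowField) -> AzimuthalFlowReport:
    """Volume-integrated azimuthal flow rate per annular region."""
    dv = flow.grid.cell_volume_nd
    hx, hy, hz = flow.grid.h
    # nondimensional inlet metrics for normalization (D_in_nd == 1)
    lumen = partition.labels >= 0
    inlet_flux = _inlet_flux(flow)
    regions, vols, q_raw, q_mean, q_norm = [], [], [], [], []
    for reg in range(partition.n_regions):
        cells = partition.labels == reg
        vol = float(cells.sum()) * dv
        q = float(u_theta[cells].sum()) * dv
        regions.append(reg)
        vols.append(vol)
        q_raw.append(q)
        q_mean.append(q / vol if vol > 0 else 0.0)
        q_norm.append(q / inlet_flux if inlet_flux > 0 else 0.0)
    total = float(u_theta[lumen].sum()) * dv
    return AzimuthalFlowReport(regions=regions, fluid_volume=vols,
                               q_raw=q_raw, q_mean=q_mean,
                               q_normalized=q_norm, total_q_raw=total)


def _inlet_flux(flow: SteadyFlowField) -> float:
    patch = flow.config.inlet
    lumen = flow.lumen
    open_mask = patch.open_mask(lumen)
    hx, hy, hz = flow.grid.h
    per = {0: hy * hz, 1: hx * hz, 2: hx * hy}[patch.axis]
    return float(open_mask.sum()) * per  # inlet speed is 1 nondimensional


def suggest_origin(skeleton: np.ndarray, inlet_xy_px: Tuple[int, int],
                   pixel_size: float) -> Tuple[float, float]:
    """Candidate analysis origin: the skeleton branch point nearest to the
    inlet position (the first bifurcation along the feeding vessel)."""
    from .morphometry import _neighbor_counts

    s = np.asarray(skeleton).astype(bool)
    branch = s & (_neighbor_counts(s) >= 3)
    ys, xs = np.nonzero(branch)
    if xs.size == 0:
        raise ValueError("skeleton has no branch points")
    ix, iy = inlet_xy_px
    d2 = (xs - ix) ** 2 + (ys - iy) ** 2
    k = int(np.argmin(d2))
    return ((xs[k] + 0.5) * pixel_size, (ys[k] + 0.5) * pixel_size)
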
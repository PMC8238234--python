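"""Synthetic 2D vessel masks: wedge-shaped artery-capillary-vein networks
and canonical solver-validation geometries.

The wedge generator emulates the minimum flow unit of a growing retinal
plexus: a single feeding artery ray and a single draining vein ray from a
common origin near the inlet, bridged by concentric capillary arcs and
radial connector segments. Branch density is tuned through
``branches_per_ring`` (and ``n_radial_rings``), giving matched hyper- vs
hypo-branching fixtures.

All geometry is rasterized analytically (point-to-segment / point-to-arc
distance below half the local vessel diameter), so the same spec and seed
always give a byte-identical mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .morphometry import VesselMask2D

__all__ = [
    "SyntheticNetworkSpec",
    "generate_wedge",
    "generate_canonical",
    "wedge_frame_hint",
    "HYPER_PRESET",
    "HYPO_PRESET",
]


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Parameters of a wedge-shaped artery-capillary-vein network.

    Lengths in micrometres; angles in degrees. ``branches_per_ring`` is the
    branch-density knob (number of radial connectors in each inter-ring gap).
    """

    domain_size: tuple = (600.0, 600.0)
    pixel_size: float = 2.0
    inlet_diameter: float = 12.0
    capillary_diameter: float = 6.0
    n_radial_rings: int = 6
    branches_per_ring: int = 8
    wedge_angle: float = 70.0
    jitter: float = 0.25
    seed: int = 0
    stub_radius_frac: float = 0.15   # rays start at this fraction of R_out

    def validate(self) -> None:
        lx, ly = self.domain_size
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.inlet_diameter < 3 * self.pixel_size:
            raise ValueError("inlet_diameter must span at least 3 pixels")
        if self.capillary_diameter < 3 * self.pixel_size:
            raise ValueError("capillary_diameter must span at least 3 pixels")
        if not 10.0 <= self.wedge_angle <= 160.0:
            raise ValueError("wedge_angle out of range")
        if self.n_radial_rings < 1 or self.branches_per_ring < 1:
            raise ValueError("need at least one ring and one branch per ring")
        r_out = self._outer_radius()
        gap = (r_out - self.stub_radius_frac * r_out) / (self.n_radial_rings + 1)
        if gap < self.capillary_diameter:
            raise ValueError("rings collide: too many rings for this domain")

    def _outer_radius(self) -> float:
        lx, ly = self.domain_size
        margin = 2.0 * self.capillary_diameter
        # wedge opens upward from an origin near the bottom boundary
        return min(lx / 2.0, ly - self._origin_y()) - margin

    def _origin_y(self) -> float:
        return 0.06 * self.domain_size[1] + self.inlet_diameter


# Matched presets: identical domain, inlet and outer radius; only branch
# density differs. Values are fixture conventions tuned to land morphometrics
# in a plausible neonatal-retina range, not biological claims.
HYPER_PRESET = SyntheticNetworkSpec(
    n_radial_rings=8, branches_per_ring=14, capillary_diameter=6.0, seed=7
)
HYPO_PRESET = SyntheticNetworkSpec(
    n_radial_rings=5, branches_per_ring=5, capillary_diameter=6.0, seed=7
)


def _pixel_grid(shape: tuple, pixel_size: float):
    """Physical coordinates of pixel centers; x = column, y = row, origin at
    the image lower-left, centers at (i + 0.5) * pixel_size."""
    ny, nx = shape
    x = (np.arange(nx) + 0.5) * pixel_size
    y = (np.arange(ny) + 0.5) * pixel_size
    return np.meshgrid(x, y)  # X, Y with shape (ny, nx)


def _paint_segment(canvas, X, Y, p0, p1, width) -> None:
    (x0, y0), (x1, y1) = p0, p1
    dx, dy = x1 - x0, y1 - y0
    l2 = dx * dx + dy * dy
    if l2 == 0:
        d2 = (X - x0) ** 2 + (Y - y0) ** 2
    else:
        t = np.clip(((X - x0) * dx + (Y - y0) * dy) / l2, 0.0, 1.0)
        d2 = (X - (x0 + t * dx)) ** 2 + (Y - (y0 + t * dy)) ** 2
    canvas |= d2 < (width / 2.0) ** 2


def _paint_arc(canvas, X, Y, center, radius, theta0, theta1, width) -> None:
    """Arc of a circle between angles theta0 < theta1 (radians)."""
    cx, cy = center
    dxg, dyg = X - cx, Y - cy
    r = np.hypot(dxg, dyg)
    ang = np.arctan2(dyg, dxg)
    in_band = np.abs(r - radius) < width / 2.0
    in_span = (ang >= theta0) & (ang <= theta1)
    canvas |= in_band & in_span
    # round caps so arcs meet the rays cleanly
    for th in (theta0, theta1):
        ex, ey = cx + radius * math.cos(th), cy + radius * math.sin(th)
        canvas |= (X - ex) ** 2 + (Y - ey) ** 2 < (width / 2.0) ** 2


def generate_wedge(spec: SyntheticNetworkSpec) -> VesselMask2D:
    """Rasterize a wedge-shaped A-V network mask from its spec.

    The mask touches the domain boundary only at the inlet (artery) and
    outlet (vein) stubs on the bottom edge.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lx, ly = spec.domain_size
    ps = spec.pixel_size
    shape = (int(round(ly / ps)), int(round(lx / ps)))
    X, Y = _pixel_grid(shape, ps)
    canvas = np.zeros(shape, dtype=bool)

    ox, oy = lx / 2.0, spec._origin_y()
    r_out = spec._outer_radius()
    r_start = spec.stub_radius_frac * r_out
    half = math.radians(spec.wedge_angle) / 2.0
    th_artery = math.pi / 2.0 + half   # left ray
    th_vein = math.pi / 2.0 - half     # right ray

    d_in = spec.inlet_diameter
    d_cap = spec.capillary_diameter

    def ray_point(theta, r):
        return (ox + r * math.cos(theta), oy + r * math.sin(theta))

    # artery/vein rays plus vertical stubs down to the bottom boundary
    for theta, width in ((th_artery, d_in), (th_vein, d_in)):
        p_start = ray_point(theta, r_start)
        p_end = ray_point(theta, r_out)
        _paint_segment(canvas, X, Y, p_start, p_end, width)
        _paint_segment(canvas, X, Y, (p_start[0], -2 * ps), p_start, width)

    # concentric capillary arcs
    radii = np.linspace(r_start + d_cap, r_out - d_cap / 2.0,
                        spec.n_radial_rings + 1)[1:]
    # taper: innermost ring slightly wider to mimic arteriole-size branches
    for r in radii:
        _paint_arc(canvas, X, Y, (ox, oy), r, th_vein, th_artery, d_cap)

    # radial connectors with angular jitter between consecutive arcs
    ring_edges = np.concatenate(([r_start], radii))
    span = th_artery - th_vein
    for gi in range(len(ring_edges) - 1):
        r0, r1 = ring_edges[gi], ring_edges[gi + 1]
        base = np.linspace(th_vein, th_artery, spec.branches_per_ring + 2)[1:-1]
        max_off = spec.jitter * span / max(spec.branches_per_ring + 1, 1)
        offs = rng.uniform(-max_off, max_off, size=base.size)
        for th in base + offs:
            _paint_segment(canvas, X, Y, ray_point(th, r0), ray_point(th, r1),
                           d_cap)

    # keep the bottom-boundary contact confined to the two stubs
    stub_xs = [ray_point(th_artery, r_start)[0], ray_point(th_vein, r_start)[0]]
    guard = np.zeros(shape, dtype=bool)
    rows_guard = Y < oy * 0.55
    for sx in stub_xs:
        guard |= np.abs(X - sx) < d_in  # generous corridor around each stub
    canvas &= ~(rows_guard & ~guard)

    return VesselMask2D(pixels=canvas.astype(np.uint8), pixel_size=ps)


def wedge_frame_hint(spec: SyntheticNetworkSpec) -> dict:
    """Analysis-frame metadata for a generated wedge: cylindrical origin
    (the common branch origin of the rays, in μm), artery/vein ray angles
    (radians) and the stub x-positions on the bottom boundary (μm)."""
    lx, ly = spec.domain_size
    ox, oy = lx / 2.0, spec._origin_y()
    r_out = spec._outer_radius()
    half = math.radians(spec.wedge_angle) / 2.0
    th_a, th_v = math.pi / 2.0 + half, math.pi / 2.0 - half
    r_start = spec.stub_radius_frac * r_out
    return {
        "origin": (ox, oy),
        "theta_artery": th_a,
        "theta_vein": th_v,
        "r_outer": r_out,
        "inlet_x": ox + r_start * math.cos(th_a),
        "outlet_x": ox + r_start * math.cos(th_v),
    }


def generate_canonical(name: str, **params) -> VesselMask2D:
    """Exact parametric masks for solver validation.

    Supported names: ``straight_tube`` (width_um, length_um, pixel_size),
    ``y_bifurcation`` (trunk_width_um, length_um, pixel_size),
    ``single_loop`` (width_um, size_um, pixel_size).
    """
    ps = float(params.get("pixel_size", 2.0))
    if name == "straight_tube":
        w = float(params.get("width_um", 12.0))
        length = float(params.get("length_um", 120.0))
        margin = float(params.get("margin_um", 2.0 * w))
        ny, nx = int(round(length / ps)), int(round((w + 2 * margin) / ps))
        X, Y = _pixel_grid((ny, nx), ps)
        cx = nx * ps / 2.0
        canvas = np.abs(X - cx) < w / 2.0
        return VesselMask2D(canvas.astype(np.uint8), ps)
    if name == "y_bifurcation":
        w = float(params.get("trunk_width_um", 12.0))
        length = float(params.get("length_um", 160.0))
        spread = float(params.get("spread_um", length * 0.45))
        lx = 2 * spread + 4 * w
        ny, nx = int(round(length / ps)), int(round(lx / ps))
        X, Y = _pixel_grid((ny, nx), ps)
        cx, ysplit = nx * ps / 2.0, length * 0.4
        canvas = np.zeros((ny, nx), dtype=bool)
        _paint_segment(canvas, X, Y, (cx, -2 * ps), (cx, ysplit), w)
        _paint_segment(canvas, X, Y, (cx, ysplit), (cx - spread, length + 2 * ps), w)
        _paint_segment(canvas, X, Y, (cx, ysplit), (cx + spread, length + 2 * ps), w)
        return VesselMask2D(canvas.astype(np.uint8), ps)
    if name == "single_loop":
        w = float(params.get("width_um", 10.0))
        size = float(params.get("size_um", 150.0))
        lx = size + 6 * w
        ly = size + 10 * w
        ny, nx = int(round(ly / ps)), int(round(lx / ps))
        X, Y = _pixel_grid((ny, nx), ps)
        cx = nx * ps / 2.0
        rad = size / 2.0
        cy = ly / 2.0
        canvas = np.zeros((ny, nx), dtype=bool)
        _paint_arc(canvas, X, Y, (cx, cy), rad, -math.pi, math.pi, w)
        ring = np.abs(np.hypot(X - cx, Y - cy) - rad) < w / 2.0
        canvas |= ring
        _paint_segment(canvas, X, Y, (cx, -2 * ps), (cx, cy - rad + w), w)
        _paint_segment(canvas, X, Y, (cx, cy + rad - w), (cx, ly + 2 * ps), w)
        return VesselMask2D(canvas.astype(np.uint8), ps)
    raise ValueError(f"unknown canonical geometry {name!r}")
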
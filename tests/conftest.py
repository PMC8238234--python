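"""Shared fixtures: small geometries and (session-scoped) steady solves.

Solver runs are expensive, so every test that needs a converged flow shares
the session-scoped fixtures below; the acceptance tests reuse them too.
All solves are sized to keep the full suite within the CI budget.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import vesselflow as vf
from vesselflow.analysis import (CylindricalFrame, azimuthal_flow_rate,
                                 partition_regions, to_cylindrical)
from vesselflow.pipeline import wedge_config
from vesselflow.reconstruct import OccupancyGrid3D
from vesselflow.solver import (BoundaryPatch, FlowConfig, FlowProblem,
                               make_grid, run_to_steady_state)
from vesselflow.solver.stepper import interpolate_state
from vesselflow.synthetic import SyntheticNetworkSpec, generate_wedge


def tube_geometry(pixel_size=1.0, width=12.0, length=90.0, smoothing=1.08):
    """Mask -> occupancy -> chi for a straight tube along y."""
    mask = vf.generate_canonical("straight_tube", width_um=width,
                                 length_um=length, pixel_size=pixel_size)
    rad = vf.local_radius_field(mask)
    occ = vf.build_occupancy(rad, spacing=pixel_size)
    ls = vf.compute_level_set(occ)
    chi = vf.solid_indicator(ls, smoothing)
    grid = make_grid(occ, D_in_star=width)
    return mask, occ, ls, chi, grid


def steady_tube_config(eta=1.0e5, steady_tol=1.0e-6, **kw):
    return FlowConfig(inlet=BoundaryPatch("y-"), outlet=BoundaryPatch("y+"),
                      Re=0.1, eta=eta, steady_tol=steady_tol, **kw)


def quiet_steady(problem, initial=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_to_steady_state(problem, initial=initial)


@pytest.fixture(scope="session")
def tube_flow():
    """Converged 12-cells-per-diameter tube (fast, shared by solver tests)."""
    _, occ, _, chi, grid = tube_geometry()
    cfg = steady_tube_config()
    problem = FlowProblem(grid, chi.chi, cfg)
    flow = quiet_steady(problem)
    return {"flow": flow, "occ": occ, "chi": chi, "grid": grid,
            "problem": problem}


@pytest.fixture(scope="session")
def tube16_flow():
    """16-cells-per-diameter tube for the Poiseuille acceptance check."""
    _, occ, _, chi, grid = tube_geometry(pixel_size=0.75)
    cfg = steady_tube_config()
    problem = FlowProblem(grid, chi.chi, cfg)
    flow = quiet_steady(problem)
    return {"flow": flow, "occ": occ, "grid": grid, "problem": problem}


@pytest.fixture(scope="session")
def channel_flow():
    """Planar channel: slab lumen between two z walls, flow along y."""
    T, pad, Nx, Ny = 16, 5, 72, 100
    Nz = T + 2 * pad
    vox = np.zeros((Nx, Ny, Nz), dtype=np.uint8)
    vox[:, :, pad:pad + T] = 1
    occ = OccupancyGrid3D(vox, (1.0, 1.0, 1.0), Nz // 2)
    chi = vf.solid_indicator(vf.compute_level_set(occ), 1.08)
    grid = make_grid(occ, D_in_star=float(T))
    problem = FlowProblem(grid, chi.chi, steady_tube_config())
    flow = quiet_steady(problem)
    return {"flow": flow, "occ": occ, "grid": grid, "problem": problem}


@pytest.fixture(scope="session")
def eta_sweep_flows():
    """Tube solves across a penalization-strength decade sweep."""
    out = {}
    for eta in (1e2, 1e3, 1e4):
        _, occ, _, chi, grid = tube_geometry(length=60.0)
        cfg = steady_tube_config(eta=eta, steady_tol=1e-5, max_steps=1000)
        problem = FlowProblem(grid, chi.chi, cfg)
        out[eta] = {"flow": quiet_steady(problem), "chi": chi}
    return out


@pytest.fixture(scope="session")
def ybif_flow():
    """Mirror-symmetric Y bifurcation, one inlet, two outlet branches."""
    mask = vf.generate_canonical("y_bifurcation", trunk_width_um=14,
                                 length_um=150, pixel_size=2.0)
    rad = vf.local_radius_field(mask)
    occ = vf.build_occupancy(rad, spacing=2.0)
    chi = vf.solid_indicator(vf.compute_level_set(occ), 1.08)
    grid = make_grid(occ, D_in_star=14.0)
    cfg = steady_tube_config(steady_tol=1e-5, max_steps=800)
    problem = FlowProblem(grid, chi.chi, cfg)
    flow = quiet_steady(problem)
    return {"flow": flow, "grid": grid, "problem": problem}


def solve_wedge(spec, spacing, mask=None, init_from=None, steady_tol=2e-5,
                max_steps=900, fractions=(0.7,)):
    """Reconstruct and solve one synthetic wedge; returns the pieces used
    by the transport analysis."""
    if mask is None:
        mask = generate_wedge(spec)
    cfg = wedge_config(spec, spacing=spacing, steady_tol=steady_tol,
                       max_steps=max_steps)
    rad = vf.local_radius_field(mask)
    occ = vf.build_occupancy(rad, spacing=spacing)
    ls = vf.compute_level_set(occ)
    chi = vf.solid_indicator(ls, cfg.smoothing_width)
    grid = make_grid(occ, D_in_star=spec.inlet_diameter)
    fcfg = FlowConfig(inlet=cfg.inlet_patch(), outlet=cfg.outlet_patch(),
                      Re=cfg.Re, eta=cfg.eta, steady_tol=steady_tol,
                      max_steps=max_steps)
    problem = FlowProblem(grid, chi.chi, fcfg)
    init = None
    if init_from is not None:
        src_flow, src_grid, src_occ = init_from
        init = interpolate_state(src_flow.state, src_grid, grid,
                                 src_occ.z_center_index, occ.z_center_index)
    flow = quiet_steady(problem, initial=init)
    frame = CylindricalFrame(cfg.origin, cfg.theta_artery, cfg.theta_vein)
    _, u_t = to_cylindrical(flow, frame)
    part = partition_regions(occ, frame, fractions=fractions)
    rep = azimuthal_flow_rate(u_t, part, flow)
    return {"mask": mask, "flow": flow, "grid": grid, "occ": occ,
            "frame": frame, "partition": part, "report": rep}


REFINEMENT_SPEC = SyntheticNetworkSpec(
    domain_size=(260.0, 260.0), pixel_size=1.25, inlet_diameter=20.0,
    capillary_diameter=16.0, n_radial_rings=3, branches_per_ring=4,
    wedge_angle=90.0, jitter=0.15, seed=1, stub_radius_frac=0.28)

_WEDGE_BASE = dict(domain_size=(300.0, 300.0), pixel_size=2.0,
                   inlet_diameter=15.0, capillary_diameter=8.0,
                   wedge_angle=80.0, jitter=0.2, seed=11)
HYPER_WEDGE = SyntheticNetworkSpec(**_WEDGE_BASE, n_radial_rings=6,
                                   branches_per_ring=11)
HYPO_WEDGE = SyntheticNetworkSpec(**_WEDGE_BASE, n_radial_rings=4,
                                  branches_per_ring=4)


@pytest.fixture(scope="session")
def wedge_refinement():
    """The same wedge solved at spacing 3.25 um and 1.625 um; the fine run
    is warm-started from the interpolated coarse solution."""
    mask = generate_wedge(REFINEMENT_SPEC)
    coarse = solve_wedge(REFINEMENT_SPEC, 3.25, mask=mask)
    fine = solve_wedge(REFINEMENT_SPEC, 1.625, mask=mask,
                       init_from=(coarse["flow"], coarse["grid"],
                                  coarse["occ"]))
    return {"coarse": coarse, "fine": fine}


@pytest.fixture(scope="session")
def hyper_hypo_wedges():
    """Matched hyper- vs hypo-branching wedges at identical inlet, domain
    and spacing; only branch density differs."""
    return {"hyper": solve_wedge(HYPER_WEDGE, 2.5, steady_tol=1e-5,
                                 max_steps=1500),
            "hypo": solve_wedge(HYPO_WEDGE, 2.5, steady_tol=1e-5,
                                max_steps=1500)}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
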
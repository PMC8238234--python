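"""Pseudo-time marching to the steady penalized Navier-Stokes solution.

Scheme: three-substep Runge-Kutta for the explicit terms (convection and
the lagged pressure gradient), Crank-Nicolson for diffusion and the
penalization force, advanced in delta form with an approximately factorized
implicit operator

    (I + a*eta*chi) (I - (a/Re) Lap) du = dt * R(u)

where ``a = theta * alpha_k * dt`` (theta = 1/2 recovers Crank-Nicolson). The factorization error multiplies ``du`` and
therefore vanishes at steady state. The constant-coefficient Helmholtz
factor is inverted exactly by sine-transform diagonalization; the pressure
correction (SMAC) solves a pure-Neumann Poisson problem per substep: a
mobility-weighted solve that lets the pressure adjust through the penalized
solid, then an exact cosine-transform cleanup that drives the discrete
divergence to round-off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .grid import BoundaryPatch, FlowConfig, SolverGrid
from .ops import (chi_to_faces, convective_tendency, diffusive_tendency,
                  divergence, penalization_tendency, pressure_gradient)
from .transforms import (HelmholtzSolver, NeumannPoissonSolver,
                         VariableCoeffPoissonSolver)

__all__ = [
    "StaggeredFlowState",
    "SteadyFlowField",
    "SolverDiverged",
    "DisconnectedLumenError",
    "apply_boundary_conditions",
    "pressure_poisson_solve",
    "time_step",
    "run_to_steady_state",
    "FlowProblem",
]

# RK3 coefficients (Rai-Moin); gamma_k + zeta_k sum to 1 over the cycle.
_GAMMA = (8.0 / 15.0, 5.0 / 12.0, 3.0 / 4.0)
_ZETA = (0.0, -17.0 / 60.0, -5.0 / 12.0)
_ALPHA = tuple(g + z for g, z in zip(_GAMMA, _ZETA))


class SolverDiverged(RuntimeError):
    """Raised when the iteration produces non-finite values."""


class DisconnectedLumenError(RuntimeError):
    """Raised when no lumen path connects the inlet to the outlet."""


@dataclass
class StaggeredFlowState:
    """Face-centered velocities + cell pressure on a uniform staggered grid."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    step: int = 0
    residual: float = np.inf

    @classmethod
    def zeros(cls, N: Tuple[int, int, int]) -> "StaggeredFlowState":
        Nx, Ny, Nz = N
        return cls(
            u=np.zeros((Nx + 1, Ny, Nz)),
            v=np.zeros((Nx, Ny + 1, Nz)),
            w=np.zeros((Nx, Ny, Nz + 1)),
            p=np.zeros((Nx, Ny, Nz)),
        )

    def copy(self) -> "StaggeredFlowState":
        return StaggeredFlowState(self.u.copy(), self.v.copy(), self.w.copy(),
                                  self.p.copy(), self.step, self.residual)

    def max_speed(self) -> float:
        return max(np.abs(self.u).max(), np.abs(self.v).max(),
                   np.abs(self.w).max())

    def cell_velocity(self):
        """Cell-centered velocity components by face averaging."""
        uc = 0.5 * (self.u[:-1] + self.u[1:])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        wc = 0.5 * (self.w[:, :, :-1] + self.w[:, :, 1:])
        return uc, vc, wc


def _face_component(state: StaggeredFlowState, axis: int) -> np.ndarray:
    return (state.u, state.v, state.w)[axis]


def _normal_sign(patch: BoundaryPatch, inflow: bool) -> float:
    """Sign of the face-normal velocity for flow entering (inflow) or
    leaving the domain through the patch."""
    into = 1.0 if not patch.is_plus else -1.0
    return into if inflow else -into


class FlowProblem:
    """Precomputed machinery for one geometry/config pair."""

    def __init__(self, grid: SolverGrid, chi: np.ndarray, config: FlowConfig):
        if chi.shape != tuple(grid.N):
            raise ValueError("chi shape must match grid cells")
        self.grid = grid
        self.chi = np.asarray(chi, dtype=np.float64)
        self.config = config
        self.h = grid.h
        self.lumen = self.chi < 0.5

        self.inlet_open = config.inlet.open_mask(self.lumen)
        self.outlet_open = config.outlet.open_mask(self.lumen)
        if not self.inlet_open.any():
            raise ValueError("inlet patch has no lumen overlap")
        if not self.outlet_open.any():
            raise ValueError("outlet patch has no lumen overlap")
        if config.inlet.face == config.outlet.face and \
                (self.inlet_open & self.outlet_open).any():
            raise ValueError("inlet and outlet patches overlap on the face")
        if config.check_connectivity:
            self._check_connectivity()

        # uniform outlet speed balancing the inlet flux exactly
        a_in = int(self.inlet_open.sum())
        a_out = int(self.outlet_open.sum())
        self.inlet_flux = self._patch_area(config.inlet) * a_in * 1.0
        self.U_out = self.inlet_flux / (self._patch_area(config.outlet) * a_out)

        self.chi_faces = chi_to_faces(self.chi)
        Nx, Ny, Nz = grid.N
        hx, hy, hz = self.h
        self._helm_u = HelmholtzSolver((Nx - 1, Ny, Nz), (hx, hy, hz),
                                       ("node", "cell-dirichlet", "cell-dirichlet"))
        self._helm_v = HelmholtzSolver((Nx, Ny - 1, Nz), (hx, hy, hz),
                                       ("cell-dirichlet", "node", "cell-dirichlet"))
        self._helm_w = HelmholtzSolver((Nx, Ny, Nz - 1), (hx, hy, hz),
                                       ("cell-dirichlet", "cell-dirichlet", "node"))
        self._poisson = NeumannPoissonSolver((Nx, Ny, Nz), (hx, hy, hz))
        self._var_poisson_cache = {}  # keyed by theta*dt_k*eta
        self._dp_prev = {}            # warm starts for the PCG projection

    def _patch_area(self, patch: BoundaryPatch) -> float:
        hx, hy, hz = self.h
        per = {0: hy * hz, 1: hx * hz, 2: hx * hy}
        return per[patch.axis]

    def _check_connectivity(self) -> None:
        labels, _ = ndimage.label(self.lumen)
        ax_i, ax_o = self.config.inlet.axis, self.config.outlet.axis
        lay_i = np.take(labels, -1 if self.config.inlet.is_plus else 0, axis=ax_i)
        lay_o = np.take(labels, -1 if self.config.outlet.is_plus else 0, axis=ax_o)
        lab_i = set(np.unique(lay_i[self.inlet_open])) - {0}
        lab_o = set(np.unique(lay_o[self.outlet_open])) - {0}
        if not (lab_i & lab_o):
            raise DisconnectedLumenError(
                "no connected lumen path between inlet and outlet patches")

    # -- boundary conditions -------------------------------------------------
    def boundary_values(self):
        """(face, component-slice assignments) for normal velocities."""
        out = []
        for patch, open_mask, speed, inflow in (
                (self.config.inlet, self.inlet_open, 1.0, True),
                (self.config.outlet, self.outlet_open, self.U_out, False)):
            sign = _normal_sign(patch, inflow)
            vals = np.where(open_mask, sign * speed, 0.0)
            out.append((patch, vals))
        return out

    def apply_bcs(self, state: StaggeredFlowState) -> StaggeredFlowState:
        # zero all boundary faces, then stamp the patches; patches sharing a
        # box face (e.g. inlet and outlet stubs both on y-) are accumulated
        # before assignment so one does not erase the other
        state.u[0] = 0.0
        state.u[-1] = 0.0
        state.v[:, 0] = 0.0
        state.v[:, -1] = 0.0
        state.w[:, :, 0] = 0.0
        state.w[:, :, -1] = 0.0
        combined = {}
        for patch, vals in self.boundary_values():
            key = (patch.axis, patch.is_plus)
            combined[key] = combined.get(key, 0.0) + vals
        for (axis, is_plus), vals in combined.items():
            comp = _face_component(state, axis)
            idx = -1 if is_plus else 0
            if axis == 0:
                comp[idx] = vals
            elif axis == 1:
                comp[:, idx] = vals
            else:
                comp[:, :, idx] = vals
        return state

    # -- one pseudo-time step ------------------------------------------------
    def step(self, state: StaggeredFlowState, dt: float) -> StaggeredFlowState:
        cfg = self.config
        h = self.h
        u, v, w, p = state.u, state.v, state.w, state.p
        conv_prev = None
        for k in range(3):
            gk, zk, ak = _GAMMA[k], _ZETA[k], _ALPHA[k]
            conv = convective_tendency(u, v, w, h)
            diff = diffusive_tendency(u, v, w, h, cfg.Re)
            pen = penalization_tendency(u, v, w, self.chi_faces, cfg.eta)
            gp = pressure_gradient(p, h)
            rhs = []
            for i in range(3):
                r = dt * (gk * conv[i] + ak * (diff[i] + pen[i] - gp[i]))
                if zk != 0.0:
                    r += dt * zk * conv_prev[i]
                rhs.append(r)
            conv_prev = conv
            a = cfg.theta * ak * dt
            cu, cv, cw = self.chi_faces
            c_visc = a / cfg.Re
            du = rhs[0][1:-1] / (1.0 + a * cfg.eta * cu[1:-1])
            du = self._helm_u.solve(du, c_visc)
            dv = rhs[1][:, 1:-1] / (1.0 + a * cfg.eta * cv[:, 1:-1])
            dv = self._helm_v.solve(dv, c_visc)
            dw = rhs[2][:, :, 1:-1] / (1.0 + a * cfg.eta * cw[:, :, 1:-1])
            dw = self._helm_w.solve(dw, c_visc)
            u = u.copy()
            v = v.copy()
            w = w.copy()
            u[1:-1] += du
            v[:, 1:-1] += dv
            w[:, :, 1:-1] += dw
            if cfg.project_every_substep or cfg.seepage_projection:
                # the mobility-weighted correction must match the substep's
                # implicit factor, so it is always applied per substep
                u, v, w, p = self._project(u, v, w, p, ak * dt)

        if not (cfg.project_every_substep or cfg.seepage_projection):
            # SMAC projection once, after the substep cycle
            u, v, w, p = self._project(u, v, w, p, dt)

        if not (np.isfinite(u).all() and np.isfinite(p).all()):
            raise SolverDiverged(
                f"non-finite values at step {state.step + 1} (dt={dt:g})")
        res = max(np.abs(u - state.u).max(), np.abs(v - state.v).max(),
                  np.abs(w - state.w).max()) / dt
        return StaggeredFlowState(u, v, w, p, step=state.step + 1, residual=res)

    def _beta_faces(self, a_eta: float):
        cu, cv, cw = self.chi_faces
        return (1.0 / (1.0 + a_eta * cu), 1.0 / (1.0 + a_eta * cv),
                1.0 / (1.0 + a_eta * cw))

    def _project(self, u, v, w, p, dtk):
        """SMAC correction: clean the divergence with a pure-Neumann Poisson
        solve and absorb the correction into the pressure.

        With ``seepage_projection`` the correction velocity is weighted by
        the face mobility ``beta = 1/(1 + theta dt eta chi)`` so the pressure
        adjusts through the penalized solid in one elliptic solve instead of
        creeping at the O(1/eta) Darcy rate; the steady state is unaffected
        (the correction vanishes there).
        """
        cfg = self.config
        h = self.h
        div = divergence(u, v, w, h)
        if cfg.seepage_projection:
            a_eta = cfg.theta * dtk * cfg.eta
            key = round(float(a_eta), 12)
            if key not in self._var_poisson_cache:
                self._var_poisson_cache[key] = VariableCoeffPoissonSolver(
                    self.grid.N, h, self._beta_faces(a_eta))
            vp = self._var_poisson_cache[key]
            # loose mobility-weighted solve handles the stiff solid coupling;
            # the exact constant-coefficient cleanup below enforces the
            # divergence to round-off regardless
            dp, _, _ = vp.solve(div / dtk, tol=max(cfg.poisson_tol, 1e-5),
                                maxiter=8, x0=self._dp_prev.get(key))
            self._dp_prev[key] = dp
            bu, bv, bw = vp.bu, vp.bv, vp.bw
            gx, gy, gz = pressure_gradient(dp, h)
            u[1:-1] -= dtk * bu[1:-1] * gx[1:-1]
            v[:, 1:-1] -= dtk * bv[:, 1:-1] * gy[:, 1:-1]
            w[:, :, 1:-1] -= dtk * bw[:, :, 1:-1] * gz[:, :, 1:-1]
            p = p + dp
            div = divergence(u, v, w, h)
        dp = self._poisson.solve(div / dtk)
        gx, gy, gz = pressure_gradient(dp, h)
        u[1:-1] -= dtk * gx[1:-1]
        v[:, 1:-1] -= dtk * gy[:, 1:-1]
        w[:, :, 1:-1] -= dtk * gz[:, :, 1:-1]
        p = p + dp
        p -= p.mean()
        return u, v, w, p

    def pick_dt(self) -> float:
        if self.config.dt is not None:
            return float(self.config.dt)
        return self.config.cfl * min(self.h) / self.config.u_ref


@dataclass
class SteadyFlowField:
    """Converged flow plus the geometry/config it was computed on."""

    state: StaggeredFlowState
    grid: SolverGrid
    chi: np.ndarray
    config: FlowConfig
    residual_history: List[float] = field(default_factory=list)
    converged: bool = True
    dt: float = np.nan

    @property
    def lumen(self) -> np.ndarray:
        return self.chi < 0.5

    def cell_velocity(self):
        return self.state.cell_velocity()

    def speed(self) -> np.ndarray:
        uc, vc, wc = self.cell_velocity()
        return np.sqrt(uc**2 + vc**2 + wc**2)

    def divergence(self) -> np.ndarray:
        return divergence(self.state.u, self.state.v, self.state.w, self.grid.h)

    def boundary_flux_imbalance(self) -> float:
        """|influx - outflux| / influx over all box faces."""
        hx, hy, hz = self.grid.h
        s = self.state
        net = (s.u[0].sum() - s.u[-1].sum()) * hy * hz \
            + (s.v[:, 0].sum() - s.v[:, -1].sum()) * hx * hz \
            + (s.w[:, :, 0].sum() - s.w[:, :, -1].sum()) * hx * hy
        influx = (np.clip(s.u[0], 0, None).sum() * hy * hz
                  + np.clip(-s.u[-1], 0, None).sum() * hy * hz
                  + np.clip(s.v[:, 0], 0, None).sum() * hx * hz
                  + np.clip(-s.v[:, -1], 0, None).sum() * hx * hz
                  + np.clip(s.w[:, :, 0], 0, None).sum() * hx * hy
                  + np.clip(-s.w[:, :, -1], 0, None).sum() * hx * hy)
        return abs(net) / influx if influx > 0 else 0.0

    def plane_flux(self, axis: int, index: int, mask2d: Optional[np.ndarray] = None) -> float:
        """Volumetric flux through one face plane (nondimensional)."""
        hx, hy, hz = self.grid.h
        comp = _face_component(self.state, axis)
        per = {0: hy * hz, 1: hx * hz, 2: hx * hy}[axis]
        plane = np.take(comp, index, axis=axis)
        if mask2d is not None:
            plane = np.where(mask2d, plane, 0.0)
        return float(plane.sum() * per)


def interpolate_state(state: StaggeredFlowState, grid_src: SolverGrid,
                      grid_dst: SolverGrid, zc_src: int, zc_dst: int
                      ) -> StaggeredFlowState:
    """Linearly interpolate a staggered state onto another grid of the same
    physical x-y footprint (z planes aligned through the mid-plane indices).

    Used to warm-start grid-refinement runs from a coarse solution; the
    first projection of the receiving solver restores a divergence-free
    field, so the interpolation only needs to be approximate.
    """
    from scipy.interpolate import RegularGridInterpolator

    def axes(grid, zc, staggered_axis):
        out = []
        for ax in range(3):
            n = grid.N[ax]
            d = grid.spacing[ax]
            if ax == staggered_axis:
                coords = np.arange(n + 1) * d
            else:
                coords = (np.arange(n) + 0.5) * d
            if ax == 2:
                coords = coords - (zc + 0.5) * grid.spacing[2]
            out.append(coords)
        return out

    def interp(comp, staggered_axis):
        src_axes = axes(grid_src, zc_src, staggered_axis)
        dst_axes = axes(grid_dst, zc_dst, staggered_axis)
        f = RegularGridInterpolator(src_axes, comp, bounds_error=False,
                                    fill_value=0.0)
        Xg, Yg, Zg = np.meshgrid(*dst_axes, indexing="ij")
        pts = np.stack([Xg.ravel(), Yg.ravel(), Zg.ravel()], axis=1)
        return f(pts).reshape(Xg.shape)

    return StaggeredFlowState(
        u=interp(state.u, 0), v=interp(state.v, 1), w=interp(state.w, 2),
        p=interp(state.p, -1),   # -1: all axes cell-centered
        step=0, residual=np.inf)


# -- spec-level functional wrappers -----------------------------------------

def apply_boundary_conditions(state: StaggeredFlowState,
                              problem: FlowProblem) -> StaggeredFlowState:
    return problem.apply_bcs(state)


def pressure_poisson_solve(rhs: np.ndarray, grid: SolverGrid,
                           tol: float = 1.0e-8) -> np.ndarray:
    """Solve Lap p = rhs (pure Neumann, zero-mean pinning) and verify the
    discrete residual against ``tol``."""
    solver = NeumannPoissonSolver(rhs.shape, grid.h)
    p = solver.solve(rhs)
    # a-posteriori residual check of the direct solve
    hx, hy, hz = grid.h
    pad = np.pad(p, 1, mode="edge")
    lap = ((pad[2:, 1:-1, 1:-1] - 2 * p + pad[:-2, 1:-1, 1:-1]) / hx**2
           + (pad[1:-1, 2:, 1:-1] - 2 * p + pad[1:-1, :-2, 1:-1]) / hy**2
           + (pad[1:-1, 1:-1, 2:] - 2 * p + pad[1:-1, 1:-1, :-2]) / hz**2)
    rhs0 = rhs - rhs.mean()
    scale = np.linalg.norm(rhs0.ravel())
    if scale > 0 and np.linalg.norm((lap - rhs0).ravel()) / scale > tol:
        raise RuntimeError("Poisson solve failed the residual check")
    return p


def time_step(state: StaggeredFlowState, problem: FlowProblem,
              dt: Optional[float] = None) -> StaggeredFlowState:
    return problem.step(state, dt if dt is not None else problem.pick_dt())


def run_to_steady_state(problem: FlowProblem,
                        initial: Optional[StaggeredFlowState] = None,
                        verbose: bool = False) -> SteadyFlowField:
    """March the pseudo-time iteration until the residual
    ``max|u^{n+1}-u^n|/dt`` stays below ``steady_tol`` for ``steady_hold``
    consecutive steps (or ``max_steps`` is hit, with a warning)."""
    cfg = problem.config
    state = initial.copy() if initial is not None else \
        StaggeredFlowState.zeros(problem.grid.N)
    problem.apply_bcs(state)
    dt = problem.pick_dt()
    history: List[float] = []
    hold = 0
    converged = False
    for _ in range(cfg.max_steps):
        state = problem.step(state, dt)
        history.append(state.residual)
        if verbose and state.step % cfg.log_every == 0:
            print(f"  step {state.step:6d}  residual {state.residual:.3e}")
        if state.residual <= cfg.steady_tol:
            hold += 1
            if hold >= cfg.steady_hold:
                converged = True
                break
        else:
            hold = 0
    if not converged:
        warnings.warn(
            f"steady state not reached in {cfg.max_steps} steps "
            f"(residual {state.residual:.3e} > {cfg.steady_tol:g})",
            RuntimeWarning, stacklevel=2)
    return SteadyFlowField(state=state, grid=problem.grid, chi=problem.chi,
                           config=cfg, residual_history=history,
                           converged=converged, dt=dt)
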
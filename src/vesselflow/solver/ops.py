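"""Staggered-grid spatial operators (uniform mesh, nondimensional).

Array layout: cells (Nx, Ny, Nz); u on x-faces (Nx+1, Ny, Nz), v on y-faces
(Nx, Ny+1, Nz), w on z-faces (Nx, Ny, Nz+1), pressure at cell centers.
Boundary faces hold the imposed velocities; tangential wall values are zero
and are realized through reflection ghosts (``f_ghost = -f_first``), so the
wall-parallel velocity vanishes exactly at the wall plane.

Tendencies are evaluated at interior faces only (boundary faces are fixed
by the BCs) and returned embedded in full-size arrays.

Convection uses the energy-conservative divergence form with midpoint
interpolation; diffusion the standard 7-point Laplacian; penalization the
pointwise body force ``-eta * chi_face * f``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "convective_tendency",
    "diffusive_tendency",
    "penalization_tendency",
    "divergence",
    "chi_to_faces",
    "pressure_gradient",
]

def _pad_tangential(f: np.ndarray) -> np.ndarray:
    """Reflection ghosts in axes 1 and 2 (wall-parallel value -> 0 at wall)."""
    fp = np.empty((f.shape[0], f.shape[1] + 2, f.shape[2] + 2), dtype=f.dtype)
    fp[:, 1:-1, 1:-1] = f
    fp[:, 0, 1:-1] = -f[:, 0, :]
    fp[:, -1, 1:-1] = -f[:, -1, :]
    fp[:, 1:-1, 0] = -f[:, :, 0]
    fp[:, 1:-1, -1] = -f[:, :, -1]
    # corners are never used by the 7-point/edge stencils; fill for safety
    fp[:, 0, 0] = fp[:, 0, -1] = fp[:, -1, 0] = fp[:, -1, -1] = 0.0
    return fp


def _conv_component(f: np.ndarray, g: np.ndarray, q: np.ndarray,
                    h: Sequence[float]) -> np.ndarray:
    """Divergence-form convection for the component normal to axis 0.

    f: (Na+1, Nb, Nc); g: (Na, Nb+1, Nc); q: (Na, Nb, Nc+1).
    Returns the full-size tendency with zeros on boundary faces.
    """
    ha, hb, hc = h
    out = np.zeros_like(f)

    # d/da (favg^2): favg at cell centers
    favg = 0.5 * (f[:-1] + f[1:])
    fa2 = favg * favg
    out[1:-1] -= (fa2[1:] - fa2[:-1]) / ha

    # d/db (gbar * fbar): edge values at (interior a-face, b-face)
    gbar = 0.5 * (g[:-1] + g[1:])                     # (Na-1, Nb+1, Nc)
    fpb = np.empty((f.shape[0], f.shape[1] + 2, f.shape[2]), dtype=f.dtype)
    fpb[:, 1:-1] = f
    fpb[:, 0] = -f[:, 0]
    fpb[:, -1] = -f[:, -1]
    fbar_b = 0.5 * (fpb[1:-1, :-1] + fpb[1:-1, 1:])   # (Na-1, Nb+1, Nc)
    eb = gbar * fbar_b
    out[1:-1] -= (eb[:, 1:] - eb[:, :-1]) / hb

    # d/dc (qbar * fbar)
    qbar = 0.5 * (q[:-1] + q[1:])                     # (Na-1, Nb, Nc+1)
    fpc = np.empty((f.shape[0], f.shape[1], f.shape[2] + 2), dtype=f.dtype)
    fpc[:, :, 1:-1] = f
    fpc[:, :, 0] = -f[:, :, 0]
    fpc[:, :, -1] = -f[:, :, -1]
    fbar_c = 0.5 * (fpc[1:-1, :, :-1] + fpc[1:-1, :, 1:])
    ec = qbar * fbar_c
    out[1:-1] -= (ec[:, :, 1:] - ec[:, :, :-1]) / hc
    return out


def convective_tendency(u: np.ndarray, v: np.ndarray, w: np.ndarray,
                        h: Sequence[float]):
    """(du, dv, dw) from -div(u u) at interior faces."""
    hx, hy, hz = h
    du = _conv_component(u, v, w, (hx, hy, hz))
    dv = _conv_component(v.transpose(1, 0, 2), u.transpose(1, 0, 2),
                         w.transpose(1, 0, 2), (hy, hx, hz)).transpose(1, 0, 2)
    dw = _conv_component(w.transpose(2, 0, 1), u.transpose(2, 0, 1),
                         v.transpose(2, 0, 1), (hz, hx, hy)).transpose(1, 2, 0)
    return du, dv, dw


def _lap_component(f: np.ndarray, h: Sequence[float]) -> np.ndarray:
    ha, hb, hc = h
    fp = _pad_tangential(f)
    out = np.zeros_like(f)
    out[1:-1] += (f[2:] - 2.0 * f[1:-1] + f[:-2]) / ha**2
    core = fp[1:-1, :, 1:-1]
    out[1:-1] += (core[:, 2:] - 2.0 * core[:, 1:-1] + core[:, :-2]) / hb**2
    core = fp[1:-1, 1:-1, :]
    out[1:-1] += (core[:, :, 2:] - 2.0 * core[:, :, 1:-1] + core[:, :, :-2]) / hc**2
    return out


def diffusive_tendency(u, v, w, h, Re: float):
    """(du, dv, dw) = Lap(u)/Re at interior faces."""
    hx, hy, hz = h
    du = _lap_component(u, (hx, hy, hz)) / Re
    dv = _lap_component(v.transpose(1, 0, 2), (hy, hx, hz)).transpose(1, 0, 2) / Re
    dw = _lap_component(w.transpose(2, 0, 1), (hz, hx, hy)).transpose(1, 2, 0) / Re
    return du, dv, dw


def chi_to_faces(chi: np.ndarray):
    """Arithmetic average of the cell-centered solid fraction to the three
    face families; boundary faces copy the adjacent cell."""
    Nx, Ny, Nz = chi.shape
    cu = np.empty((Nx + 1, Ny, Nz))
    cu[1:-1] = 0.5 * (chi[:-1] + chi[1:])
    cu[0], cu[-1] = chi[0], chi[-1]
    cv = np.empty((Nx, Ny + 1, Nz))
    cv[:, 1:-1] = 0.5 * (chi[:, :-1] + chi[:, 1:])
    cv[:, 0], cv[:, -1] = chi[:, 0], chi[:, -1]
    cw = np.empty((Nx, Ny, Nz + 1))
    cw[:, :, 1:-1] = 0.5 * (chi[:, :, :-1] + chi[:, :, 1:])
    cw[:, :, 0], cw[:, :, -1] = chi[:, :, 0], chi[:, :, -1]
    return cu, cv, cw


def penalization_tendency(u, v, w, chi_faces, eta: float):
    """(du, dv, dw) = -eta * chi_face * velocity, interior faces only."""
    if eta <= 0:
        raise ValueError("eta must be positive")
    cu, cv, cw = chi_faces
    du = np.zeros_like(u)
    dv = np.zeros_like(v)
    dw = np.zeros_like(w)
    du[1:-1] = -eta * cu[1:-1] * u[1:-1]
    dv[:, 1:-1] = -eta * cv[:, 1:-1] * v[:, 1:-1]
    dw[:, :, 1:-1] = -eta * cw[:, :, 1:-1] * w[:, :, 1:-1]
    return du, dv, dw


def divergence(u, v, w, h) -> np.ndarray:
    """Cell-centered discrete divergence (uses boundary faces as imposed)."""
    hx, hy, hz = h
    return (u[1:] - u[:-1]) / hx + (v[:, 1:] - v[:, :-1]) / hy \
        + (w[:, :, 1:] - w[:, :, :-1]) / hz


def pressure_gradient(p: np.ndarray, h):
    """(dpdx, dpdy, dpdz) at interior faces, zeros on boundary faces."""
    hx, hy, hz = h
    Nx, Ny, Nz = p.shape
    gx = np.zeros((Nx + 1, Ny, Nz))
    gx[1:-1] = (p[1:] - p[:-1]) / hx
    gy = np.zeros((Nx, Ny + 1, Nz))
    gy[:, 1:-1] = (p[:, 1:] - p[:, :-1]) / hy
    gz = np.zeros((Nx, Ny, Nz + 1))
    gz[:, :, 1:-1] = (p[:, :, 1:] - p[:, :, :-1]) / hz
    return gx, gy, gz
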
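"""Fast direct solvers for the constant-coefficient implicit systems.

On a uniform staggered grid with the boundary conventions used here
(velocity fixed on box faces, zero-gradient pressure), the 1D second-
difference operators are diagonalized by discrete sine/cosine transforms:

* ``node`` axis (a velocity component along its own axis; unknowns at
  interior faces, Dirichlet values at the two boundary faces): DST-I.
* ``cell-dirichlet`` axis (a velocity component across the other axes;
  unknowns at cell centers, wall value enforced by reflection ghost
  ``u[-1] = -u[0]``): DST-II.
* ``cell-neumann`` axis (pressure; mirror ghost ``p[-1] = p[0]``): DCT-II.

A 3D Helmholtz solve ``(I - c Lap) x = b`` (or the pure-Neumann Poisson)
is then two sets of axis transforms around a diagonal division — exact to
round-off, so the projection leaves per-cell divergence at machine level.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy import fft as sfft

__all__ = ["HelmholtzSolver", "NeumannPoissonSolver",
           "VariableCoeffPoissonSolver", "laplacian_eigenvalues"]


def laplacian_eigenvalues(n: int, h: float, kind: str) -> np.ndarray:
    """Eigenvalues (all <= 0) of the 1D second-difference operator."""
    if kind == "node":          # DST-I, unknowns 1..N-1 of an N-cell axis
        m = np.arange(1, n + 1)
        big = n + 1
    elif kind == "cell-dirichlet":   # DST-II
        m = np.arange(1, n + 1)
        big = n
    elif kind == "cell-neumann":     # DCT-II
        m = np.arange(0, n)
        big = n
    else:
        raise ValueError(f"unknown axis kind {kind!r}")
    return -(4.0 / h**2) * np.sin(np.pi * m / (2.0 * big)) ** 2


_FWD = {"node": (sfft.dst, 1), "cell-dirichlet": (sfft.dst, 2),
        "cell-neumann": (sfft.dct, 2)}
_INV = {"node": (sfft.idst, 1), "cell-dirichlet": (sfft.idst, 2),
        "cell-neumann": (sfft.idct, 2)}


def _transform(x: np.ndarray, kinds: Sequence[str], table) -> np.ndarray:
    for axis, kind in enumerate(kinds):
        func, typ = table[kind]
        x = func(x, type=typ, axis=axis, norm="ortho")
    return x


class HelmholtzSolver:
    """Exact solver for ``(I - c Lap) x = b`` with homogeneous BCs.

    ``kinds`` gives the per-axis boundary flavor ('node' or
    'cell-dirichlet'); ``h`` the per-axis spacing. The eigenvalue grid is
    precomputed once; each solve costs two 3D transforms.
    """

    def __init__(self, shape: Tuple[int, ...], h: Sequence[float],
                 kinds: Sequence[str]):
        if len(shape) != len(h) or len(shape) != len(kinds):
            raise ValueError("shape, h and kinds must have equal length")
        self.shape = tuple(shape)
        self.kinds = tuple(kinds)
        lams = []
        for n, hh, kind in zip(shape, h, kinds):
            lam = laplacian_eigenvalues(n, hh, kind)
            if lam.size != n:
                raise AssertionError("eigenvalue count mismatch")
            lams.append(lam)
        lam3 = lams[0][:, None, None] + lams[1][None, :, None] \
            + lams[2][None, None, :]
        self._lam3 = lam3

    def solve(self, b: np.ndarray, c: float) -> np.ndarray:
        if b.shape != self.shape:
            raise ValueError(f"rhs shape {b.shape} != {self.shape}")
        xh = _transform(b, self.kinds, _FWD)
        xh /= (1.0 - c * self._lam3)
        return _transform(xh, self.kinds, _INV)


class NeumannPoissonSolver:
    """Exact solver for ``Lap p = rhs`` with zero-gradient walls.

    Pure Neumann: the mean of the rhs is removed for compatibility and the
    solution is pinned to zero mean.
    """

    def __init__(self, shape: Tuple[int, ...], h: Sequence[float]):
        self.shape = tuple(shape)
        self.kinds = ("cell-neumann",) * len(shape)
        lams = [laplacian_eigenvalues(n, hh, "cell-neumann")
                for n, hh in zip(shape, h)]
        lam3 = lams[0][:, None, None] + lams[1][None, :, None] \
            + lams[2][None, None, :]
        lam3 = lam3.copy()
        lam3.flat[0] = 1.0  # zero mode pinned; numerator zeroed in solve
        self._lam3 = lam3

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        if rhs.shape != self.shape:
            raise ValueError(f"rhs shape {rhs.shape} != {self.shape}")
        rhs = rhs - rhs.mean()
        xh = _transform(rhs, self.kinds, _FWD)
        xh.flat[0] = 0.0
        xh /= self._lam3
        return _transform(xh, self.kinds, _INV)


class VariableCoeffPoissonSolver:
    """PCG solver for ``div(beta grad p) = rhs`` with zero-flux walls.

    ``beta`` is given on the three face families (face-normal mobility).
    Preconditioned with the constant-coefficient DCT Poisson solver, which
    handles the smooth spectrum; the high-contrast penalized-solid faces are
    what the CG iterations resolve. Pure Neumann: compatibility enforced by
    mean removal, solution pinned to zero mean.
    """

    def __init__(self, shape, h, beta_faces):
        self.shape = tuple(shape)
        self.h = tuple(h)
        self.bu, self.bv, self.bw = beta_faces
        self._mprec = NeumannPoissonSolver(shape, h)

    def apply(self, p: np.ndarray) -> np.ndarray:
        hx, hy, hz = self.h
        out = np.zeros_like(p)
        fx = self.bu[1:-1] * (p[1:] - p[:-1]) / hx
        out[:-1] += fx / hx
        out[1:] -= fx / hx
        fy = self.bv[:, 1:-1] * (p[:, 1:] - p[:, :-1]) / hy
        out[:, :-1] += fy / hy
        out[:, 1:] -= fy / hy
        fz = self.bw[:, :, 1:-1] * (p[:, :, 1:] - p[:, :, :-1]) / hz
        out[:, :, :-1] += fz / hz
        out[:, :, 1:] -= fz / hz
        return out

    def solve(self, rhs: np.ndarray, tol: float = 1.0e-8,
              maxiter: int = 500, x0: np.ndarray | None = None):
        """Returns (p, relative_residual, n_iterations)."""
        b = rhs - rhs.mean()
        bnorm = float(np.linalg.norm(b))
        if bnorm == 0.0:
            return np.zeros_like(b), 0.0, 0
        x = np.zeros_like(b) if x0 is None else x0 - x0.mean()
        r = b - self.apply(x)
        z = self._mprec.solve(r)
        d = z.copy()
        rz = float((r * z).sum())
        it = 0
        for it in range(1, maxiter + 1):
            Ad = self.apply(d)
            dAd = float((d * Ad).sum())
            if dAd == 0.0:
                break
            alpha = rz / dAd
            x += alpha * d
            r -= alpha * Ad
            rn = float(np.linalg.norm(r))
            if rn <= tol * bnorm:
                break
            z = self._mprec.solve(r)
            rz_new = float((r * z).sum())
            d = z + (rz_new / rz) * d
            rz = rz_new
        x -= x.mean()
        return x, float(np.linalg.norm(b - self.apply(x))) / bnorm, it
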
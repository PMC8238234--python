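"""Minimal writers for legacy ASCII VTK structured points and flat arrays.

The legacy VTK format is plain text and renders directly in ParaView; only
the subset needed here (scalars and one vector field on a uniform grid) is
implemented.
"""

from __future__ import annotations

import os
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

__all__ = ["write_structured_points", "write_array_with_header", "read_array_with_header"]


def write_structured_points(
    path: str | os.PathLike,
    spacing: Sequence[float],
    scalars: Optional[Dict[str, np.ndarray]] = None,
    vectors: Optional[Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]] = None,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> None:
    """Write point-sampled fields on a uniform grid as legacy ASCII VTK.

    All arrays must share one (nx, ny, nz) shape; VTK expects x varying
    fastest, which for C-ordered (x, y, z) arrays means transposing before
    ``ravel``.
    """
    scalars = scalars or {}
    vectors = vectors or {}
    shapes = [a.shape for a in scalars.values()]
    shapes += [c[0].shape for c in vectors.values()]
    if not shapes:
        raise ValueError("nothing to write")
    shape = shapes[0]
    if any(s != shape for s in shapes):
        raise ValueError("all fields must share one shape")
    nx, ny, nz = shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("vesselflow field export\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]:.9g} {origin[1]:.9g} {origin[2]:.9g}\n")
        fh.write(f"SPACING {spacing[0]:.9g} {spacing[1]:.9g} {spacing[2]:.9g}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in scalars.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr.transpose(2, 1, 0).ravel()[:, None], fmt="%.9g")
        for name, (ax, ay, az) in vectors.items():
            fh.write(f"VECTORS {name} double\n")
            stacked = np.stack(
                [c.transpose(2, 1, 0).ravel() for c in (ax, ay, az)], axis=1)
            np.savetxt(fh, stacked, fmt="%.9g")


def write_array_with_header(path: str | os.PathLike, arr: np.ndarray,
                            spacing: Sequence[float],
                            z_center_index: int = 0) -> None:
    """Flat text dump with a one-line header (shape, spacing, z index)."""
    arr = np.asarray(arr)
    with open(path, "w") as fh:
        shape = " ".join(str(s) for s in arr.shape)
        sp = " ".join(f"{s:.9g}" for s in spacing)
        fh.write(f"# shape {shape} spacing {sp} z_center_index {z_center_index}\n")
        np.savetxt(fh, arr.ravel()[:, None], fmt="%.9g")


def read_array_with_header(path: str | os.PathLike):
    """Inverse of :func:`write_array_with_header`; returns (array, spacing,
    z_center_index)."""
    with open(path) as fh:
        header = fh.readline().split()
        i_sh = header.index("shape") + 1
        i_sp = header.index("spacing") + 1
        i_z = header.index("z_center_index") + 1
        shape = tuple(int(x) for x in header[i_sh:i_sp - 1])
        spacing = tuple(float(x) for x in header[i_sp:i_z - 1])
        zc = int(header[i_z])
        data = np.loadtxt(fh)
    return data.reshape(shape), spacing, zc
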
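"""End-to-end pipeline: mask -> morphometry -> 3D reconstruction ->
steady penalized flow -> azimuthal transport report.

Each run writes a self-describing directory: input config echo + hash,
morphometry and per-region flow CSVs, residual history, and optional VTK
fields for rendering.
"""

from __future__ import annotations

import json
import os
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (AzimuthalFlowReport, CylindricalFrame,
                       azimuthal_flow_rate, partition_regions, to_cylindrical)
from .config import PipelineConfig, dump_config
from .morphometry import VesselMask2D, load_mask, morphometry_report
from .reconstruct import (build_occupancy, compute_level_set,
                          local_radius_field, solid_indicator)
from .solver import FlowConfig, FlowProblem, make_grid, run_to_steady_state
from .vtkio import write_structured_points

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    out_dir: Path
    morphometry: "pd.DataFrame"
    flow_report: AzimuthalFlowReport
    converged: bool
    residual: float


def _estimate_inlet_diameter(radius_um: np.ndarray) -> float:
    # the feeding artery is the widest vessel in the wedge
    return 2.0 * float(radius_um.max())


def wedge_config(spec, spacing: float, **overrides) -> PipelineConfig:
    """PipelineConfig wired for a synthetic wedge network: boundary patches
    around the inlet/outlet stubs, the cylindrical frame at the wedge origin
    and the artery/vein ray angles."""
    from .synthetic import wedge_frame_hint

    hint = wedge_frame_hint(spec)
    half_w = spec.inlet_diameter  # generous window around each stub
    # windows must not overlap (overlapping patches would stamp conflicting
    # boundary values): clamp each at the midpoint between the two stubs
    mid = 0.5 * (hint["inlet_x"] + hint["outlet_x"])
    lo_stub = min(hint["inlet_x"], hint["outlet_x"])

    def span(x_um):
        if x_um == lo_stub:   # left stub: window capped at the midpoint
            lo, hi = x_um - half_w, min(x_um + half_w, mid)
            return (max(int(lo / spacing), 0), int(hi / spacing))
        lo, hi = max(x_um - half_w, mid), x_um + half_w
        return (int(np.ceil(lo / spacing)), int(np.ceil(hi / spacing)))

    kw = dict(
        pixel_size=spec.pixel_size,
        spacing=spacing,
        D_in=spec.inlet_diameter,
        inlet_face="y-", inlet_span=span(hint["inlet_x"]),
        outlet_face="y-", outlet_span=span(hint["outlet_x"]),
        origin=hint["origin"],
        theta_artery=hint["theta_artery"],
        theta_vein=hint["theta_vein"],
        seed=spec.seed,
    )
    kw.update(overrides)
    return PipelineConfig(**kw)


def run_pipeline(config: PipelineConfig, out_dir: str | os.PathLike,
                 mask: Optional[VesselMask2D] = None,
                 verbose: bool = False) -> PipelineResult:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        if verbose:
            print(f"[{name}]")

    try:
        stage("morphometry")
        if mask is None:
            if config.mask_path is None:
                raise ValueError("config.mask_path or an in-memory mask required")
            mask = load_mask(config.mask_path, pixel_size=config.pixel_size,
                             threshold=config.threshold, otsu=config.otsu)
        rep = morphometry_report(mask)
        morpho = pd.DataFrame([rep.to_row(sample_id=str(config.mask_path or "in-memory"))])
        morpho.to_csv(out / "morphometry.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"[stage: morphometry] {exc}") from exc

    try:
        stage("reconstruction")
        rad = local_radius_field(mask)
        occ = build_occupancy(rad, spacing=config.spacing)
        ls = compute_level_set(occ)
        chi = solid_indicator(ls, smoothing_width=config.smoothing_width)
        d_in = config.D_in or _estimate_inlet_diameter(rad.r)
    except Exception as exc:
        raise RuntimeError(f"[stage: reconstruction] {exc}") from exc

    try:
        stage("solve")
        grid = make_grid(occ, D_in_star=d_in)
        fcfg = FlowConfig(inlet=config.inlet_patch(), outlet=config.outlet_patch(),
                          Re=config.Re, eta=config.eta, cfl=config.cfl,
                          dt=config.dt, steady_tol=config.steady_tol,
                          poisson_tol=config.poisson_tol,
                          max_steps=config.max_steps)
        problem = FlowProblem(grid, chi.chi, fcfg)
        flow = run_to_steady_state(problem, verbose=verbose)
        np.savetxt(out / "residual_history.txt",
                   np.asarray(flow.residual_history))
    except Exception as exc:
        raise RuntimeError(f"[stage: solve] {exc}") from exc

    try:
        stage("analysis")
        if config.origin is None:
            raise ValueError("analysis origin must be set in the config")
        frame = CylindricalFrame(origin=tuple(config.origin),
                                 theta_artery=config.theta_artery,
                                 theta_vein=config.theta_vein)
        u_r, u_t = to_cylindrical(flow, frame)
        part = partition_regions(occ, frame, fractions=config.fractions)
        report = azimuthal_flow_rate(u_t, part, flow)
        pd.DataFrame(report.as_rows()).to_csv(out / "azimuthal_flow.csv",
                                              index=False)
    except Exception as exc:
        raise RuntimeError(f"[stage: analysis] {exc}") from exc

    if config.write_vtk:
        stage("export")
        uc, vc, wc = flow.cell_velocity()
        speed = flow.speed()
        log_speed = np.log10(np.maximum(speed, 1e-16))
        write_structured_points(
            out / "fields.vtk", spacing=grid.spacing,
            scalars={"chi": chi.chi, "phi": ls.phi, "log10_speed": log_speed,
                     "u_theta": u_t, "region": part.labels.astype(float)},
            vectors={"velocity": (uc, vc, wc)})
    if config.write_png:
        _render_png(out / "speed_midplane.png", flow, part, occ)

    dump_config(config, out / "config.yaml")
    provenance = {
        "config_digest": config.digest(),
        "vesselflow_version": __version__,
        "numpy_version": np.__version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "converged": bool(flow.converged),
        "final_residual": float(flow.state.residual),
        "grid_N": list(grid.N),
        "D_in_um": d_in,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))

    return PipelineResult(out_dir=out, morphometry=morpho, flow_report=report,
                          converged=flow.converged,
                          residual=float(flow.state.residual))


def _render_png(path, flow, part, occ) -> None:
    """Midplane log-speed map with the region partition overlay."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    zc = occ.z_center_index
    speed = flow.speed()[:, :, zc].T
    lumen = flow.lumen[:, :, zc].T
    img = np.where(lumen, np.log10(np.maximum(speed, 1e-12)), np.nan)
    fig, ax = plt.subplots(figsize=(6, 6))
    m = ax.imshow(img, origin="lower", cmap="inferno", vmin=-4, vmax=0.5)
    ax.contour(part.labels[:, :, zc].T, levels=np.arange(part.n_regions) - 0.5,
               colors="cyan", linewidths=0.6)
    fig.colorbar(m, ax=ax, label="log10 |u| / U_in")
    ax.set_title("midplane speed")
    fig.savefig(path, dpi=150)
    plt.close(fig)
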
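"""Configuration-driven orchestration: geometry -> flow -> fields -> tracing
-> deposition report, with reproducible provenance on disk.

Each stage can also be run on its own (see :mod:`nasomag.cli`); ``run``
executes everything into an output directory.  The flow solution depends
only on the geometry and flow parameters, so it is computed once and shared
by every magnet protocol.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .airflow import solve_flow
from .config import RunConfig
from .deposition import compare_protocols, run_protocols
from .geometry import build_surrogate
from .io import write_states_csv, write_vtk_structured_points
from .magnetics import grad_B_map, protocol_layout
from .tracing import PROTOCOL_RELEASE_OFFSETS

log = logging.getLogger("nasomag")

__all__ = ["run", "export_flow", "export_gradB"]


def export_flow(domain, flow, outdir: Path):
    """Cell-centred velocity/pressure as CSV and legacy VTK."""
    ny, nz = domain.shape
    uc = 0.5 * (flow.u[1:, :] + flow.u[:-1, :])
    wc = 0.5 * (flow.w[:, 1:] + flow.w[:, :-1])
    y, z = domain.cell_centers()
    yy, zz = np.meshgrid(y, z, indexing="ij")
    import pandas as pd

    m = domain.mask
    pd.DataFrame(
        {
            "y": yy[m], "z": zz[m],
            "vy": uc[m], "vz": wc[m], "p": flow.p[m],
        }
    ).to_csv(outdir / "flow.csv", index=False, float_format="%.9g")
    speed = np.where(m, np.hypot(uc, wc), 0.0)
    write_vtk_structured_points(
        outdir / "flow.vtk", domain.origin, domain.grid_spacing,
        {"speed": speed, "pressure": np.where(m, flow.p, 0.0),
         "velocity": np.where(m[..., None], np.stack([uc, wc], axis=-1), 0.0)},
    )


def export_gradB(domain, config: RunConfig, outdir: Path):
    """Per-protocol |grad|B|| maps on the domain grid (CSV + VTK)."""
    import pandas as pd

    for proto in config.protocols:
        magnets = protocol_layout(proto, distance=config.magnet_distance,
                                  center_yz=config.magnet_center_yz)
        dx = PROTOCOL_RELEASE_OFFSETS[proto][1]
        y, z, g = grad_B_map(domain, magnets, x_offset=dx)
        yy, zz = np.meshgrid(y, z, indexing="ij")
        pd.DataFrame(
            {"y": yy.ravel(), "z": zz.ravel(), "gradB": g.ravel()}
        ).to_csv(outdir / f"gradB_protocol{proto}.csv", index=False,
                 float_format="%.9g")
        write_vtk_structured_points(
            outdir / f"gradB_protocol{proto}.vtk", domain.origin,
            domain.grid_spacing, {"gradB": g},
        )


def _plot_overview(domain, flow, config, outdir):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .geometry import RegionLabel
    from .magnetics import protocol_layout
    from .tracing import default_release, release_line, trace

    fig, axes = plt.subplots(1, len(config.protocols), figsize=(
        4.2 * len(config.protocols), 4), squeeze=False)
    for ax, proto in zip(axes[0], config.protocols):
        for a, b, lab in zip(domain.seg_a, domain.seg_b, domain.seg_label):
            color = {RegionLabel.OLFACTORY: "tab:red",
                     RegionLabel.INLET: "tab:green",
                     RegionLabel.OUTLET: "tab:blue"}.get(RegionLabel(int(lab)),
                                                         "0.3")
            ax.plot([a[0], b[0]], [a[1], b[1]], color=color, lw=1.5)
        magnets = protocol_layout(proto, distance=config.magnet_distance,
                                  center_yz=config.magnet_center_yz)
        spec = default_release(domain, proto, count=min(
            20, config.particle_count), line_length=config.release_length)
        parts = release_line(spec, domain)
        cfg = type(config.trace)(dt=config.trace.dt,
                                 dt_factor=config.trace.dt_factor,
                                 t_max=config.trace.t_max,
                                 trajectory_stride=10,
                                 force_mode=config.trace.force_mode)
        done = trace(parts, flow, magnets, domain, config.particle, cfg,
                     x_offset=spec.x_offset)
        for s in done:
            if s.trajectory is not None:
                ax.plot(s.trajectory[:, 0], s.trajectory[:, 1],
                        color="tab:red", lw=0.5, alpha=0.6)
        ax.set_title(f"protocol {proto}")
        ax.set_xlabel("y [m]")
        ax.set_aspect("equal")
    axes[0][0].set_ylabel("z [m]")
    fig.tight_layout()
    fig.savefig(outdir / "trajectories.png", dpi=130)
    plt.close(fig)


def run(config: RunConfig, outdir, make_figures: bool = True) -> dict:
    """Run the full pipeline and write all artifacts into ``outdir``.

    Returns the provenance record.  Deterministic: re-running the same
    config into a fresh directory reproduces byte-identical CSV outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings = {}

    log.info("building surrogate geometry")
    domain = build_surrogate(config.geometry)
    domain.to_json(outdir / "domain.json")
    timings["geometry_s"] = time.time() - t0

    log.info("solving steady airflow")
    t1 = time.time()
    flow = solve_flow(domain, config.flow)
    timings["flow_s"] = time.time() - t1
    export_flow(domain, flow, outdir)

    log.info("exporting magnetic gradient maps")
    t1 = time.time()
    export_gradB(domain, config, outdir)
    timings["fields_s"] = time.time() - t1

    log.info("tracing protocols %s", config.protocols)
    t1 = time.time()
    results = run_protocols(config, domain, flow)
    timings["trace_s"] = time.time() - t1

    rows = []
    for summary, states in results:
        (outdir / f"summary_protocol{summary.protocol}.json").write_text(
            json.dumps(summary.to_dict(), indent=2)
        )
        write_states_csv(outdir / f"states_protocol{summary.protocol}.csv",
                         states)
        row = {"protocol": summary.protocol,
               "n_released": summary.n_released,
               "delivery_efficiency_pct": summary.delivery_efficiency}
        row.update({f"n_{k.lower()}": v
                    for k, v in summary.status_counts.items()})
        row.update({f"n_on_{k.lower()}": v
                    for k, v in summary.region_counts.items()})
        rows.append(row)
    import pandas as pd

    table = pd.DataFrame(rows)
    table.to_csv(outdir / "comparison.csv", index=False, float_format="%.9g")

    if make_figures:
        try:
            _plot_overview(domain, flow, config, outdir)
        except Exception as exc:  # noqa: BLE001 - figures are best-effort
            log.warning("figure generation failed: %s", exc)

    provenance = {
        "package": "nasomag",
        "version": __version__,
        "config_hash": config.content_hash(),
        "config": config.to_dict(),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "wall_time_s": round(time.time() - t0, 3),
        "flow_iterations": int(len(flow.residual_history)),
        "flow_final_residual": float(flow.residual_history[-1]),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    config.to_yaml(outdir / "config.yaml")
    return provenance
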
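"""Plain-text exporters: CSV tables, legacy-ASCII VTK grids, figures."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["write_vtk_structured_points", "states_to_frame", "write_states_csv"]


def write_vtk_structured_points(path, origin, spacing, point_data: dict):
    """Write 2-D scalar/vector fields as a legacy-ASCII VTK structured grid.

    ``point_data`` maps names to (ny, nz) scalar arrays or (ny, nz, 2)
    vector arrays laid out on the yz-plane.
    """
    first = next(iter(point_data.values()))
    ny, nz = first.shape[:2]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nnasomag field export\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {ny} {nz} 1\n")
        fh.write(f"ORIGIN 0.0 {origin[0]} {origin[1]}\n")
        fh.write(f"SPACING 1.0 {spacing} {spacing}\n")
        fh.write(f"POINT_DATA {ny * nz}\n")
        for name, arr in point_data.items():
            if arr.ndim == 2:
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for j in range(nz):
                    fh.write(" ".join(f"{v:.6e}" for v in arr[:, j]) + "\n")
            else:
                fh.write(f"VECTORS {name} float\n")
                for j in range(nz):
                    for i in range(ny):
                        fh.write(f"0.0 {arr[i, j, 0]:.6e} {arr[i, j, 1]:.6e}\n")


def states_to_frame(states) -> pd.DataFrame:
    """Terminal particle states as a tidy table."""
    return pd.DataFrame(
        {
            "particle_id": [s.particle_id for s in states],
            "status": [s.status.name for s in states],
            "region": [s.region.name if s.region is not None else "" for s in states],
            "y": [s.position[0] for s in states],
            "z": [s.position[1] for s in states],
            "vy": [s.velocity[0] for s in states],
            "vz": [s.velocity[1] for s in states],
            "time": [s.time for s in states],
        }
    )


def write_states_csv(path, states):
    states_to_frame(states).to_csv(path, index=False, float_format="%.9g")
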
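"""Legacy-ASCII VTK export of tetrahedral solutions for external viewers."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .fem.tetmesh import TetMesh


def write_vtk_tetmesh(
    path: str | Path,
    mesh: TetMesh,
    point_data: dict | None = None,
    cell_data: dict | None = None,
) -> None:
    """Write a tet mesh with named point/cell scalar or vector fields."""
    lines = [
        "# vtk DataFile Version 3.0",
        f"patellofem {mesh.part} cartilage",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [f"{x:.8g} {y:.8g} {z:.8g}" for x, y, z in mesh.nodes]
    lines.append(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}")
    lines += [f"4 {a} {b} {c} {d}" for a, b, c, d in mesh.tets]
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines += ["10"] * mesh.n_elements

    def _fields(tag: str, n: int, data: dict | None):
        if not data:
            return
        lines.append(f"{tag} {n}")
        for name, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.8g}" for v in arr]
            else:
                lines.append(f"VECTORS {name} double")
                lines += [f"{v[0]:.8g} {v[1]:.8g} {v[2]:.8g}" for v in arr]

    _fields("POINT_DATA", mesh.n_nodes, point_data)
    _fields("CELL_DATA", mesh.n_elements, cell_data)
    Path(path).write_text("\n".join(lines) + "\n")
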
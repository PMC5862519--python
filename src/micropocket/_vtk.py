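"""Minimal legacy-ASCII VTK writers for network and field snapshots."""

from __future__ import annotations

import numpy as np


def _write_points(f, points):
    f.write(f"POINTS {len(points)} float\n")
    np.savetxt(f, np.asarray(points, dtype=float), fmt="%.6f")


def _write_point_data(f, point_data, n):
    if not point_data:
        return
    f.write(f"POINT_DATA {n}\n")
    for name, values in point_data.items():
        f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, np.asarray(values, dtype=float), fmt="%.6g")


def write_polydata(path, points, lines, point_data=None):
    """Vessel network snapshot: points + line cells with per-node scalars."""
    lines = np.asarray(lines, dtype=np.int64)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nmicropocket network\nASCII\n")
        f.write("DATASET POLYDATA\n")
        _write_points(f, points)
        f.write(f"LINES {len(lines)} {3 * len(lines)}\n")
        np.savetxt(
            f,
            np.column_stack([np.full(len(lines), 2), lines]),
            fmt="%d",
        )
        _write_point_data(f, point_data or {}, len(points))


def write_unstructured(path, mesh, point_data=None):
    """Finite-element mesh with nodal scalar fields (e.g. VEGF in nM)."""
    elems = mesh.elements
    npe = elems.shape[1]
    cell_type = 5 if npe == 3 else 10  # VTK_TRIANGLE / VTK_TETRA
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nmicropocket field\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        _write_points(f, mesh.vertices)
        f.write(f"CELLS {len(elems)} {(npe + 1) * len(elems)}\n")
        np.savetxt(f, np.column_stack([np.full(len(elems), npe), elems]), fmt="%d")
        f.write(f"CELL_TYPES {len(elems)}\n")
        np.savetxt(f, np.full(len(elems), cell_type, dtype=int), fmt="%d")
        _write_point_data(f, point_data or {}, len(mesh.vertices))
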
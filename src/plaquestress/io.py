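"""Mesh and result exports: legacy-ASCII VTK, STL surfaces, Abaqus input.

The VTK writer emits an UnstructuredGrid with the tissue label and, when a
result is attached, per-element von Mises / max-principal stress fields —
enough for ParaView inspection. The Abaqus export writes C3D10 elements
with one element set per tissue label for cross-checking against a
commercial solver.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .elasticity import FEAResult
from .labels import Label
from .meshing import TetMesh


def write_vtk(path: str | Path, mesh: TetMesh, result: FEAResult | None = None) -> None:
    """Legacy-ASCII VTK UnstructuredGrid (linear tets + cell data)."""
    lines = [
        "# vtk DataFile Version 3.0",
        "plaquestress vessel mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(mesh.nodes)} float",
    ]
    lines += [" ".join(f"{v:.6g}" for v in p) for p in mesh.nodes]
    m = len(mesh.elems)
    lines.append(f"CELLS {m} {5 * m}")
    lines += ["4 " + " ".join(map(str, e)) for e in mesh.elems]
    lines.append(f"CELL_TYPES {m}")
    lines += ["10"] * m
    lines.append(f"CELL_DATA {m}")
    lines.append("SCALARS label int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(l)) for l in mesh.labels]
    if result is not None:
        for name, vals in (("VM", result.von_mises), ("MPS", result.max_principal)):
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.6g}" for v in vals]
    Path(path).write_text("\n".join(lines) + "\n")


def write_stl(path: str | Path, verts: np.ndarray, faces: np.ndarray) -> None:
    """Triangle surface to binary STL (via trimesh)."""
    import trimesh

    trimesh.Trimesh(vertices=verts, faces=faces, process=False).export(str(path))


def write_abaqus_inp(path: str | Path, mesh: TetMesh) -> None:
    """Minimal Abaqus input deck: C3D10 elements, one elset per label."""
    nodes10, elems10 = mesh.quadratic()
    lines = ["*NODE"]
    lines += [
        f"{i + 1}, {x:.6f}, {y:.6f}, {z:.6f}" for i, (x, y, z) in enumerate(nodes10)
    ]
    lines.append("*ELEMENT, TYPE=C3D10")
    lines += [
        f"{i + 1}, " + ", ".join(str(n + 1) for n in e) for i, e in enumerate(elems10)
    ]
    for lab in np.unique(mesh.labels):
        ids = np.flatnonzero(mesh.labels == lab) + 1
        lines.append(f"*ELSET, ELSET={Label(int(lab)).name}")
        for k in range(0, len(ids), 16):
            lines.append(", ".join(map(str, ids[k : k + 16])))
    Path(path).write_text("\n".join(lines) + "\n")
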
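"""Mesh and field import/export.

Legacy-VTK (ASCII, ``DATASET UNSTRUCTURED_GRID``) carries the volume mesh
together with region labels (cell data) and node sets (point-data fields named
``nodeset_<name>``), so a round trip preserves everything the solver needs.
ASCII STL carries the boundary surface only.  Minimal, format-subset
implementations: no installed package in this environment writes these
formats.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_vtk", "read_vtk", "write_stl", "read_stl", "write_field_vtk"]

_VTK_TET = 10
CONTOUR_CLAMP_MPA = (0.0, 3.0)  # display convention for stress contour export


def _write_header(fh, title: str) -> None:
    fh.write("# vtk DataFile Version 2.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")


def _write_mesh_block(fh, nodes: np.ndarray, elements: np.ndarray) -> None:
    fh.write(f"POINTS {len(nodes)} double\n")
    np.savetxt(fh, nodes, fmt="%.10g")
    fh.write(f"CELLS {len(elements)} {len(elements) * 5}\n")
    cells = np.hstack([np.full((len(elements), 1), 4, dtype=np.int64), elements])
    np.savetxt(fh, cells, fmt="%d")
    fh.write(f"CELL_TYPES {len(elements)}\n")
    np.savetxt(fh, np.full(len(elements), _VTK_TET, dtype=np.int64), fmt="%d")


def write_vtk(mesh, path: str | Path) -> Path:
    """Write a skull mesh with region labels and node sets."""
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(fh, f"ichthyofea skull mesh {getattr(mesh.params, 'label', '')}".strip())
        _write_mesh_block(fh, mesh.nodes, mesh.elements)

        n_arrays = 1 + len(mesh.node_sets)
        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        fh.write(f"FIELD nodesets {len(mesh.node_sets)}\n")
        for name in sorted(mesh.node_sets):
            mask = np.zeros(mesh.n_nodes, dtype=np.int8)
            mask[mesh.node_sets[name]] = 1
            fh.write(f"nodeset_{name} 1 {mesh.n_nodes} int\n")
            np.savetxt(fh, mask, fmt="%d")

        fh.write(f"CELL_DATA {mesh.n_elements}\n")
        fh.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mesh.region_ids, fmt="%d")
    return path


def read_vtk(path: str | Path):
    """Read back a mesh written by :func:`write_vtk` (tet cells only)."""
    from ichthyofea.skull import REGION_NAMES, SkullMesh

    tokens: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()

    nodes = elements = None
    region = None
    node_sets: dict[str, np.ndarray] = {}
    i = 0
    n_points = n_cells = 0
    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        kw = parts[0].upper()
        if kw == "POINTS":
            n_points = int(parts[1])
            vals = []
            i += 1
            while len(vals) < 3 * n_points:
                vals.extend(float(v) for v in lines[i].split())
                i += 1
            nodes = np.array(vals).reshape(n_points, 3)
            continue
        if kw == "CELLS":
            n_cells = int(parts[1])
            vals = []
            i += 1
            while len(vals) < int(parts[2]):
                vals.extend(int(v) for v in lines[i].split())
                i += 1
            raw = np.array(vals).reshape(n_cells, -1)
            if not (raw[:, 0] == 4).all():
                raise ValueError("only linear tetrahedral cells are supported")
            elements = raw[:, 1:].astype(np.int32)
            continue
        if kw == "FIELD":
            n_arrays = int(parts[2])
            i += 1
            for _ in range(n_arrays):
                name, _, count, _ = lines[i].split()
                vals = []
                i += 1
                while len(vals) < int(count):
                    vals.extend(int(float(v)) for v in lines[i].split())
                    i += 1
                if name.startswith("nodeset_"):
                    node_sets[name[len("nodeset_") :]] = np.flatnonzero(np.array(vals))
            continue
        if kw == "SCALARS" and parts[1] == "region":
            i += 2  # skip LOOKUP_TABLE
            vals = []
            while len(vals) < n_cells:
                vals.extend(int(float(v)) for v in lines[i].split())
                i += 1
            region = np.array(vals, dtype=np.int8)
            continue
        i += 1

    if nodes is None or elements is None:
        raise ValueError(f"{path}: not a supported VTK unstructured grid")
    if region is None:
        region = np.zeros(len(elements), dtype=np.int8)
    return SkullMesh(
        nodes=nodes,
        elements=elements,
        node_sets=node_sets,
        region_ids=region,
        region_names=REGION_NAMES,
    )


def write_field_vtk(mesh, field, path: str | Path, clamp_contour: bool = True) -> Path:
    """Export a solved stress field: displacements, stress tensor components,
    von Mises, and optionally a contour-display copy clamped to 0-3 MPa."""
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(fh, f"ichthyofea stress field {field.label}".strip())
        _write_mesh_block(fh, mesh.nodes, mesh.elements)

        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        fh.write("VECTORS displacement double\n")
        np.savetxt(fh, field.displacements, fmt="%.8g")

        fh.write(f"CELL_DATA {mesh.n_elements}\n")
        fh.write("SCALARS von_mises double 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, field.von_mises, fmt="%.8g")
        if clamp_contour:
            lo, hi = CONTOUR_CLAMP_MPA
            fh.write("SCALARS von_mises_contour double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, np.clip(field.von_mises, lo, hi), fmt="%.8g")
        fh.write("TENSORS stress double\n")
        np.savetxt(fh, field.stress_tensor().reshape(-1, 9), fmt="%.8g")
        fh.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mesh.region_ids, fmt="%d")
    return path


def write_stl(mesh, path: str | Path, name: str = "skull") -> Path:
    """ASCII STL of the boundary surface (outward-oriented facets)."""
    path = Path(path)
    tris = mesh.surface_triangles()
    v = mesh.nodes[tris]
    n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    n = n / np.where(norm > 0, norm, 1.0)
    with open(path, "w") as fh:
        fh.write(f"solid {name}\n")
        for ni, vi in zip(n, v):
            fh.write(f"facet normal {ni[0]:.8g} {ni[1]:.8g} {ni[2]:.8g}\n outer loop\n")
            for p in vi:
                fh.write(f"  vertex {p[0]:.8g} {p[1]:.8g} {p[2]:.8g}\n")
            fh.write(" endloop\nendfacet\n")
        fh.write(f"endsolid {name}\n")
    return path


def read_stl(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an ASCII STL surface; returns (vertices, triangles).

    Surface only: a volume mesh (VTK) is required wherever the solver needs a
    solid.
    """
    verts: list[tuple[float, float, float]] = []
    index: dict[tuple[float, float, float], int] = {}
    tris: list[list[int]] = []
    current: list[int] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if parts and parts[0] == "vertex":
                p = (float(parts[1]), float(parts[2]), float(parts[3]))
                if p not in index:
                    index[p] = len(verts)
                    verts.append(p)
                current.append(index[p])
                if len(current) == 3:
                    tris.append(current)
                    current = []
    if not tris:
        raise ValueError(f"{path}: no facets found (is this an ASCII STL?)")
    return np.array(verts), np.array(tris, dtype=np.int64)
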
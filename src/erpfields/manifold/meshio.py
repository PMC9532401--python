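"""Minimal readers/writers for triangle meshes: OBJ, ASCII PLY, legacy ASCII VTK.

Only the triangle-surface subset of each format is supported; that is all
the pipeline needs, and keeps every artifact plain text.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np

from .mesh import TriangleMeshManifold

__all__ = ["read_mesh", "write_mesh"]


def read_mesh(path: str | os.PathLike) -> TriangleMeshManifold:
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".obj":
        return _read_obj(path)
    if ext == ".ply":
        return _read_ply(path)
    if ext in (".vtk", ".vtp", ".vtu"):
        return _read_vtk(path)
    raise ValueError(f"unsupported mesh format {ext!r} (use .obj/.ply/.vtk)")


def write_mesh(mesh: TriangleMeshManifold, path: str | os.PathLike,
               point_data: Optional[dict] = None) -> None:
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".obj":
        _write_obj(mesh, path)
    elif ext == ".ply":
        _write_ply(mesh, path)
    elif ext == ".vtk":
        _write_vtk(mesh, path, point_data or {})
    else:
        raise ValueError(f"unsupported mesh format {ext!r} (use .obj/.ply/.vtk)")


# -- OBJ ---------------------------------------------------------------------

def _read_obj(path: str) -> TriangleMeshManifold:
    verts, tris = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(tok.split("/")[0]) - 1 for tok in parts[1:]]
                for k in range(1, len(idx) - 1):  # fan-triangulate
                    tris.append([idx[0], idx[k], idx[k + 1]])
    return TriangleMeshManifold(np.array(verts), np.array(tris))


def _write_obj(mesh: TriangleMeshManifold, path: str) -> None:
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for t in mesh.triangles:
            fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")


# -- ASCII PLY ---------------------------------------------------------------

def _read_ply(path: str) -> TriangleMeshManifold:
    with open(path) as fh:
        if fh.readline().strip() != "ply":
            raise ValueError("not a PLY file")
        fmt = fh.readline().split()
        if fmt[1] != "ascii":
            raise ValueError("only ascii PLY is supported")
        n_vert = n_face = 0
        vert_props = 0
        in_vertex = False
        for line in fh:
            parts = line.split()
            if parts[0] == "element":
                in_vertex = parts[1] == "vertex"
                if in_vertex:
                    n_vert = int(parts[2])
                elif parts[1] == "face":
                    n_face = int(parts[2])
            elif parts[0] == "property" and in_vertex:
                vert_props += 1
            elif parts[0] == "end_header":
                break
        verts = np.array(
            [[float(x) for x in fh.readline().split()[:3]] for _ in range(n_vert)]
        )
        tris = []
        for _ in range(n_face):
            parts = [int(x) for x in fh.readline().split()]
            idx = parts[1 : 1 + parts[0]]
            for k in range(1, len(idx) - 1):
                tris.append([idx[0], idx[k], idx[k + 1]])
    return TriangleMeshManifold(verts, np.array(tris))


def _write_ply(mesh: TriangleMeshManifold, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(mesh.triangles)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


# -- legacy ASCII VTK (POLYDATA) --------------------------------------------

def _read_vtk(path: str) -> TriangleMeshManifold:
    with open(path) as fh:
        tokens = fh.read().split()
    def find(kw):
        for i, tok in enumerate(tokens):
            if tok.upper() == kw:
                return i
        raise ValueError(f"VTK keyword {kw} not found (only legacy POLYDATA supported)")
    ip = find("POINTS")
    n_pts = int(tokens[ip + 1])
    coords = np.array(tokens[ip + 3 : ip + 3 + 3 * n_pts], dtype=float).reshape(n_pts, 3)
    ic = find("POLYGONS")
    n_poly = int(tokens[ic + 1])
    tris = []
    pos = ic + 3
    for _ in range(n_poly):
        cnt = int(tokens[pos])
        idx = [int(x) for x in tokens[pos + 1 : pos + 1 + cnt]]
        for k in range(1, len(idx) - 1):
            tris.append([idx[0], idx[k], idx[k + 1]])
        pos += cnt + 1
    return TriangleMeshManifold(coords, np.array(tris))


def _write_vtk(mesh: TriangleMeshManifold, path: str, point_data: dict) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nerpfields mesh\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} float\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        m = len(mesh.triangles)
        fh.write(f"POLYGONS {m} {4 * m}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, values in point_data.items():
                values = np.asarray(values, dtype=float)
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for x in values:
                    fh.write(f"{x:.9g}\n")
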
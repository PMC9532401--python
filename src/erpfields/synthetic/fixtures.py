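"""Deterministic fixture meshes: sphere, open cylinder, ellipsoid with holes.

These stand in for patient atrial meshes: the holed variants have boundary
loops (like pulmonary-vein openings) to exercise boundary-exclusion rules.
"""

from __future__ import annotations

import numpy as np

from ..manifold.mesh import TriangleMeshManifold

__all__ = ["make_fixture_mesh", "icosphere"]


def _icosahedron():
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def _subdivide(verts, faces):
    """Loop-style midpoint subdivision (geometry only)."""
    edge_mid = {}
    verts = list(verts)

    def midpoint(a, b):
        key = (min(a, b), max(a, b))
        if key not in edge_mid:
            edge_mid[key] = len(verts)
            verts.append(0.5 * (np.asarray(verts[a]) + np.asarray(verts[b])))
        return edge_mid[key]

    out = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        out.extend([[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]])
    return np.array(verts), np.array(out, dtype=np.int64)


def icosphere(subdivisions: int = 3, radius: float = 1.0) -> TriangleMeshManifold:
    """Subdivided icosahedron projected onto the sphere of given radius."""
    verts, faces = _icosahedron()
    for _ in range(subdivisions):
        verts, faces = _subdivide(verts, faces)
        verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    return TriangleMeshManifold(radius * verts, faces)


def _cylinder(radius: float, height: float, n_theta: int, n_z: int) -> TriangleMeshManifold:
    """Open tube: boundary circles at both ends."""
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    z = np.linspace(-height / 2.0, height / 2.0, n_z)
    verts = np.array(
        [
            [radius * np.cos(a), radius * np.sin(a), zz]
            for zz in z
            for a in theta
        ]
    )
    tris = []
    for iz in range(n_z - 1):
        for it in range(n_theta):
            a = iz * n_theta + it
            b = iz * n_theta + (it + 1) % n_theta
            c = a + n_theta
            d = b + n_theta
            tris.append([a, b, d])
            tris.append([a, d, c])
    return TriangleMeshManifold(verts, np.array(tris, dtype=np.int64))


def _ellipsoid_with_holes(
    axes=(1.0, 0.8, 0.6), cap: float = 0.85, subdivisions: int = 3
) -> TriangleMeshManifold:
    """Scaled icosphere with the polar caps removed (two boundary loops)."""
    sph = icosphere(subdivisions)
    verts = sph.vertices * np.asarray(axes)
    keep = []
    zcut = cap * axes[2]
    for tri in sph.triangles:
        zc = verts[tri, 2].mean()
        if abs(zc) < zcut:
            keep.append(tri)
    tris = np.array(keep, dtype=np.int64)
    used = np.unique(tris)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMeshManifold(verts[used], remap[tris])


def make_fixture_mesh(kind: str, target_edge_length: float = 0.1,
                      scale: float = 1.0) -> TriangleMeshManifold:
    """Build a fixture mesh of the given kind at roughly the requested
    resolution (edge length in the same units as `scale`).

    kinds: 'sphere' (closed, radius=scale), 'cylinder-with-holes' (open tube),
    'ellipsoid-with-holes' (two boundary loops).
    """
    if kind == "sphere":
        # icosahedron edge ~1.05 R; halves per subdivision
        rel = target_edge_length / scale
        sub = max(1, int(np.ceil(np.log2(1.05 / rel))))
        return icosphere(subdivisions=min(sub, 6), radius=scale)
    if kind == "cylinder-with-holes":
        radius, height = scale, 2.0 * scale
        n_theta = max(8, int(round(2 * np.pi * radius / target_edge_length)))
        n_z = max(4, int(round(height / target_edge_length)) + 1)
        return _cylinder(radius, height, min(n_theta, 256), min(n_z, 257))
    if kind == "ellipsoid-with-holes":
        rel = target_edge_length / scale
        sub = max(1, int(np.ceil(np.log2(1.05 / rel))))
        m = _ellipsoid_with_holes(subdivisions=min(sub, 6))
        return TriangleMeshManifold(m.vertices * scale, m.triangles)
    raise ValueError(f"unknown fixture kind {kind!r}")
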
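"""Cotangent-FEM Laplace-Beltrami operator and its eigenbasis.

The stiffness matrix uses the classic cotangent weights; the mass matrix
is lumped (barycentric) by default, giving a sparse generalized
eigenproblem A phi = lambda M phi with natural (Neumann) boundary
conditions, so the constant mode survives on meshes with boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix, diags, identity
from scipy.sparse.linalg import eigsh, ArpackNoConvergence

from .mesh import TriangleMeshManifold

__all__ = ["build_lb_operator", "solve_eigenproblem", "LaplacianEigenbasis"]


def build_lb_operator(
    mesh: TriangleMeshManifold, *, lumped_mass: bool = True
) -> tuple[csr_matrix, csr_matrix]:
    """Return (stiffness, mass).  Stiffness is symmetric PSD with the constant
    vector in its null space; mass is symmetric positive definite with total
    mass equal to the surface area."""
    v = mesh.vertices
    t = mesh.triangles
    n = mesh.n_vertices

    i0, i1, i2 = t[:, 0], t[:, 1], t[:, 2]
    e0 = v[i2] - v[i1]  # edge opposite vertex 0
    e1 = v[i0] - v[i2]
    e2 = v[i1] - v[i0]
    area2 = np.linalg.norm(np.cross(e1, e2), axis=1)  # 2 * triangle area
    # cot(angle at vertex k) = dot of adjacent edges / (2 * area)
    cot0 = -np.einsum("ij,ij->i", e1, e2) / area2
    cot1 = -np.einsum("ij,ij->i", e2, e0) / area2
    cot2 = -np.einsum("ij,ij->i", e0, e1) / area2

    # off-diagonal contribution -cot(k)/2 on the edge opposite vertex k
    rows = np.concatenate([i1, i2, i2, i0, i0, i1])
    cols = np.concatenate([i2, i1, i0, i2, i1, i0])
    w = 0.5 * np.concatenate([cot0, cot0, cot1, cot1, cot2, cot2])
    A = coo_matrix((-w, (rows, cols)), shape=(n, n)).tocsr()
    A = A - diags(np.asarray(A.sum(axis=1)).ravel())

    areas = 0.5 * area2
    if lumped_mass:
        m = np.zeros(n)
        np.add.at(m, t.ravel(), np.repeat(areas / 3.0, 3))
        M = diags(m).tocsr()
    else:
        # consistent mass: area/6 on diagonal per corner, area/12 off-diagonal
        rows_m = np.concatenate([t.ravel(), rows])
        cols_m = np.concatenate([t.ravel(), cols])
        vals_m = np.concatenate(
            [np.repeat(areas / 6.0, 3), np.repeat(areas / 12.0, 6)]
        )
        M = coo_matrix((vals_m, (rows_m, cols_m)), shape=(n, n)).tocsr()
    return A, M


@dataclass(frozen=True)
class LaplacianEigenbasis:
    """Mass-orthonormal eigenpairs of the Laplace-Beltrami operator.

    eigenvalues are ascending in 1/mm^2; phi is (n_vertices, K) with
    Phi^T M Phi = I.  phi_one_magnitude is |Phi_1| = 1/sqrt(area) for a
    connected mesh, used for the amplitude normalization of GP fields.
    """

    eigenvalues: np.ndarray
    phi: np.ndarray
    mass_diagonal: np.ndarray
    surface_area: float

    @property
    def K(self) -> int:
        return self.phi.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.phi.shape[0]

    @property
    def phi_one_magnitude(self) -> float:
        return 1.0 / np.sqrt(self.surface_area)

    @cached_property
    def scaled_phi(self) -> np.ndarray:
        """phi / |Phi_1|: O(1) dimensionless basis functions."""
        return self.phi / self.phi_one_magnitude

    def truncated(self, K: int) -> "LaplacianEigenbasis":
        if K > self.K:
            raise ValueError(f"requested K={K} exceeds available {self.K} modes")
        return LaplacianEigenbasis(
            eigenvalues=self.eigenvalues[:K],
            phi=self.phi[:, :K],
            mass_diagonal=self.mass_diagonal,
            surface_area=self.surface_area,
        )

    def save(self, path) -> None:
        np.savez(
            path,
            eigenvalues=self.eigenvalues,
            phi=self.phi,
            mass_diagonal=self.mass_diagonal,
            surface_area=self.surface_area,
        )

    @classmethod
    def load(cls, path) -> "LaplacianEigenbasis":
        d = np.load(path)
        return cls(
            eigenvalues=d["eigenvalues"],
            phi=d["phi"],
            mass_diagonal=d["mass_diagonal"],
            surface_area=float(d["surface_area"]),
        )


def solve_eigenproblem(
    mesh: TriangleMeshManifold,
    K: int,
    *,
    lumped_mass: bool = True,
    tol: float = 1e-10,
) -> LaplacianEigenbasis:
    """K smallest generalized eigenpairs, mass-orthonormal, deterministic.

    Shift-invert around a small negative shift keeps the singular constant
    mode tractable; a fixed starting vector makes results reproducible.
    """
    if not 1 <= K <= mesh.n_vertices:
        raise ValueError(f"K must be in [1, {mesh.n_vertices}], got {K}")
    A, M = build_lb_operator(mesh, lumped_mass=lumped_mass)
    n = mesh.n_vertices
    scale = abs(A.diagonal()).mean()
    sigma = -1e-3 * scale
    v0 = np.full(n, 1.0 / np.sqrt(n))
    try:
        vals, vecs = eigsh(A, k=K, M=M, sigma=sigma, which="LM", tol=tol, v0=v0)
    except ArpackNoConvergence as exc:
        raise RuntimeError(
            f"eigen-solver failed to converge: {len(exc.eigenvalues)} of {K} "
            "eigenpairs converged; refine the mesh or reduce K"
        ) from exc
    order = np.argsort(vals)
    vals = vals[order]
    vecs = vecs[:, order]
    vals = np.where(np.abs(vals) < 1e-10 * max(vals.max(), 1.0), 0.0, vals)

    # enforce exact mass-orthonormality (eigsh already returns M-orthonormal
    # vectors; re-normalize against round-off) and a deterministic sign
    if lumped_mass:
        m = M.diagonal()
        norms = np.sqrt(np.einsum("ik,i,ik->k", vecs, m, vecs))
    else:
        norms = np.sqrt(np.einsum("ik,ik->k", vecs, M @ vecs))
    vecs = vecs / norms
    signs = np.sign(vecs[np.argmax(np.abs(vecs), axis=0), np.arange(K)])
    vecs = vecs * np.where(signs == 0, 1.0, signs)

    return LaplacianEigenbasis(
        eigenvalues=vals,
        phi=vecs,
        mass_diagonal=np.asarray(M.diagonal()).ravel(),
        surface_area=mesh.surface_area,
    )
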
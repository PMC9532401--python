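"""Reduced-rank Gaussian processes on mesh manifolds.

A field is expanded in the Laplace-Beltrami eigenbasis,

    theta(x) = m + (alpha/|Phi_1|) * sum_k eta_k w_k(rho) phi_k(x),

where the spectral weights w_k are derived from the stationary kernel's
spectral density evaluated at sqrt(lambda_k).  The weights are normalized
to unit total power so that alpha is (approximately) the pointwise prior
standard deviation regardless of mesh size; any fixed normalization is
equivalent up to a rescaling of alpha, which is inferred.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .laplacian import LaplacianEigenbasis
from .mesh import TriangleMeshManifold

__all__ = [
    "KernelSpec",
    "spectral_density",
    "spectral_weights",
    "evaluate_field",
    "sample_field",
    "biharmonic_distance",
    "biharmonic_distance_matrix",
    "calibrate_lengthscale_mm",
    "transfer_field",
]

KERNEL_FAMILIES = ("rbf", "matern52")
_MATERN52_C = 10.0 * math.pi * 5.0**2.5  # 2^d pi^{d/2} Gamma(nu+d/2)(2nu)^nu / Gamma(nu), d=2, nu=5/2


@dataclass(frozen=True)
class KernelSpec:
    """Stationary kernel on the 2D manifold: family, lengthscale, amplitude."""

    family: str = "rbf"
    rho: float = 1.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; use {KERNEL_FAMILIES}")
        if self.rho <= 0 or self.alpha <= 0:
            raise ValueError("rho and alpha must be positive")

    def correlation(self, r: np.ndarray) -> np.ndarray:
        """Correlation as a function of distance (unit variance)."""
        r = np.abs(np.asarray(r, dtype=float))
        if self.family == "rbf":
            return np.exp(-0.5 * (r / self.rho) ** 2)
        z = math.sqrt(5.0) * r / self.rho
        return (1.0 + z + z * z / 3.0) * np.exp(-z)


def spectral_density(family_or_kernel, omega, rho: float | None = None) -> np.ndarray:
    """2D stationary spectral density S(omega; rho), unit variance.

    Normalized so that (2 pi)^-2 * integral S(|omega|) d^2 omega = 1.
    Strictly positive and decreasing in omega.
    """
    if isinstance(family_or_kernel, KernelSpec):
        family, rho = family_or_kernel.family, family_or_kernel.rho
    else:
        family = family_or_kernel
        if rho is None:
            raise ValueError("rho required when passing a family name")
    omega = np.asarray(omega, dtype=float)
    if family == "rbf":
        return 2.0 * math.pi * rho**2 * np.exp(-0.5 * rho**2 * omega**2)
    if family == "matern52":
        return _MATERN52_C / rho**5 * (5.0 / rho**2 + omega**2) ** -3.5
    raise ValueError(f"unknown kernel family {family!r}")


def _dlogS_dlogrho(family: str, omega: np.ndarray, rho: float) -> np.ndarray:
    """d log S / d log(rho), analytic and stable where S underflows."""
    if family == "rbf":
        return 2.0 - rho**2 * omega**2
    # matern52: d/dlogrho [ -5 log rho - 3.5 log(5/rho^2 + w^2) ]
    a = 5.0 / rho**2
    return -5.0 + 7.0 * a / (a + omega**2)


def spectral_weights(
    basis: LaplacianEigenbasis,
    kernel: KernelSpec,
    *,
    with_grad: bool = False,
):
    """Normalized weights w_k = sqrt(S_k / sum_j S_j) for the K modes.

    With with_grad=True also returns d w / d log(rho) (analytic).
    """
    omega = np.sqrt(np.maximum(basis.eigenvalues, 0.0))
    S = spectral_density(kernel.family, omega, kernel.rho)
    T = S.sum()
    w = np.sqrt(S / T)
    if not with_grad:
        return w
    g = _dlogS_dlogrho(kernel.family, omega, kernel.rho)  # d log S / d log rho
    dT_over_T = float((S / T) @ g)
    # d/dlogrho sqrt(S/T) = 0.5 * w * (dlogS - dlogT); stays 0 where S underflows
    dw = 0.5 * w * (g - dT_over_T)
    return w, dw


def evaluate_field(
    basis: LaplacianEigenbasis,
    kernel: KernelSpec,
    m: float,
    eta: np.ndarray,
) -> np.ndarray:
    """Deterministic field from coefficients eta (length K) at all vertices."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (basis.K,):
        raise ValueError(f"eta must have length K={basis.K}, got shape {eta.shape}")
    w = spectral_weights(basis, kernel)
    return m + kernel.alpha * (basis.scaled_phi @ (w * eta))


def sample_field(
    basis: LaplacianEigenbasis,
    kernel: KernelSpec,
    m: float,
    seed,
) -> np.ndarray:
    """Draw eta ~ N(0, I) with the given seed and evaluate the field."""
    w = spectral_weights(basis, kernel)
    if basis.K >= 3 and w[basis.K - 1] > 0.01 * w[1]:
        warnings.warn(
            f"K={basis.K} may be too small for rho={kernel.rho:g}: last spectral "
            f"weight is {w[-1] / w[1]:.1%} of mode 2's weight",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    eta = rng.standard_normal(basis.K)
    return evaluate_field(basis, kernel, m, eta)


def biharmonic_distance(basis: LaplacianEigenbasis, i: int, j: int) -> float:
    """d_BH(i, j)^2 = sum_{k: lambda_k > 0} (phi_k(i) - phi_k(j))^2 / lambda_k^2."""
    n = basis.n_vertices
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"vertex index out of range [0, {n})")
    lam = basis.eigenvalues
    keep = lam > 1e-10 * max(lam.max(), 1.0)
    d = basis.phi[i, keep] - basis.phi[j, keep]
    return float(np.sqrt(np.sum(d * d / lam[keep] ** 2)))


def biharmonic_distance_matrix(
    basis: LaplacianEigenbasis, rows: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    """Pairwise biharmonic distances between two vertex-id sets."""
    lam = basis.eigenvalues
    keep = lam > 1e-10 * max(lam.max(), 1.0)
    U = basis.phi[:, keep] / lam[keep]  # phi_k / lambda_k
    a = U[np.asarray(rows, dtype=int)]
    b = U[np.asarray(cols, dtype=int)]
    sq = (
        np.sum(a * a, axis=1)[:, None]
        + np.sum(b * b, axis=1)[None, :]
        - 2.0 * a @ b.T
    )
    return np.sqrt(np.maximum(sq, 0.0))


def calibrate_lengthscale_mm(
    mesh: TriangleMeshManifold,
    basis: LaplacianEigenbasis,
    kernel: KernelSpec,
    *,
    n_samples: int = 1000,
    n_sources: int = 30,
    max_pairs: int = 4000,
    seed=0,
) -> float:
    """Empirical mm-per-lengthscale-unit factor.

    Draws many seeded GP samples, computes between-vertex correlations for
    sampled vertex pairs, and least-squares fits the kernel correlation
    function against graph (approximately geodesic) distance.  Returns the
    fitted distance lengthscale divided by the kernel's rho.
    """
    rng = np.random.default_rng(seed)
    etas = rng.standard_normal((n_samples, basis.K))
    w = spectral_weights(basis, kernel)
    fields = etas @ (w[:, None] * basis.scaled_phi.T)  # (n_samples, n_vertices)

    n = mesh.n_vertices
    sources = rng.choice(n, size=min(n_sources, n), replace=False)
    dists = mesh.graph_distances(sources, rings=2)  # (n_sources, n)
    targets = rng.choice(n, size=min(max_pairs // len(sources), n), replace=False)

    d = dists[:, targets].ravel()
    fc = fields - fields.mean(axis=0, keepdims=True)
    sd = fields.std(axis=0)
    num = (fc[:, sources].T @ fc[:, targets]) / n_samples
    corr = (num / (sd[sources][:, None] * sd[targets][None, :])).ravel()
    good = np.isfinite(d) & np.isfinite(corr)
    d, corr = d[good], corr[good]

    if corr.min() > 0.5:
        raise ValueError(
            "degenerate fit: all sampled correlations stay above 0.5; "
            "use a smaller rho so correlations approach zero on this mesh"
        )

    def model(log_L):
        return KernelSpec(kernel.family, float(np.exp(log_L))).correlation(d)

    res = least_squares(
        lambda p: model(p[0]) - corr, x0=[np.log(kernel.rho)], method="lm"
    )
    L_mm = float(np.exp(res.x[0]))
    return L_mm / kernel.rho


def transfer_field(
    coarse_mesh: TriangleMeshManifold,
    values: np.ndarray,
    fine_mesh: TriangleMeshManifold,
    *,
    radius: float = 3.0,
    k: int = 4,
) -> np.ndarray:
    """Inverse-distance interpolation of vertex values onto another mesh.

    Exact at coincident vertices; fine vertices farther than `radius` from
    every coarse vertex fall back (with a warning) to nearest-neighbour.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (coarse_mesh.n_vertices,):
        raise ValueError("values must be per-coarse-vertex")
    tree = cKDTree(coarse_mesh.vertices)
    k = min(k, coarse_mesh.n_vertices)
    dist, idx = tree.query(fine_mesh.vertices, k=k)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)

    out = np.empty(fine_mesh.n_vertices)
    coincident = dist[:, 0] < 1e-9
    out[coincident] = values[idx[coincident, 0]]

    far = ~coincident & (dist[:, 0] > radius)
    if far.any():
        warnings.warn(
            f"{int(far.sum())} vertices farther than radius={radius:g} mm from "
            "any source vertex; using nearest neighbour there",
            stacklevel=2,
        )
        out[far] = values[idx[far, 0]]

    rest = ~coincident & ~far
    if rest.any():
        dd = dist[rest]
        ii = idx[rest]
        wgt = 1.0 / dd**2
        wgt[dd > radius] = 0.0
        out[rest] = np.sum(wgt * values[ii], axis=1) / np.sum(wgt, axis=1)
    return out
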
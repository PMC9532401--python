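"""Ground-truth parameter-field scenarios for synthetic experiments.

Fields are independent Matern-5/2 reduced-rank GP draws (zero mean, unit
amplitude, 256 eigenfunctions) scaled affinely from their own min-max onto
the full physiological ranges, then projected through the ERP_S2 ceiling
constraint so every vertex maps to a realistic ERP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..cable.params import TRANSFORMED_RANGES
from ..calibration.fields import FieldSampleSet, constrain_fields
from ..manifold.gp import KernelSpec, evaluate_field
from ..manifold.laplacian import LaplacianEigenbasis, solve_eigenproblem
from ..manifold.mesh import TriangleMeshManifold
from ..surrogate.polynomial import ERP_S2_CEILING, SurrogateFunction

__all__ = ["GroundTruthScenario", "generate_ground_truth", "GROUND_TRUTH_K"]

GROUND_TRUTH_K = 256


@dataclass
class GroundTruthScenario:
    """Ground-truth EP parameter and ERP fields on a mesh."""

    mesh: TriangleMeshManifold
    basis: LaplacianEigenbasis
    rho: float
    seed: int
    tau_out: np.ndarray
    apd_max: np.ndarray
    cv_max: np.ndarray
    erp_s2: np.ndarray
    erp_s3: np.ndarray
    constraint_report: dict

    @property
    def n_vertices(self) -> int:
        return self.mesh.n_vertices


def _scale_into(raw: np.ndarray, lo: float, hi: float, how: str) -> np.ndarray:
    if how == "minmax":
        rmin, rmax = raw.min(), raw.max()
        if rmax - rmin < 1e-12:
            return np.full_like(raw, 0.5 * (lo + hi))
        return lo + (raw - rmin) / (rmax - rmin) * (hi - lo)
    if how == "quantile":
        ranks = np.argsort(np.argsort(raw))
        u = (ranks + 0.5) / len(raw)
        return lo + u * (hi - lo)
    raise ValueError(f"unknown scaling {how!r}")


def generate_ground_truth(
    mesh: TriangleMeshManifold,
    rho: float,
    seed: int,
    f1: SurrogateFunction,
    f2: SurrogateFunction,
    *,
    basis: Optional[LaplacianEigenbasis] = None,
    K: int = GROUND_TRUTH_K,
    kernel_family: str = "matern52",
    scaling: str = "minmax",
    ceiling: float = ERP_S2_CEILING,
) -> GroundTruthScenario:
    """Draw tau_out, apd_max, cv_max fields and derive ERP fields.

    Deterministic in (mesh, rho, seed, surrogates).  The constraint
    projection guarantees post-projection ERP_S2 <= ceiling everywhere
    (or flags the draw in the report).
    """
    if basis is None:
        basis = solve_eigenproblem(mesh, min(K, mesh.n_vertices - 2))
    kernel = KernelSpec(kernel_family, rho)
    rng = np.random.default_rng(seed)
    raws = [evaluate_field(basis, kernel, 0.0, rng.standard_normal(basis.K))
            for _ in range(3)]

    tau_out = _scale_into(raws[0], *TRANSFORMED_RANGES["tau_out"], how=scaling)
    apd_max = _scale_into(raws[1], *TRANSFORMED_RANGES["apd_max"], how=scaling)
    cv_max = _scale_into(raws[2], *TRANSFORMED_RANGES["cv_max"], how=scaling)

    fields = FieldSampleSet(
        theta1=tau_out[None, :], theta2=apd_max[None, :],
        log_posteriors=np.zeros(1),
    )
    constrained, report = constrain_fields(fields, f1, basis, ceiling=ceiling)
    tau_out = constrained.theta1[0]
    apd_max = constrained.theta2[0]

    erp_s2 = f1(tau_out, apd_max)
    erp_s3 = f2(tau_out, apd_max)
    return GroundTruthScenario(
        mesh=mesh,
        basis=basis,
        rho=rho,
        seed=seed,
        tau_out=tau_out,
        apd_max=apd_max,
        cv_max=cv_max,
        erp_s2=erp_s2,
        erp_s3=erp_s3,
        constraint_report=report,
    )
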
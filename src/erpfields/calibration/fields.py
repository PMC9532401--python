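"""Posterior field samples on the mesh and physiological constraint projection."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..manifold.gp import biharmonic_distance_matrix
from ..manifold.laplacian import LaplacianEigenbasis
from ..surrogate.polynomial import SurrogateFunction, ERP_S2_CEILING
from .hmc import PosteriorSampleSet
from .posterior import PosteriorModel

__all__ = ["FieldSampleSet", "posterior_fields", "constrain_fields"]


@dataclass
class FieldSampleSet:
    """Per-draw field values at all mesh vertices, plus pointwise summaries."""

    theta1: np.ndarray  # (n_draws, n_vertices) tau_out
    theta2: np.ndarray  # (n_draws, n_vertices) apd_max
    log_posteriors: np.ndarray

    @property
    def n_draws(self) -> int:
        return len(self.theta1)

    @property
    def map_index(self) -> int:
        return int(np.argmax(self.log_posteriors))

    def summaries(self) -> dict:
        out = {}
        for name, th in (("tau_out", self.theta1), ("apd_max", self.theta2)):
            out[name] = {
                "mean": th.mean(axis=0),
                "sd": th.std(axis=0, ddof=0),
                "map": th[self.map_index],
            }
        return out


def posterior_fields(
    samples: PosteriorSampleSet, model: PosteriorModel
) -> FieldSampleSet:
    """Evaluate both latent fields at every vertex for every retained draw."""
    if samples.n_retained == 0:
        raise ValueError("empty posterior sample set")
    n = model.basis.n_vertices
    th1 = np.empty((samples.n_retained, n))
    th2 = np.empty((samples.n_retained, n))
    for i, z in enumerate(samples.draws):
        th1[i], th2[i] = model.fields_on_mesh(z)
    return FieldSampleSet(
        theta1=th1, theta2=th2, log_posteriors=samples.log_posteriors.copy()
    )


def constrain_fields(
    fields: FieldSampleSet,
    f1: SurrogateFunction,
    basis: LaplacianEigenbasis,
    *,
    ceiling: float = ERP_S2_CEILING,
    max_iter: int = 10,
) -> tuple[FieldSampleSet, dict]:
    """Replace parameter values at vertices whose predicted ERP_S2 exceeds
    the ceiling by a 1/d_BH^4-weighted average over acceptable vertices.

    The replacement is re-checked through the surrogate and iterated up to
    max_iter passes.  Draws with no acceptable vertices are flagged invalid
    and left untouched.  Returns (constrained copy, report).
    """
    th1 = fields.theta1.copy()
    th2 = fields.theta2.copy()
    report = {
        "initial_violations": [],
        "final_violations": [],
        "iterations": [],
        "invalid_draws": [],
    }
    for d in range(fields.n_draws):
        erp = f1(th1[d], th2[d])
        bad = np.flatnonzero(erp > ceiling)
        report["initial_violations"].append(len(bad))
        iters = 0
        while len(bad) > 0 and iters < max_iter:
            good = np.flatnonzero(erp <= ceiling)
            if len(good) == 0:
                report["invalid_draws"].append(d)
                break
            dbh = biharmonic_distance_matrix(basis, bad, good)
            w = 1.0 / np.maximum(dbh, 1e-12) ** 4
            w /= w.sum(axis=1, keepdims=True)
            th1[d, bad] = w @ th1[d, good]
            th2[d, bad] = w @ th2[d, good]
            erp = f1(th1[d], th2[d])
            bad = np.flatnonzero(erp > ceiling)
            iters += 1
        report["iterations"].append(iters)
        report["final_violations"].append(len(bad))
    out = FieldSampleSet(
        theta1=th1, theta2=th2, log_posteriors=fields.log_posteriors.copy()
    )
    return out, report
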
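"""Shared fixtures.  Expensive artifacts (cable training tables, eigenbases)
are session-scoped; everything is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from erpfields.cable import generate_training_table
from erpfields.manifold import TriangleMeshManifold, solve_eigenproblem
from erpfields.surrogate import latin_hypercube, fit_surrogates
from erpfields.surrogate.polynomial import SurrogateFunction
from erpfields.synthetic import icosphere


def make_flat_square(n: int = 33, side: float = 1.0) -> TriangleMeshManifold:
    """Regular right-triangle grid on [0, side]^2 (z = 0)."""
    x = np.linspace(0.0, side, n)
    X, Y = np.meshgrid(x, x)
    verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(n * n)])
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b, c, d = a + 1, a + n, a + n + 1
            tris.append([a, b, d])
            tris.append([a, d, c])
    return TriangleMeshManifold(verts, np.array(tris, dtype=np.int64))


@pytest.fixture(scope="session")
def training_table():
    """Cable-simulator training table over a 40-point maximin LHS design
    of (cv_max, tau_out, apd_max); tau_in/tau_open at surrogate-fixed values."""
    design = latin_hypercube(
        40, [[0.1, 1.5], [1.0, 30.0], [120.0, 270.0]], seed=7
    )
    return generate_training_table(design)


@pytest.fixture(scope="session")
def surrogates(training_table):
    return fit_surrogates(training_table)


@pytest.fixture(scope="session")
def toy_surrogates():
    """Analytic cubic stand-ins with realistic scale, for calibration tests
    that should not depend on the cable simulator."""
    def mk(name, base, mask):
        c = np.zeros(10)
        c[0] = base          # constant
        c[1] = 18.0          # tau_out (standardized)
        c[2] = 55.0          # apd_max (standardized)
        c[3] = -4.0
        c[4] = 6.0
        c[6] = 1.5
        return SurrogateFunction(
            coefficients=c,
            center=(15.5, 195.0),
            halfwidth=(14.5, 75.0),
            residual_rms=1.0,
            name=name,
            mask_ceiling=mask,
        )

    return mk("erp_s2", 225.0, None), mk("erp_s3", 190.0, 280.0)


@pytest.fixture(scope="session")
def sphere25():
    return icosphere(3, radius=25.0)


@pytest.fixture(scope="session")
def sphere25_basis(sphere25):
    return solve_eigenproblem(sphere25, 256)


@pytest.fixture(scope="session")
def unit_sphere():
    return icosphere(4, radius=1.0)


@pytest.fixture(scope="session")
def unit_sphere_basis(unit_sphere):
    return solve_eigenproblem(unit_sphere, 40)


@pytest.fixture(scope="session")
def flat_square_mesh():
    return make_flat_square(33, 1.0)
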
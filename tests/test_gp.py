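import numpy as np
import pytest
from scipy.stats import spearmanr

from erpfields.manifold import (
    KernelSpec,
    TriangleMeshManifold,
    biharmonic_distance,
    biharmonic_distance_matrix,
    calibrate_lengthscale_mm,
    evaluate_field,
    sample_field,
    solve_eigenproblem,
    spectral_density,
    spectral_weights,
    transfer_field,
)
from erpfields.synthetic import icosphere

from conftest import make_flat_square


# -- spectral densities ------------------------------------------------------

def test_spectral_density_decreasing():
    w = np.linspace(0.0, 10.0, 200)
    for fam in ("rbf", "matern52"):
        S = spectral_density(fam, w, rho=1.5)
        assert np.all(S > 0)
        assert np.all(np.diff(S) < 0)
        assert S[0] > S[-1]


def test_rbf_closed_form_matches_numerical_fourier():
    # 2D radial Fourier transform of exp(-r^2 / (2 rho^2)) via Hankel integral
    from scipy.integrate import quad
    from scipy.special import j0

    rho = 0.8
    for omega in (0.5, 1.0 / rho, 2.0):
        num, _ = quad(
            lambda r: np.exp(-0.5 * (r / rho) ** 2) * j0(omega * r) * r,
            0, 30 * rho, limit=200,
        )
        num *= 2.0 * np.pi  # S(w) = 2 pi int k(r) J0(w r) r dr
        assert spectral_density("rbf", omega, rho) == pytest.approx(num, rel=1e-6)


def test_rbf_doubling_rho_closed_form():
    rho = 0.7
    omega = 1.0 / rho
    s1 = spectral_density("rbf", omega, rho)
    s2 = spectral_density("rbf", omega, 2.0 * rho)
    # closed form: 2 pi rho^2 exp(-rho^2 w^2 / 2)
    assert s2 / s1 == pytest.approx(4.0 * np.exp(-1.5), rel=1e-12)


def test_matern_heavier_tail_than_rbf():
    rho = 1.0
    ratio = [
        spectral_density("matern52", w, rho) / spectral_density("rbf", w, rho)
        for w in (2.0, 4.0, 8.0)
    ]
    assert ratio[0] < ratio[1] < ratio[2]


def test_unknown_family_rejected():
    with pytest.raises(ValueError):
        spectral_density("cauchy", 1.0, 1.0)
    with pytest.raises(ValueError):
        KernelSpec("cauchy", 1.0)


def test_spectral_weights_nonincreasing(unit_sphere_basis):
    w = spectral_weights(unit_sphere_basis, KernelSpec("rbf", 0.5))
    assert np.all(np.diff(w) <= 1e-15)


def test_spectral_weight_rho_gradient(unit_sphere_basis):
    k = KernelSpec("rbf", 0.5)
    w, dw = spectral_weights(unit_sphere_basis, k, with_grad=True)
    eps = 1e-6
    wp = spectral_weights(unit_sphere_basis, KernelSpec("rbf", 0.5 * np.exp(eps)))
    wm = spectral_weights(unit_sphere_basis, KernelSpec("rbf", 0.5 * np.exp(-eps)))
    fd = (wp - wm) / (2 * eps)
    assert np.allclose(dw, fd, atol=1e-6)


# -- field evaluation and sampling ------------------------------------------

def test_zero_eta_gives_constant_mean(unit_sphere_basis):
    f = evaluate_field(unit_sphere_basis, KernelSpec("rbf", 0.5), 3.5,
                       np.zeros(unit_sphere_basis.K))
    assert np.allclose(f, 3.5)


def test_field_linear_in_eta(unit_sphere_basis):
    k = KernelSpec("rbf", 0.5)
    rng = np.random.default_rng(0)
    ea, eb = rng.standard_normal((2, unit_sphere_basis.K))
    m = 2.0
    fa = evaluate_field(unit_sphere_basis, k, m, ea)
    fb = evaluate_field(unit_sphere_basis, k, m, eb)
    fab = evaluate_field(unit_sphere_basis, k, m, ea + eb)
    assert np.allclose(fab, fa + fb - m, atol=1e-10)


def test_eta_length_checked(unit_sphere_basis):
    with pytest.raises(ValueError):
        evaluate_field(unit_sphere_basis, KernelSpec("rbf", 0.5), 0.0,
                       np.zeros(3))


def test_pointwise_sd_approximates_alpha(unit_sphere_basis):
    k = KernelSpec("rbf", 0.4, alpha=2.5)
    fields = np.stack(
        [sample_field(unit_sphere_basis, k, 0.0, s) for s in range(2000)]
    )
    sd = fields.std(axis=0)
    assert abs(sd.mean() - 2.5) / 2.5 < 0.1


def test_sample_reproducible(unit_sphere_basis):
    k = KernelSpec("matern52", 0.5)
    a = sample_field(unit_sphere_basis, k, 1.0, seed=123)
    b = sample_field(unit_sphere_basis, k, 1.0, seed=123)
    c = sample_field(unit_sphere_basis, k, 1.0, seed=124)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_sample_mean_converges_to_m(unit_sphere_basis):
    k = KernelSpec("rbf", 0.5)
    fields = np.stack(
        [sample_field(unit_sphere_basis, k, 7.0, s) for s in range(1500)]
    )
    assert abs(fields.mean() - 7.0) < 0.15


def test_nearby_correlation_exceeds_distant(unit_sphere, unit_sphere_basis):
    k = KernelSpec("rbf", 0.5)
    fields = np.stack(
        [sample_field(unit_sphere_basis, k, 0.0, s) for s in range(800)]
    )
    v0 = 0
    d = np.linalg.norm(unit_sphere.vertices - unit_sphere.vertices[v0], axis=1)
    near = int(np.argsort(d)[1])
    far = int(np.argmax(d))
    corr = np.corrcoef(fields[:, [v0, near, far]].T)
    assert corr[0, 1] > corr[0, 2]
    assert corr[0, 1] > 0.8


def test_small_k_warns():
    basis = solve_eigenproblem(icosphere(2), 20)
    with pytest.warns(UserWarning, match="too small"):
        sample_field(basis, KernelSpec("rbf", 0.2), 0.0, 0)


# -- biharmonic distance -----------------------------------------------------

def test_biharmonic_identity_and_symmetry(unit_sphere_basis):
    assert biharmonic_distance(unit_sphere_basis, 5, 5) == 0.0
    d_ij = biharmonic_distance(unit_sphere_basis, 3, 77)
    d_ji = biharmonic_distance(unit_sphere_basis, 77, 3)
    assert d_ij == pytest.approx(d_ji, rel=1e-12)
    assert d_ij > 0


def test_biharmonic_index_checked(unit_sphere_basis):
    with pytest.raises(IndexError):
        biharmonic_distance(unit_sphere_basis, 0, 10**6)


def test_biharmonic_matches_matrix_form(unit_sphere_basis):
    D = biharmonic_distance_matrix(unit_sphere_basis, np.array([3]), np.array([77]))
    assert D[0, 0] == pytest.approx(
        biharmonic_distance(unit_sphere_basis, 3, 77), rel=1e-12
    )


def test_biharmonic_monotone_with_great_circle():
    sph = icosphere(3, 1.0)
    basis = solve_eigenproblem(sph, 192)
    rng = np.random.default_rng(0)
    idx = rng.choice(sph.n_vertices, 100, replace=False)
    gc = np.arccos(np.clip(sph.vertices[idx] @ sph.vertices[0], -1, 1))
    dbh = biharmonic_distance_matrix(basis, np.array([0]), idx)[0]
    assert spearmanr(gc, dbh).statistic > 0.99


# -- lengthscale calibration -------------------------------------------------

@pytest.fixture(scope="module")
def flat_100mm():
    mesh = make_flat_square(41, side=100.0)
    return mesh, solve_eigenproblem(mesh, 256)


def test_lengthscale_factor_near_unity_on_flat(flat_100mm):
    mesh, basis = flat_100mm
    fac = calibrate_lengthscale_mm(
        mesh, basis, KernelSpec("rbf", 10.0), n_samples=800, seed=0
    )
    assert abs(fac - 1.0) < 0.10


def test_lengthscale_factor_seed_stability(flat_100mm):
    mesh, basis = flat_100mm
    a = calibrate_lengthscale_mm(mesh, basis, KernelSpec("rbf", 10.0),
                                 n_samples=1000, seed=1)
    b = calibrate_lengthscale_mm(mesh, basis, KernelSpec("rbf", 10.0),
                                 n_samples=1000, seed=2)
    assert abs(a - b) / a < 0.05


def test_lengthscale_rescale_law(flat_100mm):
    mesh, basis = flat_100mm
    fac = calibrate_lengthscale_mm(mesh, basis, KernelSpec("rbf", 10.0),
                                   n_samples=800, seed=0)
    big = TriangleMeshManifold(2.0 * mesh.vertices, mesh.triangles)
    basis2 = solve_eigenproblem(big, 256)
    fac2 = calibrate_lengthscale_mm(big, basis2, KernelSpec("rbf", 20.0),
                                    n_samples=800, seed=0)
    # eigenvalues scale as 1/s^2, so the mm-per-unit factor is preserved
    assert fac2 == pytest.approx(fac, rel=0.05)


def test_lengthscale_degenerate_rho_rejected(flat_100mm):
    mesh, basis = flat_100mm
    with pytest.raises(ValueError, match="smaller rho"):
        calibrate_lengthscale_mm(mesh, basis, KernelSpec("rbf", 500.0),
                                 n_samples=200, seed=0)


# -- field transfer ----------------------------------------------------------

def test_transfer_constant_field():
    coarse = icosphere(2, 1.0)
    fine = icosphere(3, 1.0)
    out = transfer_field(coarse, np.full(coarse.n_vertices, 4.2), fine,
                         radius=0.5)
    assert np.allclose(out, 4.2)


def test_transfer_exact_at_coincident_vertices():
    coarse = icosphere(2, 1.0)
    rng = np.random.default_rng(1)
    vals = rng.standard_normal(coarse.n_vertices)
    out = transfer_field(coarse, vals, coarse, radius=0.5)
    assert np.allclose(out, vals)


def test_transfer_linear_field_error_bound():
    coarse = make_flat_square(21, side=1.0)
    fine = make_flat_square(41, side=1.0)
    grad = 3.0
    vals = grad * coarse.vertices[:, 0]
    radius = 0.08
    out = transfer_field(coarse, vals, fine, radius=radius)
    err = np.abs(out - grad * fine.vertices[:, 0])
    assert err.max() < radius * grad


def test_transfer_far_vertex_warns():
    coarse = icosphere(1, 1.0)
    far = TriangleMeshManifold(
        coarse.vertices + np.array([10.0, 0, 0]), coarse.triangles
    )
    with pytest.warns(UserWarning, match="nearest"):
        transfer_field(coarse, np.ones(coarse.n_vertices), far, radius=0.5)
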
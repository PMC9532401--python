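import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import invgamma

from erpfields.calibration import (
    ERPIntervalObservation,
    HyperPriors,
    MCMCConfig,
    PosteriorModel,
    PosteriorSampleSet,
    log_prior,
    retained_draw_count,
    run_mcmc,
)
from erpfields.manifold import solve_eigenproblem
from erpfields.synthetic import icosphere


@pytest.fixture(scope="module")
def small_basis():
    return solve_eigenproblem(icosphere(2, radius=25.0), 16)


@pytest.fixture(scope="module")
def obs5():
    return [
        ERPIntervalObservation(v, p, low, 10.0)
        for v, p, low in [(3, "S2", 240.0), (3, "S3", 200.0),
                          (40, "S2", 250.0), (80, "S3", 190.0),
                          (120, "S2", 230.0)]
    ]


def model_for(basis, obs, toy):
    f1, f2 = toy
    return PosteriorModel(basis, obs, f1, f2)


# -- priors ------------------------------------------------------------------

def test_invgamma_prior_mode():
    # InvGamma(1.01, 20) mode at beta/(alpha+1); verified by maximizing the pdf
    a, b = 1.01, 20.0
    res = minimize_scalar(lambda x: -invgamma.logpdf(x, a, scale=b),
                          bounds=(0.1, 100.0), method="bounded")
    assert res.x == pytest.approx(b / (a + 1.0), rel=1e-4)


def test_log_prior_values():
    eta = [np.array([0.5, -1.0]), np.array([0.0, 2.0])]
    lp = log_prior([15.0, 195.0], [3.0, 4.0], [10.0, 20.0], eta)
    expected = (
        invgamma.logpdf(10.0, 1.01, scale=20.0)
        + invgamma.logpdf(20.0, 1.01, scale=20.0)
        + invgamma.logpdf(3.0, 1.0, scale=5.0)
        + invgamma.logpdf(4.0, 1.0, scale=5.0)
        + sum(-0.5 * e @ e - len(e) * 0.5 * math.log(2 * math.pi) for e in eta)
    )
    assert lp == pytest.approx(expected, rel=1e-12)


def test_log_prior_flat_in_m_within_bounds():
    eta = [np.zeros(2), np.zeros(2)]
    a = log_prior([10.0, 180.0], [3.0, 4.0], [10.0, 20.0], eta)
    b = log_prior([20.0, 210.0], [3.0, 4.0], [10.0, 20.0], eta)
    assert a == pytest.approx(b, rel=1e-12)


def test_log_prior_nonpositive_scales():
    eta = [np.zeros(2), np.zeros(2)]
    assert log_prior([10, 180], [-1.0, 4.0], [10, 20], eta) == -math.inf
    assert log_prior([10, 180], [3.0, 4.0], [0.0, 20], eta) == -math.inf


def test_eta_prior_term():
    eta1 = np.ones(8)
    base = log_prior([10, 180], [3, 4], [10, 20], [np.zeros(8), np.zeros(8)])
    with_eta = log_prior([10, 180], [3, 4], [10, 20], [eta1, np.zeros(8)])
    assert with_eta - base == pytest.approx(-0.5 * 8.0, rel=1e-12)


# -- posterior ---------------------------------------------------------------

def test_zero_observations_equals_prior_plus_jacobian(small_basis, toy_surrogates):
    m = PosteriorModel(small_basis, [], *toy_surrogates)
    rng = np.random.default_rng(0)
    z = m.initial_position(rng)
    mm, alpha, rho, e1, e2 = m.unpack(z)
    expected = (
        log_prior(mm, alpha, rho, [e1, e2])
        + math.log(alpha[0]) + math.log(alpha[1])
        + math.log(rho[0]) + math.log(rho[1])
    )
    assert m.log_posterior(z, with_grad=False) == pytest.approx(expected, rel=1e-10)


def test_gradient_matches_finite_differences(small_basis, toy_surrogates, obs5):
    m = model_for(small_basis, obs5, toy_surrogates)
    rng = np.random.default_rng(1)
    z = m.initial_position(rng)
    lp, g = m.log_posterior(z)
    eps = 1e-6
    for i in range(m.dim):
        zp, zm = z.copy(), z.copy()
        zp[i] += eps
        zm[i] -= eps
        fd = (m.log_posterior(zp, with_grad=False)
              - m.log_posterior(zm, with_grad=False)) / (2 * eps)
        assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)


def test_likelihood_permutation_invariant(small_basis, toy_surrogates, obs5):
    m1 = model_for(small_basis, obs5, toy_surrogates)
    m2 = model_for(small_basis, list(reversed(obs5)), toy_surrogates)
    rng = np.random.default_rng(2)
    z = m1.initial_position(rng)
    assert m1.log_posterior(z, with_grad=False) == pytest.approx(
        m2.log_posterior(z, with_grad=False), rel=1e-12
    )


def test_observation_vertex_validated(small_basis, toy_surrogates):
    bad = [ERPIntervalObservation(10**6, "S2", 240.0, 10.0)]
    with pytest.raises(ValueError, match="not on the mesh"):
        PosteriorModel(small_basis, bad, *toy_surrogates)


def test_posterior_finite_in_masked_region(small_basis, toy_surrogates, obs5):
    # even where the f2 mask applies, the sampler never sees +-inf from plumbing
    m = model_for(small_basis, obs5, toy_surrogates)
    z = m.pack([29.0, 268.0], [1.0, 1.0], [20.0, 20.0],
               np.zeros(m.K), np.zeros(m.K))
    lp = m.log_posterior(z, with_grad=False)
    assert np.isfinite(lp)


def test_bracket_padding_widens_interval(small_basis, toy_surrogates):
    obs = [ERPIntervalObservation(3, "S2", 240.0, 10.0)]
    plain = PosteriorModel(small_basis, obs, *toy_surrogates)
    padded = PosteriorModel(small_basis, obs, *toy_surrogates, bracket_pad=2.0)
    sidx, intervals = padded._obs_by_proto["S2"]
    assert intervals[0] == (238.0, 14.0)
    sidx, intervals = plain._obs_by_proto["S2"]
    assert intervals[0] == (240.0, 10.0)


# -- MCMC --------------------------------------------------------------------

def std_normal_target(z):
    return -0.5 * float(z @ z), -z


def test_retained_count_default_is_200():
    assert retained_draw_count(MCMCConfig()) == 200


def test_retained_counts_various():
    assert retained_draw_count(
        MCMCConfig(iterations=1000, chains=4, thin=10)) == 200
    assert retained_draw_count(
        MCMCConfig(iterations=100, chains=2, thin=7)) == 2 * (50 // 7)


def test_mcmc_standard_normal_moments():
    cfg = MCMCConfig(iterations=3000, chains=4, thin=5, seed=11, n_leapfrog=12)
    s = run_mcmc(std_normal_target, 2, cfg)
    assert s.n_retained == retained_draw_count(cfg)
    ess = np.nanmin(s.diagnostics["ess_bulk"])
    mcse = 1.0 / np.sqrt(ess)
    assert np.all(np.abs(s.draws.mean(axis=0)) < 3.0 * mcse)
    assert np.all(np.abs(s.draws.std(axis=0) - 1.0) < 0.1)
    assert np.nanmax(s.diagnostics["split_rhat"]) < 1.05


def test_mcmc_seeded_reproducibility():
    cfg = MCMCConfig(iterations=500, chains=2, thin=10, seed=7, n_leapfrog=8)
    a = run_mcmc(std_normal_target, 3, cfg)
    b = run_mcmc(std_normal_target, 3, cfg)
    assert np.array_equal(a.draws, b.draws)
    assert np.array_equal(a.chain_ids, b.chain_ids)
    c = run_mcmc(std_normal_target, 3,
                 MCMCConfig(iterations=500, chains=2, thin=10, seed=8,
                            n_leapfrog=8))
    assert not np.array_equal(a.draws, c.draws)


def test_map_draw_property():
    cfg = MCMCConfig(iterations=400, chains=2, thin=10, seed=3, n_leapfrog=8)
    s = run_mcmc(std_normal_target, 2, cfg)
    k = int(np.argmax(s.log_posteriors))
    assert np.array_equal(s.map_draw, s.draws[k])


def test_divergence_warning():
    # hard barrier: trajectories crossing it have non-finite energy error
    def walled(z):
        if z[0] > 0.3:
            return -math.inf, np.zeros_like(z)
        return -0.5 * float(z @ z), -z

    cfg = MCMCConfig(iterations=400, chains=2, thin=10, seed=0,
                     n_leapfrog=8, max_divergence_fraction=0.001)
    with pytest.warns(UserWarning, match="divergent"):
        run_mcmc(walled, 2, cfg,
                 initial_position=lambda rng: np.array([-1.0, 0.0]))


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        MCMCConfig(iterations=1)
    with pytest.raises(ValueError):
        MCMCConfig(burn_in_fraction=1.0)
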
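import numpy as np
import pytest

from erpfields.calibration import (
    ERPIntervalObservation,
    FieldSampleSet,
    MCMCConfig,
    PosteriorModel,
    constrain_fields,
    posterior_fields,
    run_mcmc,
)
from erpfields.synthetic import (
    design_observation_sites,
    generate_ground_truth,
    observe_erp,
    validate,
)
from erpfields.synthetic.observe import _bracket
from erpfields.synthetic.truth import _scale_into


# -- posterior field evaluation ---------------------------------------------

@pytest.fixture(scope="module")
def tiny_run(toy_surrogates):
    from erpfields.manifold import solve_eigenproblem
    from erpfields.synthetic import icosphere

    basis = solve_eigenproblem(icosphere(2, radius=25.0), 12)
    obs = [ERPIntervalObservation(3, "S2", 240.0, 10.0),
           ERPIntervalObservation(40, "S3", 190.0, 10.0)]
    model = PosteriorModel(basis, obs, *toy_surrogates)
    cfg = MCMCConfig(iterations=200, chains=2, thin=20, seed=1, n_leapfrog=8)
    samples = run_mcmc(model.log_posterior, model.dim, cfg,
                       initial_position=model.initial_position)
    return basis, model, samples


def test_posterior_fields_shapes_and_map(tiny_run):
    basis, model, samples = tiny_run
    fields = posterior_fields(samples, model)
    assert fields.theta1.shape == (samples.n_retained, basis.n_vertices)
    assert fields.map_index == int(np.argmax(samples.log_posteriors))
    s = fields.summaries()
    assert s["tau_out"]["mean"].shape == (basis.n_vertices,)


def test_single_draw_summaries(tiny_run):
    basis, model, samples = tiny_run
    fields = posterior_fields(samples, model)
    one = FieldSampleSet(
        theta1=fields.theta1[:1], theta2=fields.theta2[:1],
        log_posteriors=fields.log_posteriors[:1],
    )
    s = one.summaries()
    assert np.allclose(s["tau_out"]["mean"], one.theta1[0])
    assert np.allclose(s["tau_out"]["sd"], 0.0)


def test_empty_sample_set_rejected(tiny_run):
    basis, model, samples = tiny_run
    empty = samples
    import dataclasses
    empty = dataclasses.replace(samples, draws=samples.draws[:0],
                                log_posteriors=samples.log_posteriors[:0])
    with pytest.raises(ValueError):
        posterior_fields(empty, model)


# -- constraint projection ---------------------------------------------------

def test_constrain_noop_below_ceiling(tiny_run, toy_surrogates):
    basis, model, samples = tiny_run
    f1, _ = toy_surrogates
    n = basis.n_vertices
    fields = FieldSampleSet(
        theta1=np.full((2, n), 10.0), theta2=np.full((2, n), 180.0),
        log_posteriors=np.zeros(2),
    )
    out, rep = constrain_fields(fields, f1, basis)
    assert np.array_equal(out.theta1, fields.theta1)
    assert rep["initial_violations"] == [0, 0]


def test_constrain_replaces_with_convex_combination(tiny_run, toy_surrogates):
    basis, model, samples = tiny_run
    f1, _ = toy_surrogates
    n = basis.n_vertices
    rng = np.random.default_rng(0)
    th1 = rng.uniform(5.0, 12.0, size=(1, n))
    th2 = rng.uniform(150.0, 200.0, size=(1, n))
    th2[0, :5] = 320.0  # push a few vertices far above the ceiling
    fields = FieldSampleSet(theta1=th1, theta2=th2, log_posteriors=np.zeros(1))
    assert (f1(th1[0], th2[0]) > 280.0).sum() >= 5
    out, rep = constrain_fields(fields, f1, basis)
    assert rep["initial_violations"][0] >= 5
    assert rep["final_violations"][0] == 0
    good = f1(th1[0], th2[0]) <= 280.0
    lo1, hi1 = th1[0, good].min(), th1[0, good].max()
    lo2, hi2 = th2[0, good].min(), th2[0, good].max()
    changed = ~good
    assert np.all(out.theta1[0, changed] >= lo1 - 1e-9)
    assert np.all(out.theta1[0, changed] <= hi1 + 1e-9)
    assert np.all(out.theta2[0, changed] >= lo2 - 1e-9)
    assert np.all(out.theta2[0, changed] <= hi2 + 1e-9)
    # untouched vertices preserved exactly
    assert np.array_equal(out.theta1[0, good], th1[0, good])


def test_constrain_all_bad_flagged(tiny_run, toy_surrogates):
    basis, model, samples = tiny_run
    f1, _ = toy_surrogates
    n = basis.n_vertices
    fields = FieldSampleSet(
        theta1=np.full((1, n), 29.0), theta2=np.full((1, n), 269.0),
        log_posteriors=np.zeros(1),
    )
    assert (f1(fields.theta1[0], fields.theta2[0]) > 280.0).all()
    out, rep = constrain_fields(fields, f1, basis)
    assert rep["invalid_draws"] == [0]
    assert np.array_equal(out.theta1, fields.theta1)  # not silently altered


# -- ground truth ------------------------------------------------------------

def test_scale_into_minmax_and_quantile():
    raw = np.array([-2.0, 0.0, 1.0, 5.0])
    out = _scale_into(raw, 1.0, 30.0, "minmax")
    assert out.min() == pytest.approx(1.0)
    assert out.max() == pytest.approx(30.0)
    q = _scale_into(raw, 0.0, 1.0, "quantile")
    assert np.array_equal(np.argsort(q), np.argsort(raw))


def test_ground_truth_reproducible(sphere25, sphere25_basis, surrogates):
    f1, f2 = surrogates
    a = generate_ground_truth(sphere25, 40.0, 5, f1, f2, basis=sphere25_basis)
    b = generate_ground_truth(sphere25, 40.0, 5, f1, f2, basis=sphere25_basis)
    assert np.array_equal(a.tau_out, b.tau_out)
    assert np.array_equal(a.erp_s3, b.erp_s3)


def test_ground_truth_ranges_and_ceiling(sphere25, sphere25_basis, surrogates):
    f1, f2 = surrogates
    sc = generate_ground_truth(sphere25, 40.0, 5, f1, f2, basis=sphere25_basis)
    assert sc.tau_out.min() >= 1.0 - 1e-9 and sc.tau_out.max() <= 30.0 + 1e-9
    assert sc.cv_max.min() >= 0.1 - 1e-9 and sc.cv_max.max() <= 1.5 + 1e-9
    assert np.all(sc.erp_s2 <= 280.0 + 1e-6)


def test_larger_rho_gives_smoother_fields(sphere25, sphere25_basis, surrogates):
    f1, f2 = surrogates
    edges = sphere25.edge_graph.tocoo()
    sel = edges.row < edges.col

    def roughness(field):
        return np.abs(field[edges.row[sel]] - field[edges.col[sel]]).mean()

    rough = []
    for rho in (15.0, 60.0):
        vals = []
        for seed in range(4):
            sc = generate_ground_truth(sphere25, rho, seed, f1, f2,
                                       basis=sphere25_basis)
            vals.append(roughness(sc.apd_max))
        rough.append(np.mean(vals))
    assert rough[1] < rough[0]


# -- observation designs -----------------------------------------------------

def test_design_sites_sphere(sphere25):
    d = design_observation_sites(sphere25, 10, seed=0)
    assert d.n == 10
    assert len(np.unique(d.vertex_ids)) == 10


def test_design_sites_respect_boundary_exclusion():
    from erpfields.synthetic import make_fixture_mesh

    mesh = make_fixture_mesh("cylinder-with-holes", 1.5, scale=15.0)
    d = design_observation_sites(mesh, 6, exclusion_radius=6.0, seed=1)
    bdist = mesh.distance_to_boundary()
    assert np.all(bdist[d.vertex_ids] >= 6.0)


def test_design_sites_beats_random(sphere25):
    d = design_observation_sites(sphere25, 10, seed=0)
    rng = np.random.default_rng(123)
    pts = sphere25.vertices

    def crit(ids):
        p = pts[ids]
        dd = np.linalg.norm(p[:, None] - p[None, :], axis=-1)
        np.fill_diagonal(dd, np.inf)
        return dd.min()

    beaten = sum(
        crit(rng.choice(sphere25.n_vertices, 10, replace=False)) > d.criterion
        for _ in range(100)
    )
    assert beaten == 0


def test_design_too_many_sites_rejected():
    from erpfields.synthetic import make_fixture_mesh

    mesh = make_fixture_mesh("cylinder-with-holes", 2.0, scale=10.0)
    with pytest.raises(ValueError, match="admissible"):
        design_observation_sites(mesh, 10**5, exclusion_radius=6.0)


# -- observations ------------------------------------------------------------

def test_bracket_helper():
    assert _bracket(245.3, 10.0) == 240.0
    assert _bracket(240.0, 10.0) == 230.0  # on-grid values take the lower cell
    assert _bracket(7.0, 5.0) == 5.0


def test_observe_brackets_contain_truth(sphere25, sphere25_basis, surrogates):
    f1, f2 = surrogates
    sc = generate_ground_truth(sphere25, 40.0, 5, f1, f2, basis=sphere25_basis)
    design = design_observation_sites(sphere25, 8, seed=0)
    obs = observe_erp(sc, design, 10.0)
    assert len(obs) == 16  # two protocols per site
    truth = {"S2": sc.erp_s2, "S3": sc.erp_s3}
    for o in obs:
        val = truth[o.protocol][o.vertex]
        assert o.interval_low <= val <= o.interval_low + o.interval_width
        assert o.interval_width == 10.0


def test_observe_nested_at_half_resolution(sphere25, sphere25_basis, surrogates):
    f1, f2 = surrogates
    sc = generate_ground_truth(sphere25, 40.0, 5, f1, f2, basis=sphere25_basis)
    design = design_observation_sites(sphere25, 5, seed=0)
    coarse = {(o.vertex, o.protocol): o for o in observe_erp(sc, design, 10.0)}
    fine = {(o.vertex, o.protocol): o for o in observe_erp(sc, design, 5.0)}
    for key, o in fine.items():
        c = coarse[key]
        assert c.interval_low <= o.interval_low
        assert o.interval_low + 5.0 <= c.interval_low + 10.0


def test_observe_resolution_validated(sphere25, sphere25_basis, surrogates):
    f1, f2 = surrogates
    sc = generate_ground_truth(sphere25, 40.0, 5, f1, f2, basis=sphere25_basis)
    design = design_observation_sites(sphere25, 3, seed=0)
    with pytest.raises(ValueError):
        observe_erp(sc, design, -1.0)


# -- validation metrics ------------------------------------------------------

def test_validate_perfect_posterior(sphere25, sphere25_basis, surrogates):
    f1, f2 = surrogates
    sc = generate_ground_truth(sphere25, 40.0, 5, f1, f2, basis=sphere25_basis)
    n = sphere25.n_vertices
    # two identical draws equal to truth: RMSE 0, sd 0 everywhere -> excluded
    fields = FieldSampleSet(
        theta1=np.tile(sc.tau_out, (2, 1)), theta2=np.tile(sc.apd_max, (2, 1)),
        log_posteriors=np.zeros(2),
    )
    m = validate(sc, fields, f1, f2)
    assert m.rmse_map["S2"] == pytest.approx(0.0, abs=1e-9)
    assert m.excluded["S2"] == n


def test_validate_ise_shift_invariant(sphere25, sphere25_basis, surrogates):
    f1, f2 = surrogates
    sc = generate_ground_truth(sphere25, 40.0, 5, f1, f2, basis=sphere25_basis)
    rng = np.random.default_rng(0)
    n = sphere25.n_vertices
    th1 = sc.tau_out + rng.normal(0, 0.5, size=(6, n))
    th2 = sc.apd_max + rng.normal(0, 3.0, size=(6, n))
    fields = FieldSampleSet(theta1=th1, theta2=th2,
                            log_posteriors=rng.standard_normal(6))
    m = validate(sc, fields, f1, f2)
    assert np.isfinite(m.ise["S2"]).all()
    assert 0.0 <= m.ise_below_3["S2"] <= 1.0
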
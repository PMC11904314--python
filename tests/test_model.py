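"""Linear predictor, the three observation log-likelihoods, and the joint
objective (reduction, additivity, gradient correctness)."""

import numpy as np
import pytest
from scipy.stats import poisson

from sdmfuse import (
    CovariateRaster,
    JointModel,
    KnotGrid,
    MaternParams,
    ModelSpec,
    ModelState,
    PCPrior,
    Priors,
    SpatialField,
    count_loglik,
    joint_objective,
    linear_predictor,
    make_grid,
    pa_loglik,
    po_loglik,
)
from sdmfuse.errors import SDMFuseError

from conftest import make_counts, make_pa, make_po

PRIOR = PCPrior(200.0, 0.2, 1.0, 0.01)


@pytest.fixture(scope="module")
def cov(unit_square):
    grid = make_grid(unit_square, 4, 4)
    vals = np.linspace(-1.5, 1.5, 16)
    return {"x1": CovariateRaster(grid=grid, values=vals, name="x1")}


def _state(alpha=0.0, beta=(), gamma=(), z=(), b=()):
    return ModelState(alpha=alpha, beta=np.array(beta, float), gamma=np.array(gamma, float),
                      z=np.array(z, float), b=np.array(b, float))


class TestLinearPredictor:
    def test_constant_when_only_intercept(self, cov):
        spec = ModelSpec(shared_field=False)
        locs = np.array([[0.1, 0.1], [0.9, 0.9]])
        eta = linear_predictor(_state(alpha=-1.3), spec, locs, cov)
        assert np.allclose(eta, -1.3)

    def test_covariate_contribution(self, cov):
        spec = ModelSpec(process_covariates=("x1",), shared_field=False)
        x_val = cov["x1"].value_at(0.9, 0.9)[0]
        eta = linear_predictor(_state(alpha=-1.0, beta=[2.0]), spec, [[0.9, 0.9]], cov)
        assert np.isclose(eta[0], -1.0 + 2.0 * x_val)

    def test_bias_terms_are_exactly_the_difference(self, cov):
        kg = KnotGrid.over_bounds((0, 0, 1, 1), 3, 3)
        bias = SpatialField(knots=kg, params=MaternParams(1, 1), prior=PRIOR, role="bias")
        spec = ModelSpec(process_covariates=("x1",), bias_covariates=("x1",),
                         shared_field=False, bias_field=True)
        st = _state(alpha=0.5, beta=[1.0], gamma=[0.7], b=np.arange(9.0))
        locs = np.array([[0.2, 0.3], [0.8, 0.6]])
        plain = linear_predictor(st, spec, locs, cov, with_bias=False, bias_field=bias)
        with_b = linear_predictor(st, spec, locs, cov, with_bias=True, bias_field=bias)
        bias_only = linear_predictor(
            _state(gamma=[0.7], b=np.arange(9.0)),
            ModelSpec(bias_covariates=("x1",), shared_field=False, bias_field=True),
            locs, cov, with_bias=True, bias_field=bias,
        )
        assert np.allclose(with_b - plain, bias_only)


class TestPoLoglik:
    def test_constant_intensity_closed_form(self, unit_scheme, cov):
        # lambda* = 2 on the unit square with 3 points: 3 log 2 - 2
        ds = make_po([[0.2, 0.2], [0.5, 0.5], [0.8, 0.8]])
        spec = ModelSpec(shared_field=False)
        ll = po_loglik(ds, _state(alpha=np.log(2.0)), spec, unit_scheme, cov)
        assert np.isclose(ll, 3 * np.log(2.0) - 2.0, atol=1e-9)

    def test_zero_points_unit_intensity(self, unit_scheme, cov):
        ds = make_po(np.zeros((0, 2)))
        ll = po_loglik(ds, _state(alpha=0.0), ModelSpec(shared_field=False), unit_scheme, cov)
        assert np.isclose(ll, -1.0)

    def test_quadrature_term_matches_dense_riemann(self, unit_square):
        # seeded nonconstant eta via a bilinear field; 512x512 Riemann oracle
        from sdmfuse import build_integration_scheme
        from sdmfuse.fields import bilinear_weights

        kg = KnotGrid.over_bounds((0, 0, 1, 1), 5, 5)
        rng = np.random.default_rng(42)
        z = 0.8 * rng.standard_normal(25)
        shared = SpatialField(knots=kg, params=MaternParams(1, 1), prior=PRIOR)
        spec = ModelSpec(shared_field=True)
        st = _state(alpha=0.3, z=z)
        scheme = build_integration_scheme(make_grid(unit_square, 128, 128))
        ds = make_po(np.zeros((0, 2)))
        ll = po_loglik(ds, st, spec, scheme, {}, shared_field=shared)
        quad_term = -ll  # zero points: loglik = -integral

        n = 512
        cx = (np.arange(n) + 0.5) / n
        gx, gy = np.meshgrid(cx, cx)
        B = bilinear_weights(kg, gx.ravel(), gy.ravel())
        riemann = np.exp(0.3 + B @ z).sum() / n**2
        assert abs(quad_term - riemann) / riemann < 1e-3


class TestPaLoglik:
    def test_single_presence_closed_form(self, cov):
        ds = make_pa([[0.5, 0.5]], [1])
        ll = pa_loglik(ds, _state(), ModelSpec(shared_field=False), cov)
        assert np.isclose(ll, np.log(1 - np.exp(-1.0)), atol=1e-9)

    def test_single_absence_closed_form(self, cov):
        ds = make_pa([[0.5, 0.5]], [0])
        ll = pa_loglik(ds, _state(), ModelSpec(shared_field=False), cov)
        assert np.isclose(ll, -1.0, atol=1e-9)

    def test_mixed_records_match_bruteforce(self, cov):
        rng = np.random.default_rng(3)
        sites = rng.random((10, 2))
        y = rng.integers(0, 2, 10)
        ds = make_pa(sites, y, exposure=1.7)
        spec = ModelSpec(process_covariates=("x1",), shared_field=False)
        st = _state(alpha=-0.4, beta=[0.9])
        ll = pa_loglik(ds, st, spec, cov)
        brute = 0.0
        for i in range(10):  # per-record loop oracle
            eta = -0.4 + 0.9 * cov["x1"].value_at(sites[i, 0], sites[i, 1])[0]
            p = 1 - np.exp(-1.7 * np.exp(eta))
            brute += np.log(p) if y[i] else np.log(1 - p)
        assert np.isclose(ll, brute, rtol=1e-12)

    def test_cloglog_small_exposure_linearizes(self, cov):
        # p/E -> exp(eta) as E -> 0
        ds = make_pa([[0.5, 0.5]], [1], exposure=1e-6)
        eta = 0.3
        p = 1 - np.exp(-1e-6 * np.exp(eta))
        assert np.isclose(p / 1e-6, np.exp(eta), rtol=1e-5)


class TestCountLoglik:
    def test_closed_forms(self, cov):
        spec = ModelSpec(shared_field=False)
        ll = count_loglik(make_counts([[0.5, 0.5]], [2]), _state(), spec, cov)
        assert np.isclose(ll, -1.0 - np.log(2.0), atol=1e-12)
        ll0 = count_loglik(
            make_counts([[0.5, 0.5]], [0], exposure=2.0), _state(alpha=np.log(3.0)), spec, cov
        )
        assert np.isclose(ll0, -6.0, atol=1e-12)

    def test_vector_matches_poisson_pmf_sum(self, cov):
        rng = np.random.default_rng(5)
        sites = rng.random((8, 2))
        y = rng.poisson(2.0, 8)
        ds = make_counts(sites, y, exposure=1.3)
        spec = ModelSpec(process_covariates=("x1",), shared_field=False)
        st = _state(alpha=0.2, beta=[0.5])
        brute = sum(  # loop oracle
            poisson.logpmf(
                int(y[i]),
                1.3 * np.exp(0.2 + 0.5 * cov["x1"].value_at(sites[i, 0], sites[i, 1])[0]),
            )
            for i in range(8)
        )
        assert np.isclose(count_loglik(ds, st, spec, cov), brute, rtol=1e-12)

    def test_negative_count_rejected(self, cov):
        ds = make_counts([[0.5, 0.5]], [2])
        ds.records.loc[0, "count"] = -1.0
        with pytest.raises(SDMFuseError) as exc:
            count_loglik(ds, _state(), ModelSpec(shared_field=False), cov)
        assert exc.value.code == "bad-count"


class TestJointObjective:
    def test_po_only_flat_priors_reduces_to_neg_po_loglik(self, unit_scheme, cov):
        ds = make_po([[0.2, 0.2], [0.7, 0.7]])
        spec = ModelSpec(shared_field=False)
        st = _state(alpha=0.4)
        flat = Priors(fixed_effect_sd=None)
        obj = joint_objective(st, spec, [ds], flat, unit_scheme, cov)
        assert np.isclose(obj, -po_loglik(ds, st, spec, unit_scheme, cov), atol=1e-12)

    def test_data_terms_are_additive(self, unit_scheme, cov):
        po = make_po([[0.2, 0.2], [0.7, 0.7]])
        pa = make_pa([[0.5, 0.5], [0.3, 0.8]], [1, 0])
        spec = ModelSpec(shared_field=False)
        st = _state(alpha=0.1)
        priors = Priors(fixed_effect_sd=5.0)
        both = joint_objective(st, spec, [po, pa], priors, unit_scheme, cov)
        one = joint_objective(st, spec, [po], priors, unit_scheme, cov)
        assert np.isclose(both, one - pa_loglik(pa, st, spec, cov), atol=1e-10)

    def test_empty_dataset_list_rejected(self, unit_scheme, cov):
        with pytest.raises(SDMFuseError) as exc:
            JointModel(ModelSpec(shared_field=False), [], cov, unit_scheme)
        assert exc.value.code == "no-data"

    def test_gradient_matches_central_differences(self, unit_scheme, cov):
        kg = KnotGrid.over_bounds((0, 0, 1, 1), 3, 3)
        shared = SpatialField(knots=kg, params=MaternParams(0.5, 0.8), prior=PRIOR)
        bias = SpatialField(knots=kg, params=MaternParams(0.5, 0.8), prior=PRIOR, role="bias")
        spec = ModelSpec(process_covariates=("x1",), shared_field=True, bias_field=True)
        rng = np.random.default_rng(11)
        po = make_po(rng.random((12, 2)))
        pa = make_pa(rng.random((6, 2)), rng.integers(0, 2, 6))
        cnt = make_counts(rng.random((5, 2)), rng.poisson(1.0, 5))
        jm = JointModel(
            spec, [po, pa, cnt], cov, unit_scheme, shared_field=shared,
            bias_field=bias, priors=Priors(pc_shared=PRIOR, pc_bias=PRIOR, fixed_effect_sd=4.0),
        )
        x = 0.3 * rng.standard_normal(jm.dim)
        _, g = jm.neg_log_posterior(x, want_grad=True)
        h = 1e-5
        num = np.empty(jm.dim)
        for i in range(jm.dim):  # central-difference oracle
            e = np.zeros(jm.dim)
            e[i] = h
            num[i] = (jm.neg_log_posterior(x + e) - jm.neg_log_posterior(x - e)) / (2 * h)
        assert np.allclose(g, num, rtol=1e-4, atol=1e-6)

    def test_hessian_matches_gradient_differences(self, unit_scheme, cov):
        spec = ModelSpec(process_covariates=("x1",), shared_field=False)
        rng = np.random.default_rng(13)
        po = make_po(rng.random((10, 2)))
        jm = JointModel(spec, [po], cov, unit_scheme, priors=Priors(fixed_effect_sd=3.0))
        x = np.array([0.2, -0.4])
        H = jm.hessian(x)
        h = 1e-6
        for i in range(jm.dim):
            e = np.zeros(jm.dim)
            e[i] = h
            _, gp = jm.neg_log_posterior(x + e, want_grad=True)
            _, gm = jm.neg_log_posterior(x - e, want_grad=True)
            assert np.allclose(H[:, i], (gp - gm) / (2 * h), rtol=1e-4, atol=1e-6)
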
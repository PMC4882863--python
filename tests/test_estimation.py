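import numpy as np
import pytest
from scipy.stats import multivariate_normal

from respstyle import (
    DataError,
    ItemParameters,
    ModelSpec,
    ResponseMatrix,
    build_constrained_model,
    compare_models,
    fit_mnrm,
    information_criteria,
    marginal_log_likelihood,
)
from respstyle.errors import ModelError
from respstyle.estimate import FittedModel, _person_grid_loglik
from respstyle.model import SUBSTANTIVE_SLOPES, grid_log_probs
from respstyle.quadrature import QuadratureGrid


def brute_force_ll(data, params, corr, lo=-6.0, hi=6.0, n=201):
    """Dense-trapezoid integration of the 2-dim marginal likelihood."""
    g = np.linspace(lo, hi, n)
    gx, gy = np.meshgrid(g, g, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    L = _person_grid_loglik(data.responses - 1, grid_log_probs(pts, params))
    phi = multivariate_normal(np.zeros(2), corr).logpdf(pts)
    cell = (g[1] - g[0]) ** 2
    return float(np.log((np.exp(L + phi) * cell).sum(axis=1)).sum())


class TestMarginalLogLikelihood:
    def test_uniform_single_item_is_log_one_fifth(self):
        spec = ModelSpec(n_items=1, n_categories=5, substantive_dims=("X",),
                         item_to_dim=("X",), slope_structure={"X": (0.0,) * 5})
        params = ItemParameters.from_spec(spec)
        data = ResponseMatrix(np.array([[3]]))
        ll = marginal_log_likelihood(data, params, spec, np.eye(1),
                                     QuadratureGrid(10, 1))
        assert ll == pytest.approx(np.log(0.2), abs=1e-10)

    def test_identical_persons_scale_linearly(self, toy2d):
        spec, params, data, corr = toy2d
        one = ResponseMatrix(data.responses[:1])
        many = ResponseMatrix(np.tile(data.responses[:1], (7, 1)))
        grid = QuadratureGrid(10, 2)
        ll1 = marginal_log_likelihood(one, params, spec, corr, grid)
        ll7 = marginal_log_likelihood(many, params, spec, corr, grid)
        assert ll7 == pytest.approx(7 * ll1, abs=1e-9)

    def test_adaptive_quadrature_matches_dense_grid_oracle(self, toy2d):
        spec, params, data, corr = toy2d
        oracle = brute_force_ll(data, params, corr)
        ll = marginal_log_likelihood(data, params, spec, corr,
                                     QuadratureGrid(10, 2), adaptive=True)
        assert ll == pytest.approx(oracle, abs=1e-4)

    def test_fixed_grid_converges_in_node_count(self, toy2d):
        spec, params, data, corr = toy2d
        ll10 = marginal_log_likelihood(data, params, spec, corr,
                                       QuadratureGrid(10, 2))
        ll21 = marginal_log_likelihood(data, params, spec, corr,
                                       QuadratureGrid(21, 2))
        assert ll10 == pytest.approx(ll21, abs=1e-3)

    def test_non_psd_correlation_rejected(self, toy2d):
        spec, params, data, _ = toy2d
        bad = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(ModelError):
            marginal_log_likelihood(data, params, spec, bad, QuadratureGrid(5, 2))

    def test_inert_ers_dimension_leaves_likelihood_unchanged(self):
        """With all ERS slopes 0 the extra dimension integrates out."""
        rng = np.random.default_rng(2)
        spec3, params3 = build_constrained_model(("X",), 4, ers=False)
        c = rng.normal(0, 1, (4, 5))
        params3 = ItemParameters(spec3.slope_array(), c - c.mean(1, keepdims=True))
        spec4 = ModelSpec(
            n_items=4, n_categories=5, substantive_dims=("X",),
            item_to_dim=("X",) * 4, ers_included=True,
            slope_structure={"X": SUBSTANTIVE_SLOPES, "ERS": (0.0,) * 5},
        )
        params4 = ItemParameters.from_spec(spec4, params3.intercepts)
        data = ResponseMatrix(rng.integers(1, 6, (15, 4)))
        ll3 = marginal_log_likelihood(data, params3, spec3, np.eye(1),
                                      QuadratureGrid(10, 1))
        ll4 = marginal_log_likelihood(data, params4, spec4, np.eye(2),
                                      QuadratureGrid(10, 2))
        assert ll4 == pytest.approx(ll3, abs=1e-10)


class TestInformationCriteria:
    def test_published_aic_identities(self):
        crit = information_criteria(-40525.0, 148, 1188)
        assert crit["AIC"] == pytest.approx(81346.0)
        assert crit["AIC3"] == pytest.approx(81494.0)

    def test_empty_model_all_zero(self):
        crit = information_criteria(0.0, 0, 1)
        assert all(v == 0.0 for v in crit.values())

    def test_penalty_monotone_in_parameter_count(self):
        a = information_criteria(-100.0, 10, 50)
        b = information_criteria(-100.0, 11, 50)
        assert all(a[k] < b[k] for k in a)


@pytest.fixture(scope="module")
def small_fit():
    """A quick 2-dim fit on simulated data, reused across checks."""
    rng = np.random.default_rng(8)
    spec, truth = build_constrained_model(("X", "Y"), 4, ers=False)
    c = rng.normal(0, 1, (8, 5))
    truth = ItemParameters(spec.slope_array(), c - c.mean(1, keepdims=True))
    corr = np.array([[1.0, 0.35], [0.35, 1.0]])
    thetas = rng.multivariate_normal(np.zeros(2), corr, size=400,
                                     method="cholesky")
    from respstyle import generate_responses

    data = generate_responses(thetas, truth, spec, seed=rng)
    fit = fit_mnrm(data, spec, nodes_per_dim=7, tol=1e-7, max_iter=400)
    return spec, truth, corr, data, fit


class TestFitMnrm:
    def test_converges_with_monotone_trace(self, small_fit):
        *_, fit = small_fit
        assert fit.converged
        trace = np.array(fit.iteration_trace)
        assert (np.diff(trace) >= -1e-8).all()

    def test_intercepts_effect_coded_and_slopes_untouched(self, small_fit):
        spec, truth, *_ , fit = small_fit
        np.testing.assert_allclose(fit.params.intercepts.sum(axis=1), 0,
                                   atol=1e-8)
        np.testing.assert_array_equal(fit.params.slopes, spec.slope_array())

    def test_recovers_generating_parameters(self, small_fit):
        _, truth, corr, _, fit = small_fit
        r = np.corrcoef(truth.intercepts.ravel(),
                        fit.params.intercepts.ravel())[0, 1]
        assert r > 0.9
        assert abs(fit.latent_correlations[0, 1] - corr[0, 1]) < 0.15

    def test_log_posterior_identity_and_criteria(self, small_fit):
        *_, fit = small_fit
        assert fit.log_posterior == pytest.approx(
            fit.log_likelihood + fit.log_prior, abs=1e-8
        )
        expect = information_criteria(fit.log_likelihood, fit.n_parameters,
                                      fit.n_persons)
        assert fit.criteria == pytest.approx(expect)
        # free parameters: (K-1) intercepts per item + 1 free correlation
        assert fit.n_parameters == 4 * 8 + 1

    def test_degenerate_single_person_single_item(self):
        spec, _ = build_constrained_model(("X",), 1, ers=False,
                                          correlation_structure="identity")
        data = ResponseMatrix(np.array([[5]]))
        with pytest.warns(UserWarning):  # unobserved categories flagged
            fit = fit_mnrm(data, spec, nodes_per_dim=5, max_iter=200)
        assert np.isfinite(fit.log_posterior)
        assert set(fit.flagged_items) == {0}
        # prior keeps the never-seen categories' intercepts bounded
        assert np.abs(fit.params.intercepts).max() < 10

    def test_item_count_mismatch_rejected(self, small_fit):
        spec, *_ = small_fit
        with pytest.raises(DataError):
            fit_mnrm(ResponseMatrix(np.ones((3, 5), dtype=int)), spec)


class TestCompareModels:
    def _stub(self, ll, p, n, fingerprint="abc", ers=False):
        spec, params = build_constrained_model(("X",), 2, ers=ers)
        return FittedModel(
            spec=spec, params=params,
            latent_correlations=np.eye(spec.n_dims),
            log_likelihood=ll, log_prior=0.0, log_posterior=ll,
            n_parameters=p, criteria=information_criteria(ll, p, n),
            converged=True, iteration_trace=[], n_persons=n, prior_sd=3.0,
            nodes_per_dim=10, data_fingerprint=fingerprint,
        )

    def test_dominant_model_ranks_first_everywhere(self):
        table = compare_models([self._stub(-40525, 148, 1188),
                                self._stub(-38518, 149, 1188, ers=True)])
        # the published comparison: the ERS model wins on every criterion
        for crit in ("AIC", "AIC3", "BIC", "CAIC"):
            best = table.loc[table[f"rank_{crit}"] == 1, "model"].item()
            assert best == "1dim+ERS"

    def test_fewer_parameters_wins_at_equal_likelihood(self):
        table = compare_models([self._stub(-500.0, 11, 100),
                                self._stub(-500.0, 10, 100, ers=True)])
        for crit in ("AIC", "AIC3", "BIC", "CAIC"):
            assert table.loc[table[f"rank_{crit}"] == 1, "model"].item() == "1dim+ERS"

    def test_different_data_rejected(self):
        with pytest.raises(DataError):
            compare_models([self._stub(-1, 1, 10, "aaa"),
                            self._stub(-1, 1, 10, "bbb")])
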
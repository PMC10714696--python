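"""Growth engine: df arithmetic, implied moments, FIML likelihood, fitting."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from choicetraj.growth import (
    GrowthModelSpec,
    ParamVector,
    baseline_loglik,
    count_df,
    fit,
    free_parameter_count,
    implied_moments,
    loglik_fiml,
    saturated_loglik,
)

WEEKLY = tuple(float(t) for t in range(7))
AUD_TIMES = (1.0, 2.0, 4.0, 5.0, 6.0)


def _no_cov_params(nu, psi, theta):
    q = len(nu)
    return ParamVector(np.asarray(nu, float), np.asarray(psi, float),
                       np.asarray(theta, float), np.zeros((q, 0)),
                       np.zeros(0), np.zeros((0, 0)))


@pytest.mark.parametrize("times, order, p, expected", [
    (WEEKLY, "linear", 0, 23),
    (WEEKLY, "quadratic", 0, 19),
    (AUD_TIMES, "linear", 0, 10),
    (AUD_TIMES, "quadratic", 0, 6),
    (WEEKLY, "quadratic", 5, 39),
    (AUD_TIMES, "linear", 5, 25),
])
def test_degrees_of_freedom(times, order, p, expected):
    assert count_df(GrowthModelSpec(times, order, p)) == expected


@pytest.mark.parametrize("times, order, p", [
    (WEEKLY, "linear", 0), (WEEKLY, "quadratic", 3), ((0., 1., 2.), "linear", 1),
    (AUD_TIMES, "quadratic", 5), ((0., 0.5, 1., 2.), "quadratic", 2),
])
def test_df_matches_explicit_parameter_enumeration(times, order, p):
    """Brute-force oracle: list every free parameter block by hand."""
    spec = GrowthModelSpec(times, order, p)
    q = 3 if order == "quadratic" else 2
    t = len(times)
    blocks = ([f"nu{i}" for i in range(q)]
              + [f"psi{i}{j}" for i in range(q) for j in range(i + 1)]
              + [f"theta{j}" for j in range(t)]
              + [f"b{i}{j}" for i in range(q) for j in range(p)]
              + [f"mux{j}" for j in range(p)]
              + [f"phi{i}{j}" for i in range(p) for j in range(i + 1)])
    k = t + p
    assert free_parameter_count(spec) == len(blocks)
    assert count_df(spec) == k * (k + 3) // 2 - len(blocks)


def test_implied_moments_hand_example():
    spec = GrowthModelSpec((0.0, 1.0), "linear")
    params = _no_cov_params([10., 2.], [[4., 0.], [0., 1.]], [1., 1.])
    mean, cov = implied_moments(spec, params)
    assert np.allclose(mean, [10., 12.])
    assert np.allclose(cov, [[5., 4.], [4., 6.]])


def test_implied_covariance_rank_one_without_noise():
    spec = GrowthModelSpec((0.0, 1.0, 2.0), "linear")
    params = _no_cov_params([10., 2.], [[4., 0.], [0., 0.]], [0., 0., 0.])
    _, cov = implied_moments(spec, params)
    assert np.linalg.matrix_rank(cov, tol=1e-10) == 1


def test_quadratic_loadings_are_squared_times():
    spec = GrowthModelSpec((0.0, 1.0, 2.0), "quadratic")
    lam = spec.loading_matrix()
    assert np.allclose(lam[:, 2], [0.0, 1.0, 4.0])


def test_fiml_equals_complete_data_ml(toy_complete_panel):
    """On a complete panel the FIML log-likelihood is the full joint
    density, cross-checked against scipy's multivariate normal."""
    times, y = toy_complete_panel
    spec = GrowthModelSpec(times, "linear")
    params = _no_cov_params([10., 1.5], [[4., .5], [.5, 1.]], [1., 1., 1.])
    mean, cov = implied_moments(spec, params)
    oracle = multivariate_normal.logpdf(y, mean, cov).sum()
    assert loglik_fiml(spec, params, y) == pytest.approx(oracle, rel=1e-12)


def test_deleting_cells_changes_only_those_contributions(toy_complete_panel):
    times, y = toy_complete_panel
    spec = GrowthModelSpec(times, "linear")
    params = _no_cov_params([10., 1.5], [[4., .5], [.5, 1.]], [1., 1., 1.])
    mean, cov = implied_moments(spec, params)
    full = loglik_fiml(spec, params, y)
    y2 = y.copy()
    y2[0, 2] = np.nan
    # participant 0 now contributes the bivariate marginal of (t0, t1)
    old_c = multivariate_normal.logpdf(y[0], mean, cov)
    new_c = multivariate_normal.logpdf(y[0, :2], mean[:2], cov[:2, :2])
    assert loglik_fiml(spec, params, y2) == pytest.approx(
        full - old_c + new_c, rel=1e-12)


def test_single_observed_value_is_univariate_density():
    spec = GrowthModelSpec((0.0, 1.0, 2.0), "linear")
    params = _no_cov_params([10., 1.], np.eye(2), [1., 1., 1.])
    mean, cov = implied_moments(spec, params)
    y = np.array([[np.nan, 11.0, np.nan]])
    assert loglik_fiml(spec, params, y) == pytest.approx(
        norm.logpdf(11.0, mean[1], np.sqrt(cov[1, 1])), rel=1e-12)


def test_duplicating_a_participant_doubles_the_contribution():
    spec = GrowthModelSpec((0.0, 1.0, 2.0), "linear")
    params = _no_cov_params([10., 1.], np.eye(2), [1., 1., 1.])
    row = np.array([[9.0, np.nan, 13.0]])
    single = loglik_fiml(spec, params, row)
    double = loglik_fiml(spec, params, np.vstack([row, row]))
    assert double == pytest.approx(2 * single, rel=1e-12)


def test_fit_recovers_toy_parameters(toy_complete_panel):
    times, y = toy_complete_panel
    spec = GrowthModelSpec(times, "linear")
    result = fit(spec, y)
    assert result.converged
    # generating latent means (10, 1.5) within 3 SEs
    assert abs(result.params.nu[0] - 10.0) < 3 * result.se.nu[0]
    assert abs(result.params.nu[1] - 1.5) < 3 * result.se.nu[1]
    # the reported loglik is the joint FIML likelihood at the optimum
    assert result.loglik == pytest.approx(
        loglik_fiml(spec, result.params, y), rel=1e-10)


def test_refit_from_solution_is_a_fixed_point(toy_complete_panel):
    times, y = toy_complete_panel
    spec = GrowthModelSpec(times, "linear")
    first = fit(spec, y, compute_se=False)
    second = fit(spec, y, start=first.params, compute_se=False)
    assert second.loglik == pytest.approx(first.loglik, abs=1e-6)


def test_fit_with_covariates_consistent_with_joint_likelihood(rng):
    n = 150
    times = (0.0, 1.0, 2.0, 3.0)
    x = rng.normal(0, 1, (n, 2))
    eta = (np.array([8.0, 1.0]) + x @ np.array([[0.5, -0.3], [0.2, 0.4]]).T
           + rng.multivariate_normal([0, 0], [[2.0, 0.2], [0.2, 0.5]], n))
    lam = np.column_stack([np.ones(4), times])
    y = eta @ lam.T + rng.normal(0, 1, (n, 4))
    y[rng.random((n, 4)) < 0.15] = np.nan
    y[np.isnan(y).all(axis=1)] = 8.0  # keep every row informative
    spec = GrowthModelSpec(times, "linear", 2)
    result = fit(spec, y, x)
    assert result.converged
    assert result.loglik == pytest.approx(
        loglik_fiml(spec, result.params, y, x), rel=1e-10)
    assert np.all(np.abs(result.params.b - [[0.5, -0.3], [0.2, 0.4]])
                  < 4 * np.maximum(result.se.b, 0.05))


def test_saturated_loglik_closed_form_when_complete(toy_complete_panel):
    _, y = toy_complete_panel
    mu = y.mean(axis=0)
    cov = np.cov(y, rowvar=False, bias=True)
    oracle = multivariate_normal.logpdf(y, mu, cov).sum()
    assert saturated_loglik(y) == pytest.approx(oracle, rel=1e-9)


def test_saturated_loglik_em_is_the_maximum(rng):
    """Missing-data oracle: a quasi-Newton polish over (mu, chol Sigma)
    started from the EM optimum cannot improve the likelihood, and the EM
    value dominates the value at the available-case moment start."""
    from scipy.optimize import minimize

    from choicetraj.growth import (_loglik_patterns, _moment_start,
                                   pattern_statistics, saturated_moments)

    n = 40
    y = rng.multivariate_normal([0, 1, 2],
                                [[1, .4, .2], [.4, 1, .3], [.2, .3, 1]], n)
    y[rng.random((n, 3)) < 0.2] = np.nan
    y = y[~np.isnan(y).all(axis=1)]
    pats = pattern_statistics(y)
    mu_em, sigma_em, ll_em = saturated_moments(y)

    def neg(vec):
        mu = vec[:3]
        chol = np.zeros((3, 3))
        chol[np.tril_indices(3)] = vec[3:]
        np.fill_diagonal(chol, np.exp(np.diag(chol)))
        try:
            return -_loglik_patterns(mu, chol @ chol.T, pats)
        except np.linalg.LinAlgError:
            return np.inf

    chol_em = np.linalg.cholesky(sigma_em)
    vec = chol_em[np.tril_indices(3)].copy()
    vec[[0, 2, 5]] = np.log(vec[[0, 2, 5]])
    x0 = np.concatenate([mu_em, vec])
    res = minimize(neg, x0, method="L-BFGS-B",
                   options={"maxiter": 5000, "ftol": 1e-14})
    assert ll_em == pytest.approx(-res.fun, abs=1e-4)
    mu0, sigma0 = _moment_start(y)
    assert ll_em >= _loglik_patterns(mu0, sigma0, pats) - 1e-9


def test_baseline_factorizes_per_variable(toy_complete_panel):
    _, y = toy_complete_panel
    ll, df = baseline_loglik(y)
    oracle = sum(norm.logpdf(y[:, j], y[:, j].mean(),
                             y[:, j].std()).sum() for j in range(3))
    assert ll == pytest.approx(oracle, rel=1e-12)
    assert df == 3 * (3 + 3) // 2 - 2 * 3  # k(k+3)/2 - 2k with k=3


def test_rows_without_outcomes_require_covariates():
    spec = GrowthModelSpec((0.0, 1.0), "linear")
    params = _no_cov_params([0., 0.], np.eye(2), [1., 1.])
    with pytest.raises(ValueError, match="row 1"):
        loglik_fiml(spec, params, np.array([[1.0, 2.0], [np.nan, np.nan]]))
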
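"""Latent growth curve engine: implied moments, FIML likelihood, fitting.

The model is the standard linear/quadratic latent growth curve with fixed
time-coded loadings and optional observed baseline covariates:

    y_i  = Lambda eta_i + eps_i,        eps_i ~ N(0, diag(theta))
    eta_i = nu + B x_i + zeta_i,        zeta_i ~ N(0, Psi)
    x_i  ~ N(mu_x, Phi)

with Lambda's columns = (1, t, t^2), measurement intercepts constrained to
zero, latent means/covariances and covariate moments free.  Missing
outcome values are handled by full-information maximum likelihood (FIML):
each participant contributes the multivariate-normal log-density of their
observed subvector under the corresponding sub-moments.  Participants are
grouped by missingness pattern and summarized by per-pattern sufficient
statistics, so a likelihood evaluation costs O(patterns), not O(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_solve, solve_triangular

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class GrowthModelSpec:
    """Occasions, polynomial order and covariate count of one growth model."""

    occasion_times: tuple[float, ...]
    order: str  # 'linear' or 'quadratic'
    n_covariates: int = 0

    def __post_init__(self) -> None:
        if self.order not in ("linear", "quadratic"):
            raise ValueError("order must be 'linear' or 'quadratic'")
        t = np.asarray(self.occasion_times, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("occasion times must be strictly increasing")
        if self.n_covariates < 0:
            raise ValueError("n_covariates must be non-negative")

    @property
    def n_occasions(self) -> int:
        return len(self.occasion_times)

    @property
    def n_factors(self) -> int:
        return 3 if self.order == "quadratic" else 2

    def loading_matrix(self) -> np.ndarray:
        """T x q matrix of fixed loadings (1, t, t^2)."""
        t = np.asarray(self.occasion_times, dtype=float)
        cols = [np.ones_like(t), t]
        if self.order == "quadratic":
            cols.append(t ** 2)
        return np.column_stack(cols)


@dataclass
class ParamVector:
    """Free parameters of a growth model in natural units."""

    nu: np.ndarray       # latent means given centered covariates, (q,)
    psi: np.ndarray      # latent disturbance covariance, (q, q)
    theta: np.ndarray    # occasion residual variances, (T,)
    b: np.ndarray        # latent-on-covariate regressions, (q, p)
    mu_x: np.ndarray     # covariate means, (p,)
    phi: np.ndarray      # covariate covariance, (p, p)

    def copy(self) -> "ParamVector":
        return ParamVector(self.nu.copy(), self.psi.copy(), self.theta.copy(),
                           self.b.copy(), self.mu_x.copy(), self.phi.copy())


def free_parameter_count(spec: GrowthModelSpec) -> int:
    q, t, p = spec.n_factors, spec.n_occasions, spec.n_covariates
    return q + q * (q + 1) // 2 + t + q * p + p + p * (p + 1) // 2


def count_df(spec: GrowthModelSpec) -> int:
    """Degrees of freedom: observed first/second moments minus free params.

    Observed variables are the T repeated measures plus the covariates; a
    mean-structure model with k variables has k(k+3)/2 sample moments.
    """
    k = spec.n_occasions + spec.n_covariates
    return k * (k + 3) // 2 - free_parameter_count(spec)


def implied_moments(spec: GrowthModelSpec,
                    params: ParamVector) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance of (y, x)."""
    lam = spec.loading_matrix()
    p = spec.n_covariates
    eta_mean = params.nu + (params.b @ params.mu_x if p else 0.0)
    mean_y = lam @ eta_mean
    eta_cov = params.psi + (params.b @ params.phi @ params.b.T if p else 0.0)
    cov_yy = lam @ eta_cov @ lam.T + np.diag(params.theta)
    if p == 0:
        cov = cov_yy
        mean = mean_y
    else:
        cov_yx = lam @ params.b @ params.phi
        mean = np.concatenate([mean_y, params.mu_x])
        cov = np.block([[cov_yy, cov_yx], [cov_yx.T, params.phi]])
    return mean, 0.5 * (cov + cov.T)


# --- pattern sufficient statistics ------------------------------------------

@dataclass(frozen=True)
class _Pattern:
    obs: np.ndarray      # observed-variable indices
    n: int
    mean: np.ndarray     # mean of observed subvectors
    scatter: np.ndarray  # sum of squares around the pattern mean
    rows: np.ndarray     # row indices (for diagnostics)


def pattern_statistics(data: np.ndarray) -> list[_Pattern]:
    """Group rows of an (n, k) matrix by NaN pattern and summarize them."""
    data = np.asarray(data, dtype=float)
    ok = ~np.isnan(data)
    if not ok.any(axis=1).all():
        bad = int(np.where(~ok.any(axis=1))[0][0])
        raise ValueError(f"row {bad} has no observed values")
    patterns: list[_Pattern] = []
    codes = ok @ (1 << np.arange(data.shape[1], dtype=np.uint64))
    for code in np.unique(codes):
        rows = np.where(codes == code)[0]
        obs = np.where(ok[rows[0]])[0]
        sub = data[np.ix_(rows, obs)]
        mean = sub.mean(axis=0)
        dev = sub - mean
        patterns.append(_Pattern(obs=obs, n=len(rows), mean=mean,
                                 scatter=dev.T @ dev, rows=rows))
    return patterns


def _loglik_patterns(mean: np.ndarray, cov: np.ndarray,
                     patterns: list[_Pattern]) -> float:
    ll = 0.0
    for pat in patterns:
        mu = mean[pat.obs]
        sigma = cov[np.ix_(pat.obs, pat.obs)]
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"singular implied covariance for missingness pattern with "
                f"observed variables {pat.obs.tolist()} (n={pat.n})")
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        z = solve_triangular(chol, pat.mean - mu, lower=True)
        quad_mean = z @ z
        w = solve_triangular(chol, pat.scatter, lower=True)
        w = solve_triangular(chol, w.T, lower=True)
        trace = np.trace(w)
        k = pat.obs.size
        ll += -0.5 * (pat.n * (k * _LOG2PI + logdet + quad_mean) + trace)
    return float(ll)


def loglik_fiml(spec: GrowthModelSpec, params: ParamVector,
                y: np.ndarray, x: np.ndarray | None = None) -> float:
    """FIML log-likelihood of a panel (NaN marks missing outcomes)."""
    data = _stack(spec, y, x)
    return _loglik_patterns(*implied_moments(spec, params),
                            patterns=pattern_statistics(data))


def _stack(spec: GrowthModelSpec, y: np.ndarray,
           x: np.ndarray | None) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] != spec.n_occasions:
        raise ValueError("outcome matrix shape does not match spec occasions")
    if spec.n_covariates == 0:
        return y
    x = np.asarray(x, dtype=float)
    if x.shape != (y.shape[0], spec.n_covariates):
        raise ValueError("covariate matrix shape does not match spec")
    if np.isnan(x).any():
        raise ValueError("covariates must be complete")
    return np.hstack([y, x])


# --- parameter packing -------------------------------------------------------


def _pack_chol(cov: np.ndarray) -> np.ndarray:
    chol = np.linalg.cholesky(cov)
    q = cov.shape[0]
    vec = chol[np.tril_indices(q)].copy()
    # log-transform the diagonal entries
    diag_pos = np.cumsum(np.arange(1, q + 1)) - 1
    vec[diag_pos] = np.log(vec[diag_pos])
    return vec






def _unvech(vec: np.ndarray, q: int) -> np.ndarray:
    m = np.zeros((q, q))
    m[np.tril_indices(q)] = vec
    return m + np.tril(m, -1).T


# --- fitting -----------------------------------------------------------------

@dataclass
class GrowthFit:
    """Result of a growth model fit, with fit statistics filled by
    :func:`evaluate_fit`."""

    spec: GrowthModelSpec
    params: ParamVector
    se: ParamVector | None
    loglik: float
    converged: bool
    n_used: int
    saturated_loglik: float | None = None
    chi_square: float | None = None
    df: int | None = None
    p_value: float | None = None
    cfi: float | None = None
    tli: float | None = None
    rmsea: float | None = None
    rmsea_ci90: tuple[float, float] | None = None
    standardized: np.ndarray | None = None


def _start_values(spec: GrowthModelSpec, y: np.ndarray,
                  x: np.ndarray | None) -> ParamVector:
    """Per-participant OLS curve fits regressed on the covariates for the
    latent block; sample moments for the covariate block."""
    lam = spec.loading_matrix()
    q = spec.n_factors
    p = spec.n_covariates
    coefs, rows_used, resid_vars = [], [], []
    for i, row in enumerate(y):
        obs = ~np.isnan(row)
        if obs.sum() >= q + 1:
            sol, res, *_ = np.linalg.lstsq(lam[obs], row[obs], rcond=None)
            coefs.append(sol)
            rows_used.append(i)
            dof = obs.sum() - q
            if res.size and dof > 0:
                resid_vars.append(res[0] / dof)
    if len(coefs) >= max(5, p + 2):
        coefs = np.asarray(coefs)
        if p:
            design = np.column_stack([np.ones(len(rows_used)),
                                      x[np.asarray(rows_used)]])
            c_hat, *_ = np.linalg.lstsq(design, coefs, rcond=None)
            nu, b = c_hat[0], c_hat[1:].T
            resid_coefs = coefs - design @ c_hat
        else:
            nu = coefs.mean(axis=0)
            b = np.zeros((q, 0))
            resid_coefs = coefs - nu
        psi = np.atleast_2d(np.cov(resid_coefs, rowvar=False))
        psi, _ = _repair_pd(psi)
    else:  # fall back to occasion-mean regression
        m = np.nanmean(y, axis=0)
        nu, *_ = np.linalg.lstsq(lam, m, rcond=None)
        psi = np.eye(q) * max(np.nanvar(y), 1.0) * 0.5
        b = np.zeros((q, p))
    resid = float(np.mean(resid_vars)) if resid_vars else max(np.nanvar(y), 1.0) * 0.25
    theta = np.full(spec.n_occasions, max(resid, 1e-3))
    if p:
        mu_x = x.mean(axis=0)
        phi, _ = _repair_pd(np.atleast_2d(np.cov(x, rowvar=False, bias=True)))
    else:
        mu_x = np.zeros(0); phi = np.zeros((0, 0))
    return ParamVector(np.asarray(nu), psi, theta, np.asarray(b), mu_x, phi)


def _repair_pd(m: np.ndarray, floor: float = 1e-6) -> tuple[np.ndarray, bool]:
    m = 0.5 * (m + m.T)
    vals, vecs = np.linalg.eigh(m)
    scale = max(abs(vals).max(), 1.0)
    if vals.min() > floor * scale:
        return m, False
    vals = np.clip(vals, floor * scale, None)
    return (vecs * vals) @ vecs.T, True


# The joint likelihood factorizes as f(y | x) f(x) because the covariate
# moments (mu_x, Phi) enter only the marginal of the complete covariates.
# Their MLEs are therefore the sample moments, and the optimizer works on
# the conditional model y | x ~ N(Lambda (nu + B x), Lambda Psi Lambda' +
# diag theta) with an analytic gradient.  Per-pattern cross-moment
# sufficient statistics make an evaluation O(patterns), not O(n).

@dataclass(frozen=True)
class _CondStats:
    obs: np.ndarray     # observed occasion indices
    n: int
    suu: np.ndarray     # sum y_o y_o'
    suv: np.ndarray     # sum y_o v',   v = (1, x)
    svv: np.ndarray     # sum v v'


def _conditional_stats(y: np.ndarray, x: np.ndarray | None) -> list[_CondStats]:
    """Rows with no observed outcome contribute nothing to the conditional
    likelihood and are skipped (with covariates they still enter the
    closed-form marginal block)."""
    y = np.asarray(y, dtype=float)
    v = np.ones((y.shape[0], 1)) if x is None or x.size == 0 else \
        np.hstack([np.ones((y.shape[0], 1)), np.asarray(x, dtype=float)])
    ok = ~np.isnan(y)
    codes = ok @ (1 << np.arange(y.shape[1], dtype=np.uint64))
    stats = []
    for code in np.unique(codes):
        if code == 0:
            continue
        rows = np.where(codes == code)[0]
        obs = np.where(ok[rows[0]])[0]
        u = y[np.ix_(rows, obs)]
        vv = v[rows]
        stats.append(_CondStats(obs=obs, n=len(rows), suu=u.T @ u,
                                suv=u.T @ vv, svv=vv.T @ vv))
    return stats


def _cond_loglik_grad(spec: GrowthModelSpec, nu: np.ndarray, psi: np.ndarray,
                      theta: np.ndarray, b: np.ndarray,
                      stats: list[_CondStats], want_grad: bool = True):
    """Conditional log-likelihood and its gradient w.r.t. the natural
    parameters (nu, Psi, theta, B)."""
    lam = spec.loading_matrix()
    q = spec.n_factors
    c = np.column_stack([nu, b]) if b.size else nu[:, None]
    sigma = lam @ psi @ lam.T + np.diag(theta)
    ll = 0.0
    g_c = np.zeros_like(c)
    g_psi = np.zeros((q, q))
    g_theta = np.zeros_like(theta)
    for st in stats:
        o = st.obs
        lam_o = lam[o]
        sig_o = sigma[np.ix_(o, o)]
        chol = np.linalg.cholesky(sig_o)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        w = lam_o @ c
        # residual scatter sum_i r_i r_i'
        rr = (st.suu - w @ st.suv.T - st.suv @ w.T + w @ st.svv @ w.T)
        inv_rr = solve_triangular(chol, rr, lower=True)
        inv_rr = solve_triangular(chol, inv_rr.T, lower=True)
        ll += -0.5 * (st.n * (o.size * _LOG2PI + logdet) + np.trace(inv_rr))
        if not want_grad:
            continue
        sig_inv = cho_solve((chol, True), np.eye(o.size))
        grad_sigma = 0.5 * (sig_inv @ rr @ sig_inv - st.n * sig_inv)
        grad_w = sig_inv @ (st.suv - w @ st.svv)
        g_c += lam_o.T @ grad_w
        g_psi += lam_o.T @ grad_sigma @ lam_o
        g_theta[o] += np.diag(grad_sigma)
    if not want_grad:
        return ll, None
    return ll, (g_c, 0.5 * (g_psi + g_psi.T), g_theta)


def _pack_cond(nu, psi, theta, b) -> np.ndarray:
    parts = [nu, _pack_chol(psi), np.log(theta)]
    if b.size:
        parts.append(b.ravel())
    return np.concatenate(parts)


def _unpack_cond(vec: np.ndarray, spec: GrowthModelSpec):
    q, t, p = spec.n_factors, spec.n_occasions, spec.n_covariates
    i = 0
    nu = vec[i:i + q]; i += q
    n_psi = q * (q + 1) // 2
    chol_vec = vec[i:i + n_psi]; i += n_psi
    chol = np.zeros((q, q))
    chol[np.tril_indices(q)] = chol_vec
    np.fill_diagonal(chol, np.exp(np.diag(chol)))
    theta = np.exp(vec[i:i + t]); i += t
    b = vec[i:i + q * p].reshape(q, p) if p else np.zeros((q, 0))
    return np.asarray(nu), chol, theta, b


def fit(spec: GrowthModelSpec, y: np.ndarray, x: np.ndarray | None = None, *,
        start: ParamVector | None = None, tol: float = 1e-11,
        max_iter: int = 5000, compute_se: bool = True) -> GrowthFit:
    """Maximize the FIML log-likelihood.

    The covariate moments have closed-form MLEs (sample mean/covariance);
    the conditional parameters are optimized by L-BFGS on a transformed
    parameterization (Cholesky factor of Psi with log diagonal, log
    residual variances) with an analytic gradient, so every iterate is
    admissible.  Standard errors come from the inverse observed
    information at the optimum on the natural scale.  Non-convergence is
    flagged on the result, never raised.
    """
    p = spec.n_covariates
    if p and x is None:
        raise ValueError("spec declares covariates but none were given")
    y = np.asarray(y, dtype=float)
    _stack(spec, y, x)  # shape/NaN validation
    if p == 0:  # rows with no observations carry no information
        y = y[~np.isnan(y).all(axis=1)]
    stats = _conditional_stats(y, x if p else None)
    n = y.shape[0]
    start = _start_values(spec, y, x) if start is None else start.copy()
    q = spec.n_factors

    def objective(vec):
        nu, chol, theta, b = _unpack_cond(vec, spec)
        psi = chol @ chol.T
        try:
            ll, grads = _cond_loglik_grad(spec, nu, psi, theta, b, stats)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros_like(vec)
        g_c, g_psi, g_theta = grads
        g_chol = 2.0 * g_psi @ chol
        tril = np.tril_indices(q)
        g_chol_vec = g_chol[tril].copy()
        diag_pos = np.cumsum(np.arange(1, q + 1)) - 1
        g_chol_vec[diag_pos] *= np.diag(chol)  # log-diagonal chain rule
        grad_parts = [g_c[:, 0], g_chol_vec, g_theta * theta]
        if p:
            grad_parts.append(g_c[:, 1:].ravel())
        grad = -np.concatenate(grad_parts) / n
        return -ll / n, grad

    x0 = _pack_cond(start.nu, start.psi, start.theta, start.b)
    res = optimize.minimize(objective, x0, method="L-BFGS-B", jac=True,
                            options={"maxiter": max_iter, "maxfun": 10 * max_iter,
                                     "ftol": tol, "gtol": 1e-8, "maxcor": 30})
    nu, chol, theta, b = _unpack_cond(res.x, spec)
    psi = chol @ chol.T
    if p:
        mu_x = x.mean(axis=0)
        phi = np.atleast_2d(np.cov(x, rowvar=False, bias=True))
        marg = -0.5 * n * (p * _LOG2PI
                           + np.linalg.slogdet(phi)[1] + p)
    else:
        mu_x = np.zeros(0); phi = np.zeros((0, 0)); marg = 0.0
    params = ParamVector(nu, psi, theta, b, mu_x, phi)
    loglik = -res.fun * n + marg
    converged = bool(res.success and np.isfinite(loglik))
    se = _standard_errors(spec, params, stats, n) if compute_se else None
    return GrowthFit(spec=spec, params=params, se=se, loglik=float(loglik),
                     converged=converged, n_used=n)


def _standard_errors(spec: GrowthModelSpec, params: ParamVector,
                     stats: list[_CondStats], n: int) -> ParamVector | None:
    """Inverse observed information on the natural parameter scale.

    The information is block-diagonal between the conditional parameters
    and the covariate moments (the likelihood factorizes), so the blocks
    are inverted separately.  The conditional Hessian is obtained by
    central differences of the analytic gradient.
    """
    q, t, p = spec.n_factors, spec.n_occasions, spec.n_covariates
    tril_q = np.tril_indices(q)

    def grad_nat(vec: np.ndarray) -> np.ndarray:
        i = 0
        nu = vec[i:i + q]; i += q
        psi = _unvech(vec[i:i + q * (q + 1) // 2], q); i += q * (q + 1) // 2
        theta = vec[i:i + t]; i += t
        b = vec[i:i + q * p].reshape(q, p) if p else np.zeros((q, 0))
        _, grads = _cond_loglik_grad(spec, nu, psi, theta, b, stats)
        g_c, g_psi, g_theta = grads
        # vech gradient: off-diagonals appear twice in the symmetric matrix
        g_vech = (2.0 * g_psi - np.diag(np.diag(g_psi)))[tril_q]
        parts = [-g_c[:, 0], -g_vech, -g_theta]
        if p:
            parts.append(-g_c[:, 1:].ravel())
        return np.concatenate(parts)

    x0 = np.concatenate([params.nu, params.psi[tril_q], params.theta]
                        + ([params.b.ravel()] if p else []))
    m = x0.size
    h = 1e-5 * np.maximum(np.abs(x0), 1.0)
    hess = np.zeros((m, m))
    try:
        for i in range(m):
            e = np.zeros(m); e[i] = h[i]
            hess[i] = (grad_nat(x0 + e) - grad_nat(x0 - e)) / (2 * h[i])
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(hess)):
        return None
    cov = np.linalg.pinv(0.5 * (hess + hess.T))
    se_vec = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    i = 0
    se_nu = se_vec[i:i + q]; i += q
    se_psi = _unvech(se_vec[i:i + q * (q + 1) // 2], q); i += q * (q + 1) // 2
    se_theta = se_vec[i:i + t]; i += t
    se_b = se_vec[i:i + q * p].reshape(q, p) if p else np.zeros((q, 0))
    if p:
        # covariate moments: standard MVN moment standard errors
        se_mu = np.sqrt(np.diag(params.phi) / n)
        phi = params.phi
        se_phi = np.sqrt((phi ** 2 + np.outer(np.diag(phi), np.diag(phi))) / n)
    else:
        se_mu = np.zeros(0); se_phi = np.zeros((0, 0))
    return ParamVector(se_nu, se_psi, se_theta, se_b, se_mu, se_phi)


def _numerical_hessian(f, x0: np.ndarray) -> np.ndarray:
    m = x0.size
    h = 1e-4 * np.maximum(np.abs(x0), 0.1)
    hess = np.zeros((m, m))
    f0 = f(x0)
    fp = np.empty(m); fm = np.empty(m)
    for i in range(m):
        e = np.zeros(m); e[i] = h[i]
        fp[i] = f(x0 + e); fm[i] = f(x0 - e)
        hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(m):
        ei = np.zeros(m); ei[i] = h[i]
        for j in range(i):
            ej = np.zeros(m); ej[j] = h[j]
            hess[i, j] = hess[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej)
                - f(x0 - ei + ej) + f(x0 - ei - ej)) / (4 * h[i] * h[j])
    return hess


# --- saturated and baseline models -------------------------------------------

def saturated_loglik(data: np.ndarray, *, tol: float = 1e-10,
                     max_iter: int = 10000) -> float:
    """FIML log-likelihood of the unstructured mean/covariance model."""
    return saturated_moments(data, tol=tol, max_iter=max_iter)[2]


def saturated_moments(data: np.ndarray, *, tol: float = 1e-10,
                      max_iter: int = 10000) -> tuple[np.ndarray, np.ndarray, float]:
    """MLE (mean, covariance, loglik) of the unstructured model under FIML.

    Maximized by EM for the multivariate normal with missing data, using
    per-pattern sufficient statistics (each iteration is O(patterns)).
    With complete data this converges in one step to the sample moments.
    """
    data = np.asarray(data, dtype=float)
    patterns = pattern_statistics(data)
    n, k = data.shape
    mu, sigma = _moment_start(data)
    ll_old = -np.inf
    for _ in range(max_iter):
        t1 = np.zeros(k)
        t2 = np.zeros((k, k))
        for pat in patterns:
            o = pat.obs
            m = np.setdiff1d(np.arange(k), o, assume_unique=True)
            s_oo = sigma[np.ix_(o, o)]
            d = pat.mean - mu[o]
            zbar_o = pat.mean
            t1[o] += pat.n * zbar_o
            t2[np.ix_(o, o)] += pat.scatter + pat.n * np.outer(zbar_o, zbar_o)
            if m.size:
                a = np.linalg.solve(s_oo, sigma[np.ix_(o, m)]).T  # A = S_mo S_oo^-1
                mu_m = mu[m] + a @ d
                t1[m] += pat.n * mu_m
                # sum_i z_o E[z_m|z_o]'
                cross = (pat.n * np.outer(zbar_o, mu[m])
                         + (pat.scatter + pat.n * np.outer(zbar_o, d)) @ a.T)
                t2[np.ix_(o, m)] += cross
                t2[np.ix_(m, o)] += cross.T
                cond = sigma[np.ix_(m, m)] - a @ sigma[np.ix_(o, m)]
                ee = (pat.n * np.outer(mu_m, mu_m)
                      + a @ pat.scatter @ a.T)
                t2[np.ix_(m, m)] += ee + pat.n * cond
        mu = t1 / n
        sigma = t2 / n - np.outer(mu, mu)
        sigma, _ = _repair_pd(sigma, floor=1e-12)
        ll = _loglik_patterns(mu, sigma, patterns)
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            break
        ll_old = ll
    return mu, sigma, float(ll)


def _moment_start(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    masked = np.ma.masked_invalid(data)
    mu = np.asarray(masked.mean(axis=0))
    cov = np.ma.cov(masked, rowvar=False, bias=True)
    cov = np.asarray(cov.filled(0.0))
    cov, _ = _repair_pd(cov, floor=1e-8)
    return mu, cov


def baseline_loglik(data: np.ndarray) -> tuple[float, int]:
    """Independence baseline: free means and variances, zero covariances.

    Under a diagonal covariance the FIML likelihood factorizes per
    variable, so the MLE is closed-form.  Returns (loglik, df_baseline).
    """
    data = np.asarray(data, dtype=float)
    k = data.shape[1]
    ll = 0.0
    for j in range(k):
        v = data[:, j]
        v = v[~np.isnan(v)]
        var = max(float(v.var()), 1e-12)
        ll += -0.5 * v.size * (_LOG2PI + np.log(var) + 1.0)
    df = k * (k + 3) // 2 - 2 * k
    return float(ll), df
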
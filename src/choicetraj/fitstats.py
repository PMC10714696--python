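"""Chi-square tests, fit indices, nested-model comparison, standardization.

The likelihood-ratio chi-square compares a fitted growth model to the
saturated (unstructured mean/covariance) model estimated by FIML on the
same missingness pattern.  CFI and TLI compare against the conventional
independence baseline (free means and variances, zero covariances).
RMSEA uses the N-1 convention, ``sqrt(max(chi2 - df, 0) / (df (N-1)))``,
with its 90% interval from inverting the noncentral chi-square
distribution at the 0.05 / 0.95 tails.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .growth import (
    GrowthFit,
    GrowthModelSpec,
    _stack,
    baseline_loglik,
    count_df,
    saturated_loglik,
)


def chi_square_statistic(model_loglik: float, saturated: float,
                         df: int, *, tol: float = 1e-6) -> tuple[float, int]:
    """Likelihood-ratio T = 2 (saturated - model), floored at zero."""
    t = 2.0 * (saturated - model_loglik)
    if t < -tol * (1.0 + abs(saturated)):
        raise ValueError(
            f"model log-likelihood exceeds the saturated model by {-t:.3g}; "
            "the saturated optimization has not converged")
    return max(t, 0.0), df


def fit_indices(t: float, df: int, t_baseline: float, df_baseline: int,
                n: int) -> tuple[float, float, float, tuple[float, float]]:
    """(CFI, TLI, RMSEA, RMSEA 90% CI) from chi-squares of model and baseline."""
    if df <= 0 or df_baseline <= 0:
        raise ValueError("df and baseline df must be positive")
    if n <= 1:
        raise ValueError("n must exceed 1")
    d_m = max(t - df, 0.0)
    d_b = max(t_baseline - df_baseline, 0.0)
    denom = max(d_b, d_m)
    cfi = 1.0 if denom == 0 else 1.0 - d_m / denom
    ratio_b = t_baseline / df_baseline
    tli = np.nan if ratio_b <= 1.0 else (ratio_b - t / df) / (ratio_b - 1.0)
    rmsea = float(np.sqrt(d_m / (df * (n - 1))))
    return cfi, float(tli), rmsea, rmsea_ci90(t, df, n)


def rmsea_ci90(t: float, df: int, n: int) -> tuple[float, float]:
    """90% interval by noncentrality inversion of the noncentral chi-square."""
    lo = _ncp_solve(t, df, 0.95)
    hi = _ncp_solve(t, df, 0.05)
    scale = df * (n - 1)
    return float(np.sqrt(lo / scale)), float(np.sqrt(hi / scale))


def _ncp_solve(t: float, df: int, target: float) -> float:
    """Noncentrality lambda with P(Chi2_{df,lambda} <= t) = target (0 if none)."""
    if stats.chi2.cdf(t, df) <= target:
        return 0.0
    hi = max(t, 1.0)
    while stats.ncx2.cdf(t, df, hi) > target:
        hi *= 2.0
        if hi > 1e8:
            return hi
    return brentq(lambda lam: stats.ncx2.cdf(t, df, lam) - target, 0.0, hi,
                  xtol=1e-10)


def chi_diff_test(fit_restricted: GrowthFit,
                  fit_general: GrowthFit) -> tuple[float, int, float]:
    """Nested likelihood-ratio test; keep the restricted model iff p >= 0.05.

    The two fits must share occasions and covariates and differ only in
    polynomial order (linear nested in quadratic).
    """
    r, g = fit_restricted.spec, fit_general.spec
    nested = (r.occasion_times == g.occasion_times
              and r.n_covariates == g.n_covariates
              and (r.order, g.order) in (("linear", "quadratic"),
                                         ("linear", "linear"),
                                         ("quadratic", "quadratic")))
    if not nested or fit_restricted.n_used != fit_general.n_used:
        raise ValueError("models are not nested on the same panel")
    delta_t = max(2.0 * (fit_general.loglik - fit_restricted.loglik), 0.0)
    delta_df = count_df(r) - count_df(g)
    p = 1.0 if delta_df == 0 else float(stats.chi2.sf(delta_t, delta_df))
    return delta_t, delta_df, p


def standardized_effects(fit: GrowthFit) -> np.ndarray:
    """Standardized partial regressions of latent factors on covariates.

    beta_std[f, x] = b[f, x] * SD(x) / SD(factor f), with the factor SD
    from the model-implied total latent variance (explained plus
    disturbance).
    """
    params = fit.params
    if params.b.size == 0:
        raise ValueError("fit has no covariates")
    total = params.psi + params.b @ params.phi @ params.b.T
    var_f = np.diag(total)
    if np.any(var_f <= 0):
        raise ValueError("non-positive model-implied latent variance")
    sd_f = np.sqrt(var_f)
    sd_x = np.sqrt(np.diag(params.phi))
    return params.b * sd_x[None, :] / sd_f[:, None]


def evaluate_fit(fit: GrowthFit, y: np.ndarray,
                 x: np.ndarray | None = None) -> GrowthFit:
    """Fill chi-square, p, CFI/TLI/RMSEA (+CI) and standardized effects."""
    data = _stack(fit.spec, y, x)
    data = data[~np.isnan(data).all(axis=1)]  # rows with nothing observed
    sat = saturated_loglik(data)
    fit.saturated_loglik = sat
    fit.df = count_df(fit.spec)
    fit.chi_square, _ = chi_square_statistic(fit.loglik, sat, fit.df)
    fit.p_value = float(stats.chi2.sf(fit.chi_square, fit.df)) if fit.df else 1.0
    t_b, df_b = baseline_loglik(data)
    t_base, _ = chi_square_statistic(t_b, sat, df_b)
    if fit.df > 0:
        fit.cfi, fit.tli, fit.rmsea, fit.rmsea_ci90 = fit_indices(
            fit.chi_square, fit.df, t_base, df_b, fit.n_used)
    if fit.params.b.size:
        fit.standardized = standardized_effects(fit)
    return fit
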
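"""Model-implied trajectories at covariate levels and cumulative intake.

A fitted growth model implies a group trajectory (the latent factor means
evaluated along the polynomial loadings) and, for each covariate, shifted
trajectories at one SD above/below its mean with the other covariates held
at their average.  For average daily alcohol use (g/day) the time-integral
of a trajectory over the follow-up gives cumulative intake, reported in kg
using a 365.25-day year.  Negative implied daily values are floored at
zero before integration.
"""

from __future__ import annotations

import numpy as np

from .growth import GrowthFit

GRAMS_PER_DAY_TO_KG_PER_YEAR = 365.25 / 1000.0
HEAVY_EPISODIC_THRESHOLD_G = 60.0  # WHO heavy-episodic-drinking cutoff
LEVELS = ("M_minus_SD", "M", "M_plus_SD")


def curve_coefficients(fit: GrowthFit, covariate: int | None = None,
                       level: str = "M") -> np.ndarray:
    """Polynomial coefficients (I, L[, Q]) of the implied mean trajectory.

    ``level='M'`` returns the group curve (covariates at their means, which
    requires the fit's covariates to have been mean-centered so that the
    latent intercepts are the group factor means).  ``M_plus_SD`` /
    ``M_minus_SD`` shift every factor by ``+-b[f, covariate] * SD(covariate)``.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    coefs = fit.params.nu.copy()
    if level == "M":
        return coefs
    if covariate is None:
        raise ValueError("a covariate index is required for M +/- SD levels")
    p = fit.params.b.shape[1]
    if not 0 <= covariate < p:
        raise ValueError(f"unknown covariate index {covariate} (model has {p})")
    sd_x = float(np.sqrt(fit.params.phi[covariate, covariate]))
    sign = 1.0 if level == "M_plus_SD" else -1.0
    return coefs + sign * fit.params.b[:, covariate] * sd_x


def implied_trajectory(fit: GrowthFit, times, covariate: int | None = None,
                       level: str = "M") -> np.ndarray:
    """Implied outcome values at ``times`` (years) for one covariate level."""
    coefs = curve_coefficients(fit, covariate, level)
    t = np.asarray(times, dtype=float)
    return sum(c * t ** i for i, c in enumerate(coefs))


def cumulative_intake_kg(coefficients, horizon: float = 6.0) -> float:
    """Integral of a g/day polynomial trajectory over ``horizon`` years, in kg.

    Closed form on the sub-intervals where the polynomial is non-negative;
    negative stretches contribute zero (daily intake cannot be negative).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    c = np.asarray(coefficients, dtype=float)
    # drop numerically negligible leading coefficients before root finding
    tol = 1e-12 * max(1.0, float(np.abs(c).max()))
    poly = np.polynomial.Polynomial(c).trim(tol)
    c = poly.coef
    anti = poly.integ()
    # split [0, horizon] at the curve's real roots; on each piece the sign
    # is constant, so the piece contributes iff its midpoint is positive
    roots = poly.roots() if c.size > 1 else np.array([])
    cuts = sorted({0.0, float(horizon),
                   *(float(r.real) for r in roots
                     if abs(r.imag) < 1e-12 and 0.0 < r.real < horizon)})
    total = 0.0
    for a, b in zip(cuts, cuts[1:]):
        if poly(0.5 * (a + b)) > 0:
            total += anti(b) - anti(a)
    return total * GRAMS_PER_DAY_TO_KG_PER_YEAR


def heavy_episodic(trajectory) -> np.ndarray:
    """Boolean mask of trajectory values above the WHO 60 g/occasion cutoff."""
    return np.asarray(trajectory, dtype=float) > HEAVY_EPISODIC_THRESHOLD_G


def plot_trajectory_levels(fit: GrowthFit, covariate: int, path, *,
                           horizon: float = 6.0, step: float = 0.1,
                           ylabel: str = "outcome",
                           covariate_name: str | None = None) -> None:
    """Three-line plot of the implied trajectory at M and M +/- 1 SD.

    Requires matplotlib (the ``plots`` extra); the core never imports it.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.arange(0.0, horizon + step / 2, step)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    styles = {"M_plus_SD": ("M + 1 SD", "--"), "M": ("M", "-"),
              "M_minus_SD": ("M - 1 SD", ":")}
    for level, (label, ls) in styles.items():
        ax.plot(t, implied_trajectory(fit, t, covariate=covariate,
                                      level=level), ls, label=label)
    ax.set_xlabel("years of follow-up")
    ax.set_ylabel(ylabel)
    if covariate_name:
        ax.set_title(covariate_name)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
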
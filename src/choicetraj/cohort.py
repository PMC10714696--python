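"""Synthetic cohorts with the statistical structure the analysis assumes.

The study cohort (198 men profiled at age 18 and followed annually to age
24) is not publicly deposited, so this module generates cohorts from a
fully specified generative model: a 5-variate normal over the baseline
choice dimensions (three log discount rates, log loss aversion, choice
consistency), per-outcome latent growth curves (intercept, linear and
optionally quadratic slope) regressed on the mean-centered choice
dimensions, occasion-level residual noise, and monotone dropout that
reproduces the published retention counts exactly.

Default parameters are calibrated to the published descriptive and model
tables; quantities the study did not report (latent and residual variances,
the consistency SD) are documented calibration choices, not published
values — see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

COVARIATE_NAMES = (
    "delay_discounting",      # log k, delay task
    "risk_aversion_gains",    # log k, probability discounting for gains
    "risk_seeking_losses",    # log k, probability discounting for losses
    "loss_aversion",          # log lambda
    "consistency",            # mean-centered mean log beta
)

#: published baseline means and SDs of the choice dimensions
#: (consistency is mean-centered by construction; its SD is a calibration)
COVARIATE_MEANS = (-4.6, -0.2, -0.3, 0.3, 0.0)
COVARIATE_SDS = (2.2, 1.0, 1.2, 0.8, 0.6)

#: published pairwise correlations of the five choice dimensions
COVARIATE_CORRELATIONS = (
    (1.000, 0.100, 0.011, -0.024, -0.262),
    (0.100, 1.000, -0.009, 0.141, -0.186),
    (0.011, -0.009, 1.000, -0.227, 0.252),
    (-0.024, 0.141, -0.227, 1.000, -0.211),
    (-0.262, -0.186, 0.252, -0.211, 1.000),
)

#: published retention counts at the seven annual occasions
RETENTION_COUNTS = (198, 166, 160, 135, 100, 85, 84)


@dataclass(frozen=True)
class OutcomeSpec:
    """Generative growth model for one repeated alcohol outcome."""

    name: str
    times: tuple[float, ...]                 # measurement occasions, years
    growth_means: tuple[float, ...]          # (intercept, linear[, quadratic])
    latent_sds: tuple[float, ...]            # total latent SDs, same length
    latent_correlations: tuple[tuple[float, ...], ...]
    effects_std: tuple[tuple[float, ...], ...]  # standardized, factors x 5
    residual_sd: float                       # occasion-level noise SD
    integer_valued: bool = False             # round to counts (AUD criteria)

    @property
    def order(self) -> str:
        return "quadratic" if len(self.growth_means) == 3 else "linear"


@dataclass(frozen=True)
class CohortSpec:
    """Full generative specification of a synthetic cohort."""

    n_participants: int = 198
    covariate_means: tuple[float, ...] = COVARIATE_MEANS
    covariate_sds: tuple[float, ...] = COVARIATE_SDS
    covariate_correlations: tuple[tuple[float, ...], ...] = COVARIATE_CORRELATIONS
    outcomes: tuple[OutcomeSpec, ...] = ()
    retention_counts: tuple[int, ...] = RETENTION_COUNTS
    attrition_mechanism: str = "MCAR_dropout"  # or "MAR_dropout"
    mar_coefficient: float = 0.5   # logistic weight on z-scored prior outcome
    floor_at_zero: bool = True     # consumption/counts cannot be negative
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attrition_mechanism not in ("MCAR_dropout", "MAR_dropout"):
            raise ValueError("unknown attrition mechanism")
        counts = self.retention_counts
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("retention counts must be non-increasing")
        if counts and counts[0] != self.n_participants:
            raise ValueError("retention_counts[0] must equal n_participants")


@dataclass
class CohortPanel:
    """Participants x occasions outcome matrices plus baseline covariates."""

    covariates: np.ndarray                 # (n, 5), complete
    covariate_names: tuple[str, ...]
    outcomes: dict[str, np.ndarray]        # name -> (n, T), NaN = missing
    times: dict[str, np.ndarray]           # name -> occasion times in years
    centered: bool = False                 # covariates mean-centered?

    @property
    def n(self) -> int:
        return self.covariates.shape[0]


# --- default calibration ---------------------------------------------------

_LATENT_CORR_Q = ((1.0, -0.35, 0.15), (-0.35, 1.0, -0.85), (0.15, -0.85, 1.0))
_LATENT_CORR_L = ((1.0, -0.3), (-0.3, 1.0))

# published standardized partial effects of the five choice dimensions
# (columns) on intercept / linear / quadratic factors (rows)
_EFFECTS_TYPICAL = (
    (0.119, 0.086, 0.011, 0.007, -0.038),
    (-0.160, -0.106, 0.057, -0.232, -0.237),
    (0.175, 0.086, -0.070, 0.295, 0.284),
)
_EFFECTS_AVERAGE = (
    (0.153, 0.128, -0.101, -0.075, 0.085),
    (-0.235, -0.262, -0.009, 0.181, -0.164),
    (0.244, 0.204, 0.056, -0.174, 0.165),
)
_EFFECTS_AUD = (
    (0.079, -0.274, -0.012, -0.095, -0.072),
    (-0.085, -0.011, -0.054, 0.056, 0.007),
)

TYPICAL_USE = OutcomeSpec(
    name="typical_use", times=(0, 1, 2, 3, 4, 5, 6),
    growth_means=(69.856, -8.680, 1.227), latent_sds=(35.0, 8.0, 1.3),
    latent_correlations=_LATENT_CORR_Q, effects_std=_EFFECTS_TYPICAL,
    residual_sd=20.0)

AVERAGE_USE = OutcomeSpec(
    name="average_use", times=(0, 1, 2, 3, 4, 5, 6),
    growth_means=(11.753, -0.275, 0.099), latent_sds=(10.0, 2.7, 0.40),
    latent_correlations=_LATENT_CORR_Q, effects_std=_EFFECTS_AVERAGE,
    residual_sd=6.0)

AUD_CRITERIA = OutcomeSpec(
    name="aud_criteria", times=(1, 2, 4, 5, 6),
    growth_means=(0.443, -0.030), latent_sds=(0.55, 0.08),
    latent_correlations=_LATENT_CORR_L, effects_std=_EFFECTS_AUD,
    residual_sd=0.45, integer_valued=True)


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The calibrated study-conditions cohort: n=198, three outcomes,
    published retention counts, MCAR dropout."""
    return CohortSpec(outcomes=(TYPICAL_USE, AVERAGE_USE, AUD_CRITERIA),
                      seed=seed, **overrides)


# --- correlation-matrix utilities ------------------------------------------

def _as_cov(sds, corr) -> np.ndarray:
    sds = np.asarray(sds, dtype=float)
    corr = np.asarray(corr, dtype=float)
    if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
        raise ValueError("correlation matrix must be symmetric with unit diagonal")
    return corr * np.outer(sds, sds)


def nearest_pd_repair(matrix: np.ndarray, eps: float = 1e-12) -> tuple[np.ndarray, bool]:
    """Clip negative eigenvalues to zero; returns (matrix, was_repaired)."""
    vals, vecs = np.linalg.eigh(matrix)
    if vals.min() >= -eps * max(abs(vals).max(), 1.0):
        return matrix, False
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T, True


def unstandardized_effects(outcome: OutcomeSpec, covariate_sds) -> np.ndarray:
    """Convert standardized partial effects to raw regression weights.

    b[f, x] = beta_std[f, x] * SD(factor f) / SD(covariate x), with factor
    SDs taken as the spec's total latent SDs, so that re-standardizing a
    fitted model recovers the generating standardized effects.
    """
    beta = np.asarray(outcome.effects_std, dtype=float)
    sd_f = np.asarray(outcome.latent_sds, dtype=float)
    sd_x = np.asarray(covariate_sds, dtype=float)
    return beta * sd_f[:, None] / sd_x[None, :]


def disturbance_covariance(outcome: OutcomeSpec, spec: CohortSpec) -> np.ndarray:
    """Latent disturbance covariance: total latent covariance minus the part
    explained by the covariates.  Raises if the calibration leaves it
    non-positive-definite."""
    total = _as_cov(outcome.latent_sds, outcome.latent_correlations)
    b = unstandardized_effects(outcome, spec.covariate_sds)
    phi = _as_cov(spec.covariate_sds, spec.covariate_correlations)
    psi = total - b @ phi @ b.T
    vals = np.linalg.eigvalsh(psi)
    scale = max(abs(vals).max(), 1.0)
    if vals.min() < -1e-9 * scale:
        raise ValueError(
            f"calibrated effects for {outcome.name!r} leave a non-PSD "
            f"disturbance covariance (min eigenvalue {vals.min():.3g})")
    psi, _ = nearest_pd_repair(psi)
    return psi


def loading_matrix(times, order: str) -> np.ndarray:
    """Fixed growth loadings: ones, times, and (if quadratic) squared times."""
    t = np.asarray(times, dtype=float)
    cols = [np.ones_like(t), t]
    if order == "quadratic":
        cols.append(t ** 2)
    elif order != "linear":
        raise ValueError("order must be 'linear' or 'quadratic'")
    return np.column_stack(cols)


# --- sampling ---------------------------------------------------------------

def sample_decision_profiles(spec: CohortSpec,
                             rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the n x 5 baseline covariate matrix from the spec's MVN."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    cov = _as_cov(spec.covariate_sds, spec.covariate_correlations)
    cov, _ = nearest_pd_repair(cov)
    mean = np.asarray(spec.covariate_means, dtype=float)
    return rng.multivariate_normal(mean, cov, size=spec.n_participants,
                                   method="eigh")


def sample_growth_panel(spec: CohortSpec, covariates: np.ndarray,
                        rng: np.random.Generator | None = None) -> CohortPanel:
    """Generate complete (pre-attrition) outcome panels.

    Per participant i and outcome: latent factors
    ``eta_i = growth_means + B (x_i - x_bar) + zeta_i`` with correlated
    disturbance zeta, observations ``y_it = Lambda eta_i + eps_it``.
    Noise is added first, then values are floored at zero (consumption and
    criterion counts are non-negative), then integer outcomes are rounded.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    covariates = np.asarray(covariates, dtype=float)
    if covariates.shape != (spec.n_participants, len(spec.covariate_means)):
        raise ValueError("covariate matrix shape does not match spec")
    xc = covariates - covariates.mean(axis=0)
    outcomes: dict[str, np.ndarray] = {}
    times: dict[str, np.ndarray] = {}
    for out in spec.outcomes:
        lam = loading_matrix(out.times, out.order)
        b = unstandardized_effects(out, spec.covariate_sds)
        psi = disturbance_covariance(out, spec)
        eta = (np.asarray(out.growth_means) + xc @ b.T
               + rng.multivariate_normal(np.zeros(len(out.growth_means)), psi,
                                         size=spec.n_participants))
        y = eta @ lam.T + rng.normal(0.0, out.residual_sd,
                                     size=(spec.n_participants, len(out.times)))
        if spec.floor_at_zero:
            y = np.maximum(y, 0.0)
        if out.integer_valued:
            y = np.round(y)
        outcomes[out.name] = y
        times[out.name] = np.asarray(out.times, dtype=float)
    return CohortPanel(covariates=covariates, covariate_names=COVARIATE_NAMES,
                       outcomes=outcomes, times=times, centered=False)


def _draw_dropout_times(spec: CohortSpec, reference: np.ndarray | None,
                        rng: np.random.Generator) -> np.ndarray:
    """Occasion index at which each participant drops (len(counts) = never).

    Exactly counts[j] participants remain at occasion j.  MCAR selects the
    droppers uniformly among survivors; MAR weights selection by the
    z-scored outcome observed at the previous occasion via a logistic link.
    """
    counts = spec.retention_counts
    n = spec.n_participants
    drop = np.full(n, len(counts), dtype=int)
    survivors = np.arange(n)
    for j in range(1, len(counts)):
        n_drop = counts[j - 1] - counts[j]
        if n_drop == 0:
            continue
        if n_drop > survivors.size:
            raise ValueError("retention counts exceed available participants")
        if spec.attrition_mechanism == "MAR_dropout" and reference is not None:
            prev = reference[survivors, j - 1]
            z = (prev - prev.mean()) / (prev.std() or 1.0)
            w = expit(spec.mar_coefficient * z)
            w /= w.sum()
            chosen = rng.choice(survivors, size=n_drop, replace=False, p=w)
        else:
            chosen = rng.choice(survivors, size=n_drop, replace=False)
        drop[chosen] = j
        survivors = np.setdiff1d(survivors, chosen, assume_unique=True)
    return drop


def apply_attrition(panel: CohortPanel, spec: CohortSpec,
                    rng: np.random.Generator | None = None) -> CohortPanel:
    """Mask outcomes after each participant's dropout occasion.

    Dropout is monotone and shared across outcomes: a participant who drops
    before year t is missing every outcome measured at or after t.  The
    occasion-wise observed counts on the annual grid equal the spec's
    retention counts exactly.
    """
    rng = np.random.default_rng(spec.seed + 2) if rng is None else rng
    if spec.retention_counts[0] != panel.n:
        raise ValueError("retention_counts[0] must equal the panel size")
    reference = next(iter(panel.outcomes.values())) if panel.outcomes else None
    drop = _draw_dropout_times(spec, reference, rng)
    # dropping at occasion j means unobserved from year j onward
    outcomes = {}
    for name, y in panel.outcomes.items():
        y = y.copy()
        t = panel.times[name]
        mask = t[None, :] >= drop[:, None]
        y[mask] = np.nan
        outcomes[name] = y
    return replace(panel, outcomes=outcomes)


def simulate_cohort(spec: CohortSpec) -> CohortPanel:
    """Profiles, growth panel and attrition in one seeded call."""
    rng = np.random.default_rng(spec.seed)
    x = sample_decision_profiles(spec, rng)
    panel = sample_growth_panel(spec, x, rng)
    return apply_attrition(panel, spec, rng)
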
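"""Synthetic cohort generator: moments, growth structure, attrition."""

from dataclasses import replace

import numpy as np
import pytest

from choicetraj.cohort import (
    AVERAGE_USE,
    RETENTION_COUNTS,
    TYPICAL_USE,
    apply_attrition,
    default_cohort_spec,
    disturbance_covariance,
    sample_decision_profiles,
    sample_growth_panel,
    simulate_cohort,
    unstandardized_effects,
)


def _big_spec(n=5000, seed=21, **kw):
    spec = default_cohort_spec(seed=seed, **kw)
    return replace(spec, n_participants=n, retention_counts=(n,) * 7)


def test_profile_moments_match_published_table():
    spec = _big_spec()
    x = sample_decision_profiles(spec)
    assert x.shape == (5000, 5)
    # delay discounting log k: -4.6 +/- 2.2
    assert x[:, 0].mean() == pytest.approx(-4.6, abs=0.1)
    assert x[:, 0].std() == pytest.approx(2.2, abs=0.1)
    # consistency correlates negatively with delay discounting (-0.262)
    r = np.corrcoef(x[:, 4], x[:, 0])[0, 1]
    assert r < -0.15


def test_zero_sds_collapse_to_means():
    spec = replace(_big_spec(n=50), covariate_sds=(0.0,) * 5,
                   covariate_correlations=tuple(
                       tuple(float(i == j) for j in range(5)) for i in range(5)))
    x = sample_decision_profiles(spec)
    assert np.allclose(x, np.asarray(spec.covariate_means)[None, :])


def test_growth_panel_group_curve_and_intercept():
    spec = _big_spec(n=2000)
    rng = np.random.default_rng(spec.seed)
    x = sample_decision_profiles(spec, rng)
    panel = sample_growth_panel(spec, x, rng)
    y = panel.outcomes["typical_use"]
    assert np.nanmean(y[:, 0]) == pytest.approx(69.856, abs=2.0)


def test_zero_effects_and_noise_reduce_to_group_curve():
    quiet = replace(
        TYPICAL_USE, latent_sds=(0.0, 0.0, 0.0),
        effects_std=tuple((0.0,) * 5 for _ in range(3)), residual_sd=0.0)
    spec = replace(_big_spec(n=40), outcomes=(quiet,))
    rng = np.random.default_rng(0)
    x = sample_decision_profiles(spec, rng)
    panel = sample_growth_panel(spec, x, rng)
    t = panel.times["typical_use"]
    expected = 69.856 - 8.680 * t + 1.227 * t ** 2
    assert np.allclose(panel.outcomes["typical_use"],
                       np.tile(expected, (40, 1)))
    assert panel.outcomes["typical_use"][0, 0] == pytest.approx(69.856)


def test_zero_effects_leave_covariates_uncorrelated_with_intercepts():
    no_fx = replace(TYPICAL_USE,
                    effects_std=tuple((0.0,) * 5 for _ in range(3)))
    spec = replace(_big_spec(n=2000), outcomes=(no_fx,))
    rng = np.random.default_rng(5)
    x = sample_decision_profiles(spec, rng)
    panel = sample_growth_panel(spec, x, rng)
    y0 = panel.outcomes["typical_use"][:, 0]
    for j in range(5):
        assert abs(np.corrcoef(x[:, j], y0)[0, 1]) < 0.06


def test_unstandardized_effects_round_trip():
    spec = default_cohort_spec()
    b = unstandardized_effects(AVERAGE_USE, spec.covariate_sds)
    back = b * np.asarray(spec.covariate_sds)[None, :] \
        / np.asarray(AVERAGE_USE.latent_sds)[:, None]
    assert np.allclose(back, np.asarray(AVERAGE_USE.effects_std))


def test_disturbance_covariance_positive_definite():
    spec = default_cohort_spec()
    for out in spec.outcomes:
        psi = disturbance_covariance(out, spec)
        assert np.linalg.eigvalsh(psi).min() > 0


def test_attrition_reproduces_published_retention_exactly():
    panel = simulate_cohort(default_cohort_spec(seed=9))
    y = panel.outcomes["typical_use"]
    observed = (~np.isnan(y)).sum(axis=0)
    assert tuple(observed) == RETENTION_COUNTS
    # AUD criteria measured at years 1,2,4,5,6 share the dropout times
    aud = (~np.isnan(panel.outcomes["aud_criteria"])).sum(axis=0)
    assert tuple(aud) == (166, 160, 100, 85, 84)


@pytest.mark.parametrize("mechanism", ["MCAR_dropout", "MAR_dropout"])
def test_attrition_monotone(mechanism):
    panel = simulate_cohort(default_cohort_spec(
        seed=3, attrition_mechanism=mechanism))
    for y in panel.outcomes.values():
        miss = np.isnan(y)
        # once missing, always missing
        assert not np.any(~miss[:, 1:] & miss[:, :-1])


def test_full_retention_leaves_panel_unchanged():
    spec = _big_spec(n=60, seed=2)
    rng = np.random.default_rng(0)
    x = sample_decision_profiles(spec, rng)
    panel = sample_growth_panel(spec, x, rng)
    after = apply_attrition(panel, spec, rng)
    for name in panel.outcomes:
        assert np.array_equal(panel.outcomes[name], after.outcomes[name])


def test_retention_exceeding_n_rejected():
    with pytest.raises(ValueError):
        default_cohort_spec(seed=0).__class__(
            n_participants=100, retention_counts=(100, 120, 80, 70, 60, 50, 40))


def test_seed_determinism():
    a = simulate_cohort(default_cohort_spec(seed=4))
    b = simulate_cohort(default_cohort_spec(seed=4))
    assert np.array_equal(a.covariates, b.covariates)
    for name in a.outcomes:
        assert np.array_equal(a.outcomes[name], b.outcomes[name],
                              equal_nan=True)


def test_mcar_complete_case_means_unbiased():
    """Under MCAR dropout the observed-case occasion means track the group
    curve within Monte-Carlo error."""
    spec = replace(default_cohort_spec(seed=31, floor_at_zero=False),
                   n_participants=5000,
                   retention_counts=(5000, 4200, 4000, 3400, 2500, 2100, 2100))
    panel = simulate_cohort(spec)
    t = panel.times["typical_use"]
    curve = 69.856 - 8.680 * t + 1.227 * t ** 2
    y = panel.outcomes["typical_use"]
    for j in range(7):
        col = y[:, j]
        col = col[~np.isnan(col)]
        se = col.std() / np.sqrt(col.size)
        assert abs(col.mean() - curve[j]) < 3 * se + 0.5


def test_aud_criteria_are_nonnegative_integers():
    panel = simulate_cohort(default_cohort_spec(seed=8))
    aud = panel.outcomes["aud_criteria"]
    vals = aud[~np.isnan(aud)]
    assert np.all(vals >= 0)
    assert np.allclose(vals, np.round(vals))
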
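"""Posterior machinery, offer placement and session simulation."""

import numpy as np
import pytest

from choicetraj.adaptive import (
    PosteriorGrid,
    TaskConfig,
    default_task_config,
    estimate_from_trials,
    indifference_gain,
    indifference_immediate,
    map_estimate,
    propose_offer,
    run_session,
    update_posterior,
)
from choicetraj.tasks import ChoiceOffer, DecisionProfile, choice_probability

SMALL = TaskConfig(task="delay", n_trials=8, param_range=(-8.0, 0.0),
                   log_beta_range=(-1.0, 2.0), grid_spacing=0.25)


def _profile(log_k=-4.6, log_beta=1.0):
    return DecisionProfile(log_k_delay=log_k, log_k_pgain=-0.2,
                           log_k_ploss=-0.3, log_lambda=0.3,
                           log_beta={t: log_beta for t in
                                     ("delay", "prob_gain", "prob_loss", "gamble")})


def _posterior(grid):
    return np.exp(grid.log_posterior)


def test_update_matches_bayes_rule_pointwise():
    """Posterior mass ratios equal prior ratios times likelihood ratios
    computed independently from the logistic choice rule."""
    grid = PosteriorGrid.uniform(SMALL)
    offer = ChoiceOffer(task="delay", amount_now=5.0, amount_later=10.0,
                        delay_days=31)
    updated = update_posterior(grid, offer, chose_b=True)
    post = _posterior(updated)
    # brute-force likelihood at every node
    lik = np.empty_like(post)
    for i, lk in enumerate(grid.param_axis):
        for j, lb in enumerate(grid.log_beta_axis):
            dv = 10.0 / (1.0 + np.exp(lk) * 31) - 5.0
            lik[i, j] = choice_probability(dv, np.exp(lb))
    expected = lik / lik.sum()  # uniform prior
    assert np.allclose(post, expected, atol=1e-12)
    # applying the same update twice squares the likelihood
    twice = update_posterior(updated, offer, chose_b=True)
    expected2 = lik ** 2 / (lik ** 2).sum()
    assert np.allclose(_posterior(twice), expected2, atol=1e-12)


def test_posterior_normalized_after_every_update(rng):
    grid = PosteriorGrid.uniform(SMALL)
    for _ in range(6):
        offer = propose_offer(grid, SMALL, rng)
        grid = update_posterior(grid, offer, chose_b=bool(rng.integers(2)))
        assert np.exp(grid.log_posterior).sum() == pytest.approx(1.0, abs=1e-10)


def test_sequential_equals_batch_product(rng):
    """Sequential updating equals the brute-force product of likelihoods
    over the full grid, in any trial order."""
    profile = _profile()
    trials, _ = run_session(profile, SMALL, seed=7)
    seq = PosteriorGrid.uniform(SMALL)
    log_joint = np.zeros_like(seq.log_posterior)
    for offer, chose_b in trials[:5]:
        seq = update_posterior(seq, offer, chose_b)
        for i, lk in enumerate(seq.param_axis):
            for j, lb in enumerate(seq.log_beta_axis):
                dv = offer.amount_later / (1 + np.exp(lk) * offer.delay_days) \
                    - offer.amount_now
                p = choice_probability(dv, np.exp(lb))
                p = p if chose_b else 1 - p
                log_joint[i, j] += np.log(max(p, 1e-300))
    batch = np.exp(log_joint - log_joint.max())
    batch /= batch.sum()
    assert np.allclose(_posterior(seq), batch, atol=1e-10)
    # order invariance via the offline estimator
    shuffled = [trials[:5][i] for i in rng.permutation(5)]
    grid_a = PosteriorGrid.uniform(SMALL)
    grid_b = PosteriorGrid.uniform(SMALL)
    for (o, c), (o2, c2) in zip(trials[:5], shuffled):
        grid_a = update_posterior(grid_a, o, c)
        grid_b = update_posterior(grid_b, o2, c2)
    assert np.allclose(grid_a.log_posterior, grid_b.log_posterior, atol=1e-10)


def test_update_rejects_task_mismatch():
    grid = PosteriorGrid.uniform(SMALL)
    offer = ChoiceOffer(task="gamble", gain=10.0, loss=5.0)
    with pytest.raises(ValueError, match="task"):
        update_posterior(grid, offer, True)


def test_map_estimate_tie_break_and_point_mass():
    grid = PosteriorGrid.uniform(SMALL)
    # uniform posterior: documented tie-break toward the smallest axis values
    assert map_estimate(grid) == (grid.param_axis[0], grid.log_beta_axis[0])
    lp = np.full_like(grid.log_posterior, -np.inf)
    lp[3, 5] = 0.0
    grid.log_posterior = lp
    assert map_estimate(grid) == (grid.param_axis[3], grid.log_beta_axis[5])


def test_offer_placement_arithmetic():
    config = default_task_config("delay")
    # MAP k=0.1, delay 7, later EUR 10: 10/1.7 = 5.882 -> nearest EUR 0.10
    assert indifference_immediate(10.0, 7, 0.1, config) == pytest.approx(5.90)
    # degenerate indifference amounts clip to the EUR 0.30 bound
    assert indifference_immediate(0.12, 0, 0.0, config) == pytest.approx(0.30)
    gamble = default_task_config("gamble")
    assert indifference_gain(10.0, 1.5, gamble) == pytest.approx(15.0)


def test_session_contract_and_determinism():
    profile = _profile()
    config = default_task_config("delay")
    trials, est = run_session(profile, config, seed=11)
    assert len(trials) == 30
    trials2, est2 = run_session(profile, config, seed=11)
    assert est == est2
    assert all(a == b for (a, _), (b, _) in zip(trials, trials2))
    # offers respect the task's amount bounds
    for offer, _ in trials:
        assert 0.30 <= offer.amount_now <= 10.0
        assert 0.30 <= offer.amount_later <= 10.0
        assert offer.delay_days in config.delay_set


def test_estimate_from_trials_matches_session(rng):
    profile = _profile()
    trials, est = run_session(profile, SMALL, seed=3)
    assert estimate_from_trials(trials, SMALL) == est
    shuffled = [trials[i] for i in rng.permutation(len(trials))]
    assert estimate_from_trials(shuffled, SMALL) == est


def test_estimate_from_trials_errors():
    with pytest.raises(ValueError, match="empty"):
        estimate_from_trials([], SMALL)
    mixed = [(ChoiceOffer(task="delay", amount_now=5, amount_later=10,
                          delay_days=7), True),
             (ChoiceOffer(task="gamble", gain=10, loss=5), False)]
    with pytest.raises(ValueError, match="mixed"):
        estimate_from_trials(mixed, SMALL)


def test_recovery_improves_with_trials():
    """Median absolute log-k error shrinks (weakly) from 10 to 30 trials."""
    profile = _profile(log_k=-4.6, log_beta=1.0)
    errs = {}
    for n_trials in (10, 30):
        config = default_task_config("delay", n_trials=n_trials)
        errs[n_trials] = np.median([
            abs(run_session(profile, config, seed=500 + s)[1][0] + 4.6)
            for s in range(40)])
    assert errs[30] <= errs[10] + 0.05
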
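"""Valuation models and the probabilistic choice rule for the four decision tasks.

Four computerized tasks characterize value-based decision-making at baseline:

* ``delay`` — smaller-immediate vs. larger-delayed rewards; hyperbolic
  discounting ``V = A / (1 + k D)`` with ``k`` in 1/days.
* ``prob_gain`` — smaller-certain vs. larger-probabilistic gains; hyperbolic
  discounting against the odds-against-receipt ``theta = (1 - p) / p``,
  ``V = A / (1 + k theta)``.  High ``k`` is risk aversion for gains.
* ``prob_loss`` — the same procedure on losses, modeled on signed values
  (losses negative); high ``k`` shrinks the subjective magnitude of the
  probabilistic loss and manifests as risk-seeking for losses.
* ``gamble`` — accept/reject a 50-50 mixed gamble, ``V = (G - lambda*L)/2``;
  high ``lambda`` (loss aversion) produces rejections.

Choices follow a logistic (softmax) rule on the value difference with a
per-task inverse temperature ``beta``; the consistency score is the mean of
mean-centered ``log beta`` across the four tasks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

TASKS = ("delay", "prob_gain", "prob_loss", "gamble")

#: discrete design sets used by the adaptive battery
DELAY_SET = (3, 7, 14, 31, 61, 180, 365)
PROBABILITY_SET = (2 / 3, 1 / 2, 1 / 3, 1 / 4, 1 / 5)
DISCOUNT_AMOUNT_BOUNDS = (0.30, 10.0)
GAMBLE_GAIN_BOUNDS = (1.0, 40.0)
GAMBLE_LOSS_BOUNDS = (5.0, 20.0)


@dataclass(frozen=True)
class ChoiceOffer:
    """One two-option trial.  Fields not used by ``task`` stay ``None``.

    Option A is the reference option (immediate / certain / reject the
    gamble); option B is the alternative (delayed / probabilistic / accept).
    """

    task: str
    amount_now: float | None = None
    amount_later: float | None = None
    delay_days: int | None = None
    amount_certain: float | None = None
    amount_prob: float | None = None
    probability: float | None = None
    gain: float | None = None
    loss: float | None = None
    b_shown_left: bool = False

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")


@dataclass
class DecisionProfile:
    """Per-participant decision parameters on the log scale."""

    log_k_delay: float
    log_k_pgain: float
    log_k_ploss: float
    log_lambda: float
    log_beta: dict[str, float] = field(default_factory=dict)
    consistency: float | None = None


def subjective_value_delay(amount: float, delay: float, k: float) -> float:
    """Hyperbolically discounted value ``A / (1 + k D)`` of a delayed reward.

    Parameters are the offered amount (EUR), the delay (days) and the
    discount rate ``k`` (1/days).  Equals ``amount`` at zero delay or k.
    """
    if amount < 0:
        raise ValueError("amount must be non-negative")
    if delay < 0 or k < 0:
        raise ValueError("delay and k must be non-negative")
    return amount / (1.0 + k * delay)


def subjective_value_prob(amount: float, probability: float, k: float,
                          sign: str = "gain") -> float:
    """Probability-discounted value ``A / (1 + k theta)``, ``theta=(1-p)/p``.

    Gains return a positive value, losses a negative one; the decision-maker
    maximizes the signed value, so strong discounting of a probabilistic
    loss (small magnitude) makes it preferable to a certain loss.
    """
    if not 0.0 < probability <= 1.0:
        raise ValueError("probability must be in (0, 1]")
    if amount < 0 or k < 0:
        raise ValueError("amount and k must be non-negative")
    if sign not in ("gain", "loss"):
        raise ValueError("sign must be 'gain' or 'loss'")
    theta = (1.0 - probability) / probability
    value = amount / (1.0 + k * theta)
    return value if sign == "gain" else -value


def subjective_value_gamble(gain: float, loss: float, lam: float) -> float:
    """Expected value of a 50-50 mixed gamble with loss aversion lambda."""
    if gain < 0 or loss < 0:
        raise ValueError("gain and loss must be non-negative")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return 0.5 * (gain - lam * loss)


def choice_probability(value_diff: float, beta: float) -> float:
    """Logistic probability of choosing option B given value difference B-A."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    x = beta * value_diff
    # the complement is computed as 1 - p, which is exact for p in [1/2, 1],
    # so P(B; dv) + P(B; -dv) == 1 holds exactly
    if x < 0:
        return 1.0 - choice_probability(-value_diff, beta)
    return 1.0 / (1.0 + math.exp(-x))


def offer_value_difference(offer: ChoiceOffer, k: float | None = None,
                           lam: float | None = None) -> float:
    """Signed value difference (option B minus option A) for an offer.

    ``k`` parameterizes the three discounting tasks, ``lam`` the gambles
    (option A of a gamble is the status quo, value 0; the pre-task
    endowment is bookkeeping and does not enter the valuation).
    """
    if offer.task == "delay":
        v_b = subjective_value_delay(offer.amount_later, offer.delay_days, k)
        return v_b - offer.amount_now
    if offer.task == "prob_gain":
        v_b = subjective_value_prob(offer.amount_prob, offer.probability, k, "gain")
        return v_b - offer.amount_certain
    if offer.task == "prob_loss":
        v_b = subjective_value_prob(offer.amount_prob, offer.probability, k, "loss")
        return v_b - (-offer.amount_certain)
    # gamble
    return subjective_value_gamble(offer.gain, offer.loss, lam)


def consistency_score(profile_log_betas: dict[str, float],
                      cohort_means: dict[str, float]) -> float:
    """Average of mean-centered log beta across the four tasks.

    Centering is relative to cohort means, which must therefore be supplied
    explicitly; a participant at the cohort mean on every task scores 0.
    """
    for task in TASKS:
        if task not in profile_log_betas:
            raise KeyError(f"missing log beta for task {task!r}")
        if task not in cohort_means:
            raise KeyError(f"missing cohort mean for task {task!r}")
    return sum(profile_log_betas[t] - cohort_means[t] for t in TASKS) / len(TASKS)
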
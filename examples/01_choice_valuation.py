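"""Valuation equations of the four choice tasks on worked offers.

Each task reduces a two-option offer to a signed value difference, and a
logistic rule with inverse temperature beta turns that difference into a
choice probability.
"""

from choicetraj import (
    choice_probability,
    subjective_value_delay,
    subjective_value_gamble,
    subjective_value_prob,
)

# 'EUR 7 now or EUR 10 in 7 days': at k = 3/49 per day the delayed euro
# ten is worth exactly seven euros -> indifference
v = subjective_value_delay(10.0, 7, 3 / 49)
print(f"EUR 10 in 7 days at k=3/49:        V = {v:.3f} EUR (vs EUR 7 now)")

# 'EUR 2 for certain or EUR 5 with a 20% probability': k = 0.375 makes the
# gamble worth exactly EUR 2
v = subjective_value_prob(5.0, 0.2, 0.375, "gain")
print(f"EUR 5 at p=0.2, k=0.375:           V = {v:.3f} EUR (vs EUR 2 certain)")

# a probabilistic loss shrinks with discounting: at high k the risky loss
# of EUR 5 at p=0.2 feels smaller than a certain EUR 2 loss (risk-seeking)
risky = subjective_value_prob(5.0, 0.2, 2.0, "loss")
print(f"losing EUR 5 at p=0.2, k=2:        V = {risky:.3f} EUR (vs -2.0 certain)")
p = choice_probability(risky - (-2.0), beta=2.0)
print(f"  -> probability of taking the risky loss: {p:.3f}")

# mixed gamble: gain EUR 12 / lose EUR 5 at loss aversion 1.2
v = subjective_value_gamble(12.0, 5.0, 1.2)
p = choice_probability(v, beta=1.0)
print(f"50-50 gamble +12/-5 at lambda=1.2: V = {v:.3f} EUR, "
      f"P(accept) = {p:.3f}")
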
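"""Score EQ-5D-5L health states with the packaged value set.

A health state is five severity levels (1 = no problems ... 5 = extreme),
one per dimension.  The value set maps each of the 3125 states to a single
utility anchored at 1 (perfect health) and 0 (dead); states worse than dead
are negative.
"""

from qale import (HealthState, belgian_synthetic_value_set, dichotomize,
                  enumerate_states, index_value)

vs = belgian_synthetic_value_set()
states = enumerate_states()
print(f"value set {vs.name!r}: {len(states)} states, "
      f"floor {vs.floor:.3f}")

for levels in [(1, 1, 1, 1, 1), (1, 1, 1, 1, 3), (1, 1, 3, 3, 3),
               (2, 1, 2, 3, 1), (5, 5, 5, 5, 5)]:
    state = HealthState(*levels)
    flags = dichotomize(state)
    print(f"state {state}: utility {index_value(state, vs):+.3f}, "
          f"problem-free dimensions {sum(flags)}/5")

# The utility is the health weight a year lived in that state receives in
# quality-adjusted life expectancy; the no-problem flags feed the
# dimension-specific disability-free life expectancies.
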
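"""Split a change in QALE into mortality and disutility effects.

The change in QALE between two periods decomposes exactly, age by age, into
a mortality effect (change in person-years, valued at the average health of
the two periods) and a disutility effect (change in health, applied to the
average person-years).
"""

import numpy as np

from qale import (AgeBands, belgian_synthetic_value_set, belgium_like,
                  build_lifetable, decompose_qale, estimate_norms,
                  expand_norms, generate_survey)

scenario = belgium_like()
vs = belgian_synthetic_value_set()
ages = np.arange(15, 101)

survey = generate_survey(scenario.response, 10_000, scenario.strata(),
                         seed=42)
norms = estimate_norms(survey, vs, AgeBands.default())
tables = {k: build_lifetable(ms)
          for k, ms in scenario.mortality_schedules().items()}

for gender in scenario.genders:
    sub13 = norms[(norms.year == 2013) & (norms.gender == gender)]
    sub18 = norms[(norms.year == 2018) & (norms.gender == gender)]
    for x in (15, 65):
        res = decompose_qale(tables[(2013, gender, "Belgium")],
                             expand_norms(sub13, ages),
                             tables[(2018, gender, "Belgium")],
                             expand_norms(sub18, ages), a=x)
        print(f"{gender:6s} at {x}: mortality effect {res.mor_total:+.2f}, "
              f"disutility effect {res.dis_total:+.2f}, "
              f"QALE change {res.delta_qale:+.2f} years")

# The two effects always sum exactly to the QALE change.  A positive
# mortality effect with a negative disutility effect reads: people live
# longer, but the extra (and existing) years are lived in worse health.
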
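"""Build a period life table from a Gompertz-Makeham mortality schedule.

Central death rates m_x = c + a * exp(b * x) at single years of age 15..100
are converted to a full life table (q, l, d, L, T, e) with an open last age
group at 100 closed by the constant-hazard rule L = l / m.
"""

from qale import MortalityModel, build_lifetable, generate_mortality

model = MortalityModel(a=1.857071e-05, b=0.1, c=5e-4)  # Belgian-like men 2018
schedule = generate_mortality(model)
lt = build_lifetable(schedule)

print("age   m_x      q_x      l_x        L_x        e_x")
for age in (15, 40, 65, 80, 100):
    i = lt.index_of(age)
    print(f"{age:3d}  {lt.m[i]:.5f}  {lt.q[i]:.5f}  {lt.l[i]:9.1f}  "
          f"{lt.L[i]:9.1f}  {lt.e[i]:6.2f}")

# e_x is remaining life expectancy: a 15-year-old is expected to live
# another ~64.6 years under these rates.  The L_x column (person-years
# lived in each age interval) is what the Sullivan method re-weights by
# age-specific health to obtain health expectancies.
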
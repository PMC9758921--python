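# Methods

This note records the statistical model behind `qale`, the conventions and
numerical choices the implementation commits to, and what the synthetic
scenario does and does not emulate.

## Health states and value sets

An EQ-5D-5L health state is a 5-tuple of ordinal severity levels (1–5) over
mobility, self-care, usual activities, pain/discomfort and
anxiety/depression; the state space has exactly 3125 members. A value set
is represented internally as a *total* tabulation over all 3125 states,
validated to anchor perfect health at exactly 1. Additive main-effects sets
(a per-dimension, per-level decrement subtracted from 1) are expanded to
the full table at load time, so tabulated and additive sets are
interchangeable downstream and lookups are pure, with no arithmetic at
scoring time.

The packaged `belgium-synthetic` value set is a stand-in, not the published
Belgian tariff: its twenty decrements were calibrated once so that the four
published example utilities are matched exactly (11111 → 1, 11113 → 0.849,
11333 → 0.678, 55555 → −0.532, hence floor −0.532), with the remaining
decrements chosen as plausible magnitudes (pain/discomfort and
anxiety/depression carry the largest losses). It exists so the pipeline
and its tests run self-contained; any real tabulated value set can be
supplied as a 3125-row CSV.

## Population norms

Norms are estimated per stratum (age band × gender × region × year) from
respondent-level data with positive survey weights w:

* mean utility π̂ = Σwu / Σw, with s² = Σw(u − π̂)² / Σw;
* Kish effective sample size n_eff = (Σw)² / Σw², and var(π̂) = s²/n_eff;
* per-dimension no-problem prevalence p̂ (weighted share of level 1) with
  binomial variance p̂(1 − p̂)/n_eff.

Respondents with any missing dimension are excluded per stratum
(complete-case) before weighting; a stratum×band cell with no usable record
is a hard error rather than a silent gap, because every age must carry a
norm for the Sullivan sum. Kish n_eff is the standard conservative choice
when only per-respondent weights, not the survey's design structure, are
available; the weighted variance uses the Σw-normalised form without a
small-sample correction, which is negligible at the stratum sizes this
pipeline targets and keeps π̂, s² consistent under weight rescaling
(estimates are invariant to multiplying all weights by a constant). Age
bands default to decennial bands 15–24 … 75–84 with a wider top band 85–100,
and are fully configurable; band estimates are expanded to single years of
age as a step function (closed intervals, top band through 100).

## Life tables

Single-year period tables from central death rates m_x, analysis range
15–100 with an open last group. Closed intervals use
q_x = m_x / (1 + (1 − a_x) m_x) with a_x = 0.5 (the standard adult
single-year separation factor; a_x is a parameter for users importing
official tables with other conventions). The open group takes q = 1 and the
constant-hazard closure L = l/m. A closed-interval q computing above 1
(possible only under extreme rates) is clamped to 1 with a warning rather
than rejected, so stress inputs fail loudly but not fatally. The radix
(default 100 000) cancels from every health-expectancy quantity; tests
assert radix invariance explicitly. Against an exact piecewise-constant-
hazard computation, the a = 0.5 chord approximation displaces e₁₅ by only
≈ 0.003 years for Belgian-like rate schedules.

## Sullivan health expectancies

HE(x) = (1/l_x) Σ_{y≥x} π_y L_y, with π either the utility norm (QALE) or a
no-problem prevalence (dimension-specific DFLE). Two structural facts are
worth stating: QALE equals LE exactly when π ≡ 1 and scales linearly in a
constant π; and QALE is *not* bounded by any single dimension's DFLE in
general — utilities aggregate five dimensions with severity weights, so no
such inequality is asserted or tested.

Standard errors treat mortality as fixed (register-based deaths carry no
sampling error on the survey's scale) and propagate only the health
measure's variance:

    se(x)² = (1/l_x²) Σ_b ( Σ_{y∈b, y≥x} L_y )² · v_b

The sum runs over *age bands*, not ages: all single years inside a band
share one survey estimate, so their person-years are summed before
squaring. Treating band-mates as independent would understate se by up to
the band width. For a continuous utility, v_b is s²/n_eff (the cited
variance machinery is stated for binary prevalences; the s²/n substitution
is this package's recorded convention, and reduces to the binomial form for
a 0/1 measure). At an index age inside a band, only ages ≥ x contribute to
that band's person-year sum. Comparisons use a two-sided Z-test with
independent variances — conservative for contrasts across years or genders;
no p-value is attached to plain LE (its se is 0 under the fixed-mortality
convention, so the Z-test is undefined there by construction).

## Decomposition of a QALE change

With λ_x(p) = L_x(p)/l_a(p) the person-years conditioned on survival to the
index age a within period p:

    MOR_x = π̄_x · (λ_x(t+n) − λ_x(t)),   DIS_x = λ̄_x · (π_x(t+n) − π_x(t))

where bars are two-period means. Because Δ(πλ) = π̄Δλ + λ̄Δπ is an algebraic
identity, the effects sum *exactly* (to accumulation tolerance ~1e-10 in
double precision) to QALE_a(t+n) − QALE_a(t); the half-sum weighting
allocates the interaction symmetrically, and no separate interaction term
is reported. The conditioning on l_a is a deliberate design choice: QALE at
an index age is conditional on surviving to it, and without the
normalisation the totals fail to reproduce the conditional change whenever
survival to a differs between periods (the identity then holds only at the
table's start age). Effects are computed at single-year resolution; any
binning to presentation age groups is aggregation after the fact. Sign
convention throughout: later period minus earlier period.

## Synthetic data generator

The generator defines the study conditions for all self-contained testing.

*Mortality* is Gompertz–Makeham, m_x = c + a·e^{bx}, with c = 5×10⁻⁴/yr,
b = 0.1/yr of age, and the level a set per gender and period so that the
remaining life expectancy at 15 matches Belgian-like values (63.5/64.6
years for men and 68.6/69.1 for women in the earlier/later period).

*Responses* follow an ordered probit with a Gaussian copula: respondent i
draws a shared factor and five dimension-specific latents with
cross-dimension correlation ρ = 0.4; the level on a dimension is set by
four increasing cutpoints against the latent shifted by
β_age(age − 15) + β_gender + β_year (β_age = 0.012/yr; women +0.22; later
period +0.06 — severity worsens with age, is higher for women, and drifts
worse between periods). Cutpoints per dimension were fixed once so that,
under the packaged value set, mean utility at age 15 in the later period is
0.92 for men and 0.89 for women, and pain/discomfort is the most prevalent
complaint. Survey weights are log-normal (sd 0.5 on the log scale, mean
rescaled to 1); a skewed-weights variant (sd 1.2) stresses the Kish
correction. Ages are drawn uniformly over 15–100 within each stratum.

Exact norms are available in closed form: marginal level probabilities are
normal CDFs at the cutpoints, and the mean utility integrates the
conditional product distribution over the shared factor by 48-node
Gauss–Hermite quadrature (for ρ = 0 it reduces to an exact product-form sum
over all 3125 states). Band-level truth averages the per-age values
uniformly, matching the uniform age draw.

What the generator does *not* emulate: multistage cluster sampling and
design-based weights (weights here are exchangeable noise), item
nonresponse mechanisms, proxy interviews, a realistic population age
pyramid, and any dependence of mortality on the health state (mortality
and HRQoL are generated independently). Passing recovery tests therefore
demonstrates that the estimators are correct and their variances
calibrated under clean sampling — not that design effects in a real survey
are handled beyond the Kish approximation.

## Problem sizes and tolerances

Identity-type checks (Sullivan vs brute-force summation, decomposition
additivity/antisymmetry) use 1000 random tables/period pairs at tolerance
1e-10. The life-table check simulates 10⁶ lifetimes under the
piecewise-constant hazard and compares e₁₅ within 5 Monte-Carlo standard
errors plus a 0.01-year allowance for the chord approximation. Recovery
tests use 10 000 respondents per stratum and 20 replicates, requiring
|QALÊ₁₅ − QALE₁₅| < 3·se in ≥ 95% of stratum-replicates (observed coverage
in development runs was ≈ 99%, consistent with a well-calibrated se).
Determinism is asserted byte-for-byte on all CSV outputs for a fixed
config and seed; seeding uses NumPy `SeedSequence` spawning, one child
stream per stratum in listed order.

## Known limitations

* Variance estimation is weight-aware but design-naive; replicate-weight or
  linearised design variances are out of scope.
* No imputation: missing EQ-5D responses are dropped per stratum.
* The packaged value set is synthetic; results under it are for pipeline
  validation, not substantive inference about any population.
* Life tables start at 15 (HRQoL instruments for children differ); infant
  separation-factor corrections are therefore never needed.
* Cause-of-death and counterfactual-life-table extensions of the
  decomposition are not implemented; only the exact two-effect split is.
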
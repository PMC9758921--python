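import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qale.lifetable import LifeTable, MortalitySchedule, build_lifetable
from qale.sullivan import (AgeMeasure, CoverageError,
                           DegenerateComparisonError, HealthExpectancy,
                           MissingVarianceError, compare_he, expand_norms,
                           he_le_ratio, life_expectancy, sullivan_he,
                           sullivan_se, sullivan_value)

from conftest import brute_force_sullivan, random_lifetable


def toy_three_age_table():
    """l = 100000, 60000, 20000; a = 0.5; open-age L = 10000."""
    ages = np.array([15, 16, 17])
    l = np.array([100_000.0, 60_000.0, 20_000.0])
    d = np.array([40_000.0, 40_000.0, 20_000.0])
    L = np.array([l[1] + 0.5 * d[0], l[2] + 0.5 * d[1], 10_000.0])
    T = np.cumsum(L[::-1])[::-1]
    q = d / l
    m = np.array([q[0] / (1 - 0.5 * q[0]), q[1] / (1 - 0.5 * q[1]),
                  l[2] / 10_000.0])
    return LifeTable(ages=ages, m=m, a=np.array([0.5, 0.5, np.nan]), q=q,
                     l=l, d=d, L=L, T=T, e=T / l)


class TestExpandNorms:
    def norms(self, bands_pi):
        return pd.DataFrame([
            {"band_lo": lo, "band_hi": hi, "pi": pi, "var_pi": 0.01}
            for (lo, hi, pi) in bands_pi])

    def test_single_band_constant(self):
        m = expand_norms(self.norms([(15, 100, 0.9)]), np.arange(15, 101))
        assert np.all(m.value == 0.9)
        assert np.all(m.band == 0)

    def test_boundary_closed_intervals(self):
        m = expand_norms(self.norms([(15, 49, 0.95), (50, 100, 0.80)]),
                         np.arange(15, 101))
        assert m.value[49 - 15] == 0.95
        assert m.value[50 - 15] == 0.80

    def test_uncovered_age_raises(self):
        with pytest.raises(CoverageError):
            expand_norms(self.norms([(15, 60, 0.9)]), np.arange(15, 101))


class TestSullivanValue:
    def test_pi_one_equals_le(self):
        lt = toy_three_age_table()
        ones = AgeMeasure.constant(lt.ages, 1.0)
        for x in (15, 16, 17):
            assert sullivan_value(lt, ones, x) == pytest.approx(
                lt.e_at(x), rel=1e-14)

    def test_pi_half_is_half_le(self):
        lt = toy_three_age_table()
        half = AgeMeasure.constant(lt.ages, 0.5)
        assert sullivan_value(lt, half, 15) == pytest.approx(
            lt.e_at(15) / 2, rel=1e-14)

    def test_toy_table_hand_sum(self):
        lt = toy_three_age_table()
        pi = AgeMeasure(ages=lt.ages, value=np.array([0.9, 0.8, 0.5]))
        expected = (0.9 * 80_000 + 0.8 * 40_000 + 0.5 * 10_000) / 100_000
        assert sullivan_value(lt, pi, 15) == pytest.approx(expected,
                                                           rel=1e-14)

    def test_index_age_outside_table(self):
        lt = toy_three_age_table()
        with pytest.raises(IndexError):
            sullivan_value(lt, AgeMeasure.constant(lt.ages, 1.0), 30)

    def test_brute_force_oracle_on_random_tables(self):
        """1000 random toy tables: matches an independent plain-loop
        person-year summation to 1e-10."""
        rng = np.random.default_rng(202)
        for _ in range(1000):
            lt = random_lifetable(rng)
            pi = rng.uniform(-0.5, 1.0, lt.ages.size)
            x = int(rng.choice(lt.ages))
            fast = sullivan_value(lt, AgeMeasure(ages=lt.ages, value=pi), x)
            slow = brute_force_sullivan(lt, pi, x)
            assert abs(fast - slow) < 1e-10

    def test_pointwise_monotonicity(self):
        """Increasing pi at one age weakly increases HE at index ages <= it."""
        rng = np.random.default_rng(55)
        lt = random_lifetable(rng, open_age=40)
        pi = rng.uniform(0.2, 0.8, lt.ages.size)
        j = 10
        bumped = pi.copy()
        bumped[j] += 0.1
        for x in lt.ages[:j + 1]:
            lo = sullivan_value(lt, AgeMeasure(ages=lt.ages, value=pi), int(x))
            hi = sullivan_value(lt, AgeMeasure(ages=lt.ages, value=bumped),
                                int(x))
            assert hi >= lo


class TestSullivanSe:
    def test_zero_variance_gives_zero_se(self):
        lt = toy_three_age_table()
        m = AgeMeasure.constant(lt.ages, 0.9, var=0.0)
        assert sullivan_se(lt, m, 15) == 0.0

    def test_single_age_binomial_closed_form(self):
        # One age class carrying all person-years: se = sqrt(p(1-p)/N)
        ages = np.array([15, 16])
        l = np.array([100.0, 100.0])
        L = np.array([0.0, 100.0])
        T = np.cumsum(L[::-1])[::-1]
        lt = LifeTable(ages=ages, m=np.array([1e-9, 1.0]),
                       a=np.array([0.5, np.nan]), q=np.array([0.0, 1.0]),
                       l=l, d=np.array([0.0, 100.0]), L=L, T=T, e=T / l)
        v = 0.5 * 0.5 / 100
        m = AgeMeasure(ages=ages, value=np.array([0.5, 0.5]),
                       var=np.array([v, v]), band=np.array([0, 1]))
        assert sullivan_se(lt, m, 15) == pytest.approx(0.05, rel=1e-12)

    def test_direct_resummation_oracle(self):
        """Toy 3-age table with per-age variances matches the formula
        evaluated independently term by term (each age its own band)."""
        lt = toy_three_age_table()
        var = np.array([0.01, 0.02, 0.03])
        m = AgeMeasure(ages=lt.ages, value=np.array([0.9, 0.8, 0.5]),
                       var=var, band=np.array([0, 1, 2]))
        expected = np.sqrt((lt.L ** 2 * var).sum()) / lt.l[0]
        assert sullivan_se(lt, m, 15) == pytest.approx(expected, rel=1e-12)

    def test_band_grouping_inflates_variance(self):
        """Ages sharing one survey estimate must pool person-years before
        squaring: (L1+L2)^2 v > L1^2 v + L2^2 v."""
        lt = toy_three_age_table()
        var = np.array([0.01, 0.01, 0.01])
        value = np.array([0.9, 0.9, 0.5])
        shared = AgeMeasure(ages=lt.ages, value=value, var=var,
                            band=np.array([0, 0, 1]))
        split = AgeMeasure(ages=lt.ages, value=value, var=var,
                           band=np.array([0, 1, 2]))
        se_shared = sullivan_se(lt, shared, 15)
        se_split = sullivan_se(lt, split, 15)
        expected = np.sqrt((lt.L[0] + lt.L[1]) ** 2 * 0.01
                           + lt.L[2] ** 2 * 0.01) / lt.l[0]
        assert se_shared == pytest.approx(expected, rel=1e-12)
        assert se_shared > se_split

    def test_partial_band_at_index_age(self):
        # only ages >= x contribute to the band person-year sum
        lt = toy_three_age_table()
        m = AgeMeasure(ages=lt.ages, value=np.array([0.9, 0.9, 0.9]),
                       var=np.array([0.01, 0.01, 0.01]),
                       band=np.array([0, 0, 0]))
        se_16 = sullivan_se(lt, m, 16)
        expected = np.sqrt((lt.L[1] + lt.L[2]) ** 2 * 0.01) / lt.l[1]
        assert se_16 == pytest.approx(expected, rel=1e-12)

    def test_missing_variance_raises(self):
        lt = toy_three_age_table()
        m = AgeMeasure(ages=lt.ages, value=np.array([0.9, 0.8, 0.5]))
        with pytest.raises(MissingVarianceError):
            sullivan_se(lt, m, 15)

    def test_se_radix_invariant(self):
        rng = np.random.default_rng(90)
        ages = np.arange(15, 101)
        mx = rng.uniform(0.001, 0.2, ages.size)
        value = rng.uniform(0.3, 1.0, ages.size)
        band = np.repeat(np.arange(ages.size // 2 + 1), 2)[:ages.size]
        band_var = rng.uniform(0.0001, 0.001, band.max() + 1)
        var = band_var[band]
        ses = []
        for radix in (1.0, 100_000.0):
            lt = build_lifetable(MortalitySchedule(ages=ages, mx=mx),
                                 radix=radix)
            m = AgeMeasure(ages=ages, value=value, var=var, band=band)
            ses.append(sullivan_se(lt, m, 15))
        assert ses[0] == pytest.approx(ses[1], rel=1e-12)


class TestDfleEqualsLe:
    def test_prevalence_one_everywhere(self):
        rng = np.random.default_rng(13)
        lt = random_lifetable(rng)
        m = AgeMeasure.constant(lt.ages, 1.0)
        he = sullivan_he(lt, m, int(lt.ages[0]), kind="DFLE_mo")
        assert he.value == pytest.approx(lt.e_at(int(lt.ages[0])), rel=1e-12)


class TestCompare:
    def test_identical_expectancies(self):
        a = HealthExpectancy(15, 50.0, 0.1, "QALE")
        res = compare_he(a, a)
        assert (res.delta, res.z, res.p) == (0.0, 0.0, 1.0)

    def test_z_two_closed_form(self):
        a = HealthExpectancy(15, 51.0, 0.3, "QALE")
        b = HealthExpectancy(15, 50.0, 0.4, "QALE")
        res = compare_he(a, b)
        assert res.z == pytest.approx(2.0)
        assert res.p == pytest.approx(2 * stats.norm.sf(2.0), rel=1e-12)
        assert res.p == pytest.approx(0.0455, abs=5e-4)

    def test_sign_symmetry(self):
        a = HealthExpectancy(15, 51.0, 0.3, "QALE")
        b = HealthExpectancy(15, 50.0, 0.4, "QALE")
        fwd, rev = compare_he(a, b), compare_he(b, a)
        assert rev.z == -fwd.z
        assert rev.p == pytest.approx(fwd.p, rel=1e-12)

    def test_degenerate_comparison(self):
        a = HealthExpectancy(15, 51.0, 0.0, "QALE")
        b = HealthExpectancy(15, 50.0, 0.0, "QALE")
        with pytest.raises(DegenerateComparisonError):
            compare_he(a, b)

    def test_mismatched_kind_rejected(self):
        a = HealthExpectancy(15, 51.0, 0.1, "QALE")
        b = HealthExpectancy(15, 50.0, 0.1, "LE")
        with pytest.raises(ValueError):
            compare_he(a, b)


class TestRatio:
    def test_pi_one_ratio_one(self):
        lt = toy_three_age_table()
        frame = he_le_ratio(lt, AgeMeasure.constant(lt.ages, 1.0))
        assert frame.ratio.to_numpy() == pytest.approx(np.ones(3), rel=1e-12)

    def test_pi_half_ratio_half(self):
        lt = toy_three_age_table()
        frame = he_le_ratio(lt, AgeMeasure.constant(lt.ages, 0.5))
        assert frame.ratio.to_numpy() == pytest.approx(np.full(3, 0.5),
                                                       rel=1e-12)

    def test_declining_pi_matches_oracle(self):
        lt = toy_three_age_table()
        pi = np.array([0.9, 0.8, 0.5])
        frame = he_le_ratio(lt, AgeMeasure(ages=lt.ages, value=pi))
        for _, row in frame.iterrows():
            x = int(row.age)
            assert row.ratio == pytest.approx(
                brute_force_sullivan(lt, pi, x) / lt.e_at(x), rel=1e-12)


def test_life_expectancy_helper_matches_e():
    rng = np.random.default_rng(77)
    lt = random_lifetable(rng)
    he = life_expectancy(lt, int(lt.ages[0]))
    assert he.value == pytest.approx(lt.e_at(int(lt.ages[0])), rel=1e-12)
    assert he.se == 0.0 and he.kind == "LE"
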
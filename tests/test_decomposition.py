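import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qale.decomposition import (AlignmentError, decompose_qale,
                                decomposition_profile)
from qale.lifetable import MortalitySchedule, build_lifetable
from qale.sullivan import AgeMeasure, sullivan_value

from conftest import random_lifetable


def _random_period(rng, ages):
    mx = rng.uniform(0.01, 0.3, ages.size)
    lt = build_lifetable(MortalitySchedule(ages=ages, mx=mx))
    pi = AgeMeasure(ages=ages, value=rng.uniform(-0.3, 1.0, ages.size))
    return lt, pi


class TestTrivialCases:
    def test_identical_periods_all_zero(self):
        rng = np.random.default_rng(0)
        ages = np.arange(15, 40)
        lt, pi = _random_period(rng, ages)
        res = decompose_qale(lt, pi, lt, pi, 15)
        assert np.all(res.mor == 0.0)
        assert np.all(res.dis == 0.0)
        assert res.delta_qale == 0.0

    def test_pure_health_change_has_zero_mortality_effect(self):
        rng = np.random.default_rng(1)
        ages = np.arange(15, 40)
        lt, pi_t = _random_period(rng, ages)
        pi_tn = AgeMeasure(ages=ages, value=rng.uniform(0.0, 1.0, ages.size))
        res = decompose_qale(lt, pi_t, lt, pi_tn, 15)
        assert res.mor_total == 0.0
        dq = (sullivan_value(lt, pi_tn, 15) - sullivan_value(lt, pi_t, 15))
        assert res.dis_total == pytest.approx(dq, abs=1e-10)

    def test_pure_mortality_change_has_zero_disutility_effect(self):
        rng = np.random.default_rng(2)
        ages = np.arange(15, 40)
        lt_t, pi = _random_period(rng, ages)
        lt_tn = build_lifetable(MortalitySchedule(
            ages=ages, mx=rng.uniform(0.01, 0.3, ages.size)))
        res = decompose_qale(lt_t, pi, lt_tn, pi, 15)
        assert res.dis_total == 0.0


def test_two_age_hand_computed():
    """Two-age toy with simple fractions, checked against the formulas
    evaluated by hand on conditioned person-years."""
    ages = np.array([15, 16])
    # period 1: l = (100, 50), L = (75, 100); period 2: l = (100, 80), L = (90, 200)
    from qale.lifetable import LifeTable

    def table(l2, L0, L1):
        l = np.array([100.0, l2])
        L = np.array([L0, L1])
        T = np.cumsum(L[::-1])[::-1]
        return LifeTable(ages=ages, m=np.array([0.1, l2 / L1]),
                         a=np.array([0.5, np.nan]),
                         q=np.array([1 - l2 / 100, 1.0]), l=l,
                         d=np.array([100 - l2, l2]), L=L, T=T, e=T / l)

    lt_t = table(50.0, 75.0, 100.0)
    lt_tn = table(80.0, 90.0, 200.0)
    pi_t = AgeMeasure(ages=ages, value=np.array([0.8, 0.6]))
    pi_tn = AgeMeasure(ages=ages, value=np.array([0.9, 0.4]))
    res = decompose_qale(lt_t, pi_t, lt_tn, pi_tn, 15)
    # lambda_t = (0.75, 1.0), lambda_tn = (0.9, 2.0)
    mor_expected = [((0.8 + 0.9) / 2) * (0.9 - 0.75),
                    ((0.6 + 0.4) / 2) * (2.0 - 1.0)]
    dis_expected = [((0.75 + 0.9) / 2) * (0.9 - 0.8),
                    ((1.0 + 2.0) / 2) * (0.4 - 0.6)]
    assert res.mor == pytest.approx(mor_expected, rel=1e-12)
    assert res.dis == pytest.approx(dis_expected, rel=1e-12)
    dq = (sullivan_value(lt_tn, pi_tn, 15) - sullivan_value(lt_t, pi_t, 15))
    assert res.delta_qale == pytest.approx(dq, abs=1e-12)


class TestAlgebraicProperties:
    def test_additivity_and_antisymmetry_bulk(self):
        """1000 random period pairs: effects sum exactly to the QALE change,
        and swapping periods negates every effect."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(3, 15))
            ages = np.arange(15, 15 + n)
            lt_t, pi_t = _random_period(rng, ages)
            lt_tn, pi_tn = _random_period(rng, ages)
            a = int(rng.choice(ages))
            res = decompose_qale(lt_t, pi_t, lt_tn, pi_tn, a)
            dq = (sullivan_value(lt_tn, pi_tn, a)
                  - sullivan_value(lt_t, pi_t, a))
            assert abs(res.mor_total + res.dis_total - dq) < 1e-10
            rev = decompose_qale(lt_tn, pi_tn, lt_t, pi_t, a)
            assert rev.mor == pytest.approx(-res.mor, abs=1e-12)
            assert rev.dis == pytest.approx(-res.dis, abs=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**16), c=st.floats(-0.5, 0.5))
    def test_translation_shifts_only_mortality_effect(self, seed, c):
        """Adding a constant c to every pi in both periods leaves the
        disutility effect unchanged and shifts mor_x by c * delta lambda_x."""
        rng = np.random.default_rng(seed)
        ages = np.arange(15, 30)
        lt_t, pi_t = _random_period(rng, ages)
        lt_tn, pi_tn = _random_period(rng, ages)
        base = decompose_qale(lt_t, pi_t, lt_tn, pi_tn, 15)
        shift_t = AgeMeasure(ages=ages, value=pi_t.value + c)
        shift_tn = AgeMeasure(ages=ages, value=pi_tn.value + c)
        shifted = decompose_qale(lt_t, shift_t, lt_tn, shift_tn, 15)
        lam_t = lt_t.L / lt_t.l[0]
        lam_tn = lt_tn.L / lt_tn.l[0]
        assert shifted.dis == pytest.approx(base.dis, abs=1e-12)
        assert shifted.mor == pytest.approx(
            base.mor + c * (lam_tn - lam_t), abs=1e-12)

    def test_additivity_conditional_on_index_age_with_different_radices(self):
        """Normalising person-years by survivors at the index age makes the
        totals match the change in conditional QALE even when radices and
        survival to the index age differ."""
        rng = np.random.default_rng(9)
        ages = np.arange(15, 60)
        lt_t, pi_t = _random_period(rng, ages)
        mx = rng.uniform(0.01, 0.3, ages.size)
        lt_tn = build_lifetable(MortalitySchedule(ages=ages, mx=mx),
                                radix=1.0)
        pi_tn = AgeMeasure(ages=ages, value=rng.uniform(0, 1, ages.size))
        for a in (15, 30, 45):
            res = decompose_qale(lt_t, pi_t, lt_tn, pi_tn, a)
            dq = (sullivan_value(lt_tn, pi_tn, a)
                  - sullivan_value(lt_t, pi_t, a))
            assert res.delta_qale == pytest.approx(dq, abs=1e-10)


class TestProfileAndBinning:
    def test_profile_consistent_with_per_age_results(self):
        rng = np.random.default_rng(21)
        ages = np.arange(15, 40)
        lt_t, pi_t = _random_period(rng, ages)
        lt_tn, pi_tn = _random_period(rng, ages)
        prof = decomposition_profile(lt_t, pi_t, lt_tn, pi_tn, [15, 20, 30])
        for _, row in prof.iterrows():
            res = decompose_qale(lt_t, pi_t, lt_tn, pi_tn,
                                 int(row.index_age))
            assert row.mor_total == pytest.approx(res.mor_total, rel=1e-12)
            assert row.dis_total == pytest.approx(res.dis_total, rel=1e-12)

    def test_identical_periods_profile_all_zero(self):
        rng = np.random.default_rng(22)
        ages = np.arange(15, 30)
        lt, pi = _random_period(rng, ages)
        prof = decomposition_profile(lt, pi, lt, pi, ages)
        assert np.all(prof[["mor_total", "dis_total", "delta_qale"]] == 0)

    def test_binned_totals_preserved(self):
        rng = np.random.default_rng(23)
        ages = np.arange(15, 60)
        lt_t, pi_t = _random_period(rng, ages)
        lt_tn, pi_tn = _random_period(rng, ages)
        res = decompose_qale(lt_t, pi_t, lt_tn, pi_tn, 15)
        binned = res.binned([15, 30, 45])
        assert binned.mor.sum() == pytest.approx(res.mor_total, rel=1e-12)
        assert binned.dis.sum() == pytest.approx(res.dis_total, rel=1e-12)
        assert list(binned.group_lo) == [15, 30, 45]


def test_mismatched_age_ranges_rejected():
    rng = np.random.default_rng(3)
    ages_a = np.arange(15, 40)
    ages_b = np.arange(15, 41)
    lt_a, pi_a = _random_period(rng, ages_a)
    lt_b, pi_b = _random_period(rng, ages_b)
    with pytest.raises(AlignmentError):
        decompose_qale(lt_a, pi_a, lt_b, pi_b, 15)
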
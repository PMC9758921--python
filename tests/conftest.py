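import numpy as np
import pandas as pd
import pytest

from qale.lifetable import MortalitySchedule, build_lifetable
from qale.valueset import belgian_synthetic_value_set, toy_value_set


@pytest.fixture(scope="session")
def toy_vs():
    return toy_value_set()


@pytest.fixture(scope="session")
def be_vs():
    return belgian_synthetic_value_set()


def random_lifetable(rng, start_age=15, open_age=None, radix=100_000.0):
    """A small random but valid life table for property tests."""
    if open_age is None:
        open_age = start_age + int(rng.integers(3, 20))
    ages = np.arange(start_age, open_age + 1)
    mx = rng.uniform(0.01, 0.4, size=ages.size)
    ms = MortalitySchedule(ages=ages, mx=mx)
    return build_lifetable(ms, radix=radix)


def brute_force_sullivan(lt, pi, x):
    """Independent oracle: plain Python loop over ages.

    pi is a dict or array aligned with lt.ages; returns
    sum_{y >= x} pi_y * L_y / l_x accumulated one age at a time.
    """
    total = 0.0
    for i, age in enumerate(lt.ages):
        if age >= x:
            total += float(pi[i]) * float(lt.L[i])
    return total / float(lt.l[lt.index_of(x)])


def survey_frame(rows):
    """Build a survey DataFrame from (age, gender, region, weight, levels)."""
    records = []
    for age, gender, region, weight, levels in rows:
        rec = dict(year=2018, age=age, gender=gender, region=region,
                   weight=weight)
        for code, level in zip(("mo", "sc", "ua", "pd", "ad"),
                               levels or [np.nan] * 5):
            rec[code] = level
        records.append(rec)
    return pd.DataFrame(records)
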
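"""Non-abridged period life tables with an open last age group.

Tables are built from central death rates m_x at single years of age, from an
analysis start age (15 by default in this pipeline) up to an open interval at
age 100.  Closed intervals convert rates to probabilities with the standard
actuarial relation q_x = m_x / (1 + (1 - a_x) m_x), where a_x is the average
fraction of the year lived by those who die in it (0.5 for adult single-year
ages).  The open group is closed with the constant-hazard rule: q = 1 and
L = l / m.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_RADIX = 100_000
OPEN_AGE = 100

LIFETABLE_COLUMNS = ["age", "m", "a", "q", "l", "d", "L", "T", "e"]


class ScheduleError(ValueError):
    """Malformed mortality schedule (gaps, duplicates, bad rates)."""


@dataclass(frozen=True)
class MortalitySchedule:
    """Age-specific central death rates for one stratum.

    ``ages`` are consecutive single years ending at the open age (100); the
    rate at the open age is the open-interval rate.
    """

    ages: np.ndarray
    mx: np.ndarray
    year: int | None = None
    gender: str | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        mx = np.asarray(self.mx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "mx", mx)
        if ages.ndim != 1 or ages.size < 2 or mx.shape != ages.shape:
            raise ScheduleError("ages and mx must be matching 1-d arrays")
        if not np.all(np.diff(ages) == 1):
            gaps = ages[:-1][np.diff(ages) != 1] + 1
            raise ScheduleError(f"ages must be consecutive; gap at {gaps[0]}")
        if np.any(mx <= 0):
            bad = ages[mx <= 0][0]
            raise ScheduleError(f"non-positive death rate at age {bad}")

    @property
    def start_age(self) -> int:
        return int(self.ages[0])

    @property
    def open_age(self) -> int:
        return int(self.ages[-1])


@dataclass(frozen=True)
class LifeTable:
    """Single-year period life table (columns m, a, q, l, d, L, T, e).

    ``l`` are survivors to exact age x out of ``radix``; ``L`` person-years
    lived in [x, x+1); ``T`` person-years remaining; ``e = T / l`` remaining
    life expectancy.  The last age is an open interval with q = 1.
    """

    ages: np.ndarray
    m: np.ndarray
    a: np.ndarray
    q: np.ndarray
    l: np.ndarray
    d: np.ndarray
    L: np.ndarray
    T: np.ndarray
    e: np.ndarray
    radix: float = DEFAULT_RADIX
    year: int | None = None
    gender: str | None = None
    region: str | None = None

    @property
    def start_age(self) -> int:
        return int(self.ages[0])

    def index_of(self, age: int) -> int:
        if not self.ages[0] <= age <= self.ages[-1]:
            raise IndexError(
                f"age {age} outside table range "
                f"[{self.ages[0]}, {self.ages[-1]}]")
        return int(age - self.ages[0])

    def e_at(self, age: int) -> float:
        return float(self.e[self.index_of(age)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age": self.ages, "m": self.m, "a": self.a, "q": self.q,
            "l": self.l, "d": self.d, "L": self.L, "T": self.T, "e": self.e,
        })


def build_lifetable(ms: MortalitySchedule, radix: float = DEFAULT_RADIX,
                    a_default: float = 0.5) -> LifeTable:
    """Build a period life table from a mortality schedule.

    Parameters
    ----------
    ms:
        Central death rates for consecutive single years of age; the last
        entry is the open-interval rate.
    radix:
        Starting cohort size l at the first age (conventionally 100000).
        All health-expectancy quantities downstream are radix-free.
    a_default:
        Average fraction of the interval lived by those dying in it, applied
        to every closed interval.  0.5 is the standard choice for adult
        single-year ages.

    Notes
    -----
    A closed-interval q that computes above 1 (possible for extreme rates)
    is clamped to 1 with a warning; survivorship is then exhausted early and
    later l, L are zero.
    """
    if not 0 < a_default < 1:
        raise ValueError("a_default must be in (0, 1)")
    n = ms.ages.size
    m = ms.mx.astype(float)
    a = np.full(n, a_default)
    q = np.empty(n)
    q[:-1] = m[:-1] / (1.0 + (1.0 - a[:-1]) * m[:-1])
    if np.any(q[:-1] > 1):
        ages_bad = ms.ages[:-1][q[:-1] > 1]
        log.warning("q > 1 clamped at ages %s", ages_bad.tolist())
        warnings.warn(f"q > 1 clamped at ages {ages_bad.tolist()}",
                      RuntimeWarning, stacklevel=2)
        q[:-1] = np.minimum(q[:-1], 1.0)
    q[-1] = 1.0
    a[-1] = np.nan  # undefined for the open interval

    l = np.empty(n)
    l[0] = radix
    for i in range(n - 1):
        l[i + 1] = l[i] * (1.0 - q[i])
    d = np.empty(n)
    d[:-1] = l[:-1] - l[1:]
    d[-1] = l[-1]

    L = np.empty(n)
    L[:-1] = l[1:] + a[:-1] * d[:-1]
    L[-1] = l[-1] / m[-1]  # constant-hazard closure of the open group

    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, 0.0)

    return LifeTable(ages=ms.ages.copy(), m=m, a=a, q=q, l=l, d=d, L=L,
                     T=T, e=e, radix=radix, year=ms.year, gender=ms.gender,
                     region=ms.region)


MORTALITY_COLUMNS = ["year", "gender", "region", "age", "mx"]


def read_mortality_csv(path: str | Path) -> dict[tuple, MortalitySchedule]:
    """Read age-specific mortality rates, one schedule per stratum.

    The file must have columns year, gender, region, age, mx; within each
    (year, gender, region) group, ages must be consecutive single years with
    strictly positive rates.  Returns a dict keyed by (year, gender, region).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MORTALITY_COLUMNS if c not in df.columns]
    if missing:
        raise ScheduleError(f"{path}: missing columns {missing}")
    out: dict[tuple, MortalitySchedule] = {}
    for key, grp in df.groupby(["year", "gender", "region"], sort=True):
        grp = grp.sort_values("age")
        ages = grp["age"].to_numpy(dtype=int)
        if len(np.unique(ages)) != len(ages):
            dup = ages[pd.Series(ages).duplicated().to_numpy()][0]
            raise ScheduleError(f"{path}: duplicate age {dup} in {key}")
        try:
            out[key] = MortalitySchedule(
                ages=ages, mx=grp["mx"].to_numpy(dtype=float),
                year=int(key[0]), gender=str(key[1]), region=str(key[2]))
        except ScheduleError as err:
            raise ScheduleError(f"{path}: stratum {key}: {err}") from err
    return out


def write_mortality_csv(schedules: dict[tuple, MortalitySchedule],
                        path: str | Path) -> None:
    frames = []
    for (year, gender, region), ms in sorted(schedules.items(),
                                             key=lambda kv: tuple(map(str, kv[0]))):
        frames.append(pd.DataFrame({
            "year": year, "gender": gender, "region": region,
            "age": ms.ages, "mx": ms.mx}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_lifetable_csv(lt: LifeTable, path: str | Path) -> None:
    """Write the eight standard columns at full precision."""
    lt.to_frame().to_csv(path, index=False)
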
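"""Sullivan health expectancies with standard errors.

The Sullivan method weights life-table person-years L_x by an age-specific
health measure pi_x and sums from an index age:

    HE(x) = (1 / l_x) * sum_{y >= x} pi_y * L_y

With pi a utility-valued population norm the result is quality-adjusted life
expectancy (QALE); with pi a no-problem prevalence it is a dimension-specific
disability-free life expectancy (DFLE).  Standard errors follow the classic
health-expectancy variance formula: mortality is treated as fixed (register
based), and only the sampling variance of the health measure propagates,

    se(x)^2 = (1 / l_x^2) * sum_b (sum_{y in band b, y >= x} L_y)^2 * v_b

where v_b is the variance of the band-level estimate.  The band grouping
matters: ages sharing an age band share a single survey estimate, so their
person-years are summed before squaring (treating them as independent would
understate the variance).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .lifetable import LifeTable
from .norms import AgeBands


class CoverageError(ValueError):
    """The health measure does not cover every requested age."""


class MissingVarianceError(ValueError):
    """Variance/effective-N unavailable where a standard error was asked."""


class DegenerateComparisonError(ValueError):
    """Z-test undefined: both standard errors are zero but the values differ."""


@dataclass(frozen=True)
class AgeMeasure:
    """A per-single-age health measure (utility or prevalence).

    ``value[i]`` applies to ``ages[i]``; ``var`` is the sampling variance of
    the stratum-level estimate (already on the scale of a mean, i.e. s^2/N or
    p(1-p)/N); ``band`` tags ages sharing one survey estimate so that the
    variance formula can group them.  ``band = -1`` marks an age estimated on
    its own.
    """

    ages: np.ndarray
    value: np.ndarray
    var: np.ndarray | None = None
    band: np.ndarray | None = None

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        value = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "value", value)
        if value.shape != ages.shape:
            raise ValueError("ages and value must align")
        if self.var is not None:
            var = np.asarray(self.var, dtype=float)
            if var.shape != ages.shape:
                raise ValueError("var must align with ages")
            object.__setattr__(self, "var", var)
        if self.band is not None:
            band = np.asarray(self.band, dtype=int)
            if band.shape != ages.shape:
                raise ValueError("band must align with ages")
            object.__setattr__(self, "band", band)

    @classmethod
    def constant(cls, ages: np.ndarray, value: float,
                 var: float = 0.0) -> "AgeMeasure":
        ages = np.asarray(ages, dtype=int)
        return cls(ages=ages, value=np.full(ages.size, float(value)),
                   var=np.full(ages.size, float(var)),
                   band=np.zeros(ages.size, dtype=int))

    def slice_from(self, age: int) -> "AgeMeasure":
        keep = self.ages >= age
        return AgeMeasure(
            ages=self.ages[keep], value=self.value[keep],
            var=None if self.var is None else self.var[keep],
            band=None if self.band is None else self.band[keep])


def expand_norms(norms: pd.DataFrame, ages: np.ndarray,
                 value_col: str = "pi",
                 var_col: str | None = "var_pi") -> AgeMeasure:
    """Step-function expansion of band-level norms to single years of age.

    Each age receives the estimate of the band containing it; the top band
    extends through the last requested age.  ``norms`` holds one stratum:
    one row per band with columns ``band_lo``, ``band_hi``, the value column
    and (optionally) its variance column.
    """
    ages = np.asarray(ages, dtype=int)
    bands = AgeBands(tuple((int(lo), int(hi)) for lo, hi in
                           zip(norms["band_lo"], norms["band_hi"])))
    sorted_norms = norms.sort_values("band_lo").reset_index(drop=True)
    if ages.min() < bands.start or ages.max() > bands.stop:
        uncovered = ages[(ages < bands.start) | (ages > bands.stop)]
        raise CoverageError(
            f"ages {uncovered.tolist()} not covered by bands {bands.bands}")
    idx = bands.assign(ages)
    value = sorted_norms[value_col].to_numpy(dtype=float)[idx]
    var = None
    if var_col is not None and var_col in sorted_norms:
        var = sorted_norms[var_col].to_numpy(dtype=float)[idx]
    return AgeMeasure(ages=ages, value=value, var=var, band=idx)


@dataclass(frozen=True)
class HealthExpectancy:
    """A Sullivan health expectancy at an index age, in years."""

    index_age: int
    value: float
    se: float
    kind: str  # "LE", "QALE", or "DFLE_<dim>"
    year: int | None = None
    gender: str | None = None
    region: str | None = None


@dataclass(frozen=True)
class ComparisonResult:
    """Z-score comparison of two health expectancies."""

    delta: float
    z: float
    p: float


def _aligned(lt: LifeTable, measure: AgeMeasure, x: int):
    i = lt.index_of(x)
    ages = lt.ages[i:]
    m = measure.slice_from(x)
    if m.ages.size != ages.size or np.any(m.ages != ages):
        missing = sorted(set(ages.tolist()) - set(m.ages.tolist()))
        raise CoverageError(
            f"health measure does not cover ages {missing} of the life table")
    return i, m


def sullivan_value(lt: LifeTable, measure: AgeMeasure, x: int) -> float:
    """Health expectancy value: (1/l_x) * sum_{y>=x} pi_y L_y."""
    i, m = _aligned(lt, measure, x)
    return float(np.dot(m.value, lt.L[i:]) / lt.l[i])


def sullivan_se(lt: LifeTable, measure: AgeMeasure, x: int) -> float:
    """Standard error of the Sullivan estimate, mortality held fixed.

    Person-years of ages that share an age-band estimate are summed before
    squaring; ages tagged ``band = -1`` contribute individually.
    """
    i, m = _aligned(lt, measure, x)
    if m.var is None:
        raise MissingVarianceError("measure carries no variance information")
    if np.any(~np.isfinite(m.var)):
        raise MissingVarianceError("non-finite variance in measure")
    L = lt.L[i:]
    band = m.band if m.band is not None else -np.ones(m.ages.size, dtype=int)
    var_sum = 0.0
    solo = band < 0
    var_sum += float(np.dot(L[solo] ** 2, m.var[solo]))
    for b in np.unique(band[~solo]):
        in_b = band == b
        v = m.var[in_b]
        if not np.allclose(v, v[0]):
            raise ValueError(f"band {b} carries inconsistent variances")
        var_sum += float(L[in_b].sum() ** 2 * v[0])
    return float(np.sqrt(var_sum) / lt.l[i])


def sullivan_he(lt: LifeTable, measure: AgeMeasure, x: int,
                kind: str = "QALE") -> HealthExpectancy:
    """Value and standard error bundled into a :class:`HealthExpectancy`.

    If the measure carries no variance, the standard error is reported as 0
    (appropriate for e.g. plain LE, where pi is identically 1 and fixed).
    """
    value = sullivan_value(lt, measure, x)
    se = sullivan_se(lt, measure, x) if measure.var is not None else 0.0
    return HealthExpectancy(index_age=x, value=value, se=se, kind=kind,
                            year=lt.year, gender=lt.gender, region=lt.region)


def life_expectancy(lt: LifeTable, x: int) -> HealthExpectancy:
    """Plain LE as a degenerate Sullivan estimate (pi identically 1)."""
    ones = AgeMeasure.constant(lt.ages, 1.0)
    he = sullivan_he(lt, ones, x, kind="LE")
    return replace(he, se=0.0)


def compare_he(a: HealthExpectancy, b: HealthExpectancy) -> ComparisonResult:
    """Two-sided Z-test for the difference a - b.

    The two estimates are treated as independent, which is conservative for
    the usual contrasts (different survey years or genders).
    """
    if a.index_age != b.index_age or a.kind != b.kind:
        raise ValueError("compared expectancies must share index age and kind")
    delta = a.value - b.value
    pooled = float(np.hypot(a.se, b.se))
    if pooled == 0.0:
        if delta != 0.0:
            raise DegenerateComparisonError(
                "both standard errors are zero but the values differ")
        return ComparisonResult(delta=0.0, z=0.0, p=1.0)
    z = delta / pooled
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ComparisonResult(delta=delta, z=float(z), p=p)


def he_le_ratio(lt: LifeTable, measure: AgeMeasure,
                ages: np.ndarray | None = None) -> pd.DataFrame:
    """Ratio of health expectancy to life expectancy at each index age.

    Returns a DataFrame with columns ``age``, ``he``, ``le``, ``ratio``.
    """
    if ages is None:
        ages = lt.ages
    rows = []
    for x in np.asarray(ages, dtype=int):
        e_x = lt.e_at(int(x))
        if e_x == 0:
            raise ZeroDivisionError(f"life expectancy is zero at age {x}")
        he = sullivan_value(lt, measure, int(x))
        rows.append((int(x), he, e_x, he / e_x))
    return pd.DataFrame(rows, columns=["age", "he", "le", "ratio"])
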
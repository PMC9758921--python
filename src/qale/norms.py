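"""Survey-weighted population norms for EQ-5D-5L.

Population norms are the average index value (and per-dimension no-problem
prevalences) per stratum, where a stratum is an age band crossed with any
grouping keys (typically survey year, gender and region).  Estimation is
design-naive but weight-aware: weighted means with a Kish effective sample
size (sum w)^2 / sum w^2 standing in for design-based variance, the standard
conservative choice when only per-respondent weights are available.

Respondents with a missing health state are dropped per stratum before
weighting (complete-case analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .states import DIMENSION_CODES, DIMENSIONS
from .valueset import ValueSet

DEFAULT_BY = ("year", "gender", "region")

SURVEY_COLUMNS = ["year", "age", "gender", "region", "weight",
                  *DIMENSION_CODES]


class MissingStratumError(ValueError):
    """A stratum to be reported has no usable (complete-case) record."""


@dataclass(frozen=True)
class AgeBands:
    """Closed integer age intervals partitioning [start, stop].

    Bands are inclusive on both ends; e.g. (15, 24) covers ages 15..24.
    """

    bands: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        bands = tuple(sorted(self.bands))
        object.__setattr__(self, "bands", bands)
        for (lo, hi) in bands:
            if lo > hi:
                raise ValueError(f"band ({lo}, {hi}) is empty")
        for (_, hi_prev), (lo, _) in zip(bands, bands[1:]):
            if lo != hi_prev + 1:
                raise ValueError(
                    f"bands must tile contiguously; gap/overlap at {lo}")

    @classmethod
    def default(cls, start: int = 15, stop: int = 100,
                width: int = 10) -> "AgeBands":
        """Decennial bands from start; the last band absorbs the remainder.

        With the defaults: 15-24, 25-34, ..., 75-84, 85-100.
        """
        edges = list(range(start, stop - width + 1, width))
        bands = [(lo, lo + width - 1) for lo in edges[:-1]]
        bands.append((edges[-1], stop))
        return cls(tuple(bands))

    @property
    def start(self) -> int:
        return self.bands[0][0]

    @property
    def stop(self) -> int:
        return self.bands[-1][1]

    def index_of(self, age: int) -> int:
        for i, (lo, hi) in enumerate(self.bands):
            if lo <= age <= hi:
                return i
        raise KeyError(f"age {age} not covered by bands {self.bands}")

    def assign(self, ages: np.ndarray) -> np.ndarray:
        """Band index per age; -1 for uncovered ages."""
        los = np.array([lo for lo, _ in self.bands])
        his = np.array([hi for _, hi in self.bands])
        idx = np.searchsorted(los, ages, side="right") - 1
        idx = np.clip(idx, 0, len(self.bands) - 1)
        ok = (ages >= los[idx]) & (ages <= his[idx])
        return np.where(ok, idx, -1)

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)


def _state_codes(frame: pd.DataFrame) -> np.ndarray:
    """Lexicographic state index (base-5) per row; -1 where any level missing."""
    levels = frame[list(DIMENSION_CODES)].to_numpy(dtype=float)
    missing = np.isnan(levels).any(axis=1)
    lv = np.where(np.isnan(levels), 1, levels).astype(int)
    if ((lv < 1) | (lv > 5)).any():
        bad = np.argwhere((lv < 1) | (lv > 5))[0]
        raise ValueError(f"level outside 1..5 at row {bad[0]}")
    code = np.zeros(len(frame), dtype=int)
    for col in range(5):
        code = code * 5 + (lv[:, col] - 1)
    return np.where(missing, -1, code)


def _utility_lookup(vs: ValueSet) -> np.ndarray:
    """Utilities as a length-3125 array in lexicographic state order."""
    return vs.to_frame()["utility"].to_numpy()


def kish_n_eff(weights: np.ndarray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / (w ** 2).sum())


def estimate_norms(records: pd.DataFrame, vs: ValueSet,
                   age_bands: AgeBands | None = None,
                   by: Sequence[str] = DEFAULT_BY) -> pd.DataFrame:
    """Stratified population norms from survey microdata.

    Parameters
    ----------
    records:
        One row per respondent with columns ``age``, ``weight``, the five
        level columns ``mo, sc, ua, pd, ad`` (NaN = missing) and the
        grouping keys in ``by``.
    vs:
        Value set used to score each response.
    age_bands:
        Partition of the analysis age range; defaults to decennial bands
        15-24 ... 85-100.
    by:
        Stratification keys beyond the age band.

    Returns
    -------
    DataFrame with one row per (stratum x band): columns ``band_lo``,
    ``band_hi``, ``pi`` (weighted mean utility), ``var_pi`` (sampling
    variance of the mean, s^2 / n_eff), ``n_eff``, ``n_obs``, and per
    dimension code ``prev_<code>`` / ``var_prev_<code>`` (weighted
    no-problem prevalence with binomial variance p(1-p)/n_eff).

    Raises
    ------
    MissingStratumError
        If any (stratum, band) cell contains no complete-case record.
    """
    age_bands = age_bands or AgeBands.default()
    df = records.copy()
    if (df["weight"] <= 0).any():
        raise ValueError("survey weights must be strictly positive")
    if (df["age"] < age_bands.start).any() or (df["age"] > age_bands.stop).any():
        raise ValueError(
            f"ages outside [{age_bands.start}, {age_bands.stop}] in records")

    codes = _state_codes(df)
    util = _utility_lookup(vs)
    df = df.assign(_code=codes, _band=age_bands.assign(
        df["age"].to_numpy(dtype=int)))
    complete = df[df["_code"] >= 0].copy()
    complete["_u"] = util[complete["_code"].to_numpy()]

    strata = df[list(by)].drop_duplicates().itertuples(index=False, name=None)
    expected = {s + (b,) for s in strata for b in range(len(age_bands))}

    rows = []
    seen = set()
    group_keys = list(by) + ["_band"]
    for key, grp in complete.groupby(group_keys, sort=True):
        seen.add(tuple(key))
        w = grp["weight"].to_numpy(dtype=float)
        u = grp["_u"].to_numpy(dtype=float)
        wsum = w.sum()
        pi = float((w * u).sum() / wsum)
        s2 = float((w * (u - pi) ** 2).sum() / wsum)
        n_eff = kish_n_eff(w)
        band = age_bands.bands[key[-1]]
        row = dict(zip(by, key[:-1]))
        row.update(band_lo=band[0], band_hi=band[1], pi=pi,
                   var_pi=s2 / n_eff, n_eff=n_eff, n_obs=len(grp))
        lv = grp[list(DIMENSION_CODES)].to_numpy(dtype=float)
        for code_col, lv_col in zip(DIMENSION_CODES, lv.T):
            p = float((w * (lv_col == 1)).sum() / wsum)
            row[f"prev_{code_col}"] = p
            row[f"var_prev_{code_col}"] = p * (1 - p) / n_eff
        rows.append(row)

    empty = expected - seen
    if empty:
        labels = sorted(
            str(dict(zip(list(by) + ["band"],
                         key[:-1] + (age_bands.bands[key[-1]],))))
            for key in empty)
        raise MissingStratumError(
            "no complete-case records in strata: " + "; ".join(labels))

    out = pd.DataFrame(rows)
    return out.sort_values(list(by) + ["band_lo"]).reset_index(drop=True)


def read_survey_csv(path: str | Path) -> pd.DataFrame:
    """Read survey microdata (CSV; empty level cells = missing response)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_survey_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)
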
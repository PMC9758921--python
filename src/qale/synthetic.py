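"""Synthetic mortality schedules and EQ-5D-5L survey microdata.

The generator provides inputs with known ground truth for every pipeline
stage:

* mortality follows a Gompertz-Makeham hazard m_x = c + a * exp(b * x), the
  standard two-process description of adult mortality (a constant background
  rate plus exponentially age-increasing senescent mortality);
* EQ-5D-5L responses follow an ordered-probit model with a Gaussian copula
  across dimensions: each respondent draws one shared latent factor and five
  dimension-specific latents (cross-dimension correlation rho through the
  shared factor); the severity level on a dimension is determined by where
  the shifted latent falls among four increasing cutpoints.  The shift is
  linear in age and includes gender and period offsets, so severity worsens
  with age and can differ by gender and survey year.

Because the model is an explicit Gaussian copula, exact population norms are
computable (Gauss-Hermite integration over the shared factor), giving the
ground truth that the survey estimators should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import roots_hermitenorm

from .lifetable import MortalitySchedule
from .norms import SURVEY_COLUMNS, AgeBands
from .states import DIMENSION_CODES, DIMENSIONS
from .valueset import ValueSet

START_AGE = 15
OPEN_AGE = 100


class ModelError(ValueError):
    """Invalid generator parameters."""


# ---------------------------------------------------------------------------
# Mortality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MortalityModel:
    """Gompertz-Makeham hazard m_x = c + a * exp(b * x).

    ``c`` is the age-independent (Makeham) component per person-year;
    ``a`` and ``b`` the Gompertz level and slope.  ``modifier`` scales the
    Gompertz level multiplicatively (used for gender/region variants).
    """

    a: float
    b: float
    c: float = 0.0
    modifier: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b < 0 or self.c < 0 or self.modifier <= 0:
            raise ModelError("require a > 0, b >= 0, c >= 0, modifier > 0")

    def rate(self, age: np.ndarray) -> np.ndarray:
        return self.c + self.modifier * self.a * np.exp(
            self.b * np.asarray(age, dtype=float))


def generate_mortality(model: MortalityModel,
                       start_age: int = START_AGE,
                       open_age: int = OPEN_AGE,
                       year: int | None = None,
                       gender: str | None = None,
                       region: str | None = None) -> MortalitySchedule:
    """Deterministic age-specific rates from the hazard model.

    The last age carries the open-interval rate (the hazard evaluated at the
    open age, consistent with the constant-hazard closure of the life table).
    """
    ages = np.arange(start_age, open_age + 1)
    mx = model.rate(ages)
    if np.any(mx <= 0):
        raise ModelError("hazard model produced non-positive rates")
    return MortalitySchedule(ages=ages, mx=mx, year=year, gender=gender,
                             region=region)


# ---------------------------------------------------------------------------
# EQ-5D-5L responses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseModel:
    """Ordered-probit EQ-5D-5L response model with a shared latent factor.

    ``cutpoints[dim]`` are four strictly increasing thresholds on the latent
    scale; the level is 1 plus the number of cutpoints below the shifted
    latent, so a larger shift means worse health.  The shift is
    ``beta_age * (age - 15) + gender_offsets[gender] + year_offsets[year]``.
    ``rho`` in [0, 1) is the cross-dimension correlation induced by the
    shared factor (Gaussian copula).
    """

    cutpoints: Mapping[str, tuple[float, float, float, float]]
    beta_age: float = 0.0
    gender_offsets: Mapping[str, float] = field(default_factory=dict)
    year_offsets: Mapping[int, float] = field(default_factory=dict)
    rho: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ModelError("rho must lie in [0, 1)")
        for dim in DIMENSIONS:
            kappa = self.cutpoints.get(dim)
            if kappa is None or len(kappa) != 4:
                raise ModelError(f"need 4 cutpoints for {dim}")
            if not all(k1 < k2 for k1, k2 in zip(kappa, kappa[1:])):
                raise ModelError(f"cutpoints for {dim} must strictly increase")

    def shift(self, age: np.ndarray, gender: str, year: int) -> np.ndarray:
        return (self.beta_age * (np.asarray(age, dtype=float) - START_AGE)
                + self.gender_offsets.get(gender, 0.0)
                + self.year_offsets.get(year, 0.0))

    def level_probs(self, age: float, gender: str, year: int) -> np.ndarray:
        """Marginal level probabilities, shape (5 dims, 5 levels).

        P(level <= k) = Phi(kappa_k - shift): closed-form ordered-probit
        marginals (the shared factor does not affect marginals).
        """
        mu = float(self.shift(np.array([age]), gender, year)[0])
        probs = np.empty((5, 5))
        for d, dim in enumerate(DIMENSIONS):
            kappa = np.asarray(self.cutpoints[dim], dtype=float)
            cdf = np.concatenate([stats.norm.cdf(kappa - mu), [1.0]])
            probs[d] = np.diff(np.concatenate([[0.0], cdf]))
        return probs


def generate_survey(model: ResponseModel, n_per_stratum: int,
                    strata: Sequence[tuple[int, str, str]], seed: int,
                    age_range: tuple[int, int] = (START_AGE, OPEN_AGE),
                    weight_sigma: float = 0.5) -> pd.DataFrame:
    """Draw survey microdata, ``n_per_stratum`` respondents per stratum.

    ``strata`` is a sequence of (year, gender, region) labels.  Ages are
    uniform over ``age_range`` (inclusive); survey weights are log-normal
    with log-scale sd ``weight_sigma``, rescaled to mean 1 within each
    stratum.  Fully reproducible from ``seed``: each stratum consumes an
    independent child stream in the listed order.
    """
    if n_per_stratum < 1:
        raise ValueError("n_per_stratum must be >= 1")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(strata))
    frames = []
    sqrt_rho = np.sqrt(model.rho)
    sqrt_com = np.sqrt(1.0 - model.rho)
    for (year, gender, region), child in zip(strata, children):
        rng = np.random.default_rng(child)
        ages = rng.integers(age_range[0], age_range[1] + 1, n_per_stratum)
        shared = rng.standard_normal(n_per_stratum)
        eps = rng.standard_normal((n_per_stratum, 5))
        latent = sqrt_rho * shared[:, None] + sqrt_com * eps
        mu = model.shift(ages, gender, year)
        shifted = latent + mu[:, None]
        levels = np.empty((n_per_stratum, 5), dtype=int)
        for d, dim in enumerate(DIMENSIONS):
            kappa = np.asarray(model.cutpoints[dim], dtype=float)
            levels[:, d] = 1 + np.searchsorted(kappa, shifted[:, d],
                                               side="left")
        w = rng.lognormal(mean=0.0, sigma=weight_sigma, size=n_per_stratum)
        w = w / w.mean()
        frame = pd.DataFrame({
            "year": year, "age": ages, "gender": gender, "region": region,
            "weight": w})
        for code, d in zip(DIMENSION_CODES, range(5)):
            frame[code] = levels[:, d]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)[SURVEY_COLUMNS]


# ---------------------------------------------------------------------------
# Exact population norms (ground truth)
# ---------------------------------------------------------------------------

_GH_NODES = 48


def _state_mean_utility(model: ResponseModel, vs_util: np.ndarray,
                        age: float, gender: str, year: int) -> float:
    """Exact E[utility] at one age, integrating the shared factor.

    Conditional on the shared factor u, dimensions are independent with
    latent N(sqrt(rho) u, 1 - rho); the conditional state probability is the
    product of conditional level probabilities, and the expectation over u is
    evaluated with Gauss-Hermite quadrature (exact to quadrature precision).
    """
    mu = float(model.shift(np.array([age]), gender, year)[0])
    util5 = vs_util.reshape((5, 5, 5, 5, 5))
    if model.rho == 0.0:
        probs = model.level_probs(age, gender, year)
        return float(np.einsum("a,b,c,d,e,abcde->", *probs, util5))
    nodes, weights = roots_hermitenorm(_GH_NODES)
    omega = weights / np.sqrt(2.0 * np.pi)
    scale = np.sqrt(1.0 - model.rho)
    loc = np.sqrt(model.rho) * nodes
    total = 0.0
    for u_loc, om in zip(loc, omega):
        probs = np.empty((5, 5))
        for d, dim in enumerate(DIMENSIONS):
            kappa = np.asarray(model.cutpoints[dim], dtype=float)
            cdf = np.concatenate(
                [stats.norm.cdf((kappa - mu - u_loc) / scale), [1.0]])
            probs[d] = np.diff(np.concatenate([[0.0], cdf]))
        total += om * float(np.einsum("a,b,c,d,e,abcde->", *probs, util5))
    return total


def true_norms(model: ResponseModel, vs: ValueSet,
               age_bands: AgeBands | None = None,
               strata: Sequence[tuple[int, str, str]] = ()) -> pd.DataFrame:
    """Exact population norms implied by the response model.

    Returns the same layout as :func:`qale.norms.estimate_norms`, with
    ``var_pi`` and the prevalence variances set to 0 (these are population
    values, not estimates) and ``n_eff``/``n_obs`` set to 0.  Band values
    average the exact per-age values uniformly over the integer ages in the
    band, matching the generator's uniform age draw.
    """
    age_bands = age_bands or AgeBands.default()
    vs_util = vs.to_frame()["utility"].to_numpy()
    rows = []
    for (year, gender, region) in strata:
        for (lo, hi) in age_bands:
            ages = np.arange(lo, hi + 1)
            pis = [_state_mean_utility(model, vs_util, a, gender, year)
                   for a in ages]
            row = dict(year=year, gender=gender, region=region,
                       band_lo=lo, band_hi=hi, pi=float(np.mean(pis)),
                       var_pi=0.0, n_eff=0.0, n_obs=0)
            mus = model.shift(ages, gender, year)
            for code, dim in zip(DIMENSION_CODES, DIMENSIONS):
                kappa1 = model.cutpoints[dim][0]
                prev = float(np.mean(stats.norm.cdf(kappa1 - mus)))
                row[f"prev_{code}"] = prev
                row[f"var_prev_{code}"] = 0.0
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """A named bundle of generator settings for a two-period analysis."""

    name: str
    years: tuple[int, int]
    genders: tuple[str, ...]
    regions: tuple[str, ...]
    mortality: Mapping[tuple[int, str], MortalityModel]
    response: ResponseModel
    region_modifiers: Mapping[str, float] = field(default_factory=dict)

    def strata(self) -> list[tuple[int, str, str]]:
        return [(y, g, r) for y in self.years for g in self.genders
                for r in self.regions]

    def mortality_schedules(self) -> dict[tuple, MortalitySchedule]:
        out = {}
        for (year, gender), mm in self.mortality.items():
            for region in self.regions:
                mod = self.region_modifiers.get(region, 1.0)
                model = MortalityModel(a=mm.a, b=mm.b, c=mm.c,
                                       modifier=mm.modifier * mod)
                out[(year, gender, region)] = generate_mortality(
                    model, year=year, gender=gender, region=region)
        return out


# Gompertz-Makeham parameters per (year, gender), calibrated so that the
# synthetic life tables reproduce Belgian-like remaining life expectancies at
# age 15 (about 63.5/64.6 years for men and 68.6/69.1 for women in the two
# periods).  b and c are held common; the level a carries the differences.
_BELGIUM_LIKE_MORTALITY = {
    (2013, "men"): MortalityModel(a=2.081181e-05, b=0.1, c=5e-04),
    (2018, "men"): MortalityModel(a=1.857071e-05, b=0.1, c=5e-04),
    (2013, "women"): MortalityModel(a=1.231413e-05, b=0.1, c=5e-04),
    (2018, "women"): MortalityModel(a=1.170617e-05, b=0.1, c=5e-04),
}

# Ordered-probit settings chosen so that mean utility at young ages sits near
# 0.92 (men) / 0.89 (women) in the later period under the packaged synthetic
# value set, with severity worsening by age, pain/discomfort the most
# prevalent complaint, and a mild between-period decline in reported health.
_BELGIUM_LIKE_RESPONSE = ResponseModel(
    cutpoints={
        "mobility": (1.372, 1.932, 2.532, 2.932),
        "self_care": (1.782, 2.332, 2.832, 3.232),
        "usual_activities": (1.012, 1.632, 2.332, 2.832),
        "pain_discomfort": (0.252, 1.232, 2.132, 2.732),
        "anxiety_depression": (0.572, 1.332, 2.132, 2.732),
    },
    beta_age=0.012,
    gender_offsets={"men": 0.0, "women": 0.22},
    year_offsets={2013: 0.0, 2018: 0.06},
    rho=0.4,
)


def belgium_like() -> Scenario:
    """Default scenario emulating the Belgian two-period national analysis."""
    return Scenario(
        name="belgium-like",
        years=(2013, 2018),
        genders=("men", "women"),
        regions=("Belgium",),
        mortality=_BELGIUM_LIKE_MORTALITY,
        response=_BELGIUM_LIKE_RESPONSE,
    )


def skewed_weights_scenario() -> Scenario:
    """Belgium-like scenario intended for use with a large weight_sigma.

    Stress case for the Kish effective-sample-size correction; pass
    ``weight_sigma=1.2`` to :func:`generate_survey` when drawing from it.
    """
    base = belgium_like()
    return Scenario(name="belgium-like-skewed-weights", years=base.years,
                    genders=base.genders, regions=base.regions,
                    mortality=base.mortality, response=base.response)
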
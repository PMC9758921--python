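"""End-to-end analysis workflow.

Orchestrates the pipeline: survey microdata -> population norms; mortality
rates -> life tables; Sullivan QALE / dimension-specific no-problem life
expectancies with standard errors; change tests between the two periods;
decomposition of the QALE change into mortality and disutility effects; and
HE/LE ratio curves.  Outputs are tidy CSV files plus a run log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decomposition import decompose_qale, decomposition_profile
from .lifetable import LifeTable, build_lifetable, read_mortality_csv
from .norms import AgeBands, estimate_norms, read_survey_csv
from .states import DIMENSION_CODES
from .sullivan import (AgeMeasure, HealthExpectancy, compare_he,
                       expand_norms, he_le_ratio, life_expectancy,
                       sullivan_he)
from .valueset import (ValueSet, belgian_synthetic_value_set,
                       read_value_set_csv)

log = logging.getLogger(__name__)

KINDS = ["LE", "QALE"] + [f"DFLE_{c}" for c in DIMENSION_CODES]


class WorkflowError(RuntimeError):
    """A pipeline stage failed; carries stage and stratum context."""

    def __init__(self, stage: str, stratum, cause: Exception):
        super().__init__(f"stage {stage!r}, stratum {stratum}: {cause}")
        self.stage = stage
        self.stratum = stratum
        self.cause = cause


@dataclass
class AnalysisConfig:
    """Settings for one two-period analysis run."""

    mortality_csv: Path
    survey_csv: Path
    value_set_csv: Path | None = None  # None -> packaged synthetic set
    years: tuple[int, int] = (2013, 2018)
    genders: tuple[str, ...] = ("men", "women")
    regions: tuple[str, ...] = ("Belgium",)
    age_bands: AgeBands = field(default_factory=AgeBands.default)
    index_ages: tuple[int, ...] = (15, 65)
    seed: int = 0
    output_dir: Path = Path("qale-output")
    small_stratum_n: int = 30
    plots: bool = False

    def __post_init__(self) -> None:
        if self.years[0] == self.years[1]:
            raise ValueError("the two analysis years must differ")
        for x in self.index_ages:
            if not self.age_bands.start <= x <= self.age_bands.stop:
                raise ValueError(f"index age {x} outside analysis range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config file; relative paths resolve against its location."""
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent

        def _p(key):
            value = raw.get(key)
            return None if value is None else (base / value)

        kwargs = dict(
            mortality_csv=_p("mortality_csv"),
            survey_csv=_p("survey_csv"),
            value_set_csv=_p("value_set_csv"),
        )
        if "years" in raw:
            kwargs["years"] = tuple(int(y) for y in raw["years"])
        if "genders" in raw:
            kwargs["genders"] = tuple(raw["genders"])
        if "regions" in raw:
            kwargs["regions"] = tuple(raw["regions"])
        if "age_bands" in raw:
            kwargs["age_bands"] = AgeBands(
                tuple((int(lo), int(hi)) for lo, hi in raw["age_bands"]))
        if "index_ages" in raw:
            kwargs["index_ages"] = tuple(int(x) for x in raw["index_ages"])
        for key in ("seed", "small_stratum_n", "plots"):
            if key in raw:
                kwargs[key] = raw[key]
        if "output_dir" in raw:
            kwargs["output_dir"] = base / raw["output_dir"]
        return cls(**kwargs)

    def load_value_set(self) -> ValueSet:
        if self.value_set_csv is None:
            return belgian_synthetic_value_set()
        return read_value_set_csv(self.value_set_csv)


@dataclass
class Finding:
    severity: str  # "fatal" | "warning"
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def fatal(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "fatal"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    def ok(self) -> bool:
        return not self.fatal


def validate_inputs(cfg: AnalysisConfig) -> ValidationReport:
    """Schema and coverage checks on all inputs; non-fatal issues warn."""
    report = ValidationReport()

    def fatal(msg):
        report.findings.append(Finding("fatal", msg))

    def warn(msg):
        report.findings.append(Finding("warning", msg))

    try:
        cfg.load_value_set()
    except Exception as err:
        fatal(f"value set: {err}")

    schedules = None
    try:
        schedules = read_mortality_csv(cfg.mortality_csv)
    except Exception as err:
        fatal(f"mortality file: {err}")
    if schedules is not None:
        for year in cfg.years:
            for gender in cfg.genders:
                for region in cfg.regions:
                    key = (year, gender, region)
                    ms = schedules.get(key)
                    if ms is None:
                        fatal(f"mortality file: stratum {key} absent")
                    elif (ms.start_age > cfg.age_bands.start
                          or ms.open_age < cfg.age_bands.stop):
                        fatal(f"mortality file: stratum {key} covers "
                              f"[{ms.start_age}, {ms.open_age}], analysis "
                              f"needs [{cfg.age_bands.start}, "
                              f"{cfg.age_bands.stop}]")

    try:
        survey = read_survey_csv(cfg.survey_csv)
    except Exception as err:
        fatal(f"survey file: {err}")
        survey = None
    if survey is not None:
        if (survey["weight"] <= 0).any():
            fatal("survey file: non-positive weights")
        counts = survey.groupby(["year", "gender", "region"]).size()
        for year in cfg.years:
            for gender in cfg.genders:
                for region in cfg.regions:
                    n = counts.get((year, gender, region), 0)
                    if n == 0:
                        fatal(f"survey file: stratum "
                              f"{(year, gender, region)} has no records")
                    elif n < cfg.small_stratum_n * len(cfg.age_bands):
                        warn(f"survey stratum {(year, gender, region)}: "
                             f"only {n} records across "
                             f"{len(cfg.age_bands)} age bands")
    return report


@dataclass
class ResultBundle:
    """In-memory results of :func:`run_analysis` (also written as CSV)."""

    expectancies: pd.DataFrame   # year, gender, region, index_age, kind, value, se
    changes: pd.DataFrame        # gender, region, index_age, kind, delta, z, p
    table: pd.DataFrame          # presentation view, years rounded to 1 dp
    decomposition_totals: pd.DataFrame
    decomposition_ages: pd.DataFrame
    ratios: pd.DataFrame
    norms: pd.DataFrame
    lifetables: pd.DataFrame


def _measure_for_kind(stratum_norms: pd.DataFrame, ages: np.ndarray,
                      kind: str) -> AgeMeasure:
    if kind == "LE":
        return AgeMeasure.constant(ages, 1.0)
    if kind == "QALE":
        return expand_norms(stratum_norms, ages, "pi", "var_pi")
    code = kind.removeprefix("DFLE_")
    return expand_norms(stratum_norms, ages, f"prev_{code}",
                        f"var_prev_{code}")


def _presentation_table(expectancies: pd.DataFrame, changes: pd.DataFrame,
                        years: tuple[int, int]) -> pd.DataFrame:
    """Rounded wide table: one row per (age, gender, region, year/Change/P)."""
    rows = []
    for (region, x, gender), sub in expectancies.groupby(
            ["region", "index_age", "gender"], sort=True):
        for year in years:
            vals = sub[sub.year == year].set_index("kind")["value"]
            rows.append({"index_age": x, "gender": gender, "region": region,
                         "row": str(year),
                         **{k: round(vals[k], 1) for k in KINDS}})
        ch = changes[(changes.region == region) & (changes.index_age == x)
                     & (changes.gender == gender)].set_index("kind")
        rows.append({"index_age": x, "gender": gender, "region": region,
                     "row": "Change",
                     **{k: round(ch.loc[k, "delta"], 1) + 0.0
                        for k in KINDS}})
        rows.append({"index_age": x, "gender": gender, "region": region,
                     "row": "P-value",
                     **{k: (round(ch.loc[k, "p"], 3)
                            if pd.notna(ch.loc[k, "p"]) else "")
                        for k in KINDS}})
    return pd.DataFrame(rows)


def run_analysis(cfg: AnalysisConfig) -> ResultBundle:
    """Run the full pipeline and write the output bundle.

    Outputs (CSV, full precision unless noted) in ``cfg.output_dir``:

    - ``lifetables.csv`` — all period life tables;
    - ``norms.csv`` — estimated population norms per stratum and band;
    - ``expectancies.csv`` — LE, QALE and five no-problem DFLEs with
      standard errors, per year x gender x region x index age;
    - ``changes.csv`` — later-minus-earlier change per kind with Z and
      two-sided p (no p for LE: mortality is register-based, treated fixed);
    - ``table1.csv`` — presentation view rounded to one decimal;
    - ``decomposition_totals.csv`` — mortality/disutility totals for every
      index age (stacked-bar-plus-line data);
    - ``decomposition_ages.csv`` — per-age effects at the configured index
      ages;
    - ``ratios.csv`` — HE/LE ratio curves per kind;
    - ``run.log`` — config echo and warnings.

    On error, files created by this run are removed before re-raising.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    def _write(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        created.append(path)

    log_lines = [f"config: {cfg}"]
    try:
        vs = cfg.load_value_set()
        schedules = read_mortality_csv(cfg.mortality_csv)
        survey = read_survey_csv(cfg.survey_csv)
        ages = np.arange(cfg.age_bands.start, cfg.age_bands.stop + 1)

        try:
            norms = estimate_norms(survey, vs, cfg.age_bands)
        except Exception as err:
            raise WorkflowError("norms", "all", err) from err

        lts: dict[tuple, LifeTable] = {}
        lt_frames = []
        for year in cfg.years:
            for gender in cfg.genders:
                for region in cfg.regions:
                    key = (year, gender, region)
                    try:
                        lt = build_lifetable(schedules[key])
                    except Exception as err:
                        raise WorkflowError("lifetable", key, err) from err
                    lts[key] = lt
                    lt_frames.append(lt.to_frame().assign(
                        year=year, gender=gender, region=region))
        lifetables = pd.concat(lt_frames, ignore_index=True)

        he_rows, ratio_frames = [], []
        for key, lt in lts.items():
            year, gender, region = key
            sub = norms[(norms.year == year) & (norms.gender == gender)
                        & (norms.region == region)]
            for kind in KINDS:
                try:
                    measure = _measure_for_kind(sub, ages, kind)
                    for x in cfg.index_ages:
                        he = (life_expectancy(lt, x) if kind == "LE"
                              else sullivan_he(lt, measure, x, kind))
                        he_rows.append((year, gender, region, x, kind,
                                        he.value, he.se))
                    if kind != "LE":
                        rc = he_le_ratio_frame(lt, measure, kind, key)
                        ratio_frames.append(rc)
                except WorkflowError:
                    raise
                except Exception as err:
                    raise WorkflowError("sullivan", key + (kind,), err) from err
        expectancies = pd.DataFrame(
            he_rows, columns=["year", "gender", "region", "index_age",
                              "kind", "value", "se"]).sort_values(
            ["region", "gender", "index_age", "kind", "year"],
            ignore_index=True)
        ratios = pd.concat(ratio_frames, ignore_index=True)

        t0, t1 = cfg.years
        ch_rows = []
        for (region, gender, x, kind), sub in expectancies.groupby(
                ["region", "gender", "index_age", "kind"], sort=True):
            sub = sub.set_index("year")
            a = HealthExpectancy(x, sub.loc[t1, "value"], sub.loc[t1, "se"],
                                 kind)
            b = HealthExpectancy(x, sub.loc[t0, "value"], sub.loc[t0, "se"],
                                 kind)
            if kind == "LE":
                ch_rows.append((gender, region, x, kind,
                                a.value - b.value, np.nan, np.nan))
            else:
                cr = compare_he(a, b)
                ch_rows.append((gender, region, x, kind, cr.delta, cr.z,
                                cr.p))
        changes = pd.DataFrame(
            ch_rows, columns=["gender", "region", "index_age", "kind",
                              "delta", "z", "p"])

        dec_tot_frames, dec_age_frames = [], []
        for gender in cfg.genders:
            for region in cfg.regions:
                sub_t = norms[(norms.year == t0) & (norms.gender == gender)
                              & (norms.region == region)]
                sub_tn = norms[(norms.year == t1) & (norms.gender == gender)
                               & (norms.region == region)]
                pi_t = expand_norms(sub_t, ages, "pi", "var_pi")
                pi_tn = expand_norms(sub_tn, ages, "pi", "var_pi")
                lt_t = lts[(t0, gender, region)]
                lt_tn = lts[(t1, gender, region)]
                try:
                    prof = decomposition_profile(lt_t, pi_t, lt_tn, pi_tn,
                                                 ages)
                except Exception as err:
                    raise WorkflowError("decomposition", (gender, region),
                                        err) from err
                dec_tot_frames.append(prof.assign(gender=gender,
                                                  region=region))
                for x in cfg.index_ages:
                    res = decompose_qale(lt_t, pi_t, lt_tn, pi_tn, x)
                    dec_age_frames.append(res.to_frame().assign(
                        gender=gender, region=region))
        decomposition_totals = pd.concat(dec_tot_frames, ignore_index=True)
        decomposition_ages = pd.concat(dec_age_frames, ignore_index=True)

        table = _presentation_table(expectancies, changes, cfg.years)

        _write(lifetables, "lifetables.csv")
        _write(norms, "norms.csv")
        _write(expectancies, "expectancies.csv")
        _write(changes, "changes.csv")
        _write(table, "table1.csv")
        _write(decomposition_totals, "decomposition_totals.csv")
        _write(decomposition_ages, "decomposition_ages.csv")
        _write(ratios, "ratios.csv")

        if cfg.plots:
            created.extend(render_plots(cfg, decomposition_totals, ratios))

        log_path = out / "run.log"
        log_path.write_text("\n".join(log_lines) + "\n")
    except Exception:
        for path in created:
            path.unlink(missing_ok=True)
        raise

    return ResultBundle(expectancies=expectancies, changes=changes,
                        table=table,
                        decomposition_totals=decomposition_totals,
                        decomposition_ages=decomposition_ages,
                        ratios=ratios, norms=norms, lifetables=lifetables)


def he_le_ratio_frame(lt: LifeTable, measure: AgeMeasure, kind: str,
                      key: tuple) -> pd.DataFrame:
    frame = he_le_ratio(lt, measure)
    year, gender, region = key
    return frame.assign(kind=kind, year=year, gender=gender, region=region)


def render_plots(cfg: AnalysisConfig, decomposition_totals: pd.DataFrame,
                 ratios: pd.DataFrame) -> list[Path]:
    """Optional rendering of decomposition bars and HE/LE ratio curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(cfg.output_dir)
    written = []
    for gender in cfg.genders:
        sub = decomposition_totals[decomposition_totals.gender == gender]
        fig, ax = plt.subplots(figsize=(8, 4))
        ax.bar(sub.index_age, sub.mor_total, label="mortality effect",
               color="black")
        ax.bar(sub.index_age, sub.dis_total, label="disutility effect",
               color="orange")
        ax.plot(sub.index_age, sub.delta_qale, color="red",
                label="change in QALE")
        ax.set_xlabel("index age")
        ax.set_ylabel("years")
        ax.set_title(f"QALE change decomposition, {gender}")
        ax.legend()
        path = out / f"decomposition_{gender}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

        fig, ax = plt.subplots(figsize=(8, 4))
        for (kind, year), s in ratios[ratios.gender == gender].groupby(
                ["kind", "year"]):
            ax.plot(s.age, s.ratio, label=f"{kind} {year}",
                    alpha=0.8, lw=1)
        ax.set_xlabel("age")
        ax.set_ylabel("HE / LE")
        ax.set_title(f"Health expectancy as share of LE, {gender}")
        ax.legend(fontsize=6, ncol=2)
        path = out / f"ratios_{gender}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
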
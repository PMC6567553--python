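"""Forward projection of incident and prevalent cases under demographic change.

Holding the estimated age/sex-specific incidence rates fixed (the
constant-incidence assumption), incident cases in a future year are the
rates applied to that year's projected population.  Prevalence follows
the classic identity

    prevalent cases = incidence rate x population x mean disease duration,

with duration supplied as the Kaplan-Meier median of each age cohort,
converted from months to years.  Treatment scenarios act on duration
only: a fixed month increment for everyone, a multiplicative survival
gain for a carrier subgroup, or — for a progression-halting therapy —
replacement of the subgroup's disease duration by the period life
expectancy at their age, sex and calendar year.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .bands import BAND_LABELS, SEXES, band_of_age, cohort_of_band, representative_age
from .rates import RateTable


class PopulationProjection:
    """Projected persons by (year, sex, single year of age)."""

    def __init__(self, frame: pd.DataFrame):
        required = {"year", "sex", "age", "count"}
        if not required.issubset(frame.columns):
            raise ValueError(f"projection frame needs columns {sorted(required)}")
        if (frame["count"] < 0).any():
            raise ValueError("negative projected counts")
        self.frame = frame
        years = sorted(frame["year"].unique())
        if years != list(range(years[0], years[-1] + 1)):
            raise ValueError("projection years must be contiguous")
        self.years = range(years[0], years[-1] + 1)
        # cache: (year, sex, band) -> persons, plus all-age totals
        sub = frame[frame["age"] >= 15].copy()
        sub["band"] = [band_of_age(a) for a in sub["age"]]
        self._bands = sub.groupby(["year", "sex", "band"])["count"].sum()
        self._totals = frame.groupby(["year", "sex"])["count"].sum()

    @classmethod
    def from_csv(cls, path) -> "PopulationProjection":
        return cls(pd.read_csv(path))

    def band_pop(self, year: int, sex: str, band: str) -> float:
        if year not in self.years:
            raise ValueError(f"year {year} outside projection coverage {self.years}")
        try:
            return float(self._bands.loc[(year, sex, band)])
        except KeyError:
            return 0.0

    def total(self, year: int, sex: str | None = None) -> float:
        """All-age projected population (the prevalence denominator)."""
        if year not in self.years:
            raise ValueError(f"year {year} outside projection coverage {self.years}")
        if sex is None:
            return float(sum(self._totals.loc[(year, s)] for s in SEXES))
        return float(self._totals.loc[(year, sex)])


class LifeTable:
    """Period life expectancy (expected remaining years) by year, sex, age."""

    def __init__(self, frame: pd.DataFrame):
        required = {"year", "sex", "age", "expected_years"}
        if not required.issubset(frame.columns):
            raise ValueError(f"life table needs columns {sorted(required)}")
        if (frame["expected_years"] <= 0).any():
            raise ValueError("life expectancy must be positive")
        self._table = frame.set_index(["year", "sex", "age"])["expected_years"]
        self.years = frozenset(frame["year"].unique())
        self.max_age = int(frame["age"].max())

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))


def life_expectancy_lookup(life: LifeTable, age: float, sex: str, year: int) -> float:
    """Expected remaining life in months at (age, sex, year); no extrapolation.

    Fractional ages (band midpoints) resolve to the nearest tabulated age
    at or below.
    """
    if year not in life.years:
        raise ValueError(f"year {year} not covered by the life table")
    age_key = int(age)
    if age_key > life.max_age:
        raise ValueError(f"age {age} above life-table maximum {life.max_age}")
    try:
        return float(life._table.loc[(year, sex, age_key)]) * 12.0
    except KeyError:
        raise ValueError(f"life table has no entry for ({year}, {sex}, {age_key})")


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """A hypothetical treatment: a duration transform for a population fraction.

    ``transform`` is one of:
      * ("add_months", delta) — everyone gains delta months of median survival;
      * ("multiply", m)       — the affected fraction's median is multiplied by m;
      * ("life_table", None)  — the affected fraction survives to their period
        life expectancy (progression halted).
    ``affected_fraction`` is the carrier share of the patient population.
    ``year_cap`` bounds life-table scenarios to the years the table covers.
    """

    name: str
    affected_fraction: float
    transform: tuple[str, float | None]
    year_cap: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must be in [0, 1]")
        kind, param = self.transform
        if kind == "add_months" and (param is None or param < 0):
            raise ValueError("add_months requires a nonnegative month increment")
        if kind == "multiply" and (param is None or param <= 0):
            raise ValueError("multiply requires a positive factor")
        if kind not in {"add_months", "multiply", "life_table"}:
            raise ValueError(f"unknown transform {kind!r}")


#: The four treatment scenarios: a Riluzole-equivalent 3-month gain for all,
#: a 50% survival gain for SOD1 carriers (4%), a 50% gain for C9orf72
#: carriers (10%), and halted progression for C9orf72 carriers with survival
#: from period life tables (available to 2066).
STANDARD_SCENARIOS: dict[str, ScenarioSpec] = {
    "baseline": ScenarioSpec("baseline", 0.0, ("multiply", 1.0)),
    "s1": ScenarioSpec("s1", 1.0, ("add_months", 3.0)),
    "s2": ScenarioSpec("s2", 0.04, ("multiply", 1.5)),
    "s3": ScenarioSpec("s3", 0.10, ("multiply", 1.5)),
    "s4": ScenarioSpec("s4", 0.10, ("life_table", None), year_cap=2066),
}


def scenario_multiplier(
    f: float,
    transform: tuple[str, float | None],
    median_months: float | None = None,
    life_expectancy_months: float | None = None,
) -> float:
    """Effective duration multiplier implied by a scenario.

    The population-mean duration after treating a fraction f is
    (1 - f) x median + f x transformed median, so:

      * multiply(m):   1 - f + f*m  (cohort-independent);
      * add_months(d): (median + d) / median;
      * life_table:    1 - f + f * E / median, with E the subgroup's life
        expectancy in months.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    kind, param = transform
    if kind == "multiply":
        return 1.0 - f + f * float(param)
    if median_months is None or median_months <= 0:
        raise ValueError("a positive median is required for this transform")
    if kind == "add_months":
        return (median_months + float(param)) / median_months
    if kind == "life_table":
        if life_expectancy_months is None:
            raise ValueError("life_table transform requires a life expectancy")
        return 1.0 - f + f * life_expectancy_months / median_months
    raise ValueError(f"unknown transform {kind!r}")


def project_incidence(
    rates: RateTable, proj: PopulationProjection, years: range
) -> pd.DataFrame:
    """Incident cases per (year, sex, band): rate/100,000 x projected persons.

    Returns a tidy frame with per-stratum cases; totals by sex and
    overall are exact sums of the strata.
    """
    rows = []
    for year in years:
        for sex in SEXES:
            for band in BAND_LABELS:
                pop = proj.band_pop(year, sex, band)
                rows.append(
                    {
                        "year": year,
                        "sex": sex,
                        "age_band": band,
                        "population": pop,
                        "cases": rates.rate(sex, band) / 1e5 * pop,
                    }
                )
    return pd.DataFrame(rows)


def incident_totals(incidence: pd.DataFrame) -> pd.DataFrame:
    """Per-year incident totals by sex and overall."""
    by_sex = incidence.pivot_table(index="year", columns="sex", values="cases", aggfunc="sum")
    by_sex["overall"] = by_sex[list(SEXES)].sum(axis=1)
    return by_sex


def _duration_months_for(
    year: int,
    sex: str,
    band: str,
    durations: Mapping[str, float],
    spec: ScenarioSpec,
    life: LifeTable | None,
    add_months_basis: str,
) -> float:
    """Population-mean duration (months) for one stratum under a scenario."""
    median = durations[cohort_of_band(band)]
    kind, param = spec.transform
    if kind == "multiply":
        return median * scenario_multiplier(spec.affected_fraction, spec.transform)
    if kind == "add_months":
        if add_months_basis == "overall":
            overall = durations["overall"]
            return median * (overall + float(param)) / overall
        return median + float(param)
    # life_table: the treated fraction survives to period life expectancy
    e_months = life_expectancy_lookup(life, representative_age(band), sex, year)
    f = spec.affected_fraction
    return (1.0 - f) * median + f * e_months


def project_prevalence(
    rates: RateTable,
    proj: PopulationProjection,
    durations: Mapping[str, float],
    years: range,
    spec: ScenarioSpec | None = None,
    life: LifeTable | None = None,
    add_months_basis: str = "overall",
) -> pd.DataFrame:
    """Prevalent cases and prevalence per 100,000 per year, by sex and overall.

    ``durations`` maps the three duration cohorts (plus "overall") to
    median months.  Per stratum, prevalent cases are
    rate/100,000 x projected persons x duration in years; prevalence
    divides each sex's (or the overall) case total by the full projected
    population of all ages.

    ``spec`` defaults to baseline (no treatment).  ``add_months_basis``
    selects whether a fixed-increment scenario scales every cohort by
    (overall median + d)/(overall median) ("overall", the default) or
    adds d to each cohort median ("per_cohort").
    """
    if spec is None:
        spec = STANDARD_SCENARIOS["baseline"]
    if spec.transform[0] == "life_table":
        if life is None:
            raise ValueError(f"scenario {spec.name}: life table required")
        over = [y for y in years if spec.year_cap is not None and y > spec.year_cap]
        if over:
            raise ValueError(
                f"scenario {spec.name}: years beyond the life-table cap "
                f"{spec.year_cap} requested (first: {over[0]})"
            )
    for cohort in set(cohort_of_band(b) for b in BAND_LABELS):
        if cohort not in durations or not durations[cohort] > 0:
            raise ValueError(f"missing or non-positive duration for cohort {cohort!r}")

    rows = []
    for year in years:
        cases_by_sex = {}
        for sex in SEXES:
            total = 0.0
            for band in BAND_LABELS:
                months = _duration_months_for(
                    year, sex, band, durations, spec, life, add_months_basis
                )
                total += (
                    rates.rate(sex, band) / 1e5
                    * proj.band_pop(year, sex, band)
                    * months / 12.0
                )
            cases_by_sex[sex] = total
        overall_cases = sum(cases_by_sex.values())
        row = {"scenario": spec.name, "year": year}
        for sex in SEXES:
            row[f"{sex}_cases"] = cases_by_sex[sex]
            row[f"{sex}_per_100k"] = cases_by_sex[sex] / proj.total(year, sex) * 1e5
        row["overall_cases"] = overall_cases
        row["overall_per_100k"] = overall_cases / proj.total(year) * 1e5
        rows.append(row)
    return pd.DataFrame(rows)


def apply_scenario(
    rates: RateTable,
    proj: PopulationProjection,
    durations: Mapping[str, float],
    spec: ScenarioSpec,
    years: range,
    life: LifeTable | None = None,
    add_months_basis: str = "overall",
) -> pd.DataFrame:
    """Recompute the prevalence series with a scenario's duration transform."""
    return project_prevalence(
        rates, proj, durations, years, spec=spec, life=life,
        add_months_basis=add_months_basis,
    )
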
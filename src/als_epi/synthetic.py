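"""Synthetic registry, population, projection, and life-table generator.

The pipeline's real inputs are clinic case registers and national
statistics products that cannot be redistributed.  This module generates
stand-ins with the statistical structure the estimators assume — an
age/sex incidence gradient peaking in the eighth decade with a male
excess of about 1.17, exponential-like survival with cohort medians near
(56, 35, 26) months, administrative- or independent-censoring follow-up,
planted records that trigger each exclusion rule, and population
structures whose old-age cohorts grow severalfold over the projection
horizon.  Every generator is seeded and returns a ground-truth sidecar
describing what was planted, so parameter-recovery tests can compare
estimates against the values used for simulation.

Region presets mirror the shape of the study samples: ``lsl`` (an inner
London catchment with fractional postcode-sector weights), ``canterbury``
(a suburban/rural register with whole-person weights), ``seals`` (the
larger survival register), and ``uk`` (the standard population,
projection, and life table).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import Any

import numpy as np
import pandas as pd

from .bands import BAND_LABELS, BAND_LOWER, SEXES, cohort_of_age
from .registry import CASE_COLUMNS

#: Relative incidence by 5-year band (peaks at 75-84, dips slightly at 90+).
AGE_SHAPE = np.array(
    [0.06, 0.08, 0.10, 0.15, 0.22, 0.35, 0.55, 0.85, 1.25, 1.75,
     2.30, 2.80, 3.10, 3.20, 3.00, 2.40]
)

#: Share of the 15+ population in each band (aging-country pyramid).
PYRAMID = np.array(
    [0.072, 0.082, 0.085, 0.082, 0.080, 0.086, 0.088, 0.080, 0.072, 0.070,
     0.058, 0.048, 0.040, 0.030, 0.018, 0.009]
)
PYRAMID = PYRAMID / PYRAMID.sum()

#: Inner-city pyramid: young, ~10% aged 65+, so standardizing to the national
#: structure lifts the standardized rate well above the crude rate.
PYRAMID_YOUNG = np.array(
    [0.11, 0.115, 0.12, 0.115, 0.105, 0.095, 0.08, 0.065, 0.05, 0.04,
     0.032, 0.025, 0.020, 0.015, 0.009, 0.004]
)
PYRAMID_YOUNG = PYRAMID_YOUNG / PYRAMID_YOUNG.sum()

#: Suburban/rural pyramid: older than the national structure (~24% aged 65+),
#: so the standardized rate falls slightly below the crude rate.
PYRAMID_OLD = np.array(
    [0.062, 0.066, 0.068, 0.068, 0.070, 0.077, 0.082, 0.079, 0.073, 0.071,
     0.063, 0.054, 0.045, 0.035, 0.023, 0.012]
)
PYRAMID_OLD = PYRAMID_OLD / PYRAMID_OLD.sum()

_EL_ESCORIAL = ["definite", "probable", "probable_lab", "possible", "suspected", ""]
_EL_PROBS = [0.20, 0.35, 0.04, 0.12, 0.02, 0.27]
_DIAGNOSES = ["ALS", "PLS", "PMA", "pseudobulbar_palsy"]
_DX_PROBS = [0.88, 0.07, 0.03, 0.02]

LN2 = float(np.log(2.0))


@dataclasses.dataclass
class GeneratorConfig:
    """Everything a generator run needs; presets encode the study samples.

    ``n_cases`` fixes the registry size exactly (preset mode); setting it
    to ``None`` instead draws cell counts as Poisson with mean
    rate x person-years from the configured surface, which is what the
    confidence-interval coverage tests require.
    """

    seed: int = 0
    region: str = "canterbury"
    study_start: _dt.date = _dt.date(2004, 1, 1)
    study_end: _dt.date = _dt.date(2017, 12, 31)
    n_cases: int | None = 269
    n_lmn: int = 1
    n_kennedys: int = 2
    n_other: int = 0
    n_missing_age: int = 2
    n_missing_onset: int = 0
    p_female: float = 0.48
    base_rate: float = 3.6          # per 100,000 person-years at shape 1.0
    male_female_ratio: float = 1.17
    medians_months: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"<40": 56.0, "40-79": 35.0, "80+": 26.0}
    )
    survival_model: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.3
    censoring_mode: str = "independent"  # or "administrative"
    censoring_fraction: float = 0.15
    follow_up_end: _dt.date = _dt.date(2019, 12, 31)
    sector_plan: list[tuple[str, float, int]] | None = None
    default_sector: str = "ZZ1 1"
    pop_15plus: float = 522_400.0
    prevalence_population: float = 530_100.0
    n_prevalent_alive: int = 44
    reference_year: int = 2011
    # uk preset extras
    standard_total: float = 62_760_000.0
    projection_years: tuple[int, int] = (2020, 2116)
    growth_scale: float = 1.0  # multiplies the age-specific annual growth
    life_table_years: tuple[int, int] = (2020, 2066)
    target_incident_2020: float = 1701.0
    target_prevalence_2020: float = 8.58
    pyramid: np.ndarray = dataclasses.field(default_factory=lambda: PYRAMID.copy())

    @property
    def study_years(self) -> float:
        return (self.study_end.year - self.study_start.year) + 1.0

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "GeneratorConfig":
        if name == "lsl":
            return cls(
                seed=seed, region="lsl", n_cases=152, n_lmn=1, n_kennedys=0,
                n_missing_age=0, p_female=0.474,
                sector_plan=[("SE1 1", 1.0, 70), ("SE5 9", 0.9, 31), ("SE21 7", 0.5, 50)],
                default_sector="SE1 1",
                pop_15plus=682_600.0, prevalence_population=699_400.0,
                n_prevalent_alive=37, reference_year=2010,
                pyramid=PYRAMID_YOUNG.copy(),
            )
        if name == "canterbury":
            return cls(seed=seed, region="canterbury", default_sector="CT1 1",
                       pyramid=PYRAMID_OLD.copy())
        if name == "seals":
            return cls(
                seed=seed, region="seals", n_cases=953, n_lmn=1, n_kennedys=3,
                n_other=2, n_missing_age=2, n_missing_onset=43, p_female=0.454,
                default_sector="CT1 1", pop_15plus=1_500_000.0,
            )
        if name == "uk":
            return cls(seed=seed, region="uk", n_cases=None)
        raise ValueError(f"unknown preset {name!r}")


def rate_surface(config: GeneratorConfig) -> pd.DataFrame:
    """True incidence rates per 100,000 person-years by (band, sex)."""
    m_mult = np.sqrt(config.male_female_ratio)
    rates = pd.DataFrame(index=list(BAND_LABELS), columns=list(SEXES), dtype=float)
    rates["male"] = config.base_rate * AGE_SHAPE * m_mult
    rates["female"] = config.base_rate * AGE_SHAPE / m_mult
    return rates


def _draw_duration_months(rng: np.random.Generator, config: GeneratorConfig, age: float) -> float:
    median = config.medians_months[cohort_of_age(age)]
    if config.survival_model == "weibull":
        k = config.weibull_shape
        scale = median / LN2 ** (1.0 / k)
        return float(scale * rng.weibull(k))
    return float(rng.exponential(median / LN2))


def _observe(
    rng: np.random.Generator,
    config: GeneratorConfig,
    duration: float,
    onset: _dt.date,
    age: float,
) -> tuple[float, int]:
    """Apply censoring, returning (observed months, event flag).

    Independent mode draws an exponential censoring time whose rate is
    tuned to the cohort's event rate so that P(censored) equals the
    configured fraction exactly; administrative mode censors everyone
    still alive at the fixed end-of-follow-up date.
    """
    if config.censoring_mode == "administrative":
        horizon = (config.follow_up_end - onset).days / 30.4375
        if duration > horizon:
            return max(horizon, 1.0), 0
        return max(duration, 1.0), 1
    c = config.censoring_fraction
    if c <= 0:
        return max(duration, 1.0), 1
    event_rate = LN2 / config.medians_months[cohort_of_age(age)]
    censor = rng.exponential(1.0 / (event_rate * c / (1.0 - c)))
    if censor < duration:
        return max(censor, 1.0), 0
    return max(duration, 1.0), 1


def _sample_age(rng: np.random.Generator, config: GeneratorConfig) -> float:
    """Age at diagnosis, drawn from the incidence-weighted region pyramid."""
    probs = AGE_SHAPE * config.pyramid
    probs = probs / probs.sum()
    band_idx = rng.choice(len(BAND_LABELS), p=probs)
    lo = BAND_LOWER[band_idx]
    width = 8 if lo == 90 else 5
    return float(lo + rng.uniform(0, width))


def _row(
    rng: np.random.Generator,
    config: GeneratorConfig,
    idx: int,
    diagnosis: str,
    missing_age: bool = False,
    missing_onset: bool = False,
    sector: str | None = None,
) -> dict[str, Any]:
    sex = "female" if rng.random() < config.p_female else "male"
    age = _sample_age(rng, config)
    window_days = (config.study_end - config.study_start).days
    onset = config.study_start + _dt.timedelta(days=int(rng.integers(0, window_days)))
    delay_months = float(rng.uniform(2, 14))
    duration = _draw_duration_months(rng, config, age)
    observed, event = _observe(rng, config, max(duration, delay_months + 1), onset, age)
    end_date = onset + _dt.timedelta(days=int(round(observed * 30.4375)))
    dx_date = onset + _dt.timedelta(days=int(round(delay_months * 30.4375)))
    if diagnosis == "ALS_like":
        diagnosis = str(rng.choice(_DIAGNOSES, p=_DX_PROBS))
    return {
        "patient_id": f"{config.region}-{idx:05d}",
        "sex": sex,
        "date_of_onset": "" if missing_onset else onset.isoformat(),
        "date_of_diagnosis": dx_date.isoformat(),
        "age_at_diagnosis": "" if missing_age else f"{age:.1f}",
        "end_date": end_date.isoformat(),
        "end_event": "died" if event else "censored",
        "diagnosis": diagnosis,
        "el_escorial": str(rng.choice(_EL_ESCORIAL, p=_EL_PROBS)),
        "sector_id": sector if sector is not None else config.default_sector,
    }


def gen_registry(config: GeneratorConfig) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Generate a case-registry table plus its ground-truth sidecar.

    In preset mode (``n_cases`` set) the table holds exactly ``n_cases``
    rows: the planted exclusions (non-MND diagnoses, missing age, missing
    onset) plus well-formed kept cases, with sectors assigned per the
    ``sector_plan``.  In Poisson mode (``n_cases`` None) each (sex, band)
    cell count is drawn Poisson with mean rate x person-years from
    :func:`rate_surface` against ``pop_15plus`` split by ``PYRAMID``.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict[str, Any]] = []
    truth: dict[str, Any] = {
        "region": config.region,
        "seed": config.seed,
        "medians_months": dict(config.medians_months),
        "study_years": config.study_years,
    }

    if config.n_cases is not None:
        n_excl = config.n_lmn + config.n_kennedys + config.n_other
        n_kept = config.n_cases - n_excl - config.n_missing_age - config.n_missing_onset
        if n_kept < 0:
            raise ValueError("planted exclusions exceed the configured case count")
        idx = 0
        for diag, count in (
            ("LMN_syndrome", config.n_lmn),
            ("kennedys", config.n_kennedys),
            ("other", config.n_other),
        ):
            for _ in range(count):
                rows.append(_row(rng, config, idx, diag)); idx += 1
        for _ in range(config.n_missing_age):
            rows.append(_row(rng, config, idx, "ALS_like", missing_age=True)); idx += 1
        for _ in range(config.n_missing_onset):
            rows.append(_row(rng, config, idx, "ALS_like", missing_onset=True)); idx += 1

        sectors: list[str] = []
        if config.sector_plan is not None:
            planned = sum(n for _, _, n in config.sector_plan)
            if planned != n_kept:
                raise ValueError(
                    f"sector plan covers {planned} cases but {n_kept} are kept"
                )
            for sector, _frac, n in config.sector_plan:
                sectors.extend([sector] * n)
        else:
            sectors = [config.default_sector] * n_kept
        for sector in sectors:
            rows.append(_row(rng, config, idx, "ALS_like", sector=sector)); idx += 1

        truth["expected_exclusions"] = {
            "diagnosis": n_excl,
            "missing_age": config.n_missing_age,
            "missing_onset": config.n_missing_onset,
        }
        truth["kept_incidence"] = n_kept + config.n_missing_onset
        truth["kept_survival"] = n_kept
        if config.sector_plan is not None:
            truth["expected_weighted_total"] = round(
                sum(frac * n for _, frac, n in config.sector_plan)
                + config.n_missing_onset * 1.0,
                6,
            )
        else:
            truth["expected_weighted_total"] = float(truth["kept_incidence"])
    else:
        rates = rate_surface(config)
        truth["true_rates"] = rates
        pop = population_structure(config)
        expected = rates * pop * config.study_years / 1e5
        if (expected.to_numpy() > pop.to_numpy()).any():
            raise ValueError("configured rates imply more cases than people")
        idx = 0
        for band_i, band in enumerate(BAND_LABELS):
            for sex in SEXES:
                n_cell = rng.poisson(expected.at[band, sex])
                lo = BAND_LOWER[band_i]
                width = 8 if lo == 90 else 5
                for _ in range(n_cell):
                    row = _row(rng, config, idx, "ALS_like")
                    row["sex"] = sex
                    row["age_at_diagnosis"] = f"{lo + rng.uniform(0, width):.1f}"
                    rows.append(row); idx += 1
        truth["expected_exclusions"] = {"diagnosis": 0, "missing_age": 0, "missing_onset": 0}
        truth["kept_incidence"] = len(rows)
        truth["kept_survival"] = len(rows)
        truth["expected_weighted_total"] = float(len(rows))
        truth["population"] = pop

    frame = pd.DataFrame(rows, columns=CASE_COLUMNS)
    truth["n_rows"] = len(frame)
    return frame, truth


def gen_sector_overlaps(config: GeneratorConfig) -> pd.DataFrame:
    """Overlap table covering every sector the registry can emit."""
    plan = config.sector_plan or [(config.default_sector, 1.0, 0)]
    seen: dict[str, float] = {}
    for sector, frac, _ in plan:
        seen[sector] = frac
    seen.setdefault(config.default_sector, 1.0)
    return pd.DataFrame(
        {"sector_id": list(seen), "fraction_in_catchment": list(seen.values())}
    )


def population_structure(config: GeneratorConfig) -> pd.DataFrame:
    """15+ population by (band, sex): region-pyramid shares of ``pop_15plus``."""
    frame = pd.DataFrame(index=list(BAND_LABELS), columns=list(SEXES), dtype=float)
    # women outnumber men in old age: tilt the male share downward with age
    tilt = np.linspace(1.04, 0.80, len(BAND_LABELS))
    male = config.pyramid * 0.49 * tilt / tilt.mean()
    female = np.clip(config.pyramid - male, 1e-9, None)
    frame["male"] = male * config.pop_15plus
    frame["female"] = female * config.pop_15plus
    return frame


def gen_population(config: GeneratorConfig) -> pd.DataFrame:
    """Region population CSV frame: region,sex,age_band,count,reference_year."""
    structure = population_structure(config)
    rows = []
    for band in BAND_LABELS:
        for sex in SEXES:
            rows.append(
                {
                    "region": config.region,
                    "sex": sex,
                    "age_band": band,
                    "count": structure.at[band, sex],
                    "reference_year": config.reference_year,
                }
            )
    return pd.DataFrame(rows)


def gen_standard_population(config: GeneratorConfig) -> pd.DataFrame:
    """Standard (UK-scale) population frame on the same CSV schema."""
    uk = dataclasses.replace(config, region="uk_standard", pop_15plus=config.standard_total)
    return gen_population(uk)


# ---------------------------------------------------------------------------
# projections and life tables

#: Annual growth by age: concentrated in old age so the 80+/90+ cohorts grow
#: severalfold over a century while the working-age population is near-flat.
def _growth_rate(age: int) -> float:
    if age >= 90:
        return 0.013
    if age >= 80:
        return 0.010
    if age >= 70:
        return 0.006
    return 0.001


def _single_year_base(config: GeneratorConfig) -> pd.DataFrame:
    """Unscaled 2020 single-year-of-age adult population (ages 15-100)."""
    rows = []
    band_pop = population_structure(config)
    for band_i, band in enumerate(BAND_LABELS):
        lo = BAND_LOWER[band_i]
        ages = list(range(lo, 101)) if band == "90+" else list(range(lo, lo + 5))
        for sex in SEXES:
            # within the open band, thin out the very old geometrically
            weights = np.array([0.7 ** (a - lo) for a in ages]) if band == "90+" else np.ones(len(ages))
            weights = weights / weights.sum()
            for age, w in zip(ages, weights):
                rows.append({"sex": sex, "age": age, "count": band_pop.at[band, sex] * w})
    return pd.DataFrame(rows)


def gen_projection(
    config: GeneratorConfig,
    rates: pd.DataFrame | None = None,
    medians: dict[str, float] | None = None,
    calibrate_prevalence: bool = True,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Population projection frame (year,sex,age,count) for 2020-2116.

    The 2020 structure is calibrated so that, at the supplied incidence
    rates (default: the generator's true surface) and cohort medians
    (default: the configured ones), the 2020 incident total matches
    ``target_incident_2020`` and the 2020 overall prevalence matches
    ``target_prevalence_2020`` — the all-age denominator is padded at
    ages 0-14 to hit the prevalence target, so the fixture reproduces the
    rate x duration -> prevalence structure rather than real demography.
    Passing the pipeline's own estimated rates and medians keeps the
    projection consistent with the estimates that will be applied to it.
    Later years apply age-specific growth concentrated in the 80+
    cohorts.
    """
    from .bands import band_of_age, cohort_of_band

    if rates is None:
        rates = rate_surface(config)
    if medians is None:
        medians = config.medians_months
    base = _single_year_base(config)
    adults = base[base["age"] >= 15].copy()
    adults["band"] = [band_of_age(a) for a in adults["age"]]

    incident = sum(
        rates.at[band, sex] / 1e5 * grp["count"].sum()
        for (sex, band), grp in adults.groupby(["sex", "band"])
    )
    scale = config.target_incident_2020 / incident
    adults["count"] *= scale

    prevalent = sum(
        rates.at[band, sex] / 1e5 * grp["count"].sum()
        * medians[cohort_of_band(band)] / 12.0
        for (sex, band), grp in adults.groupby(["sex", "band"])
    )
    if calibrate_prevalence:
        total_needed = prevalent / (config.target_prevalence_2020 / 1e5)
        child_total = total_needed - adults["count"].sum()
        if child_total <= 0:
            raise ValueError(
                "prevalence target infeasible: adult population already exceeds "
                "the implied all-age total; calibrate on incidence only"
            )
    else:
        # a fixed under-15 share; baseline prevalence lands wherever the
        # supplied rates and durations put it
        child_total = adults["count"].sum() * 0.21
    children = pd.DataFrame(
        [
            {"sex": sex, "age": age, "count": child_total / 30.0}
            for sex in SEXES
            for age in range(0, 15)
        ]
    )
    base2020 = pd.concat([adults.drop(columns="band"), children], ignore_index=True)

    y0, y1 = config.projection_years
    frames = []
    for year in range(y0, y1 + 1):
        f = base2020.copy()
        f["count"] = [
            c * (1.0 + config.growth_scale * _growth_rate(a)) ** (year - 2020)
            for c, a in zip(f["count"], f["age"])
        ]
        f["year"] = year
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)[["year", "sex", "age", "count"]]
    truth = {
        "incident_2020": config.target_incident_2020,
        "prevalence_2020": (
            config.target_prevalence_2020 if calibrate_prevalence
            else prevalent / (adults["count"].sum() + child_total) * 1e5
        ),
        "adult_scale": scale,
        "child_total": child_total,
    }
    return out, truth


def gen_life_table(config: GeneratorConfig) -> pd.DataFrame:
    """Period life table frame (year,sex,age,expected_years), 2020-2066.

    Expected remaining years fall linearly with age, improve mildly by
    calendar year, and are lower for males at every age — the structural
    features the life-table scenario consumes.
    """
    y0, y1 = config.life_table_years
    rows = []
    for year in range(y0, y1 + 1):
        improve = 0.02 * (year - y0)
        for sex in SEXES:
            sex_gap = 0.0 if sex == "female" else -2.5
            for age in range(15, 101):
                e = max((104 - age) * 0.82 + improve + sex_gap, 1.5)
                rows.append(
                    {"year": year, "sex": sex, "age": age, "expected_years": e}
                )
    return pd.DataFrame(rows)
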
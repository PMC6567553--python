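"""Incidence and prevalence estimation.

Crude and age/sex-specific rates per 100,000 person-years with exact
Poisson confidence intervals, direct standardization to an external
standard population with a binomial-approximation standard error,
standardized rate ratios (log-normal CI), pooling of two study regions,
and Wilson-interval point prevalence.

Event counts may be fractional: postcode-sector weighting and the 0.5
zero-cell substitution both produce non-integer counts, so the exact
Poisson interval is evaluated through its continuous chi-square form.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .bands import BAND_LABELS, SEXES
from .registry import CountTable, substitute_zero_cells


@dataclasses.dataclass(frozen=True)
class RateEstimate:
    """A rate per 100,000 (person-years for incidence, persons for prevalence)."""

    rate: float
    ci_low: float
    ci_high: float
    ci_level: float
    method: str  # poisson_exact | binomial_se | wilson
    n_events: float
    person_years: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be nonnegative")
        if not self.ci_low <= self.rate <= self.ci_high:
            raise ValueError(
                f"CI ({self.ci_low}, {self.ci_high}) does not bracket rate {self.rate}"
            )

    @property
    def se(self) -> float:
        """Normal-scale SE recovered from the interval width."""
        z = stats.norm.ppf(1 - (1 - self.ci_level) / 2)
        return (self.ci_high - self.ci_low) / (2 * z)


class GridTable:
    """A value per (sex, 5-year band) cell; base for population tables."""

    value_name = "value"

    def __init__(self, values: pd.DataFrame, label: str = "", reference_year: int | None = None):
        values = values.reindex(index=list(BAND_LABELS), columns=list(SEXES))
        if values.isna().any().any():
            raise ValueError(f"{type(self).__name__} does not cover the sex x band grid")
        self.values = values.astype(float)
        self.label = label
        self.reference_year = reference_year

    def __getitem__(self, key: tuple[str, str]) -> float:
        sex, band = key
        return float(self.values.at[band, sex])

    def total(self, sex: str | None = None) -> float:
        if sex is None:
            return float(self.values.to_numpy().sum())
        return float(self.values[sex].sum())


class PopulationTable(GridTable):
    """Mid-year person counts per (sex, band) used as rate denominators."""

    def __init__(self, values, label="", reference_year=None):
        super().__init__(values, label, reference_year)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("population counts must be nonnegative")


class StandardPopulation(GridTable):
    """The external standard (e.g. UK mid-2010) used for direct standardization."""

    def __init__(self, values, label="", reference_year=None):
        super().__init__(values, label, reference_year)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("standard weights must be nonnegative")
        if self.total() <= 0:
            raise ValueError("standard population total must be positive")


def load_population_csv(path, region: str | None = None) -> PopulationTable:
    """Read a population CSV (region,sex,age_band,count,reference_year)."""
    frame = pd.read_csv(path)
    if region is not None:
        frame = frame[frame["region"] == region]
        if frame.empty:
            raise ValueError(f"region {region!r} not present in {path}")
    wide = frame.pivot_table(index="age_band", columns="sex", values="count", aggfunc="sum")
    year = int(frame["reference_year"].iloc[0]) if "reference_year" in frame else None
    label = str(frame["region"].iloc[0]) if "region" in frame else ""
    return PopulationTable(wide, label=label, reference_year=year)


def load_standard_csv(path) -> StandardPopulation:
    frame = pd.read_csv(path)
    wide = frame.pivot_table(index="age_band", columns="sex", values="count", aggfunc="sum")
    label = str(frame["region"].iloc[0]) if "region" in frame else ""
    year = int(frame["reference_year"].iloc[0]) if "reference_year" in frame else None
    return StandardPopulation(wide, label=label, reference_year=year)


class RateTable:
    """A :class:`RateEstimate` per (sex, band) cell plus the study period length."""

    def __init__(self, estimates: dict[tuple[str, str], RateEstimate], study_years: float):
        expected = {(sex, band) for sex in SEXES for band in BAND_LABELS}
        if set(estimates) != expected:
            missing = expected - set(estimates)
            raise ValueError(f"rate table incomplete; missing cells {sorted(missing)[:4]}...")
        self.estimates = estimates
        self.study_years = study_years

    def __getitem__(self, key: tuple[str, str]) -> RateEstimate:
        return self.estimates[key]

    def rate(self, sex: str, band: str) -> float:
        return self.estimates[sex, band].rate

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sex, band), est in sorted(
            self.estimates.items(), key=lambda kv: (kv[0][0], BAND_LABELS.index(kv[0][1]))
        ):
            rows.append(
                {
                    "sex": sex,
                    "age_band": band,
                    "rate": est.rate,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n_events": est.n_events,
                    "person_years": est.person_years,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, study_years: float) -> "RateTable":
        estimates = {}
        for row in frame.itertuples(index=False):
            estimates[row.sex, row.age_band] = RateEstimate(
                rate=float(row.rate),
                ci_low=float(row.ci_low),
                ci_high=float(row.ci_high),
                ci_level=0.95,
                method="poisson_exact",
                n_events=float(row.n_events),
                person_years=float(row.person_years),
            )
        return cls(estimates, study_years)


# ---------------------------------------------------------------------------
# interval machinery


def poisson_exact_ci(k: float, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson interval for an event count.

    ``low`` is the mean whose upper tail mass at ``k`` is (1-level)/2
    (zero when k = 0); ``high`` the mean whose lower tail mass at ``k``
    is (1-level)/2.  Fractional ``k`` — which arises from sector
    weighting and the 0.5 substitution — is handled by the continuous
    chi-square formulation ``low = chi2.ppf(alpha/2, 2k)/2``,
    ``high = chi2.ppf(1-alpha/2, 2k+2)/2``.
    """
    if k < 0:
        raise ValueError("event count must be nonnegative")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1 - level
    low = 0.0 if k == 0 else 0.5 * stats.chi2.ppf(alpha / 2, 2 * k)
    high = 0.5 * stats.chi2.ppf(1 - alpha / 2, 2 * k + 2)
    return float(low), float(high)


def crude_rate(n_events: float, person_years: float, level: float = 0.95) -> RateEstimate:
    """Events per 100,000 person-years with the exact Poisson interval."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    low, high = poisson_exact_ci(n_events, level)
    scale = 1e5 / person_years
    return RateEstimate(
        rate=n_events * scale,
        ci_low=low * scale,
        ci_high=high * scale,
        ci_level=level,
        method="poisson_exact",
        n_events=n_events,
        person_years=person_years,
    )


def wilson_ci(k: float, n: float, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a proportion k/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if k < 0 or k > n:
        raise ValueError("k must lie in [0, n]")
    z = stats.norm.ppf(1 - (1 - level) / 2)
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    low = 0.0 if k == 0 else max(0.0, centre - half)  # exact at the boundaries
    high = 1.0 if k == n else min(1.0, centre + half)
    return float(low), float(high)


# ---------------------------------------------------------------------------
# rate tables


def specific_rates(
    counts: CountTable, pop: PopulationTable, study_years: float, level: float = 0.95
) -> RateTable:
    """Age/sex-specific rates: count / (population x study years) per cell.

    Person-years per cell are the mid-period population multiplied by the
    study length (14 years for a 2004-2017 window), mirroring the use of
    a single census-year denominator.
    """
    if study_years <= 0:
        raise ValueError("study_years must be positive")
    estimates = {}
    for sex in SEXES:
        for band in BAND_LABELS:
            denom = pop[sex, band]
            if denom <= 0:
                raise ValueError(f"zero population in cell ({sex}, {band})")
            estimates[sex, band] = crude_rate(counts[sex, band], denom * study_years, level)
    return RateTable(estimates, study_years)


def direct_standardize(
    rates: RateTable,
    standard: StandardPopulation,
    sex: str | None = None,
    level: float = 0.95,
) -> RateEstimate:
    """Directly standardized rate: standard-population-weighted mean of cell rates.

    ``sex=None`` gives the overall rate, with each sex's cell rates
    weighted by that sex's own standard counts.  The CI comes from
    :func:`standardized_rate_se` with the standard's total as the
    effective denominator.
    """
    sexes = SEXES if sex is None else (sex,)
    num = 0.0
    den = 0.0
    events = 0.0
    pys = 0.0
    for s in sexes:
        for band in BAND_LABELS:
            w = standard[s, band]
            est = rates[s, band]
            num += est.rate * w
            den += w
            events += est.n_events
            pys += est.person_years
    if den <= 0:
        raise ValueError("standard population weights sum to zero")
    std_rate = num / den
    se, low, high = standardized_rate_se(std_rate, den, level)
    return RateEstimate(
        rate=std_rate,
        ci_low=low,
        ci_high=high,
        ci_level=level,
        method="binomial_se",
        n_events=events,
        person_years=pys,
    )


def standardized_rate_se(
    std_rate: float, effective_n: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Binomial-approximation SE for a standardized rate.

    The per-100,000 rate is treated as a proportion p with denominator
    the standard population total: se = sqrt(p(1-p)/n), CI = p +/- z*se,
    rescaled to per-100,000 and floored at zero.
    """
    if effective_n <= 0:
        raise ValueError("effective_n must be positive")
    p = std_rate / 1e5
    if not 0 <= p <= 1:
        raise ValueError("standardized rate outside the proportion range")
    se = float(np.sqrt(p * (1 - p) / effective_n))
    z = stats.norm.ppf(1 - (1 - level) / 2)
    low = max(0.0, (p - z * se) * 1e5)
    high = (p + z * se) * 1e5
    return se * 1e5, low, high


def standardized_rate_ratio(
    r1: RateEstimate, r2: RateEstimate, level: float = 0.95
) -> tuple[float, float, float]:
    """Ratio of two standardized rates with a log-normal confidence interval.

    Var(log ratio) is approximated by (se1/r1)^2 + (se2/r2)^2 using the
    SEs recovered from each rate's interval.
    """
    if r2.rate <= 0:
        raise ValueError("reference rate must be positive")
    ratio = r1.rate / r2.rate
    se_log = np.sqrt((r1.se / r1.rate) ** 2 + (r2.se / r2.rate) ** 2)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    return float(ratio), float(ratio * np.exp(-z * se_log)), float(ratio * np.exp(z * se_log))


def pool_regions(
    counts_a: CountTable,
    pop_a: PopulationTable,
    counts_b: CountTable,
    pop_b: PopulationTable,
    study_years: float,
    level: float = 0.95,
) -> tuple[RateTable, CountTable, PopulationTable]:
    """Pool two regions cellwise and recompute rates on the pooled grid.

    Counts add, populations add.  The 0.5 substitution is re-evaluated on
    the pooled table — only cells still at zero after pooling are
    substituted, so one region's real cases rescue the other's empty
    cells.  Pre-pooling substitutions are undone first.
    """
    pooled_counts = CountTable(study_years=study_years)
    for sex in SEXES:
        for band in BAND_LABELS:
            a = 0.0 if (sex, band) in counts_a.substituted else counts_a[sex, band]
            b = 0.0 if (sex, band) in counts_b.substituted else counts_b[sex, band]
            pooled_counts.set(sex, band, a + b)
    pooled_counts = substitute_zero_cells(pooled_counts)
    pooled_pop = PopulationTable(
        pop_a.values + pop_b.values,
        label=f"{pop_a.label}+{pop_b.label}".strip("+"),
        reference_year=pop_a.reference_year,
    )
    return specific_rates(pooled_counts, pooled_pop, study_years, level), pooled_counts, pooled_pop


def point_prevalence(
    n_alive: float, population: float, date_label: str = "", level: float = 0.95
) -> RateEstimate:
    """Point prevalence per 100,000 persons with a Wilson interval.

    ``n_alive`` is the count of cases diagnosed after the register's
    ascertainment start and alive on the prevalence date.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    low, high = wilson_ci(n_alive, population, level)
    return RateEstimate(
        rate=n_alive / population * 1e5,
        ci_low=low * 1e5,
        ci_high=high * 1e5,
        ci_level=level,
        method="wilson",
        n_events=n_alive,
        person_years=population,
    )
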
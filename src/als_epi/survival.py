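"""Kaplan-Meier estimation of disease duration.

Duration runs from symptom onset to death or last follow-up, in whole
months.  The product-limit estimator, its Greenwood variance, the median
with a Brookmeyer-Crowley (log-log transformed) confidence interval, and
the restricted mean are implemented here directly; an established
survival library is used only as an independent cross-check in the test
suite.  Estimates are produced for three age cohorts (<40, 40-79, 80+)
and overall, because age at diagnosis is the dominant prognostic factor
for this disease.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bands import COHORT_LABELS, cohort_of_age
from .registry import CaseRecord


@dataclasses.dataclass(frozen=True)
class SurvivalSample:
    """One subject's follow-up: months from onset, event flag, age cohort."""

    duration_months: float
    event: int  # 1 = died, 0 = censored
    age_cohort: str

    def __post_init__(self) -> None:
        if self.duration_months <= 0:
            raise ValueError("duration must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclasses.dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate at the distinct event times.

    ``var_factor`` is the cumulative Greenwood sum d/(n(n-d)), from which
    Var S(t) = S(t)^2 * var_factor(t).
    """

    times: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    var_factor: np.ndarray
    n_subjects: int
    max_observed: float  # largest observed time, event or censored

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (S = 1 before the first event)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def duration_in_months(start, end) -> int:
    """Whole months between two dates, rounded down; minimum one month.

    Medians are reported in integer months, so fractional months are
    floored; a same-month follow-up is recorded as one month rather than
    zero so the subject still contributes to the risk set.
    """
    if end < start:
        raise ValueError("end date precedes start date")
    months = (end.year - start.year) * 12 + (end.month - start.month)
    if end.day < start.day:
        months -= 1
    return max(months, 1)


def samples_from_cases(cases: Iterable[CaseRecord]) -> list[SurvivalSample]:
    """Build survival samples from registry records that passed the
    survival-purpose exclusions (onset date and age both present)."""
    samples = []
    for case in cases:
        if case.date_of_onset is None or case.end_date is None:
            raise ValueError(f"case {case.patient_id}: missing dates for survival")
        if case.age_at_diagnosis is None:
            raise ValueError(f"case {case.patient_id}: missing age for cohorting")
        samples.append(
            SurvivalSample(
                duration_months=duration_in_months(case.date_of_onset, case.end_date),
                event=1 if case.end_event == "died" else 0,
                age_cohort=cohort_of_age(case.age_at_diagnosis),
            )
        )
    return samples


def km_fit(samples: Sequence[SurvivalSample]) -> KMCurve:
    """Product-limit estimator with events-first tie handling.

    A censoring at time t leaves the risk set after the events at t have
    been counted, the standard convention.
    """
    if len(samples) == 0:
        raise ValueError("cannot fit a survival curve to an empty sample")
    durations = np.array([s.duration_months for s in samples], dtype=float)
    events = np.array([s.event for s in samples], dtype=int)

    order = np.argsort(durations, kind="stable")
    durations, events = durations[order], events[order]

    event_times = np.unique(durations[events == 1])
    n = len(samples)
    n_risk = np.empty(len(event_times))
    d = np.empty(len(event_times))
    for i, t in enumerate(event_times):
        n_risk[i] = np.sum(durations >= t)
        d[i] = np.sum((durations == t) & (events == 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / n_risk)
        greenwood_terms = np.where(n_risk > d, d / (n_risk * (n_risk - d)), np.inf)
    return KMCurve(
        times=event_times,
        n_risk=n_risk,
        n_events=d,
        survival=surv,
        var_factor=np.cumsum(greenwood_terms),
        n_subjects=n,
        max_observed=float(durations.max()),
    )


def km_median(curve: KMCurve, level: float = 0.95) -> tuple[float, float, tuple[float, float]]:
    """Median survival time with a Brookmeyer-Crowley confidence interval.

    The median is the smallest event time with S(t) <= 0.5; NaN when the
    curve never reaches 0.5.  The CI is the set of event times at which
    the hypothesis S(t) = 0.5 is not rejected at the stated level, using
    the log(-log S) transform with Greenwood variance; the SE is reported
    as the CI width over 2z.  Unbounded interval ends are NaN.
    """
    z = stats.norm.ppf(1 - (1 - level) / 2)
    below = np.nonzero(curve.survival <= 0.5)[0]
    median = float(curve.times[below[0]]) if below.size else math.nan

    lo = hi = math.nan
    target = math.log(-math.log(0.5))
    in_set = []
    for i, t in enumerate(curve.times):
        s = curve.survival[i]
        if not 0.0 < s < 1.0:
            continue
        se_loglog = math.sqrt(curve.var_factor[i]) / abs(math.log(s))
        if abs((math.log(-math.log(s)) - target) / se_loglog) <= z:
            in_set.append((i, float(t)))
    if in_set:
        lo = in_set[0][1]
        # the upper bound is open when the confidence set runs to the end
        last_idx = in_set[-1][0]
        hi = in_set[-1][1] if last_idx < len(curve.times) - 1 else math.nan
    se = (hi - lo) / (2 * z) if not (math.isnan(lo) or math.isnan(hi)) else math.nan
    return median, se, (lo, hi)


def km_mean_restricted(
    curve: KMCurve, tau: float | None = None
) -> tuple[float, float]:
    """Restricted mean survival: area under S up to tau.

    ``tau`` defaults to the largest event time.  The SE uses the
    standard Greenwood-based area formula
    Var = sum_i A_i^2 d_i / (n_i (n_i - d_i)) with A_i the area under S
    from t_i to tau.
    """
    if tau is None:
        tau = float(curve.times[-1]) if curve.times.size else curve.max_observed
    if tau <= 0:
        raise ValueError("tau must be positive")
    knots = np.concatenate(([0.0], curve.times[curve.times < tau], [tau]))
    heights = np.concatenate(([1.0], curve.survival[curve.times < tau]))
    area_segments = heights * np.diff(knots)
    mean = float(area_segments.sum())

    # A_i = area under S over (t_i, tau], accumulated from the right
    var = 0.0
    for i in range(len(curve.times)):
        t_i = curve.times[i]
        if t_i >= tau:
            break
        mask = knots[1:] > t_i
        a_i = float(area_segments[mask].sum())
        n_i, d_i = curve.n_risk[i], curve.n_events[i]
        if n_i > d_i:
            var += a_i**2 * d_i / (n_i * (n_i - d_i))
        else:
            var = math.inf
    return mean, math.sqrt(var)


def survival_by_age_cohort(
    samples: Sequence[SurvivalSample], level: float = 0.95
) -> pd.DataFrame:
    """Mean and median duration per age cohort and overall.

    Returns one row per cohort plus "overall", with columns cohort, n,
    mean, mean_se, mean_ci_low/high, median, median_se,
    median_ci_low/high and a flag for cohorts with fewer than two
    subjects.  Row layout mirrors the standard reporting table.
    """
    z = stats.norm.ppf(1 - (1 - level) / 2)
    rows = []
    groups = list(COHORT_LABELS) + ["overall"]
    for cohort in groups:
        sub = (
            list(samples)
            if cohort == "overall"
            else [s for s in samples if s.age_cohort == cohort]
        )
        if not sub:
            rows.append({"cohort": cohort, "n": 0, "flagged": True})
            continue
        curve = km_fit(sub)
        median, med_se, (med_lo, med_hi) = km_median(curve, level)
        mean, mean_se = km_mean_restricted(curve)
        rows.append(
            {
                "cohort": cohort,
                "n": len(sub),
                "mean": mean,
                "mean_se": mean_se,
                "mean_ci_low": mean - z * mean_se,
                "mean_ci_high": mean + z * mean_se,
                "median": median,
                "median_se": med_se,
                "median_ci_low": med_lo,
                "median_ci_high": med_hi,
                "flagged": len(sub) < 2,
            }
        )
    return pd.DataFrame(rows).set_index("cohort")


def duration_table(samples: Sequence[SurvivalSample], level: float = 0.95) -> dict[str, float]:
    """Median months per cohort plus overall, as consumed by the projector."""
    table = survival_by_age_cohort(samples, level)
    return {cohort: float(table.loc[cohort, "median"]) for cohort in table.index}
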
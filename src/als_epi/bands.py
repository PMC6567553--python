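"""Age-band scheme shared across the pipeline.

The study grid is sixteen 5-year bands per sex, from 15-19 up to 85-89,
with an open-ended 90+ band.  Under-15s are outside the scheme: ALS is an
adult-onset disease and the incidence denominators start at age 15.

Duration (survival) cohorts are coarser: <40, 40-79, 80+.
"""

from __future__ import annotations

SEXES: tuple[str, str] = ("male", "female")

#: Ordered band labels, "15-19" ... "85-89", "90+".
BAND_LABELS: tuple[str, ...] = tuple(
    f"{lo}-{lo + 4}" for lo in range(15, 90, 5)
) + ("90+",)

#: Lower edge of each band, aligned with BAND_LABELS.
BAND_LOWER: tuple[int, ...] = tuple(range(15, 90, 5)) + (90,)

#: Survival cohorts used for duration modelling, in display order.
COHORT_LABELS: tuple[str, str, str] = ("<40", "40-79", "80+")

MIN_AGE = 15


def band_of_age(age: float) -> str:
    """Map an age in years to its 5-year band label.

    Ages of 90 and above pool into the open band.  Ages below 15 are
    outside the scheme and raise ``ValueError``.
    """
    if age < MIN_AGE:
        raise ValueError(f"age {age} is below the band scheme minimum of {MIN_AGE}")
    if age >= 90:
        return "90+"
    lo = int(age) - (int(age) - 15) % 5
    return f"{lo}-{lo + 4}"


def cohort_of_age(age: float) -> str:
    """Map an age to its duration cohort: <40, 40-79, or 80+."""
    if age < 40:
        return "<40"
    if age < 80:
        return "40-79"
    return "80+"


def cohort_of_band(band: str) -> str:
    """Map a 5-year band to the duration cohort that supplies its median.

    Bands 15-39 map to "<40", 40-79 to "40-79", 85-89 and 90+ to "80+".
    """
    if band not in BAND_LABELS:
        raise KeyError(f"unknown age band {band!r}")
    lo = BAND_LOWER[BAND_LABELS.index(band)]
    return cohort_of_age(lo)


def representative_age(band: str) -> float:
    """Midpoint age of a band; 92 for the open 90+ band."""
    if band == "90+":
        return 92.0
    lo = BAND_LOWER[BAND_LABELS.index(band)]
    return lo + 2.0
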
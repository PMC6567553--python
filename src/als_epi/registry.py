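"""Case-registry ingest: load, validate, exclude, weight, and bin cases.

The registry is a CSV with one row per patient referred to a motor nerve
clinic.  This module turns it into the weighted sex x age-band count table
that the incidence estimators consume, applying the study's exclusion
rules (non-MND diagnoses, missing age at diagnosis, and — for survival —
missing date of onset) and fractional postcode-sector catchment weights.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bands import BAND_LABELS, SEXES, band_of_age

VALID_SEXES = frozenset(SEXES)
VALID_DIAGNOSES = frozenset(
    {"ALS", "PLS", "PMA", "pseudobulbar_palsy", "kennedys", "LMN_syndrome", "other"}
)
#: Diagnoses retained for incidence and survival (all El Escorial categories kept).
INCLUDED_DIAGNOSES = frozenset({"ALS", "PLS", "PMA", "pseudobulbar_palsy"})
VALID_EL_ESCORIAL = frozenset(
    {"definite", "probable", "probable_lab", "possible", "suspected", "missing"}
)

CASE_COLUMNS = [
    "patient_id",
    "sex",
    "date_of_onset",
    "date_of_diagnosis",
    "age_at_diagnosis",
    "end_date",
    "end_event",
    "diagnosis",
    "el_escorial",
    "sector_id",
]


class RegistryError(ValueError):
    """Raised for malformed registry files or rows."""


@dataclasses.dataclass(frozen=True)
class CaseRecord:
    """One registry row.

    Missing values are ``None``; they are preserved, never imputed.
    ``end_event`` is "died" or "censored"; a missing end_event is treated
    as censored at ``end_date``.
    """

    patient_id: str
    sex: str
    date_of_onset: _dt.date | None
    date_of_diagnosis: _dt.date | None
    age_at_diagnosis: float | None
    end_date: _dt.date | None
    end_event: str
    diagnosis: str
    el_escorial: str
    sector_id: str


@dataclasses.dataclass(frozen=True)
class SectorOverlap:
    """Fraction of a postcode sector lying inside the study catchment."""

    sector_id: str
    fraction_in_catchment: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_in_catchment <= 1.0:
            raise ValueError(
                f"sector {self.sector_id}: fraction {self.fraction_in_catchment} "
                "outside [0, 1]"
            )


class CountTable:
    """Weighted case counts on the sex x 5-year-band grid.

    Backed by a DataFrame indexed by band label with one column per sex.
    Counts may be fractional (sector weighting) or 0.5 (zero-cell
    substitution); ``substituted`` records which cells were substituted.
    """

    def __init__(
        self,
        counts: pd.DataFrame | None = None,
        study_years: float | None = None,
        substituted: frozenset[tuple[str, str]] = frozenset(),
    ) -> None:
        if counts is None:
            counts = pd.DataFrame(0.0, index=list(BAND_LABELS), columns=list(SEXES))
        if list(counts.index) != list(BAND_LABELS) or list(counts.columns) != list(SEXES):
            counts = counts.reindex(index=list(BAND_LABELS), columns=list(SEXES))
            if counts.isna().any().any():
                raise ValueError("count table does not cover the full sex x band grid")
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")
        self.counts = counts.astype(float)
        self.study_years = study_years
        self.substituted = substituted

    def __getitem__(self, key: tuple[str, str]) -> float:
        sex, band = key
        return float(self.counts.at[band, sex])

    def set(self, sex: str, band: str, value: float) -> None:
        self.counts.at[band, sex] = value

    def total(self) -> float:
        return float(self.counts.to_numpy().sum())

    def copy(self) -> "CountTable":
        return CountTable(self.counts.copy(), self.study_years, self.substituted)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CountTable(total={self.total():.1f}, study_years={self.study_years})"


def _parse_date(value, row: int, field: str, errors: list[str]) -> _dt.date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    try:
        return _dt.date.fromisoformat(str(value).strip())
    except ValueError:
        errors.append(f"row {row}: malformed {field} {value!r} (expected ISO-8601)")
        return None


def load_cases(path: str | Path) -> list[CaseRecord]:
    """Read a case-registry CSV into validated :class:`CaseRecord` objects.

    Raises :class:`RegistryError` listing every offending row if any row
    has a malformed date, an unknown sex/diagnosis code, or an end date
    before the onset date.  Missing values pass through as ``None`` (or
    ``"missing"`` for El Escorial); nothing is imputed.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise RegistryError(f"cannot read registry file {path}: {exc}") from exc
    return cases_from_frame(frame, source=str(path))


def cases_from_frame(frame: pd.DataFrame, source: str = "<frame>") -> list[CaseRecord]:
    """Validate an in-memory registry table (string-typed, '' = missing)."""
    frame = frame.astype(str).replace({"nan": "", "None": ""})
    missing_cols = set(CASE_COLUMNS) - set(frame.columns)
    if missing_cols:
        raise RegistryError(f"{source}: missing columns {sorted(missing_cols)}")

    records: list[CaseRecord] = []
    errors: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # 1 = header
        sex = row.sex.strip()
        if sex not in VALID_SEXES:
            errors.append(f"row {i}: unknown sex code {sex!r}")
        diagnosis = row.diagnosis.strip()
        if diagnosis not in VALID_DIAGNOSES:
            errors.append(f"row {i}: unknown diagnosis code {diagnosis!r}")
        el = row.el_escorial.strip() or "missing"
        if el not in VALID_EL_ESCORIAL:
            errors.append(f"row {i}: unknown El Escorial category {el!r}")
        end_event = row.end_event.strip() or "censored"
        if end_event not in {"died", "censored"}:
            errors.append(f"row {i}: unknown end_event {end_event!r}")
        onset = _parse_date(row.date_of_onset, i, "date_of_onset", errors)
        dx_date = _parse_date(row.date_of_diagnosis, i, "date_of_diagnosis", errors)
        end = _parse_date(row.end_date, i, "end_date", errors)
        age: float | None
        if row.age_at_diagnosis.strip() == "":
            age = None
        else:
            try:
                age = float(row.age_at_diagnosis)
                if age < 0:
                    errors.append(f"row {i}: negative age_at_diagnosis {age}")
            except ValueError:
                errors.append(
                    f"row {i}: malformed age_at_diagnosis {row.age_at_diagnosis!r}"
                )
                age = None
        if onset is not None and end is not None and end < onset:
            errors.append(f"row {i}: end_date {end} precedes date_of_onset {onset}")
        records.append(
            CaseRecord(
                patient_id=row.patient_id,
                sex=sex,
                date_of_onset=onset,
                date_of_diagnosis=dx_date,
                age_at_diagnosis=age,
                end_date=end,
                end_event=end_event,
                diagnosis=diagnosis,
                el_escorial=el,
                sector_id=row.sector_id.strip(),
            )
        )
    if errors:
        raise RegistryError(
            f"{source}: {len(errors)} invalid record(s):\n" + "\n".join(errors)
        )
    return records


def load_sector_overlaps(path: str | Path) -> dict[str, SectorOverlap]:
    """Read the sector-overlap CSV (sector_id, fraction_in_catchment)."""
    frame = pd.read_csv(path, dtype={"sector_id": str})
    return {
        str(r.sector_id): SectorOverlap(str(r.sector_id), float(r.fraction_in_catchment))
        for r in frame.itertuples(index=False)
    }


def apply_exclusions(
    cases: Sequence[CaseRecord], purpose: str
) -> tuple[list[CaseRecord], "OrderedDict[str, int]"]:
    """Apply the study exclusion rules, returning kept cases and an audit.

    Rules, in fixed order so audits are reproducible:

    1. ``diagnosis`` — drop Kennedy's disease, unspecified lower motor
       neuron syndromes, and other non-MND diagnoses.  ALS, PLS, PMA and
       pure pseudobulbar palsy are kept in every El Escorial category,
       including "suspected" and missing.
    2. ``missing_age`` — drop records with no age at diagnosis.
    3. ``missing_onset`` — survival only: drop records with no onset date
       (duration is measured from symptom onset).

    The audit tallies plus the kept count always equal the input count.
    """
    if purpose not in {"incidence", "survival"}:
        raise ValueError(f"unknown purpose {purpose!r}")
    audit: OrderedDict[str, int] = OrderedDict(
        [("diagnosis", 0), ("missing_age", 0), ("missing_onset", 0)]
    )
    kept: list[CaseRecord] = []
    for case in cases:
        if case.diagnosis not in INCLUDED_DIAGNOSES:
            audit["diagnosis"] += 1
        elif case.age_at_diagnosis is None:
            audit["missing_age"] += 1
        elif purpose == "survival" and case.date_of_onset is None:
            audit["missing_onset"] += 1
        else:
            kept.append(case)
    return kept, audit


def weight_by_sector(
    cases: Sequence[CaseRecord],
    overlaps: dict[str, SectorOverlap],
    default_weight: float | None = None,
) -> list[tuple[CaseRecord, float]]:
    """Attach the catchment fraction of each case's postcode sector as its weight.

    A case in an unknown sector raises unless ``default_weight`` is given.
    """
    weighted: list[tuple[CaseRecord, float]] = []
    for case in cases:
        overlap = overlaps.get(case.sector_id)
        if overlap is None:
            if default_weight is None:
                raise RegistryError(
                    f"case {case.patient_id}: sector {case.sector_id!r} not in "
                    "overlap table and no default weight configured"
                )
            weighted.append((case, default_weight))
        else:
            weighted.append((case, overlap.fraction_in_catchment))
    return weighted


def bin_cases(
    weighted_cases: Iterable[tuple[CaseRecord, float]], study_years: float
) -> CountTable:
    """Sum case weights into (sex, 5-year band) cells keyed by age at diagnosis.

    Ages of 90+ pool into the open band; ages below 15 are an error.
    """
    table = CountTable(study_years=study_years)
    for case, weight in weighted_cases:
        if case.age_at_diagnosis is None:
            raise RegistryError(
                f"case {case.patient_id}: cannot bin without age_at_diagnosis"
            )
        band = band_of_age(case.age_at_diagnosis)
        table.set(case.sex, band, table[case.sex, band] + weight)
    return table


def substitute_zero_cells(table: CountTable) -> CountTable:
    """Replace exactly-zero cells with 0.5 so every cell yields a finite rate.

    Positive fractional counts below 0.5 are left untouched; only exact
    zeros are substituted.  Substituted cells are flagged in metadata.
    """
    out = table.copy()
    substituted = set(table.substituted)
    for sex in SEXES:
        for band in BAND_LABELS:
            if out[sex, band] == 0.0:
                out.set(sex, band, 0.5)
                substituted.add((sex, band))
    out.substituted = frozenset(substituted)
    return out


def audit_to_dict(audit: "OrderedDict[str, int]", kept: int, total: int) -> dict:
    """Flowchart-shaped audit payload for JSON export."""
    return {"input": total, "excluded": dict(audit), "kept": kept}
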
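"""Endpoint construction: HFD-90, 90-day secondary outcomes, analysis cohorts.

Day-counting conventions (fixed so the arithmetic is reproducible):

* day 0 is the day of surgery; the follow-up window is days ``[0, 90)``;
* a patient discharged on day ``d`` is out of hospital from day ``d``
  onward, so an uncomplicated discharge on day 2 scores 88;
* readmission intervals are half-open ``[start, end)`` day ranges;
* any death on or before day 90 scores -1, regardless of hospital days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import HospitalCourse, Patient
from .errors import DataIntegrityError, EndpointUndefinedError

__all__ = [
    "HFDOutcome",
    "SecondaryOutcomes",
    "compute_hfd90",
    "compute_secondary",
    "build_cohorts",
    "outcomes_frame",
]


@dataclass(frozen=True)
class HFDOutcome:
    """The ordinal primary endpoint, an integer in {-1, 0, 1, ..., 90}."""

    value: int

    def __post_init__(self):
        if not -1 <= self.value <= 90:
            raise ValueError(f"HFD-90 must lie in [-1, 90], got {self.value}")


@dataclass(frozen=True)
class SecondaryOutcomes:
    """90-day binary/time-to-event secondary endpoints for one patient."""

    reoperation_90: bool
    reoperation_time: int | None
    readmission_90: bool
    readmission_time: int | None
    morbidity_90: bool
    morbidity_time: int | None
    mortality_90: bool
    mortality_time: int | None
    index_los_days: int
    censor_day: int
    excluded_from_tte: bool


def compute_hfd90(course: HospitalCourse) -> HFDOutcome:
    """Score one hospital course on the HFD-90 composite.

    -1 for death intraoperatively or within 90 postoperative days; 0 for
    patients alive but never discharged within the window; otherwise the
    count of days in ``[0, 90)`` spent alive and out of hospital.

    Raises ``EndpointUndefinedError`` if no surgery was performed (such
    patients are excluded upstream when building analysis cohorts).
    """
    course.validate()
    if not course.surgery_performed:
        raise EndpointUndefinedError(
            f"HFD-90 undefined for {course.patient_id}: surgery not performed"
        )
    if course.death_day is not None:
        return HFDOutcome(-1)
    if course.discharge_day is None:
        return HFDOutcome(0)
    d = course.discharge_day
    in_hospital_after = sum(
        max(0, min(e, 90) - max(s, d)) for s, e in course.readmission_intervals
    )
    value = 90 - d - in_hospital_after
    return HFDOutcome(max(0, value))


def compute_secondary(course: HospitalCourse) -> SecondaryOutcomes:
    """Derive the 90-day secondary endpoints from one hospital course.

    Patients who withdrew are flagged for exclusion from time-to-event
    analyses (the default handling; censoring at withdrawal is a
    downstream choice).
    """
    course.validate()
    death = course.death_day
    readmit_time = (
        course.readmission_intervals[0][0] if course.readmission_intervals else None
    )
    if course.discharge_day is not None:
        index_los = course.discharge_day
    elif death is not None:
        index_los = death
    else:
        index_los = 90
    censor = 90 if death is None else death
    return SecondaryOutcomes(
        reoperation_90=course.reoperation_day is not None,
        reoperation_time=course.reoperation_day,
        readmission_90=readmit_time is not None,
        readmission_time=readmit_time,
        morbidity_90=course.morbidity_day is not None,
        morbidity_time=course.morbidity_day,
        mortality_90=death is not None,
        mortality_time=death,
        index_los_days=index_los,
        censor_day=censor,
        excluded_from_tte=course.withdrew,
    )


def build_cohorts(
    patients: Sequence[Patient],
    assignments: Mapping[str, object],
    courses: Iterable[HospitalCourse],
) -> tuple[list[str], list[str]]:
    """Build the intention-to-treat and per-protocol analysis sets.

    ITT: randomized patients who underwent surgery.  PPA: ITT patients who
    were adherent and did not withdraw.  Returns the two sets as lists of
    patient ids; PPA is a subset of ITT by construction.

    Raises ``DataIntegrityError`` on duplicated patient ids.
    """
    ids = [p.patient_id for p in patients]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataIntegrityError(f"duplicated patient ids: {dupes}")
    course_by_id: dict[str, HospitalCourse] = {}
    for c in courses:
        if c.patient_id in course_by_id:
            raise DataIntegrityError(f"duplicated course for {c.patient_id}")
        course_by_id[c.patient_id] = c
    itt, ppa = [], []
    for pid in ids:
        if pid not in assignments or pid not in course_by_id:
            continue
        c = course_by_id[pid]
        if not c.surgery_performed:
            continue
        itt.append(pid)
        if c.adherent and not c.withdrew:
            ppa.append(pid)
    return itt, ppa


def outcomes_frame(courses: Sequence[HospitalCourse]) -> pd.DataFrame:
    """One row per operated patient: HFD-90 plus all secondary endpoints."""
    rows = []
    for c in courses:
        if not c.surgery_performed:
            continue
        sec = compute_secondary(c)
        rows.append(
            {
                "patient_id": c.patient_id,
                "hfd90": compute_hfd90(c).value,
                **{k: getattr(sec, k) for k in sec.__dataclass_fields__},
            }
        )
    return pd.DataFrame(rows)
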
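"""Core record types for longitudinal nursing-home resident data.

A cohort is a list of :class:`ResidentRecord` objects.  Each record carries a
resident's stay dates, demographics, timestamped clinical observations, Braden
assessments, pressure-injury (PrI) events and a weight series (used together
with height to derive BMI).  Dates are :class:`datetime.date`; stays are the
half-open interval ``[admission_date, end_date)`` with ``end_date`` the
discharge / death / end-of-period date.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)


class RecordError(ValueError):
    """A resident record violates a structural invariant."""


@dataclass(frozen=True)
class Observation:
    """One timestamped numeric clinical observation.

    ``value`` is the observed quantity in the indicator's metric; for
    clinician-coded qualitative findings the value is the coded 1-4 severity
    itself.  For locomotion indicators the value is the number of assistance
    events documented on ``date``.
    """

    resident_id: str
    indicator_id: str
    date: dt.date
    value: float
    sex_context: Optional[str] = None

    def __post_init__(self) -> None:
        v = float(self.value)
        if v != v or v in (float("inf"), float("-inf")):
            raise RecordError(
                f"non-finite value for {self.indicator_id} on {self.date}"
            )


@dataclass
class ResidentRecord:
    """One resident's stay, demographics and longitudinal data."""

    resident_id: str
    sex: str
    age: float
    race_ethnicity: str
    admission_date: dt.date
    end_date: dt.date
    end_reason: str = "period_end"
    height_cm: Optional[float] = None
    observations: list[Observation] = field(default_factory=list)
    braden_assessments: list = field(default_factory=list)  # BradenAssessment
    pri_events: list[dt.date] = field(default_factory=list)
    weights: list[tuple[dt.date, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise RecordError(
                f"resident {self.resident_id}: sex must be one of {SEXES}, "
                f"got {self.sex!r}"
            )
        if self.admission_date > self.end_date:
            raise RecordError(
                f"resident {self.resident_id}: admission_date after end_date"
            )
        self.pri_events = sorted(self.pri_events)

    # -- derived -----------------------------------------------------------
    @property
    def stay_days(self) -> int:
        return (self.end_date - self.admission_date).days

    @property
    def first_pri_date(self) -> Optional[dt.date]:
        return self.pri_events[0] if self.pri_events else None

    @property
    def has_pri(self) -> bool:
        return bool(self.pri_events)

    def bmi_series(self) -> list[tuple[dt.date, float]]:
        """BMI (kg/m^2) at each weight measurement; empty without height."""
        if not self.height_cm or self.height_cm <= 0:
            return []
        m2 = (self.height_cm / 100.0) ** 2
        return [(d, w / m2) for d, w in self.weights]

    def validate(self) -> None:
        """Check temporal invariants; raise :class:`RecordError` on violation."""
        for obs in self.observations:
            if not (self.admission_date <= obs.date < self.end_date):
                raise RecordError(
                    f"resident {self.resident_id}: observation of "
                    f"{obs.indicator_id} on {obs.date} outside stay "
                    f"[{self.admission_date}, {self.end_date})"
                )
        for d in self.pri_events:
            if not (self.admission_date <= d <= self.end_date):
                raise RecordError(
                    f"resident {self.resident_id}: PrI event on {d} "
                    f"outside stay"
                )
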
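"""Braden scale totals, window summaries and risk categories.

The Braden Scale for Predicting Pressure Sore Risk has six subscales —
sensory perception, mobility, activity, moisture, nutrition (each rated 1-4)
and friction/shear (rated 1-3) — summed to a 6-23 total; lower totals mean
worse risk.  Cohort summaries used downstream are the First (earliest in the
observation period), MEAN (arithmetic mean over the period) and Worst
(minimum within the 92-day exposure window) totals.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from statistics import fmean
from typing import Optional, Sequence

from .windows import ExposureWindow

SUBSCALES_1_4 = (
    "sensory_perception",
    "mobility",
    "activity",
    "moisture",
    "nutrition",
)
FRICTION_SHEAR = "friction_shear"

RISK_LOW = "low"
RISK_MILD = "mild"
RISK_MODERATE = "moderate"
RISK_HIGH = "high"
RISK_CATEGORIES = (RISK_LOW, RISK_MILD, RISK_MODERATE, RISK_HIGH)


class BradenError(ValueError):
    pass


@dataclass(frozen=True)
class BradenAssessment:
    resident_id: str
    date: dt.date
    sensory_perception: int
    mobility: int
    activity: int
    moisture: int
    nutrition: int
    friction_shear: int

    def __post_init__(self) -> None:
        for name in SUBSCALES_1_4:
            v = getattr(self, name)
            if not 1 <= v <= 4:
                raise BradenError(
                    f"{self.resident_id} {self.date}: subscale {name}={v} "
                    "outside 1-4"
                )
        if not 1 <= self.friction_shear <= 3:
            raise BradenError(
                f"{self.resident_id} {self.date}: friction_shear="
                f"{self.friction_shear} outside 1-3"
            )

    @property
    def total(self) -> int:
        return braden_total(self)


def braden_total(assessment: BradenAssessment) -> int:
    """Sum of the six subscales (6-23 possible)."""
    return (
        sum(getattr(assessment, name) for name in SUBSCALES_1_4)
        + assessment.friction_shear
    )


def risk_category(total: int) -> str:
    """Braden risk band: 19-23 low, 15-18 mild, 13-14 moderate, <=12 high.

    The published bands stop at 10, but any admissible total down to 6 is a
    valid score; totals 6-9 extend the bottom (high-risk) band.
    """
    total = int(total)
    if not 6 <= total <= 23:
        raise BradenError(f"Braden total {total} outside 6-23")
    if total >= 19:
        return RISK_LOW
    if total >= 15:
        return RISK_MILD
    if total >= 13:
        return RISK_MODERATE
    return RISK_HIGH


@dataclass(frozen=True)
class BradenSummary:
    """First / MEAN / Worst Braden totals over a period and window."""

    braden_first: int
    braden_mean: float
    braden_worst: Optional[int]
    n_period: int
    n_window: int

    @property
    def worst_risk_category(self) -> Optional[str]:
        return None if self.braden_worst is None else risk_category(self.braden_worst)


def summarize_braden(
    assessments: Sequence[BradenAssessment],
    period: tuple[dt.date, dt.date],
    window: ExposureWindow,
) -> BradenSummary:
    """Summarise assessments: First and MEAN over the (half-open) period,
    Worst (= numeric minimum, most severe) over the exposure window.

    Raises :class:`BradenError` with no assessment in the period; an empty
    window yields ``braden_worst=None`` (reported absent, for the caller to
    log).
    """
    p_start, p_end = period
    in_period = sorted(
        (a for a in assessments if p_start <= a.date < p_end),
        key=lambda a: a.date,
    )
    if not in_period:
        raise BradenError(
            f"no Braden assessment in period [{p_start}, {p_end})"
        )
    in_window = [a for a in in_period if window.contains(a.date)]
    worst = min((a.total for a in in_window), default=None)
    return BradenSummary(
        braden_first=in_period[0].total,
        braden_mean=fmean(a.total for a in in_period),
        braden_worst=worst,
        n_period=len(in_period),
        n_window=len(in_window),
    )
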
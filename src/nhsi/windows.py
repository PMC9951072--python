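"""Exposure-window computation.

Severity is scored over an up-to-92-day window: for residents who develop a
pressure injury the window ends on the day of the first PrI (half-open, so
the PrI day itself is excluded as outcome-contaminated); for everyone else it
ends at discharge / death / end of the observation period.  The window start
is clipped at admission, so short stays yield short windows.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

from .records import ResidentRecord

WINDOW_DAYS = 92

ANCHOR_FIRST_PRI = "first_pri"
ANCHOR_DISCHARGE = "discharge_or_period_end"


class WindowError(ValueError):
    """The resident is ineligible for an exposure window."""


@dataclass(frozen=True)
class ExposureWindow:
    """Half-open date interval ``[start_date, end_date)``."""

    start_date: dt.date
    end_date: dt.date
    anchor: str
    target_length_days: int = WINDOW_DAYS

    def __post_init__(self) -> None:
        if self.start_date >= self.end_date:
            raise WindowError(
                f"empty window [{self.start_date}, {self.end_date})"
            )
        if self.length_days > self.target_length_days:
            raise WindowError(
                f"window longer than {self.target_length_days} days"
            )

    @property
    def length_days(self) -> int:
        return (self.end_date - self.start_date).days

    def contains(self, date: dt.date) -> bool:
        return self.start_date <= date < self.end_date


def compute_exposure_window(
    record: ResidentRecord, period_end: dt.date
) -> ExposureWindow:
    """Exposure window for one resident.

    With a PrI the window is ``[first_pri - 92d, first_pri)``; without, it is
    the final up-to-92 days before ``min(end_date, period_end)``.  Both are
    clipped at admission.  A PrI on or before admission violates the
    "no existing PrI on entry" inclusion criterion and is rejected.
    """
    first_pri = record.first_pri_date
    if first_pri is not None:
        if first_pri <= record.admission_date:
            raise WindowError(
                f"resident {record.resident_id}: PrI on or before admission "
                f"({first_pri}) — violates inclusion criteria"
            )
        end = first_pri
        anchor = ANCHOR_FIRST_PRI
    else:
        end = min(record.end_date, period_end)
        anchor = ANCHOR_DISCHARGE
        if end <= record.admission_date:
            raise WindowError(
                f"resident {record.resident_id}: stay does not intersect the "
                f"period ending {period_end}"
            )
    start = max(record.admission_date, end - dt.timedelta(days=WINDOW_DAYS))
    return ExposureWindow(start_date=start, end_date=end, anchor=anchor)
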
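"""Delimited-text readers and writers for cohort data.

Dialect: comma-separated, UTF-8, header row required, strict ISO-8601 dates.
Five files describe a cohort::

    residents.csv     resident_id,sex,age,race_ethnicity,admission_date,
                      end_date,end_reason,height_cm
    observations.csv  resident_id,indicator_id,date,value
    braden.csv        resident_id,date,sensory_perception,mobility,activity,
                      moisture,nutrition,friction_shear
    pri_events.csv    resident_id,date
    weights.csv       resident_id,date,weight_kg

Malformed rows are never silently dropped: every reader returns a
:class:`ReaderReport` with ``rows_read == rows_used + rows_rejected`` and a
reason per rejected row.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .braden import BradenAssessment, BradenError
from .catalog import CriteriaCatalog
from .records import Observation, RecordError, ResidentRecord

log = logging.getLogger(__name__)

RESIDENTS_FILE = "residents.csv"
OBSERVATIONS_FILE = "observations.csv"
BRADEN_FILE = "braden.csv"
PRI_FILE = "pri_events.csv"
WEIGHTS_FILE = "weights.csv"
GROUND_TRUTH_FILE = "ground_truth.csv"


class IOError_(ValueError):
    pass


@dataclass
class ReaderReport:
    path: str
    rows_read: int = 0
    rows_used: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def rows_rejected(self) -> int:
        return len(self.rejected)

    def reject(self, row: int, reason: str) -> None:
        self.rejected.append((row, reason))
        log.warning("%s row %d rejected: %s", self.path, row, reason)


def _date(s) -> dt.date:
    return dt.date.fromisoformat(str(s).strip())


def _float(s) -> float:
    v = float(s)
    if not math.isfinite(v):
        raise ValueError(f"non-finite value {s!r}")
    return v


def _read(path: Path, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise IOError_(f"missing input file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing columns {missing}")
    return df


def load_cohort(
    directory, catalog: Optional[CriteriaCatalog] = None
) -> tuple[list[ResidentRecord], dict[str, ReaderReport]]:
    """Read a cohort directory into validated resident records.

    With a catalog, observation rows naming unknown indicators are rejected
    (with the offending id in the reason).  Rows referencing unknown
    residents, unparsable dates/values, or out-of-range Braden subscales are
    rejected row-by-row; structural problems (missing file/column) raise.
    """
    directory = Path(directory)
    reports: dict[str, ReaderReport] = {}

    res_df = _read(
        directory / RESIDENTS_FILE,
        ["resident_id", "sex", "age", "race_ethnicity", "admission_date",
         "end_date", "end_reason", "height_cm"],
    )
    rep = ReaderReport(RESIDENTS_FILE, rows_read=len(res_df))
    records: dict[str, ResidentRecord] = {}
    for i, row in enumerate(res_df.itertuples(index=False)):
        try:
            rec = ResidentRecord(
                resident_id=str(row.resident_id),
                sex=str(row.sex),
                age=_float(row.age),
                race_ethnicity=str(row.race_ethnicity),
                admission_date=_date(row.admission_date),
                end_date=_date(row.end_date),
                end_reason=str(row.end_reason),
                height_cm=_float(row.height_cm),
            )
            if rec.resident_id in records:
                raise RecordError(f"duplicate resident_id {rec.resident_id}")
            records[rec.resident_id] = rec
            rep.rows_used += 1
        except (ValueError, RecordError) as err:
            rep.reject(i, str(err))
    reports[RESIDENTS_FILE] = rep

    obs_df = _read(
        directory / OBSERVATIONS_FILE,
        ["resident_id", "indicator_id", "date", "value"],
    )
    rep = ReaderReport(OBSERVATIONS_FILE, rows_read=len(obs_df))
    for i, row in enumerate(obs_df.itertuples(index=False)):
        rid = str(row.resident_id)
        rec = records.get(rid)
        if rec is None:
            rep.reject(i, f"unknown resident {rid}")
            continue
        iid = str(row.indicator_id)
        if catalog is not None and iid not in catalog:
            rep.reject(i, f"unknown indicator {iid}")
            continue
        try:
            rec.observations.append(
                Observation(
                    resident_id=rid, indicator_id=iid,
                    date=_date(row.date), value=_float(row.value),
                )
            )
            rep.rows_used += 1
        except (ValueError, RecordError) as err:
            rep.reject(i, str(err))
    reports[OBSERVATIONS_FILE] = rep

    br_df = _read(
        directory / BRADEN_FILE,
        ["resident_id", "date", "sensory_perception", "mobility", "activity",
         "moisture", "nutrition", "friction_shear"],
    )
    rep = ReaderReport(BRADEN_FILE, rows_read=len(br_df))
    for i, row in enumerate(br_df.itertuples(index=False)):
        rid = str(row.resident_id)
        rec = records.get(rid)
        if rec is None:
            rep.reject(i, f"unknown resident {rid}")
            continue
        try:
            rec.braden_assessments.append(
                BradenAssessment(
                    resident_id=rid,
                    date=_date(row.date),
                    sensory_perception=int(row.sensory_perception),
                    mobility=int(row.mobility),
                    activity=int(row.activity),
                    moisture=int(row.moisture),
                    nutrition=int(row.nutrition),
                    friction_shear=int(row.friction_shear),
                )
            )
            rep.rows_used += 1
        except (ValueError, BradenError) as err:
            rep.reject(i, str(err))
    reports[BRADEN_FILE] = rep

    pri_df = _read(directory / PRI_FILE, ["resident_id", "date"])
    rep = ReaderReport(PRI_FILE, rows_read=len(pri_df))
    for i, row in enumerate(pri_df.itertuples(index=False)):
        rid = str(row.resident_id)
        rec = records.get(rid)
        if rec is None:
            rep.reject(i, f"unknown resident {rid}")
            continue
        try:
            rec.pri_events.append(_date(row.date))
            rec.pri_events.sort()
            rep.rows_used += 1
        except ValueError as err:
            rep.reject(i, str(err))
    reports[PRI_FILE] = rep

    wt_df = _read(directory / WEIGHTS_FILE, ["resident_id", "date", "weight_kg"])
    rep = ReaderReport(WEIGHTS_FILE, rows_read=len(wt_df))
    for i, row in enumerate(wt_df.itertuples(index=False)):
        rid = str(row.resident_id)
        rec = records.get(rid)
        if rec is None:
            rep.reject(i, f"unknown resident {rid}")
            continue
        try:
            rec.weights.append((_date(row.date), _float(row.weight_kg)))
            rep.rows_used += 1
        except ValueError as err:
            rep.reject(i, str(err))
    reports[WEIGHTS_FILE] = rep

    for rec in records.values():
        rec.observations.sort(key=lambda o: (o.date, o.indicator_id))
        rec.braden_assessments.sort(key=lambda a: a.date)
        rec.weights.sort()
    return list(records.values()), reports


def write_cohort(records, directory, ground_truth: Optional[pd.DataFrame] = None) -> None:
    """Write a cohort back out in exactly the reader schemas."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    res_rows, obs_rows, br_rows, pri_rows, wt_rows = [], [], [], [], []
    for rec in records:
        res_rows.append(
            {
                "resident_id": rec.resident_id, "sex": rec.sex,
                "age": rec.age, "race_ethnicity": rec.race_ethnicity,
                "admission_date": rec.admission_date.isoformat(),
                "end_date": rec.end_date.isoformat(),
                "end_reason": rec.end_reason, "height_cm": rec.height_cm,
            }
        )
        for o in rec.observations:
            obs_rows.append(
                {"resident_id": rec.resident_id, "indicator_id": o.indicator_id,
                 "date": o.date.isoformat(), "value": o.value}
            )
        for a in rec.braden_assessments:
            br_rows.append(
                {"resident_id": rec.resident_id, "date": a.date.isoformat(),
                 "sensory_perception": a.sensory_perception,
                 "mobility": a.mobility, "activity": a.activity,
                 "moisture": a.moisture, "nutrition": a.nutrition,
                 "friction_shear": a.friction_shear}
            )
        for d in rec.pri_events:
            pri_rows.append({"resident_id": rec.resident_id, "date": d.isoformat()})
        for d, w in rec.weights:
            wt_rows.append(
                {"resident_id": rec.resident_id, "date": d.isoformat(),
                 "weight_kg": w}
            )
    pd.DataFrame(res_rows).to_csv(directory / RESIDENTS_FILE, index=False)
    pd.DataFrame(
        obs_rows, columns=["resident_id", "indicator_id", "date", "value"]
    ).to_csv(directory / OBSERVATIONS_FILE, index=False)
    pd.DataFrame(
        br_rows,
        columns=["resident_id", "date", "sensory_perception", "mobility",
                 "activity", "moisture", "nutrition", "friction_shear"],
    ).to_csv(directory / BRADEN_FILE, index=False)
    pd.DataFrame(pri_rows, columns=["resident_id", "date"]).to_csv(
        directory / PRI_FILE, index=False
    )
    pd.DataFrame(
        wt_rows, columns=["resident_id", "date", "weight_kg"]
    ).to_csv(directory / WEIGHTS_FILE, index=False)
    if ground_truth is not None:
        ground_truth.to_csv(directory / GROUND_TRUTH_FILE, index=False)
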
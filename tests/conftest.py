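from __future__ import annotations

import datetime as dt

import pytest

from nhsi.braden import BradenAssessment
from nhsi.catalog import default_catalog
from nhsi.pipeline import build_analysis_table
from nhsi.records import Observation, ResidentRecord
from nhsi.simulate import SimulationConfig, simulate_cohort

D0 = dt.date(2019, 1, 1)


def day(n: int) -> dt.date:
    return D0 + dt.timedelta(days=int(n))


def make_record(
    resident_id="R1",
    sex="female",
    stay_days=365,
    observations=(),
    pri_days=(),
    braden=(),
    weights=(),
    height_cm=160.0,
):
    """Small hand-built resident record; days are offsets from admission."""
    rec = ResidentRecord(
        resident_id=resident_id,
        sex=sex,
        age=80.0,
        race_ethnicity="white",
        admission_date=D0,
        end_date=day(stay_days),
        height_cm=height_cm,
    )
    for iid, d, v in observations:
        rec.observations.append(
            Observation(resident_id=resident_id, indicator_id=iid,
                        date=day(d), value=float(v))
        )
    rec.pri_events = [day(d) for d in pri_days]
    for d, subs in braden:
        kw = dict(
            zip(("sensory_perception", "mobility", "activity", "moisture",
                 "nutrition", "friction_shear"), subs)
        )
        rec.braden_assessments.append(
            BradenAssessment(resident_id=resident_id, date=day(d), **kw)
        )
    rec.weights = [(day(d), float(w)) for d, w in weights]
    return rec


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def sim_cohort_small():
    """Default-condition cohort at modest size for structural tests."""
    cfg = SimulationConfig(seed=42, n_residents=250)
    records, truth = simulate_cohort(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def sim_cohort_2000():
    """Default-condition cohort (n=2000) with its analysis table."""
    cfg = SimulationConfig(seed=11, n_residents=2000)
    records, truth = simulate_cohort(cfg)
    analysis, rejections = build_analysis_table(records, period_end=cfg.period_end)
    assert not rejections
    return cfg, records, truth, analysis
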
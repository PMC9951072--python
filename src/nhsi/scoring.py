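"""The severity scoring engine.

Turns a resident's longitudinal observations into the four NHSI-PrI dimension
scores over an exposure window:

1. every indicator is scored once, from its single most abnormal in-window
   observation (locomotion indicators first aggregate to an average events/day
   rate, underweight to the minimum in-window BMI);
2. the 1-4 severity level maps to a weight through the convex level-weight
   function ``base**(level-1) - 1`` (default base 2: weights 0, 1, 3, 7), so
   normal findings contribute nothing;
3. within an equivalence set only the most abnormal member contributes (ties
   broken by catalog order; losers are flagged suppressed in the audit trail);
4. dimension scores are the sums of contributing weights.

An indicator never observed in the window scores level 1 / weight 0: in a
setting where labs are drawn infrequently and mostly on acute events, absence
is treated as (weak) evidence of normality.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .catalog import (
    AGG_DAILY_FREQUENCY,
    DIMENSIONS,
    CatalogError,
    CriteriaCatalog,
    IndicatorDefinition,
    default_catalog,
)
from .records import ResidentRecord
from .windows import ExposureWindow, WindowError, compute_exposure_window

BMI_INDICATOR = "bmi_underweight"


def level_weight(level: int, weight_base: float = 2.0) -> float:
    """Weight of a severity level: ``base**(level-1) - 1``.

    Strictly increasing and convex in the level for any base > 1; level 1
    (normal) always weighs 0.
    """
    if level not in (1, 2, 3, 4):
        raise ValueError(f"severity level must be 1..4, got {level}")
    if not weight_base > 1:
        raise ValueError(f"weight_base must exceed 1, got {weight_base}")
    return float(weight_base) ** (level - 1) - 1.0


def assign_severity_level(
    ind: IndicatorDefinition, value: float, sex: Optional[str] = None
) -> int:
    """Severity level of ``value`` under the indicator's bands.

    Sex-restricted indicators require ``sex`` and must match it.
    """
    if ind.sex_specific is not None:
        if sex is None:
            raise ValueError(
                f"{ind.indicator_id} is sex-specific; sex must be provided"
            )
        if sex != ind.sex_specific:
            raise ValueError(
                f"{ind.indicator_id} applies to {ind.sex_specific} residents, "
                f"not {sex}"
            )
    return ind.level_of(float(value))


def locomotion_daily_frequency(
    record: ResidentRecord, window: ExposureWindow, indicator_id: str
) -> float:
    """Average events/day of a locomotion indicator over the window."""
    days = window.length_days
    if days < 1:
        raise WindowError("zero-length window")
    total = sum(
        obs.value
        for obs in record.observations
        if obs.indicator_id == indicator_id and window.contains(obs.date)
    )
    return total / days


_FOUR_CAT = ("<18.5", "18.5 to <25", "25 to <30", ">=30")
_FIVE_CAT = ("<18.5", "18.5-25.0", "25.1-30.0", "30.1-40.0", ">40.0")


def bmi_category(bmi: float, scheme: str = "four_cat") -> str:
    """BMI bin label under the four-category or five-category scheme."""
    if not bmi > 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    if scheme == "four_cat":
        if bmi < 18.5:
            return _FOUR_CAT[0]
        if bmi < 25.0:
            return _FOUR_CAT[1]
        if bmi < 30.0:
            return _FOUR_CAT[2]
        return _FOUR_CAT[3]
    if scheme == "five_cat":
        if bmi < 18.5:
            return _FIVE_CAT[0]
        if bmi <= 25.0:
            return _FIVE_CAT[1]
        if bmi <= 30.0:
            return _FIVE_CAT[2]
        if bmi <= 40.0:
            return _FIVE_CAT[3]
        return _FIVE_CAT[4]
    raise ValueError(f"unknown BMI scheme {scheme!r}")


@dataclass(frozen=True)
class IndicatorScore:
    """Audit-trail row: how one indicator was scored for one resident."""

    indicator_id: str
    level: int
    weight: float
    source_date: Optional[dt.date] = None
    source_value: Optional[float] = None
    suppressed_by_equivalence: bool = False


@dataclass
class DimensionScoreSet:
    """The four dimension scores for one resident's exposure window."""

    resident_id: str
    window: ExposureWindow
    laboratory: float = 0.0
    weights_vitals_pain: float = 0.0
    locomotion: float = 0.0
    underweight: float = 0.0
    indicator_scores: list[IndicatorScore] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {dim: getattr(self, dim) for dim in DIMENSIONS}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DimensionScoreSet):
            return NotImplemented
        return (
            self.resident_id == other.resident_id
            and self.as_dict() == other.as_dict()
        )


def score_dimensions(
    record: ResidentRecord,
    window: ExposureWindow,
    catalog: Optional[CriteriaCatalog] = None,
) -> DimensionScoreSet:
    """Score one resident over a window; returns scores plus audit trail."""
    if catalog is None:
        catalog = default_catalog()
    sex = record.sex
    base = catalog.weight_base

    # most abnormal in-window observation per most-abnormal-type indicator
    best: dict[str, tuple[int, dt.date, float]] = {}
    for obs in record.observations:
        if not window.contains(obs.date):
            continue
        ind = catalog.indicator(obs.indicator_id)  # raises on unknown id
        if ind.aggregation == AGG_DAILY_FREQUENCY:
            continue  # handled as a windowed rate below
        if not ind.applies_to(sex):
            continue
        level = ind.level_of(obs.value)
        cur = best.get(ind.indicator_id)
        if cur is None or level > cur[0]:
            best[ind.indicator_id] = (level, obs.date, obs.value)

    # BMI from the weight series feeds the underweight indicator
    if BMI_INDICATOR in catalog:
        bmis = [
            (d, v) for d, v in record.bmi_series() if window.contains(d)
        ]
        if bmis:
            ind = catalog.indicator(BMI_INDICATOR)
            d_min, v_min = min(bmis, key=lambda dv: dv[1])
            level = ind.level_of(v_min)
            cur = best.get(BMI_INDICATOR)
            if cur is None or level > cur[0]:
                best[BMI_INDICATOR] = (level, d_min, v_min)

    scores: list[IndicatorScore] = []
    for ind in catalog.indicators:
        if not ind.applies_to(sex):
            continue
        if ind.aggregation == AGG_DAILY_FREQUENCY:
            rate = locomotion_daily_frequency(record, window, ind.indicator_id)
            level = ind.level_of(rate)
            scores.append(
                IndicatorScore(
                    indicator_id=ind.indicator_id,
                    level=level,
                    weight=level_weight(level, base),
                    source_value=rate,
                )
            )
        else:
            hit = best.get(ind.indicator_id)
            if hit is None:
                scores.append(
                    IndicatorScore(ind.indicator_id, 1, 0.0)
                )
            else:
                level, d, v = hit
                scores.append(
                    IndicatorScore(
                        indicator_id=ind.indicator_id,
                        level=level,
                        weight=level_weight(level, base),
                        source_date=d,
                        source_value=v,
                    )
                )

    scores = _suppress_equivalence(scores, catalog)

    out = DimensionScoreSet(
        resident_id=record.resident_id, window=window, indicator_scores=scores
    )
    for sc in scores:
        if sc.suppressed_by_equivalence:
            continue
        dim = catalog.indicator(sc.indicator_id).dimension_id
        setattr(out, dim, getattr(out, dim) + sc.weight)
    return out


def _suppress_equivalence(
    scores: list[IndicatorScore], catalog: CriteriaCatalog
) -> list[IndicatorScore]:
    """Keep only the most abnormal member of each equivalence set.

    Ties at equal level go to the member listed first in the catalog
    (deterministic, audit-logged).
    """
    order = {ind.indicator_id: i for i, ind in enumerate(catalog.indicators)}
    winners: dict[str, tuple[int, int]] = {}  # set_id -> (level, order)
    winner_ids: dict[str, str] = {}
    for sc in scores:
        set_id = catalog.equivalence_set_of(sc.indicator_id)
        if set_id is None:
            continue
        key = (-sc.level, order[sc.indicator_id])
        if set_id not in winners or key < winners[set_id]:
            winners[set_id] = key
            winner_ids[set_id] = sc.indicator_id
    out = []
    for sc in scores:
        set_id = catalog.equivalence_set_of(sc.indicator_id)
        if set_id is not None and winner_ids[set_id] != sc.indicator_id:
            sc = IndicatorScore(
                indicator_id=sc.indicator_id,
                level=sc.level,
                weight=sc.weight,
                source_date=sc.source_date,
                source_value=sc.source_value,
                suppressed_by_equivalence=True,
            )
        out.append(sc)
    return out


@dataclass
class CohortScores:
    """Scored cohort: per-resident dimension scores, audit trail, rejections."""

    scores: pd.DataFrame  # index resident_id; DIMENSIONS + window columns
    audit: pd.DataFrame  # long per-resident indicator audit trail
    rejections: list[tuple[str, str]] = field(default_factory=list)


class SeverityScorer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: resident records -> dimension-score frame.

    Parameters
    ----------
    catalog : CriteriaCatalog, optional
        Severity matrix; the bundled default catalog when omitted.
    period_end : datetime.date, optional
        End of the observation period; the latest ``end_date`` in the cohort
        when omitted.

    The transformer is stateless (``fit`` only resolves parameters); residents
    whose records violate inclusion criteria (e.g. a PrI on admission) are
    dropped from the output and listed in ``rejections_``.
    """

    def __init__(self, catalog=None, period_end=None):
        self.catalog = catalog
        self.period_end = period_end

    def fit(self, X: Sequence[ResidentRecord], y=None) -> "SeverityScorer":
        self.catalog_ = self.catalog if self.catalog is not None else default_catalog()
        return self

    def transform(self, X: Sequence[ResidentRecord]) -> pd.DataFrame:
        return self.score(X).scores

    def score(self, X: Sequence[ResidentRecord]) -> CohortScores:
        if not hasattr(self, "catalog_"):
            self.fit(X)
        records = list(X)
        if not records:
            raise ValueError("empty cohort")
        period_end = self.period_end or max(r.end_date for r in records)
        rows, audit_rows, rejections = [], [], []
        for rec in records:
            try:
                window = compute_exposure_window(rec, period_end)
            except WindowError as err:
                rejections.append((rec.resident_id, str(err)))
                continue
            dss = score_dimensions(rec, window, self.catalog_)
            row = {"resident_id": rec.resident_id, **dss.as_dict()}
            row.update(
                window_start=window.start_date,
                window_end=window.end_date,
                window_days=window.length_days,
                window_anchor=window.anchor,
            )
            rows.append(row)
            for sc in dss.indicator_scores:
                audit_rows.append(
                    {
                        "resident_id": rec.resident_id,
                        "indicator_id": sc.indicator_id,
                        "level": sc.level,
                        "weight": sc.weight,
                        "source_date": sc.source_date,
                        "source_value": sc.source_value,
                        "suppressed_by_equivalence": sc.suppressed_by_equivalence,
                    }
                )
        scores = pd.DataFrame(rows).set_index("resident_id") if rows else (
            pd.DataFrame(columns=list(DIMENSIONS)).rename_axis("resident_id")
        )
        audit = pd.DataFrame(audit_rows)
        return CohortScores(scores=scores, audit=audit, rejections=rejections)


def score_cohort(
    records: Sequence[ResidentRecord],
    catalog: Optional[CriteriaCatalog] = None,
    period_end: Optional[dt.date] = None,
) -> CohortScores:
    """Functional wrapper over :class:`SeverityScorer`."""
    return SeverityScorer(catalog=catalog, period_end=period_end).score(records)
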
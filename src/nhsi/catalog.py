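"""Severity-criteria catalog: indicators, level bands, equivalence sets.

The catalog is the data-driven "matrix" behind the scoring engine: for each
clinical indicator it defines up to four severity-level bands over the
indicator's metric, the dimension the indicator belongs to, and optional
equivalence-set membership (interchangeable indicators describing one
clinical attribute, scored only once).  A documented default catalog ships
with the package (``data/default_catalog.yaml``); institutions can load their
own file with the same schema.

Band convention: half-open intervals ``[lo, hi)`` that tile the whole real
line, so every finite value maps to exactly one level.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

DIMENSIONS = ("laboratory", "weights_vitals_pain", "locomotion", "underweight")
DIRECTIONS = ("high_is_worse", "low_is_worse", "band")
AGG_MOST_ABNORMAL = "most_abnormal_in_window"
AGG_DAILY_FREQUENCY = "daily_frequency_then_band"
AGGREGATIONS = (AGG_MOST_ABNORMAL, AGG_DAILY_FREQUENCY)

_INF = float("inf")


class CatalogError(ValueError):
    """The catalog (or a config file for one) violates its schema."""


@dataclass(frozen=True)
class Band:
    """One severity-level band ``[lo, hi)``; ``±inf`` for unbounded sides."""

    level: int
    lo: float
    hi: float

    def contains(self, value: float) -> bool:
        return self.lo <= value < self.hi


@dataclass(frozen=True)
class IndicatorDefinition:
    indicator_id: str
    display_name: str
    dimension_id: str
    metric: str
    direction: str
    level_bands: tuple[Band, ...]  # ordered by position on the value axis
    sex_specific: Optional[str] = None  # None, "female" or "male"
    aggregation: str = AGG_MOST_ABNORMAL

    def __post_init__(self) -> None:
        iid = self.indicator_id
        if self.dimension_id not in DIMENSIONS:
            raise CatalogError(f"{iid}: unknown dimension {self.dimension_id!r}")
        if self.direction not in DIRECTIONS:
            raise CatalogError(f"{iid}: unknown direction {self.direction!r}")
        if self.aggregation not in AGGREGATIONS:
            raise CatalogError(f"{iid}: unknown aggregation {self.aggregation!r}")
        if self.sex_specific not in (None, "female", "male"):
            raise CatalogError(f"{iid}: bad sex restriction {self.sex_specific!r}")
        self._validate_bands()

    def _validate_bands(self) -> None:
        iid = self.indicator_id
        bands = self.level_bands
        if not bands:
            raise CatalogError(f"{iid}: no level bands defined")
        levels = [b.level for b in bands]
        if any(lv not in (1, 2, 3, 4) for lv in levels):
            raise CatalogError(f"{iid}: levels must be in 1..4, got {levels}")
        if len(set(levels)) != len(levels):
            raise CatalogError(f"{iid}: duplicate level in bands")
        if 1 not in levels:
            raise CatalogError(f"{iid}: no level-1 (normal) band")
        for b in bands:
            if not b.lo < b.hi:
                raise CatalogError(
                    f"{iid}: empty or inverted band [{b.lo}, {b.hi}) "
                    f"for level {b.level}"
                )
        ordered = sorted(bands, key=lambda b: b.lo)
        if ordered[0].lo != -_INF or ordered[-1].hi != _INF:
            raise CatalogError(f"{iid}: bands do not cover the real line")
        for a, b in zip(ordered, ordered[1:]):
            if a.hi > b.lo:
                mid = b.lo  # a value in both bands
                raise CatalogError(
                    f"{iid}: overlapping bands — value {mid} falls in the "
                    f"level-{a.level} and level-{b.level} bands"
                )
            if a.hi < b.lo:
                raise CatalogError(
                    f"{iid}: gap between bands at [{a.hi}, {b.lo})"
                )
        seq = [b.level for b in ordered]
        if self.direction == "high_is_worse" and seq != sorted(seq):
            raise CatalogError(f"{iid}: high_is_worse levels not monotone: {seq}")
        if self.direction == "low_is_worse" and seq != sorted(seq, reverse=True):
            raise CatalogError(f"{iid}: low_is_worse levels not monotone: {seq}")
        object.__setattr__(self, "_ordered_bands", tuple(ordered))
        object.__setattr__(
            self, "_edges", np.array([b.hi for b in ordered[:-1]], dtype=float)
        )
        object.__setattr__(
            self, "_edge_levels", np.array(seq, dtype=np.int64)
        )

    # -- level lookup ------------------------------------------------------
    def level_of(self, value: float) -> int:
        """Severity level of a single finite value (half-open bands)."""
        if not math.isfinite(value):
            raise CatalogError(f"{self.indicator_id}: non-finite value {value}")
        idx = int(np.searchsorted(self._edges, value, side="right"))
        return int(self._edge_levels[idx])

    def levels_of(self, values: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`level_of`."""
        idx = np.searchsorted(self._edges, np.asarray(values, float), side="right")
        return self._edge_levels[idx]

    def applies_to(self, sex: Optional[str]) -> bool:
        return self.sex_specific is None or self.sex_specific == sex


@dataclass(frozen=True)
class EquivalenceSet:
    set_id: str
    member_indicator_ids: tuple[str, ...]
    description: str = ""


@dataclass(frozen=True)
class DimensionDefinition:
    dimension_id: str
    display_name: str
    member_indicator_ids: tuple[str, ...]


@dataclass
class CriteriaCatalog:
    """A validated severity matrix plus the level-weight base."""

    indicators: tuple[IndicatorDefinition, ...]
    equivalence_sets: tuple[EquivalenceSet, ...]
    dimension_names: dict[str, str]
    weight_base: float = 2.0
    version: str = "unversioned"
    _by_id: dict[str, IndicatorDefinition] = field(
        default_factory=dict, repr=False, compare=False
    )
    _set_of: dict[str, str] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.indicators = tuple(self.indicators)
        self.equivalence_sets = tuple(self.equivalence_sets)
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if not self.indicators:
            raise CatalogError("no indicators defined")
        if not self.weight_base > 1:
            raise CatalogError(f"weight_base must exceed 1, got {self.weight_base}")
        by_id: dict[str, IndicatorDefinition] = {}
        for ind in self.indicators:
            if ind.indicator_id in by_id:
                raise CatalogError(f"duplicate indicator id {ind.indicator_id}")
            by_id[ind.indicator_id] = ind
        set_of: dict[str, str] = {}
        for es in self.equivalence_sets:
            dims = set()
            for iid in es.member_indicator_ids:
                if iid not in by_id:
                    raise CatalogError(
                        f"equivalence set {es.set_id}: unknown indicator {iid}"
                    )
                if iid in set_of:
                    raise CatalogError(
                        f"indicator {iid} appears in equivalence sets "
                        f"{set_of[iid]} and {es.set_id}"
                    )
                set_of[iid] = es.set_id
                dims.add(by_id[iid].dimension_id)
            if len(dims) > 1:
                raise CatalogError(
                    f"equivalence set {es.set_id} spans dimensions {sorted(dims)}"
                )
        for dim in DIMENSIONS:
            if dim not in self.dimension_names:
                raise CatalogError(f"dimension {dim} missing a display name")
        for ind in self.indicators:
            if ind.dimension_id == "underweight" and ind.metric != "kg/m2":
                raise CatalogError(
                    f"{ind.indicator_id}: underweight dimension admits only "
                    "BMI (kg/m2) indicators"
                )
        self._by_id = by_id
        self._set_of = set_of

    # -- lookups -----------------------------------------------------------
    def indicator(self, indicator_id: str) -> IndicatorDefinition:
        try:
            return self._by_id[indicator_id]
        except KeyError:
            raise CatalogError(f"unknown indicator {indicator_id}") from None

    def __contains__(self, indicator_id: str) -> bool:
        return indicator_id in self._by_id

    def equivalence_set_of(self, indicator_id: str) -> Optional[str]:
        return self._set_of.get(indicator_id)

    def catalog_order(self, indicator_id: str) -> int:
        """Position in the catalog; used to break equivalence-set ties."""
        for i, ind in enumerate(self.indicators):
            if ind.indicator_id == indicator_id:
                return i
        raise CatalogError(f"unknown indicator {indicator_id}")

    @property
    def dimensions(self) -> tuple[DimensionDefinition, ...]:
        return tuple(
            DimensionDefinition(
                dimension_id=dim,
                display_name=self.dimension_names[dim],
                member_indicator_ids=tuple(
                    i.indicator_id for i in self.indicators if i.dimension_id == dim
                ),
            )
            for dim in DIMENSIONS
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CriteriaCatalog):
            return NotImplemented
        return (
            self.indicators == other.indicators
            and self.equivalence_sets == other.equivalence_sets
            and self.dimension_names == other.dimension_names
            and self.weight_base == other.weight_base
            and self.version == other.version
        )

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        def edge(x: float):
            return None if not math.isfinite(x) else x

        inds = []
        for ind in self.indicators:
            d = {
                "id": ind.indicator_id,
                "name": ind.display_name,
                "dimension": ind.dimension_id,
                "metric": ind.metric,
                "direction": ind.direction,
                "levels": {
                    b.level: [edge(b.lo), edge(b.hi)] for b in ind.level_bands
                },
            }
            if ind.sex_specific:
                d["sex"] = ind.sex_specific
            if ind.aggregation != AGG_MOST_ABNORMAL:
                d["aggregation"] = ind.aggregation
            inds.append(d)
        return {
            "version": self.version,
            "weight_base": self.weight_base,
            "dimensions": dict(self.dimension_names),
            "indicators": inds,
            "equivalence_sets": [
                {
                    "id": es.set_id,
                    "description": es.description,
                    "members": list(es.member_indicator_ids),
                }
                for es in self.equivalence_sets
            ],
        }


def _band_from_pair(level: int, pair: Sequence, indicator_id: str) -> Band:
    if not isinstance(pair, (list, tuple)) or len(pair) != 2:
        raise CatalogError(f"{indicator_id}: level {level} band must be [lo, hi]")
    lo = -_INF if pair[0] is None else float(pair[0])
    hi = _INF if pair[1] is None else float(pair[1])
    return Band(level=int(level), lo=lo, hi=hi)


def catalog_from_dict(data: dict) -> CriteriaCatalog:
    """Build and validate a catalog from the documented config mapping."""
    if not isinstance(data, dict):
        raise CatalogError("catalog config must be a mapping")
    raw_inds = data.get("indicators") or []
    if not raw_inds:
        raise CatalogError("no indicators defined")
    indicators = []
    for raw in raw_inds:
        iid = raw.get("id")
        if not iid:
            raise CatalogError("indicator without an id")
        levels = raw.get("levels")
        if not isinstance(levels, dict) or not levels:
            raise CatalogError(f"{iid}: missing levels mapping")
        bands = tuple(
            _band_from_pair(int(lv), pair, iid) for lv, pair in levels.items()
        )
        indicators.append(
            IndicatorDefinition(
                indicator_id=str(iid),
                display_name=str(raw.get("name", iid)),
                dimension_id=str(raw.get("dimension", "")),
                metric=str(raw.get("metric", "")),
                direction=str(raw.get("direction", "high_is_worse")),
                level_bands=bands,
                sex_specific=raw.get("sex"),
                aggregation=str(raw.get("aggregation", AGG_MOST_ABNORMAL)),
            )
        )
    eq_sets = tuple(
        EquivalenceSet(
            set_id=str(raw["id"]),
            member_indicator_ids=tuple(raw.get("members") or ()),
            description=str(raw.get("description", "")),
        )
        for raw in (data.get("equivalence_sets") or [])
    )
    dims = data.get("dimensions") or {}
    return CriteriaCatalog(
        indicators=tuple(indicators),
        equivalence_sets=eq_sets,
        dimension_names={str(k): str(v) for k, v in dims.items()},
        weight_base=float(data.get("weight_base", 2.0)),
        version=str(data.get("version", "unversioned")),
    )


def load_catalog(path) -> CriteriaCatalog:
    """Load and validate a catalog config file (YAML)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        raise CatalogError("no indicators defined")
    return catalog_from_dict(data)


def save_catalog(catalog: CriteriaCatalog, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(catalog.to_dict(), fh, sort_keys=False)


def default_catalog() -> CriteriaCatalog:
    """The bundled default catalog (fresh copy each call)."""
    ref = resources.files("nhsi").joinpath("data/default_catalog.yaml")
    data = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return copy.deepcopy(catalog_from_dict(data))
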
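"""Exposure windows, level weights, and the dimension-scoring engine."""

import datetime as dt
import random

import numpy as np
import pytest

from nhsi.catalog import default_catalog
from nhsi.records import Observation
from nhsi.scoring import (
    assign_severity_level,
    bmi_category,
    level_weight,
    locomotion_daily_frequency,
    score_cohort,
    score_dimensions,
)
from nhsi.windows import WindowError, compute_exposure_window

from _oracles import brute_force_dimension_scores
from conftest import D0, day, make_record


class TestExposureWindow:
    def test_pri_anchors_92_days_before_first_event(self):
        rec = make_record(stay_days=365, pri_days=[200])
        w = compute_exposure_window(rec, day(365))
        assert (w.start_date, w.end_date) == (day(108), day(200))
        assert w.anchor == "first_pri"

    def test_short_stay_clips_at_admission(self):
        rec = make_record(stay_days=30)
        w = compute_exposure_window(rec, day(365))
        assert (w.start_date, w.end_date) == (D0, day(30))
        assert w.length_days == 30

    def test_pri_on_admission_rejected(self):
        rec = make_record(stay_days=100, pri_days=[0])
        with pytest.raises(WindowError, match="inclusion"):
            compute_exposure_window(rec, day(365))

    def test_window_never_exceeds_92_days(self):
        rec = make_record(stay_days=365)
        w = compute_exposure_window(rec, day(365))
        assert w.length_days == 92

    def test_period_end_truncates_no_pri_window(self):
        rec = make_record(stay_days=365)
        w = compute_exposure_window(rec, day(200))
        assert (w.start_date, w.end_date) == (day(108), day(200))


class TestLevelWeight:
    def test_level_one_contributes_nothing_for_any_base(self):
        for base in (1.5, 2, 3, 10):
            assert level_weight(1, base) == 0.0

    def test_default_base_gives_0_1_3_7(self):
        assert [level_weight(lv, 2) for lv in (1, 2, 3, 4)] == [0, 1, 3, 7]

    @pytest.mark.parametrize("base", np.linspace(1.1, 6.0, 12).tolist())
    def test_weights_convex_in_level(self, base):
        w = [level_weight(lv, base) for lv in (1, 2, 3, 4)]
        assert w[3] - w[2] > w[2] - w[1] > w[1] - w[0] > 0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            level_weight(5, 2)
        with pytest.raises(ValueError):
            level_weight(2, 1.0)


class TestAssignSeverityLevel:
    def test_normal_band_gives_level_one(self, catalog):
        assert assign_severity_level(catalog.indicator("highest_glucose"), 100) == 1
        assert assign_severity_level(catalog.indicator("lowest_platelets"), 250) == 1

    def test_band_lower_bound_is_inclusive(self, catalog):
        ind = catalog.indicator("highest_bun")
        assert assign_severity_level(ind, 25.0) == 2

    def test_monotone_against_band_table_grid_scan(self, catalog):
        # brute-force scan over a dense value grid for every directional indicator
        for ind in catalog.indicators:
            if ind.direction != "high_is_worse" or ind.sex_specific:
                continue
            grid = np.linspace(-50, 600, 500)
            levels = [assign_severity_level(ind, v) for v in grid]
            assert all(a <= b for a, b in zip(levels, levels[1:]))

    def test_sex_specific_requires_matching_sex(self, catalog):
        ind = catalog.indicator("lowest_hgb_female")
        assert assign_severity_level(ind, 9.0, sex="female") == 3
        with pytest.raises(ValueError, match="sex"):
            assign_severity_level(ind, 9.0)
        with pytest.raises(ValueError, match="female"):
            assign_severity_level(ind, 9.0, sex="male")


class TestLocomotionFrequency:
    def test_46_events_in_92_days_is_half_per_day(self, catalog):
        obs = [("loco_on_unit_one_person_assist", d, 1) for d in range(46)]
        rec = make_record(stay_days=92, observations=obs)
        w = compute_exposure_window(rec, day(92))
        assert locomotion_daily_frequency(rec, w, "loco_on_unit_one_person_assist") == pytest.approx(0.5)

    def test_no_events_is_level_one(self, catalog):
        rec = make_record(stay_days=92)
        w = compute_exposure_window(rec, day(92))
        rate = locomotion_daily_frequency(rec, w, "loco_on_unit_total_dependence")
        assert rate == 0.0
        assert catalog.indicator("loco_on_unit_total_dependence").level_of(rate) == 1

    def test_level_non_decreasing_in_event_count(self, catalog):
        ind = catalog.indicator("loco_off_unit_total_dependence")
        prev = 0
        for count in range(0, 400, 20):
            level = ind.level_of(count / 92.0)
            assert level >= prev
            prev = level


class TestScoreDimensions:
    def test_all_normal_observations_score_zero(self, catalog):
        obs = [("highest_glucose", 5, 100), ("highest_temperature", 10, 98.2),
               ("lowest_platelets", 20, 300)]
        rec = make_record(stay_days=92, observations=obs)
        w = compute_exposure_window(rec, day(92))
        dss = score_dimensions(rec, w, catalog)
        assert dss.as_dict() == {
            "laboratory": 0.0, "weights_vitals_pain": 0.0,
            "locomotion": 0.0, "underweight": 0.0,
        }

    def test_most_abnormal_temperature_counted_exactly_once(self, catalog):
        # three dates at levels 1, 3, 2 -> contributes weight(3) = 3 once
        obs = [("highest_temperature", 5, 98.6),
               ("highest_temperature", 30, 102.0),
               ("highest_temperature", 60, 100.0)]
        rec = make_record(stay_days=92, observations=obs)
        w = compute_exposure_window(rec, day(92))
        dss = score_dimensions(rec, w, catalog)
        assert dss.weights_vitals_pain == 3.0
        sc = {s.indicator_id: s for s in dss.indicator_scores}
        assert sc["highest_temperature"].level == 3

    def test_equivalence_set_scores_only_most_abnormal_member(self, catalog):
        # pulse level 2, ECG rhythm level 4 -> only weight(4)=7 contributes
        obs = [("highest_pulse_rate", 5, 110), ("ecg_rhythm", 10, 4)]
        rec = make_record(stay_days=92, observations=obs)
        w = compute_exposure_window(rec, day(92))
        dss = score_dimensions(rec, w, catalog)
        assert dss.weights_vitals_pain == 7.0
        sc = {s.indicator_id: s for s in dss.indicator_scores}
        assert sc["highest_pulse_rate"].suppressed_by_equivalence
        assert not sc["ecg_rhythm"].suppressed_by_equivalence

    def test_equivalence_tie_goes_to_catalog_order(self, catalog):
        obs = [("highest_pulse_rate", 5, 125), ("ecg_rhythm", 10, 3)]
        rec = make_record(stay_days=92, observations=obs)
        w = compute_exposure_window(rec, day(92))
        dss = score_dimensions(rec, w, catalog)
        sc = {s.indicator_id: s for s in dss.indicator_scores}
        # both level 3; highest_pulse_rate is listed first in the catalog
        assert not sc["highest_pulse_rate"].suppressed_by_equivalence
        assert sc["ecg_rhythm"].suppressed_by_equivalence
        assert dss.weights_vitals_pain == 3.0

    def test_underweight_scored_from_minimum_bmi(self, catalog):
        # height 160 cm; weights give BMI 21.5 then 16.4 -> level 3, weight 3
        rec = make_record(stay_days=92, weights=[(10, 55.0), (50, 42.0)])
        w = compute_exposure_window(rec, day(92))
        dss = score_dimensions(rec, w, catalog)
        assert dss.underweight == 3.0

    def test_out_of_window_observations_ignored(self, catalog):
        obs = [("highest_glucose", 5, 450)]  # level 4, but before the window
        rec = make_record(stay_days=200, observations=obs)
        w = compute_exposure_window(rec, day(200))  # window [108, 200)
        dss = score_dimensions(rec, w, catalog)
        assert dss.laboratory == 0.0

    def test_shuffling_observations_never_changes_scores(self, catalog):
        rec = _random_record(random.Random(5), "RS")
        w = compute_exposure_window(rec, rec.end_date)
        ref = score_dimensions(rec, w, catalog).as_dict()
        for k in range(5):
            random.Random(k).shuffle(rec.observations)
            assert score_dimensions(rec, w, catalog).as_dict() == ref

    def test_adding_an_observation_never_decreases_any_dimension(self, catalog):
        rng = random.Random(9)
        rec = _random_record(rng, "RM")
        w = compute_exposure_window(rec, rec.end_date)
        before = score_dimensions(rec, w, catalog).as_dict()
        extra = Observation("RM", "highest_glucose", day(45), 450.0)
        rec.observations.append(extra)
        after = score_dimensions(rec, w, catalog).as_dict()
        assert all(after[k] >= before[k] for k in before)

    def test_deleting_a_dimensions_observations_zeroes_only_it(self, catalog):
        rng = random.Random(21)
        rec = _random_record(rng, "RD")
        w = compute_exposure_window(rec, rec.end_date)
        before = score_dimensions(rec, w, catalog).as_dict()
        lab_ids = {i.indicator_id for i in catalog.indicators
                   if i.dimension_id == "laboratory"}
        rec.observations = [o for o in rec.observations
                            if o.indicator_id not in lab_ids]
        after = score_dimensions(rec, w, catalog).as_dict()
        assert after["laboratory"] == 0.0
        for k in ("weights_vitals_pain", "locomotion", "underweight"):
            assert after[k] == before[k]


def _random_record(rng: random.Random, rid: str):
    """Small randomized record mixing labs, vitals, coded, locomotion, BMI."""
    cat = default_catalog()
    sex = rng.choice(["female", "male"])
    stay = rng.randint(10, 180)
    obs = []
    for ind in cat.indicators:
        if ind.sex_specific and ind.sex_specific != sex:
            continue
        if ind.dimension_id == "underweight":
            continue
        for _ in range(rng.randint(0, 3)):
            d = rng.randint(0, stay - 1)
            if ind.aggregation == "daily_frequency_then_band":
                obs.append((ind.indicator_id, d, rng.randint(1, 4)))
            elif ind.metric == "coded severity 1-4":
                obs.append((ind.indicator_id, d, rng.randint(1, 4)))
            else:
                finite = [e for b in ind.level_bands
                          for e in (b.lo, b.hi) if e not in (float("inf"), float("-inf"))]
                lo, hi = min(finite), max(finite)
                pad = (hi - lo) or 1.0
                obs.append((ind.indicator_id, d, rng.uniform(lo - pad, hi + pad)))
    weights = [(rng.randint(0, stay - 1), rng.uniform(35, 90))
               for _ in range(rng.randint(0, 4))]
    return make_record(resident_id=rid, sex=sex, stay_days=stay,
                       observations=obs, weights=weights)


class TestOracleEquivalence:
    def test_engine_matches_brute_force_rescorer_on_200_random_records(self, catalog):
        rng = random.Random(2024)
        for i in range(200):
            rec = _random_record(rng, f"O{i}")
            w = compute_exposure_window(rec, rec.end_date)
            engine = score_dimensions(rec, w, catalog).as_dict()
            oracle = brute_force_dimension_scores(rec, w, catalog)
            assert engine == oracle, f"record {i}: {engine} != {oracle}"

    def test_cohort_scorer_agrees_with_single_record_path(self, catalog):
        rng = random.Random(7)
        records = [_random_record(rng, f"C{i}") for i in range(30)]
        period_end = max(r.end_date for r in records)
        cohort = score_cohort(records, catalog, period_end)
        for rec in records:
            w = compute_exposure_window(rec, period_end)
            single = score_dimensions(rec, w, catalog).as_dict()
            row = cohort.scores.loc[rec.resident_id]
            for k, v in single.items():
                assert row[k] == v


class TestBmiCategory:
    @pytest.mark.parametrize(
        "bmi,scheme,expected",
        [
            (17.0, "four_cat", "<18.5"),
            (30.0, "four_cat", ">=30"),
            (24.9, "four_cat", "18.5 to <25"),
            (25.0, "four_cat", "25 to <30"),
            (45.0, "five_cat", ">40.0"),
            (19.0, "five_cat", "18.5-25.0"),
            (33.0, "five_cat", "30.1-40.0"),
        ],
    )
    def test_binning(self, bmi, scheme, expected):
        assert bmi_category(bmi, scheme) == expected

    def test_non_positive_bmi_rejected(self):
        with pytest.raises(ValueError):
            bmi_category(0.0)
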
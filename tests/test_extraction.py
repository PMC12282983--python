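"""Cohort rules (boundaries, ordering, attrition), first-24h worst-value
extraction, the dialect round-trip property, and outcome attachment."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from conftest import make_store
from icubench.extraction import (
    ExtractionConfig,
    ExtractionError,
    VariableSpec,
    attach_outcome,
    extract_first24h,
    select_cohort,
)
from icubench.pipeline import packaged_extraction_config
from icubench.synthetic_data import SimConfig, generate_store, truth_wide


def _one_person_store(year_of_birth=1980, admit="2020-06-01T08:00:00",
                      discharge="2020-06-04T08:00:00", measurements=(),
                      conditions=(), observations=None, deaths=()):
    obs = observations
    if obs is None:  # a reason-for-admission record so the cohort keeps the row
        obs = [(1, 1, 20, 2000000001, admit, 101)]
    return make_store(
        persons=[(1, 8507, year_of_birth)],
        visits=[(10, 1, admit[:10], discharge[:10])],
        details=[(20, 10, 1, 1001, admit, discharge)],
        measurements=measurements,
        observations=obs,
        conditions=conditions,
        deaths=deaths,
    )


class TestCohortRules:
    @pytest.mark.parametrize("birth,included", [(2004, False), (2003, True)])
    def test_age_boundary_seventeen_is_eligible(self, toy_extraction_config,
                                                birth, included):
        store = _one_person_store(year_of_birth=birth)
        cohort, report = select_cohort(store, toy_extraction_config)
        assert (len(cohort) == 1) is included
        removed = dict(zip(report["step"], report["removed"]))
        assert removed["age_under_17"] == (0 if included else 1)

    @pytest.mark.parametrize(
        "admit,included",
        [("2019-06-30T23:00:00", False), ("2019-07-01T00:30:00", True),
         ("2022-12-31T23:00:00", True), ("2023-01-01T01:00:00", False)],
    )
    def test_date_window_boundaries(self, toy_extraction_config, admit, included):
        store = _one_person_store(
            admit=admit,
            discharge=(pd.Timestamp(admit) + pd.Timedelta(days=2)).isoformat(),
        )
        cohort, _ = select_cohort(store, toy_extraction_config)
        assert (len(cohort) == 1) is included

    def test_burns_diagnosis_excluded(self, toy_extraction_config):
        store = _one_person_store(
            conditions=[(1, 1, 20, 4033240, "2020-06-01T09:00:00")]
        )
        cohort, report = select_cohort(store, toy_extraction_config)
        assert len(cohort) == 0
        assert dict(zip(report["step"], report["removed"]))["burns"] == 1

    def test_missing_reason_excluded(self, toy_extraction_config):
        store = _one_person_store(observations=[])
        cohort, report = select_cohort(store, toy_extraction_config)
        assert len(cohort) == 0
        assert dict(zip(report["step"], report["removed"]))["missing_reason"] == 1

    def test_readmission_keeps_earliest_stay(self, toy_extraction_config):
        store = make_store(
            persons=[(1, 8507, 1980)],
            visits=[(10, 1, "2020-06-01", "2020-06-20")],
            details=[
                (21, 10, 1, 1001, "2020-06-10T08:00:00", "2020-06-12T08:00:00"),
                (20, 10, 1, 1001, "2020-06-01T08:00:00", "2020-06-04T08:00:00"),
            ],
            observations=[
                (1, 1, 20, 2000000001, "2020-06-01T08:00:00", 101),
                (2, 1, 21, 2000000001, "2020-06-10T08:00:00", 101),
            ],
        )
        cohort, report = select_cohort(store, toy_extraction_config)
        assert cohort["visit_detail_id"].tolist() == [20]
        assert dict(zip(report["step"], report["removed"]))["icu_readmission"] == 1

    def test_simultaneous_stays_tie_breaks_on_lowest_id(self, toy_extraction_config):
        t0 = "2020-06-01T08:00:00"
        store = make_store(
            persons=[(1, 8507, 1980)],
            visits=[(10, 1, "2020-06-01", "2020-06-20")],
            details=[
                (21, 10, 1, 1001, t0, "2020-06-12T08:00:00"),
                (20, 10, 1, 1001, t0, "2020-06-04T08:00:00"),
            ],
            observations=[
                (1, 1, 20, 2000000001, t0, 101),
                (2, 1, 21, 2000000001, t0, 101),
            ],
        )
        cohort, _ = select_cohort(store, toy_extraction_config)
        assert cohort["visit_detail_id"].tolist() == [20]

    def test_attrition_counts_sum(self, small_store, toy_extraction_config):
        store, _ = small_store
        cfg = packaged_extraction_config("A")
        cohort, report = select_cohort(store, cfg)
        total = report.loc[report["step"] == "total", "remaining"].iloc[0]
        assert total - report["removed"].sum() == len(cohort)
        assert report["remaining"].iloc[-1] == len(cohort)

    def test_config_without_reason_variable_fatal(self):
        cfg = ExtractionConfig(
            source_name="bad",
            variables=[VariableSpec("temperature", [1], "measurement", "both")],
            date_window=(dt.date(2019, 7, 1), dt.date(2022, 12, 31)),
        )
        with pytest.raises(ExtractionError, match="reason"):
            select_cohort(make_store(), cfg)


class TestFirst24h:
    def _store_with_temp(self, events):
        ms = [
            (i + 1, 1, 20, 3020891, t, v, 586323) for i, (t, v) in enumerate(events)
        ]
        return _one_person_store(measurements=ms)

    def test_single_measurement_is_both_extrema(self, toy_extraction_config):
        store = self._store_with_temp([("2020-06-01T09:00:00", 37.2)])
        cohort, _ = select_cohort(store, toy_extraction_config)
        wide = extract_first24h(store, cohort, toy_extraction_config)
        assert wide["temperature_high"].iloc[0] == 37.2
        assert wide["temperature_low"].iloc[0] == 37.2

    def test_window_is_half_open_24h(self, toy_extraction_config):
        store = self._store_with_temp(
            [
                ("2020-06-01T09:00:00", 33.1),  # +1 h
                ("2020-06-02T07:00:00", 39.8),  # +23 h
                ("2020-06-02T09:00:00", 40.0),  # +25 h -> excluded
                ("2020-06-02T08:00:00", 41.0),  # exactly +24 h -> excluded
            ]
        )
        cohort, _ = select_cohort(store, toy_extraction_config)
        wide = extract_first24h(store, cohort, toy_extraction_config)
        assert wide["temperature_high"].iloc[0] == 39.8
        assert wide["temperature_low"].iloc[0] == 33.1

    def test_no_qualifying_event_is_absent(self, toy_extraction_config):
        store = self._store_with_temp([])
        cohort, _ = select_cohort(store, toy_extraction_config)
        wide = extract_first24h(store, cohort, toy_extraction_config)
        assert np.isnan(wide["temperature_high"].iloc[0])

    def test_multiple_concepts_pooled_before_extrema(self, toy_extraction_config):
        # leukocytes recorded under automated and manual count codes
        store = _one_person_store(
            measurements=[
                (1, 1, 20, 3000905, "2020-06-01T09:00:00", 4.2, 8848),
                (2, 1, 20, 3003282, "2020-06-01T10:00:00", 17.5, 8848),
            ]
        )
        cohort, _ = select_cohort(store, toy_extraction_config)
        wide = extract_first24h(store, cohort, toy_extraction_config)
        assert wide["wbc_low"].iloc[0] == 4.2
        assert wide["wbc_high"].iloc[0] == 17.5

    def test_unexpected_unit_dropped_with_warning(self, toy_extraction_config):
        cfg = toy_extraction_config
        cfg.variable("temperature").unit_concept_id = 586323
        store = self._store_with_temp([("2020-06-01T09:00:00", 37.0)])
        store.measurement.loc[0, "unit_concept_id"] = 9999  # some other unit
        cohort, _ = select_cohort(store, cfg)
        with pytest.warns(UserWarning, match="temperature"):
            wide = extract_first24h(store, cohort, cfg)
        assert np.isnan(wide["temperature_high"].iloc[0])

    def test_numeric_aggregation_over_conditions_is_fatal(self):
        with pytest.raises(ExtractionError, match="presence"):
            VariableSpec("x", [1], "condition_occurrence", "both").validate()

    def test_presence_variable(self, toy_extraction_config):
        store = _one_person_store(
            conditions=[(1, 1, 20, 4064161, "2020-06-01T08:00:00")]
        )
        cohort, _ = select_cohort(store, toy_extraction_config)
        wide = extract_first24h(store, cohort, toy_extraction_config)
        assert bool(wide["chronic_insufficiency"].iloc[0]) is True


class TestOutcome:
    def test_death_before_discharge_counts(self, toy_extraction_config):
        store = _one_person_store(deaths=[(1, "2020-06-04T07:00:00")])
        cohort, _ = select_cohort(store, toy_extraction_config)
        out = attach_outcome(store, cohort)
        assert bool(out["icu_death"].iloc[0]) is True

    def test_death_after_discharge_is_hospital_death(self, toy_extraction_config):
        store = _one_person_store(deaths=[(1, "2020-06-06T08:00:00")])
        cohort, _ = select_cohort(store, toy_extraction_config)
        out = attach_outcome(store, cohort)
        assert bool(out["icu_death"].iloc[0]) is False

    def test_los_fractional_days(self, toy_extraction_config):
        store = _one_person_store(
            admit="2020-01-01T08:00:00", discharge="2020-01-03T20:00:00"
        )
        cohort, _ = select_cohort(store, toy_extraction_config)
        out = attach_outcome(store, cohort)
        assert out["icu_los_days"].iloc[0] == pytest.approx(2.5)

    def test_death_before_admission_flagged(self, toy_extraction_config):
        store = _one_person_store(deaths=[(1, "2020-05-30T08:00:00")])
        cohort, _ = select_cohort(store, toy_extraction_config)
        out = attach_outcome(store, cohort)
        assert out["outcome_flag"].iloc[0] == "death_before_admission"
        assert bool(out["icu_death"].iloc[0]) is False


class TestAgainstTruth:
    def test_zero_missingness_extraction_equals_truth(self, small_store):
        store, truth = small_store
        cfg = packaged_extraction_config("A")
        cohort, _ = select_cohort(store, cfg)
        cohort = attach_outcome(store, cohort)
        wide = extract_first24h(store, cohort, cfg)
        tw = truth_wide(truth)
        common = wide.index.intersection(tw.index)
        # cohort = analysable truth rows + rows excluded later for unmappable codes
        assert len(common) == int(truth["in_cohort"].sum())
        got = wide.loc[common, tw.columns].sort_index()
        want = tw.loc[common].sort_index()
        assert np.allclose(
            got.to_numpy(dtype=float), want.to_numpy(dtype=float), equal_nan=True
        )

    def test_outcomes_match_truth(self, small_store):
        store, truth = small_store
        cfg = packaged_extraction_config("A")
        cohort, _ = select_cohort(store, cfg)
        cohort = attach_outcome(store, cohort)
        t = truth.set_index("visit_detail_id")
        joined = cohort.set_index("visit_detail_id").join(
            t[["death", "los_days"]], how="inner"
        )
        assert (joined["icu_death"] == joined["death"]).all()
        assert np.allclose(joined["icu_los_days"], joined["los_days"], atol=2e-5)

    def test_dialect_round_trip(self, definition):
        base = dict(seed=17, n_registries=1, icus_per_registry=2,
                    patients_per_icu=120)
        sa, _ = generate_store(SimConfig(dialect="A", **base), definition)
        sb, _ = generate_store(
            SimConfig(dialect="B", schema_version="5.4", **base), definition
        )
        wa = extract_first24h(
            sa, select_cohort(sa, packaged_extraction_config("A"))[0],
            packaged_extraction_config("A"),
        )
        wb = extract_first24h(
            sb, select_cohort(sb, packaged_extraction_config("B"))[0],
            packaged_extraction_config("B"),
        )
        pd.testing.assert_frame_equal(wa.sort_index(), wb.sort_index())
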
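import numpy as np
import pandas as pd
import pytest

from icubench.apache2 import load_scoring_definition
from icubench.synthetic_data import SimConfig, generate_store


@pytest.fixture(scope="session")
def definition():
    return load_scoring_definition()


@pytest.fixture(scope="session")
def small_sim_config():
    return SimConfig(
        seed=11, dialect="A", source_name="src_a",
        n_registries=2, icus_per_registry=2, patients_per_icu=150,
    )


@pytest.fixture(scope="session")
def small_store(small_sim_config, definition):
    return generate_store(small_sim_config, definition)


def _int64(values):
    return pd.array(values, dtype="Int64")


def make_store(
    persons=(),
    visits=(),
    details=(),
    measurements=(),
    observations=(),
    conditions=(),
    deaths=(),
    care_sites=None,
):
    """Hand-build a tiny OMOP store from row tuples (test fixture helper).

    persons: (person_id, gender_concept_id, year_of_birth)
    visits: (visit_occurrence_id, person_id, start_date, end_date)
    details: (visit_detail_id, visit_occurrence_id, person_id, care_site_id,
              start, end)
    measurements: (id, person_id, visit_detail_id, concept_id, datetime,
                   value, unit_concept_id)
    observations: (id, person_id, visit_detail_id, concept_id, datetime, value)
    conditions: (id, person_id, visit_detail_id, concept_id, datetime)
    deaths: (person_id, datetime)
    """
    from icubench.omop_store import OmopStore

    def dt(x):
        return pd.to_datetime(x) if x is not None else pd.NaT

    person = pd.DataFrame(
        {
            "person_id": _int64([p[0] for p in persons]),
            "gender_concept_id": _int64([p[1] for p in persons]),
            "year_of_birth": _int64([p[2] for p in persons]),
        }
    )
    visit_occurrence = pd.DataFrame(
        {
            "visit_occurrence_id": _int64([v[0] for v in visits]),
            "person_id": _int64([v[1] for v in visits]),
            "visit_start_date": pd.to_datetime([v[2] for v in visits]),
            "visit_end_date": pd.to_datetime([v[3] for v in visits]),
            "admitted_from_concept_id": _int64([None] * len(visits)),
        }
    )
    visit_detail = pd.DataFrame(
        {
            "visit_detail_id": _int64([d[0] for d in details]),
            "visit_occurrence_id": _int64([d[1] for d in details]),
            "person_id": _int64([d[2] for d in details]),
            "care_site_id": _int64([d[3] for d in details]),
            "visit_detail_start_datetime": pd.to_datetime([d[4] for d in details]),
            "visit_detail_end_datetime": pd.Series([dt(d[5]) for d in details],
                                                   dtype="datetime64[ns]"),
            "discharged_to_concept_id": _int64([None] * len(details)),
        }
    )
    measurement = pd.DataFrame(
        {
            "measurement_id": _int64([m[0] for m in measurements]),
            "person_id": _int64([m[1] for m in measurements]),
            "visit_detail_id": _int64([m[2] for m in measurements]),
            "measurement_concept_id": _int64([m[3] for m in measurements]),
            "measurement_datetime": pd.to_datetime([m[4] for m in measurements]),
            "value_as_number": pd.Series([m[5] for m in measurements], dtype=float),
            "unit_concept_id": _int64([m[6] for m in measurements]),
        }
    )
    observation = pd.DataFrame(
        {
            "observation_id": _int64([o[0] for o in observations]),
            "person_id": _int64([o[1] for o in observations]),
            "visit_detail_id": _int64([o[2] for o in observations]),
            "observation_concept_id": _int64([o[3] for o in observations]),
            "observation_datetime": pd.to_datetime([o[4] for o in observations]),
            "value_as_number": pd.Series([o[5] for o in observations], dtype=float),
        }
    )
    condition = pd.DataFrame(
        {
            "condition_occurrence_id": _int64([c[0] for c in conditions]),
            "person_id": _int64([c[1] for c in conditions]),
            "visit_detail_id": _int64([c[2] for c in conditions]),
            "condition_concept_id": _int64([c[3] for c in conditions]),
            "condition_start_datetime": pd.to_datetime([c[4] for c in conditions]),
        }
    )
    death = pd.DataFrame(
        {
            "person_id": _int64([d[0] for d in deaths]),
            "death_datetime": pd.to_datetime([d[1] for d in deaths]),
        }
    )
    cs = None
    if care_sites is not None:
        cs = pd.DataFrame(
            {
                "care_site_id": _int64([c[0] for c in care_sites]),
                "care_site_name": [c[1] for c in care_sites],
            }
        )
    return OmopStore(
        person=person,
        visit_occurrence=visit_occurrence,
        visit_detail=visit_detail,
        measurement=measurement,
        observation=observation,
        condition_occurrence=condition,
        death=death,
        care_site=cs,
    )


@pytest.fixture
def toy_extraction_config():
    """Minimal single-variable-friendly extraction config for handcrafted stores."""
    import datetime as _dt

    from icubench.extraction import ExtractionConfig, VariableSpec

    def var(name, concepts, table="measurement", agg="both", unit=None):
        return VariableSpec(name, concepts, table, agg, unit)

    variables = [
        var("temperature", [3020891]),
        var("mean_arterial_pressure", [3027598]),
        var("heart_rate", [3027018]),
        var("respiratory_rate", [3024171]),
        var("pao2", [3027801], agg="lowest"),
        var("fio2", [3020716], agg="highest"),
        var("aado2", [3022875], agg="highest"),
        var("arterial_ph", [3010421]),
        var("sodium", [3019550]),
        var("potassium", [3023103]),
        var("creatinine", [3016723]),
        var("hematocrit", [3023314]),
        var("wbc", [3000905, 3003282]),
        var("gcs", [3032652], agg="lowest"),
        var("reason_for_admission", [2000000001], table="observation", agg="code"),
        var("chronic_insufficiency", [4064161], table="condition_occurrence",
            agg="presence"),
    ]
    return ExtractionConfig(
        source_name="toy",
        variables=variables,
        date_window=(_dt.date(2019, 7, 1), _dt.date(2022, 12, 31)),
        burns_concept_ids=[4033240],
    )
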
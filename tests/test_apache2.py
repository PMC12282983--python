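"""APACHE II engine: band lookup vs an independent oracle, hand-scored
vignettes, totals, risk equation and reason-for-admission mapping."""

import math

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from icubench.apache2 import (
    PHYSIOLOGY_COMPONENTS,
    TWO_SIDED_COMPONENTS,
    UNMAPPED,
    Apache2Error,
    DiagnosisMap,
    OxygenationContext,
    _parse_bands,
    compute_total,
    load_scoring_definition,
    map_reason,
    mortality_risk,
    score_admission,
    score_component,
)
from icubench.pipeline import packaged_path

# --------------------------------------------------------------------------
# independent brute-force oracle: linear scan of the printed bands with the
# documented gap rule (value between two printed bands -> the more severe)
# --------------------------------------------------------------------------


def _raw_bands(variable):
    raw = yaml.safe_load(packaged_path("apache2_scoring.yaml").read_text())
    return raw["variables"][variable]


def oracle_points(bands, v):
    inside = [
        b["points"]
        for b in bands
        if v >= b.get("min", -math.inf) and v <= b.get("max", math.inf)
    ]
    if inside:
        return max(inside)
    below = [b for b in bands if b.get("max", math.inf) < v]
    above = [b for b in bands if b.get("min", -math.inf) > v]
    cand = []
    if below:
        cand.append(max(below, key=lambda b: b["max"])["points"])
    if above:
        cand.append(min(above, key=lambda b: b["min"])["points"])
    return max(cand)


_GRID_VARS = [v for v in TWO_SIDED_COMPONENTS] + ["pao2", "aado2", "serum_hco3"]


@pytest.mark.parametrize("variable", _GRID_VARS)
def test_engine_matches_oracle_on_dense_grid(definition, variable):
    spec = _raw_bands(variable)
    lo, hi = spec["domain"]
    grid = np.round(np.linspace(lo, hi, 4001), 6)
    # include every printed edge and near-edge values
    edges = [b[k] for b in spec["bands"] for k in ("min", "max") if k in b]
    extra = np.array(
        [e for e in edges] + [e + 0.01 for e in edges] + [e - 0.01 for e in edges]
    )
    grid = np.concatenate([grid, extra[(extra >= lo) & (extra <= hi)]])
    engine = definition.variables[variable].points_of(grid)
    expect = np.array([oracle_points(spec["bands"], v) for v in grid])
    assert (engine == expect).all()


def test_boundary_values_take_more_severe_band(definition):
    # shared printed edges and gap values both resolve to the higher points
    assert score_component("temperature", None, 38.45, definition) == 1  # gap
    assert score_component("creatinine", None, 3.45, definition) == 4  # gap
    assert score_component("mean_arterial_pressure", None, 109.5, definition) == 2
    assert score_component("sodium", None, 149.5, definition) == 1


# --------------------------------------------------------------------------
# hand-scored vignettes (scored manually against the published sheet before
# the engine was written; risks hand-evaluated from the logistic constants)
# --------------------------------------------------------------------------

VIGNETTES = [
    {
        # 45 y, nonoperative sepsis, no chronic insufficiency
        "values": {
            "temperature": (36.5, 39.5),
            "mean_arterial_pressure": (72, 130),
            "heart_rate": (80, 118),
            "respiratory_rate": (14, 26),
            "arterial_ph": (7.28, 7.44),
            "sodium": (136, 151),
            "potassium": (3.6, 5.6),
            "creatinine": (1.0, 2.1),
            "hematocrit": (28, 34),
            "wbc": (9, 21),
        },
        "oxygenation": dict(pao2_low=62, fio2_high=0.4, aado2_high=None),
        "gcs": 13,
        "arf": False,
        "age": 45,
        "chronic": False,
        "elective": False,
        "emergency": False,
        "category": "sepsis",
        "expect": dict(aps=23, age_points=2, chronic_points=0, total=25,
                       eta=0.246, risk=0.561192),
    },
    {
        # 78 y, emergency postoperative GI perforation, chronic insufficiency,
        # acute renal failure (creatinine points doubled)
        "values": {
            "temperature": (33.5, 37.0),
            "mean_arterial_pressure": (55, 95),
            "heart_rate": (88, 145),
            "respiratory_rate": (16, 38),
            "arterial_ph": (7.18, 7.40),
            "sodium": (128, 140),
            "potassium": (2.8, 5.0),
            "creatinine": (1.2, 3.6),
            "hematocrit": (38, 52),
            "wbc": (0.8, 9.0),
        },
        "oxygenation": dict(pao2_low=80, fio2_high=0.6, aado2_high=380),
        "gcs": 6,
        "arf": True,
        "age": 78,
        "chronic": True,
        "elective": False,
        "emergency": True,
        "category": "gi_perforation_obstruction",
        "expect": dict(aps=43, age_points=6, chronic_points=5, total=54,
                       eta=5.030, risk=0.993504),
    },
    {
        # 30 y, elective craniotomy for neoplasm, chronic insufficiency,
        # entirely normal physiology
        "values": {
            "temperature": (36.8, 36.8),
            "mean_arterial_pressure": (85, 85),
            "heart_rate": (75, 75),
            "respiratory_rate": (14, 14),
            "arterial_ph": (7.40, 7.40),
            "sodium": (140, 140),
            "potassium": (4.0, 4.0),
            "creatinine": (0.9, 0.9),
            "hematocrit": (40, 40),
            "wbc": (8, 8),
        },
        "oxygenation": dict(pao2_low=95, fio2_high=0.21, aado2_high=None),
        "gcs": 15,
        "arf": False,
        "age": 30,
        "chronic": True,
        "elective": True,
        "emergency": False,
        "category": "craniotomy_neoplasm",
        "expect": dict(aps=0, age_points=0, chronic_points=2, total=2,
                       eta=-4.470, risk=0.011318),
    },
]


@pytest.mark.parametrize("case", VIGNETTES, ids=["sepsis", "gi_perf", "craniotomy"])
def test_hand_scored_vignette(definition, case):
    comp = {}
    for var, (lo, hi) in case["values"].items():
        comp[var] = score_component(
            var, lo, hi, definition, acute_renal_failure=case["arf"]
        )
    comp["oxygenation"] = score_component(
        "oxygenation",
        case["oxygenation"]["pao2_low"],
        None,
        definition,
        oxygenation=OxygenationContext(
            fio2_high=case["oxygenation"]["fio2_high"],
            aado2_high=case["oxygenation"]["aado2_high"],
        ),
    )
    comp["gcs"] = score_component("gcs", case["gcs"], None, definition)
    result = score_admission(
        comp, case["age"], case["chronic"], case["elective"], case["emergency"],
        case["category"], definition,
    )
    exp = case["expect"]
    assert result.aps == exp["aps"]
    assert result.age_points == exp["age_points"]
    assert result.chronic_points == exp["chronic_points"]
    assert result.total_score == exp["total"]
    assert result.risk == pytest.approx(exp["risk"], abs=5e-7)


# --------------------------------------------------------------------------
# component-level behaviour
# --------------------------------------------------------------------------


@pytest.mark.parametrize("variable", TWO_SIDED_COMPONENTS)
def test_normal_band_scores_zero(definition, variable):
    vb = definition.variables[variable]
    normal = [b for b in vb.bands if b.points == 0][0]
    mid = (max(normal.lo, vb.domain[0]) + min(normal.hi, vb.domain[1])) / 2
    assert score_component(variable, mid, mid, definition) == 0


def test_both_extrema_absent_is_deferred(definition):
    assert score_component("temperature", None, None, definition) is None


def test_worst_of_both_extrema(definition):
    # low extreme worth 2, high extreme worth 4 -> component takes 4
    assert score_component("potassium", 2.6, 7.2, definition) == 4
    assert score_component("potassium", 2.6, 5.0, definition) == 2


def test_oxygenation_rail_switch(definition):
    ctx_low = OxygenationContext(fio2_high=0.4, aado2_high=400)
    ctx_high = OxygenationContext(fio2_high=0.5, aado2_high=400)
    assert score_component("oxygenation", 65, None, definition, oxygenation=ctx_low) == 1
    assert score_component("oxygenation", 65, None, definition, oxygenation=ctx_high) == 3


def test_creatinine_doubles_under_arf(definition):
    base = score_component("creatinine", None, 2.1, definition)
    doubled = score_component(
        "creatinine", None, 2.1, definition, acute_renal_failure=True
    )
    assert (base, doubled) == (3, 6)


def test_gcs_points_are_fifteen_minus_scale(definition):
    assert score_component("gcs", 15, None, definition) == 0
    assert score_component("gcs", 3, None, definition) == 12


def test_out_of_domain_value_names_variable(definition):
    with pytest.raises(Apache2Error, match="temperature.*50"):
        score_component("temperature", None, 50.0, definition)


# --------------------------------------------------------------------------
# totals and the risk equation
# --------------------------------------------------------------------------


def _zero_components():
    return {v: 0 for v in PHYSIOLOGY_COMPONENTS}


def test_all_zero_young_no_chronic_total_zero(definition):
    aps, agep, chp, total = compute_total(
        _zero_components(), 30, False, False, definition
    )
    assert (aps, agep, chp, total) == (0, 0, 0, 0)


def test_chronic_health_rule(definition):
    _, _, chp_el, _ = compute_total(_zero_components(), 30, True, True, definition)
    _, _, chp_em, _ = compute_total(_zero_components(), 30, True, False, definition)
    assert chp_el == 2  # elective postoperative
    assert chp_em == 5  # nonoperative or emergency postoperative


def test_unresolved_component_is_fatal(definition):
    comp = _zero_components()
    comp["potassium"] = None
    with pytest.raises(Apache2Error, match="potassium"):
        compute_total(comp, 30, False, False, definition)


def test_risk_monotone_in_total(definition):
    risks = [mortality_risk(t, 0.0, False, definition) for t in range(72)]
    assert all(b > a for a, b in zip(risks, risks[1:]))
    assert all(0 < r < 1 for r in risks)


def test_risk_half_when_eta_zero(definition):
    c = definition.logistic
    weight = -c["intercept"] - c["per_point"] * 20
    assert mortality_risk(20, weight, False, definition) == pytest.approx(0.5)


def test_risk_rejects_out_of_range_total(definition):
    with pytest.raises(Apache2Error):
        mortality_risk(72, 0.0, False, definition)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    pts=st.lists(st.integers(0, 4), min_size=11, max_size=11),
    gcs=st.integers(3, 15),
    age=st.integers(17, 100),
    chronic=st.booleans(),
    elective=st.booleans(),
)
def test_total_always_within_published_range(definition, pts, gcs, age, chronic, elective):
    comp = dict(zip([v for v in PHYSIOLOGY_COMPONENTS if v != "gcs"], pts))
    comp["gcs"] = 15 - gcs
    _, _, _, total = compute_total(comp, age, chronic, elective, definition)
    assert 0 <= total <= 71


# --------------------------------------------------------------------------
# scoring-definition validation
# --------------------------------------------------------------------------


def test_overlapping_bands_rejected():
    with pytest.raises(Apache2Error, match="overlap"):
        _parse_bands("x", [{"min": 0, "max": 5, "points": 0},
                           {"min": 5, "max": 9, "points": 1}])


def test_packaged_definition_invariants(definition):
    for name, vb in definition.variables.items():
        if not vb.bands:
            continue
        zero = [b for b in vb.bands if b.points == 0]
        assert len(zero) == 1, name  # exactly one normal band


# --------------------------------------------------------------------------
# reason-for-admission mapping
# --------------------------------------------------------------------------


def test_map_reason_lookup_and_unmapped():
    dmap = DiagnosisMap(source="toy", entries={"7": "sepsis"})
    assert map_reason("7", dmap) == "sepsis"
    assert map_reason(7, dmap) == "sepsis"
    assert map_reason(7.0, dmap) == "sepsis"  # float-formatted numeric code
    assert map_reason("8", dmap) == UNMAPPED


def test_two_stage_map_equals_composition():
    stage1 = {"a1": "x", "a2": "y", "a3": "z"}
    stage2 = {"x": "sepsis", "y": "cardiovascular"}  # z unmapped downstream
    dmap = DiagnosisMap(
        source="toy", entries=stage1, intermediate_entries=stage2,
        intermediate="mid",
    )
    for code in stage1:
        expect = stage2.get(stage1[code], UNMAPPED)
        assert map_reason(code, dmap) == expect
    assert map_reason("missing", dmap) == UNMAPPED


def test_duplicate_conflicting_codes_fatal(tmp_path):
    from icubench.apache2 import load_diagnosis_map

    f = tmp_path / "map.yaml"
    f.write_text(
        "source: bad\nentries:\n"
        "  - {code: '1', target: sepsis}\n"
        "  - {code: '1', target: cardiovascular}\n"
    )
    with pytest.raises(Apache2Error, match="duplicate"):
        load_diagnosis_map(f)


def test_packaged_dialect_maps_agree(definition):
    from icubench.apache2 import load_diagnosis_map

    a = load_diagnosis_map(packaged_path("synthetic_dialect_a_diagnosis_map.yaml"))
    b = load_diagnosis_map(packaged_path("synthetic_dialect_b_diagnosis_map.yaml"))
    # the two vocabularies cover the same categories, all weighted in both arms
    cats_a = {map_reason(c, a) for c in a.entries}
    cats_b = {map_reason(c, b) for c in b.entries}
    assert cats_a == cats_b
    for cat in cats_a:
        definition.diagnostic_weight(cat, postoperative=False)
        definition.diagnostic_weight(cat, postoperative=True)
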
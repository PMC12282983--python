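"""APACHE II severity scoring and ICU mortality risk.

The Acute Physiology and Chronic Health Evaluation II model assigns 0-4 points
to the most deranged value of each of 12 physiologic variables in the first
24 hours of ICU admission, adds age and chronic-health points (total 0-71),
and converts the total to a mortality risk through a logistic equation with a
diagnostic-category weight and an emergency-surgery term.

The numeric content of the model — value bands, age bands, the chronic-health
rule, diagnostic-category weights and the logistic coefficients — lives in a
packaged, human-auditable data file (``data/apache2_scoring.yaml``) transcribed
from the published model, not in code.

Scoring conventions (documented, deterministic):

* a value exactly on a band edge, or in the gap between two printed bands,
  belongs to the adjacent band with the **higher** point value;
* the component score is ``max(points(lowest), points(highest))`` over the
  recorded extrema;
* oxygenation uses the alveolar-arterial gradient bands when FiO2 >= 0.5 and
  the arterial PO2 bands otherwise;
* creatinine points are doubled under acute renal failure;
* neurologic points are ``15 - Glasgow Coma Scale``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

#: the 12 physiologic components of the acute physiology score
PHYSIOLOGY_COMPONENTS = (
    "temperature",
    "mean_arterial_pressure",
    "heart_rate",
    "respiratory_rate",
    "oxygenation",
    "arterial_ph",
    "sodium",
    "potassium",
    "creatinine",
    "hematocrit",
    "wbc",
    "gcs",
)

#: banded variables scored on both recorded extrema
TWO_SIDED_COMPONENTS = (
    "temperature",
    "mean_arterial_pressure",
    "heart_rate",
    "respiratory_rate",
    "arterial_ph",
    "sodium",
    "potassium",
    "creatinine",
    "hematocrit",
    "wbc",
)

UNMAPPED = "__unmapped__"


class Apache2Error(Exception):
    pass


@dataclass(frozen=True)
class Band:
    lo: float  # -inf if open below
    hi: float  # +inf if open above
    points: int


@dataclass
class VariableBands:
    name: str
    unit: str
    domain: tuple[float, float]
    bands: tuple[Band, ...]  # sorted ascending by lo
    gaps: tuple[Band, ...]  # gap intervals with resolved (more severe) points

    def points_of(self, values: np.ndarray) -> np.ndarray:
        """Vectorised band lookup; NaN in -> NaN out; out-of-domain -> error."""
        v = np.asarray(values, dtype=float)
        out = np.full(v.shape, np.nan)
        ok = ~np.isnan(v)
        lo, hi = self.domain
        bad = ok & ((v < lo) | (v > hi))
        if bad.any():
            first = float(v[bad].ravel()[0])
            raise Apache2Error(
                f"{self.name}: value {first} outside validated domain [{lo}, {hi}]"
            )
        for b in self.bands + self.gaps:
            inside = ok & (v >= b.lo) & (v <= b.hi)
            out[inside] = np.fmax(out[inside], b.points)
        return out


@dataclass
class ScoringDefinition:
    version: str
    logistic: dict[str, float]
    age_bands: tuple[Band, ...]
    chronic_health: dict[str, int]
    variables: dict[str, VariableBands]
    diagnostic_weights: dict[str, dict[str, float]]
    gcs_rule: str = "fifteen_minus_value"

    def diagnostic_weight(self, category: str, postoperative: bool) -> float:
        arm = "postoperative" if postoperative else "nonoperative"
        table = self.diagnostic_weights[arm]
        if category not in table:
            raise Apache2Error(
                f"diagnostic category {category!r} has no {arm} weight"
            )
        return table[category]

    def age_points(self, age: np.ndarray) -> np.ndarray:
        a = np.asarray(age, dtype=float)
        out = np.full(a.shape, np.nan)
        for b in self.age_bands:
            out[(a >= b.lo) & (a <= b.hi)] = b.points
        if np.isnan(out[~np.isnan(a)]).any():
            raise Apache2Error("age outside the age-band table")
        return out


def _parse_bands(name: str, raw: Sequence[Mapping]) -> tuple[tuple[Band, ...], tuple[Band, ...]]:
    bands = sorted(
        (
            Band(
                float(b.get("min", -np.inf)),
                float(b.get("max", np.inf)),
                int(b["points"]),
            )
            for b in raw
        ),
        key=lambda b: (b.lo, b.hi),
    )
    # overlap check
    for a, b in zip(bands, bands[1:]):
        if b.lo <= a.hi:
            raise Apache2Error(f"{name}: overlapping bands {a} and {b}")
    # gap between printed bands resolves to the more severe neighbour
    gaps = tuple(
        Band(np.nextafter(a.hi, np.inf), np.nextafter(b.lo, -np.inf),
             max(a.points, b.points))
        for a, b in zip(bands, bands[1:])
        if np.nextafter(a.hi, np.inf) <= np.nextafter(b.lo, -np.inf)
    )
    return tuple(bands), gaps


def _validate_variable(vb: VariableBands) -> None:
    pts = [b.points for b in vb.bands]
    zeros = [i for i, p in enumerate(pts) if p == 0]
    if not zeros:
        raise Apache2Error(f"{vb.name}: no normal (0-point) band")
    lo_z, hi_z = zeros[0], zeros[-1]
    below = pts[: lo_z + 1][::-1]  # from normal outward to low values
    above = pts[hi_z:]
    for side in (below, above):
        if any(b < a for a, b in zip(side, side[1:])):
            raise Apache2Error(
                f"{vb.name}: points not weakly increasing away from normal"
            )


def load_scoring_definition(path: str | Path | None = None) -> ScoringDefinition:
    """Load and validate the packaged (or a user-supplied) scoring data file."""
    if path is None:
        src = resources.files("icubench.data").joinpath("apache2_scoring.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())

    variables: dict[str, VariableBands] = {}
    gcs_rule = "fifteen_minus_value"
    for name, spec in raw["variables"].items():
        domain = tuple(float(x) for x in spec["domain"])
        if spec.get("rule") == "fifteen_minus_value":
            gcs_rule = "fifteen_minus_value"
            variables[name] = VariableBands(name, spec.get("unit", ""), domain, (), ())
            continue
        bands, gaps = _parse_bands(name, spec["bands"])
        vb = VariableBands(name, spec.get("unit", ""), domain, bands, gaps)
        _validate_variable(vb)
        variables[name] = vb

    age_bands, _ = _parse_bands("age", raw["age_points"])
    return ScoringDefinition(
        version=str(raw["version"]),
        logistic={k: float(v) for k, v in raw["logistic"].items()},
        age_bands=age_bands,
        chronic_health={k: int(v) for k, v in raw["chronic_health"].items()},
        variables=variables,
        diagnostic_weights={
            arm: {k: float(v) for k, v in table.items()}
            for arm, table in raw["diagnostic_weights"].items()
        },
        gcs_rule=gcs_rule,
    )


# ---------------------------------------------------------------------------
# component scoring
# ---------------------------------------------------------------------------


@dataclass
class OxygenationContext:
    """Inputs the oxygenation component needs besides PaO2."""

    fio2_high: float | np.ndarray | None = None
    aado2_high: float | np.ndarray | None = None


def _score_two_sided(vb: VariableBands, lowest, highest) -> np.ndarray:
    lo = vb.points_of(np.asarray(lowest, dtype=float))
    hi = vb.points_of(np.asarray(highest, dtype=float))
    return np.fmax(lo, hi)  # fmax ignores NaN unless both NaN


def _score_gcs(definition: ScoringDefinition, lowest) -> np.ndarray:
    v = np.asarray(lowest, dtype=float)
    lo, hi = definition.variables["gcs"].domain
    ok = ~np.isnan(v)
    if ((v[ok] < lo) | (v[ok] > hi)).any():
        bad = float(v[ok][(v[ok] < lo) | (v[ok] > hi)][0])
        raise Apache2Error(f"gcs: value {bad} outside validated domain [{lo}, {hi}]")
    return 15.0 - v


def _score_oxygenation(
    definition: ScoringDefinition, pao2_low, fio2_high, aado2_high
) -> np.ndarray:
    pao2 = np.asarray(pao2_low, dtype=float)
    fio2 = np.asarray(
        fio2_high if fio2_high is not None else np.nan, dtype=float
    )
    aado2 = np.asarray(
        aado2_high if aado2_high is not None else np.nan, dtype=float
    )
    pao2, fio2, aado2 = np.broadcast_arrays(pao2, fio2, aado2)
    high_fio2 = ~np.isnan(fio2) & (fio2 >= 0.5)
    pts_pao2 = definition.variables["pao2"].points_of(pao2)
    pts_aado2 = definition.variables["aado2"].points_of(aado2)
    return np.where(high_fio2, pts_aado2, pts_pao2)


def score_component(
    variable: str,
    lowest: float | None,
    highest: float | None,
    definition: ScoringDefinition,
    *,
    acute_renal_failure: bool = False,
    oxygenation: OxygenationContext | None = None,
) -> int | None:
    """Score one physiologic component from its first-24h extrema.

    Returns the integer point value, or ``None`` when the inputs needed for
    the component are all absent (resolution is then deferred to the
    missing-data strategy).
    """
    lo = np.nan if lowest is None else float(lowest)
    hi = np.nan if highest is None else float(highest)
    if variable == "gcs":
        pts = _score_gcs(definition, [lo])[0]
    elif variable == "oxygenation":
        ctx = oxygenation or OxygenationContext()
        fio2 = np.nan if ctx.fio2_high is None else ctx.fio2_high
        aado2 = np.nan if ctx.aado2_high is None else ctx.aado2_high
        pts = _score_oxygenation(definition, [lo], [fio2], [aado2])[0]
    elif variable in definition.variables:
        pts = _score_two_sided(definition.variables[variable], [lo], [hi])[0]
    else:
        raise Apache2Error(f"unknown variable {variable!r}")
    if variable == "creatinine" and acute_renal_failure and not np.isnan(pts):
        pts *= 2
    return None if np.isnan(pts) else int(pts)


def score_components(
    wide: pd.DataFrame,
    definition: ScoringDefinition,
    acute_renal_failure: np.ndarray | pd.Series | None = None,
) -> pd.DataFrame:
    """Vectorised component scoring of a wide first-24h extrema table.

    ``wide`` carries ``<var>_low`` / ``<var>_high`` columns for the two-sided
    variables, plus ``gcs_low``, ``pao2_low``, ``fio2_high`` and (optionally)
    ``aado2_high``.  Returns one float column per component; NaN marks a
    component whose inputs were absent.
    """
    out = pd.DataFrame(index=wide.index)

    def col(name: str) -> np.ndarray:
        if name in wide.columns:
            return wide[name].to_numpy(dtype=float)
        return np.full(len(wide), np.nan)

    for var in TWO_SIDED_COMPONENTS:
        out[var] = _score_two_sided(
            definition.variables[var], col(f"{var}_low"), col(f"{var}_high")
        )
    out["oxygenation"] = _score_oxygenation(
        definition, col("pao2_low"), col("fio2_high"), col("aado2_high")
    )
    out["gcs"] = _score_gcs(definition, col("gcs_low"))
    if acute_renal_failure is not None:
        arf = np.asarray(acute_renal_failure, dtype=bool)
        out.loc[arf, "creatinine"] = out.loc[arf, "creatinine"] * 2
    return out[list(PHYSIOLOGY_COMPONENTS)]


# ---------------------------------------------------------------------------
# totals and risk
# ---------------------------------------------------------------------------


def chronic_points(
    chronic: np.ndarray, elective_postop: np.ndarray, definition: ScoringDefinition
) -> np.ndarray:
    """Chronic-health points: 5 nonoperative/emergency-postop, 2 elective."""
    chronic = np.asarray(chronic, dtype=bool)
    elective = np.asarray(elective_postop, dtype=bool)
    pts = np.where(elective, definition.chronic_health["elective_postop"],
                   definition.chronic_health["nonoperative"])
    return np.where(chronic, pts, definition.chronic_health["none"])


def compute_totals(
    points: pd.DataFrame,
    age: np.ndarray | pd.Series,
    chronic: np.ndarray | pd.Series,
    elective_postop: np.ndarray | pd.Series,
    definition: ScoringDefinition,
) -> pd.DataFrame:
    """APS, age points, chronic points and total score for resolved components.

    Every component must already be resolved (no NaN) — run the missing-data
    strategy first.
    """
    comp = points[list(PHYSIOLOGY_COMPONENTS)]
    if comp.isna().any().any():
        bad = comp.columns[comp.isna().any()].tolist()
        raise Apache2Error(
            f"unresolved components {bad}: apply a missingness strategy first"
        )
    aps = comp.to_numpy(dtype=float).sum(axis=1)
    agep = definition.age_points(np.asarray(age, dtype=float))
    chp = chronic_points(chronic, elective_postop, definition)
    total = aps + agep + chp
    return pd.DataFrame(
        {
            "aps": aps.astype(int),
            "age_points": agep.astype(int),
            "chronic_points": chp.astype(int),
            "total": total.astype(int),
        },
        index=points.index,
    )


def compute_total(
    components: Mapping[str, int],
    age: int,
    chronic: bool,
    elective_postop: bool,
    definition: ScoringDefinition,
) -> tuple[int, int, int, int]:
    """Scalar convenience wrapper: (aps, age_points, chronic_points, total)."""
    missing = [v for v in PHYSIOLOGY_COMPONENTS if components.get(v) is None]
    if missing:
        raise Apache2Error(
            f"unresolved components {missing}: apply a missingness strategy first"
        )
    row = pd.DataFrame({v: [float(components[v])] for v in PHYSIOLOGY_COMPONENTS})
    t = compute_totals(row, [age], [chronic], [elective_postop], definition)
    return (
        int(t["aps"].iloc[0]),
        int(t["age_points"].iloc[0]),
        int(t["chronic_points"].iloc[0]),
        int(t["total"].iloc[0]),
    )


def mortality_risk(
    total: np.ndarray | int,
    category_weight: np.ndarray | float,
    emergency_postop: np.ndarray | bool,
    definition: ScoringDefinition,
) -> np.ndarray | float:
    """Predicted ICU mortality risk: inverse-logit of the APACHE II equation."""
    t = np.asarray(total, dtype=float)
    if np.isnan(t).any():
        raise Apache2Error("total score contains NaN")
    if ((t < 0) | (t > 71)).any():
        raise Apache2Error("total score outside [0, 71]")
    w = np.asarray(category_weight, dtype=float)
    if np.isnan(w).any():
        raise Apache2Error("category weight absent: row should have been excluded")
    c = definition.logistic
    eta = (
        c["intercept"]
        + c["per_point"] * t
        + c["emergency_postop"] * np.asarray(emergency_postop, dtype=float)
        + w
    )
    risk = expit(eta)
    if np.ndim(total) == 0 and np.ndim(category_weight) == 0:
        return float(risk)
    return risk


@dataclass
class Apache2Result:
    """Scored admission: component points, score parts, and mortality risk."""

    component_points: dict[str, int]
    aps: int
    age_points: int
    chronic_points: int
    total_score: int
    diagnostic_weight: float
    risk: float


def score_admission(
    components: Mapping[str, int],
    age: int,
    chronic: bool,
    elective_postop: bool,
    emergency_postop: bool,
    category: str,
    definition: ScoringDefinition,
) -> Apache2Result:
    aps, agep, chp, total = compute_total(
        components, age, chronic, elective_postop, definition
    )
    weight = definition.diagnostic_weight(
        category, postoperative=elective_postop or emergency_postop
    )
    risk = mortality_risk(total, weight, emergency_postop, definition)
    return Apache2Result(
        component_points=dict(components),
        aps=aps,
        age_points=agep,
        chronic_points=chp,
        total_score=total,
        diagnostic_weight=weight,
        risk=float(risk),
    )


# ---------------------------------------------------------------------------
# reason-for-admission mapping
# ---------------------------------------------------------------------------


@dataclass
class DiagnosisMap:
    """Per-source mapping of reason-for-admission codes to APACHE II categories.

    Supports an optional intermediate classification stage (e.g. a source that
    records reasons in its own vocabulary, maps them to an APACHE IV-style
    grouping, and from there to APACHE II categories).
    """

    source: str
    entries: dict[str, str]
    intermediate_entries: dict[str, str] = field(default_factory=dict)
    intermediate: str | None = None


def _entries_from(raw, what: str) -> dict[str, str]:
    if raw is None:
        return {}
    if isinstance(raw, dict):
        return {str(k): str(v) for k, v in raw.items()}
    out: dict[str, str] = {}
    for item in raw:
        code, target = str(item["code"]), str(item["target"])
        if code in out and out[code] != target:
            raise Apache2Error(
                f"{what}: duplicate code {code!r} maps to both "
                f"{out[code]!r} and {target!r}"
            )
        out[code] = target
    return out


def load_diagnosis_map(path: str | Path) -> DiagnosisMap:
    raw = yaml.safe_load(Path(path).read_text())
    return DiagnosisMap(
        source=str(raw.get("source", "")),
        entries=_entries_from(raw.get("entries"), "entries"),
        intermediate_entries=_entries_from(
            raw.get("intermediate_entries"), "intermediate_entries"
        ),
        intermediate=raw.get("intermediate"),
    )


def map_reason(code, dmap: DiagnosisMap) -> str:
    """Deterministic lookup of a source reason code; ``UNMAPPED`` if unknown.

    Unmapped codes are never defaulted to a category — the row is excluded
    upstream, matching the cohort rule that admissions without an APACHE II
    reason for admission are dropped.
    """
    key = str(code)
    # normalise float-formatted numeric codes ("12.0" -> "12")
    if key.endswith(".0"):
        key = key[:-2]
    if key not in dmap.entries:
        return UNMAPPED
    target = dmap.entries[key]
    if dmap.intermediate_entries:
        return dmap.intermediate_entries.get(target, UNMAPPED)
    return target
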
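"""Seeded synthetic OMOP stores with known ground truth.

The generator emulates the structure of two ICU quality-registry OMOP CDM
databases so that every downstream stage (cohort selection, first-24h worst
value extraction, APACHE II scoring, missing-data handling, SMR benchmarking)
can be exercised end to end with a known answer:

* each admission draws a latent severity ``z ~ Normal(0, 1)``; every
  physiologic variable's worst first-24h value is a monotone (stochastic) map
  of ``z``, sampled inside the scoring definition's value bands so that total
  scores span roughly 0-40;
* death is Bernoulli with probability ``min(1, multiplier x risk)`` where the
  risk is the APACHE II risk of the generated values and the multiplier is the
  per-ICU true SMR (1.0 = on-target care), which makes SMR estimation a
  parameter-recovery experiment;
* raw measurement events (2-6 per variable per stay) are timestamped inside
  the first 24 hours with extrema equal to the truth values, plus occasional
  more-extreme distractor events after the 24 h window;
* two source dialects are emulated: dialect A and dialect B differ in the
  leukocyte concept code (automated 3000905 vs manual 3003282), in the table
  holding the chronic-organ-insufficiency comorbidity (condition_occurrence vs
  observation) and in the reason-for-admission vocabulary (dialect B chains
  through an intermediate classification);
* MCAR and MAR missingness can be layered on afterwards, MAR through a
  logistic link in ``z`` whose intercept is solved so the requested rate is
  the marginal missing fraction.

Dialect never influences a random draw: the same seed yields stores that
differ only in concept codes, table placement and reason vocabulary.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .apache2 import (
    PHYSIOLOGY_COMPONENTS,
    TWO_SIDED_COMPONENTS,
    ScoringDefinition,
    compute_totals,
    load_scoring_definition,
    mortality_risk,
    score_components,
)
from .omop_store import OmopStore

# ---------------------------------------------------------------------------
# vocabulary of the two synthetic dialects
# ---------------------------------------------------------------------------

#: measurement concept ids; dialect B differs only for the leukocyte count
MEASUREMENT_CONCEPTS: dict[str, dict[str, int]] = {
    "temperature": {"A": 3020891, "B": 3020891},
    "mean_arterial_pressure": {"A": 3027598, "B": 3027598},
    "heart_rate": {"A": 3027018, "B": 3027018},
    "respiratory_rate": {"A": 3024171, "B": 3024171},
    "pao2": {"A": 3027801, "B": 3027801},
    "fio2": {"A": 3020716, "B": 3020716},
    "aado2": {"A": 3022875, "B": 3022875},
    "arterial_ph": {"A": 3010421, "B": 3010421},
    "sodium": {"A": 3019550, "B": 3019550},
    "potassium": {"A": 3023103, "B": 3023103},
    "creatinine": {"A": 3016723, "B": 3016723},
    "hematocrit": {"A": 3023314, "B": 3023314},
    "wbc": {"A": 3000905, "B": 3003282},  # automated vs manual count
    "gcs": {"A": 3032652, "B": 3032652},
}

UNIT_CONCEPTS: dict[str, int] = {
    "temperature": 586323,
    "mean_arterial_pressure": 8876,
    "heart_rate": 8541,
    "respiratory_rate": 8541,
    "pao2": 8876,
    "aado2": 8876,
    "fio2": 8523,
    "arterial_ph": 8482,
    "sodium": 8753,
    "potassium": 8753,
    "creatinine": 8840,
    "hematocrit": 8554,
    "wbc": 8848,
    "gcs": 0,
}

REASON_CONCEPT = 2000000001  # custom "reason for ICU admission" observation
ELECTIVE_POSTOP_CONCEPT = 2000000002
EMERGENCY_POSTOP_CONCEPT = 2000000003
CHRONIC_CONCEPT = 4064161  # severe chronic organ insufficiency / immunocompromise
ARF_CONCEPT = 197320  # acute renal failure
BURNS_CONCEPT = 4033240

GENDER_MALE = 8507
GENDER_FEMALE = 8532

#: dialect A records reasons in an APACHE-IV-like numeric code list
REASON_CODES_A: dict[str, int] = {
    "cardiovascular": 101,
    "respiratory": 102,
    "gastrointestinal": 103,
    "neurologic": 104,
    "metabolic_renal": 105,
    "sepsis": 106,
    "multiple_trauma": 107,
    "gi_bleeding": 108,
    "head_trauma": 109,
    "hemorrhagic_shock_hypovolemia": 110,
}

#: dialect B records SNOMED-CT-like codes mapped via the dialect-A list
REASON_CODES_B: dict[str, int] = {cat: 91000000 + code for cat, code in REASON_CODES_A.items()}

UNMAPPED_REASON_CODE = 999  # a code deliberately absent from both maps

_PRECISION = {
    "temperature": 1,
    "mean_arterial_pressure": 0,
    "heart_rate": 0,
    "respiratory_rate": 0,
    "pao2": 0,
    "aado2": 0,
    "arterial_ph": 2,
    "sodium": 0,
    "potassium": 1,
    "creatinine": 1,
    "hematocrit": 1,
    "wbc": 1,
    "fio2": 2,
}

#: clinically plausible outer limits used to close the open outer bands
_PLAUSIBLE = {
    "temperature": (27.0, 43.0),
    "mean_arterial_pressure": (30.0, 190.0),
    "heart_rate": (25.0, 210.0),
    "respiratory_rate": (2.0, 65.0),
    "pao2": (35.0, 120.0),
    "aado2": (20.0, 650.0),
    "arterial_ph": (6.8, 7.95),
    "sodium": (105.0, 195.0),
    "potassium": (1.5, 8.5),
    "creatinine": (0.3, 6.0),
    "hematocrit": (12.0, 70.0),
    "wbc": (0.2, 60.0),
}

#: probability that a variable's worst derangement is on the high side
_P_HIGH_SIDE = {
    "temperature": 0.5,
    "mean_arterial_pressure": 0.3,
    "heart_rate": 0.7,
    "respiratory_rate": 0.6,
    "arterial_ph": 0.3,
    "sodium": 0.5,
    "potassium": 0.5,
    "creatinine": 0.9,
    "hematocrit": 0.3,
    "wbc": 0.7,
}

#: GCS worst value sampled per severity level (inclusive integer ranges)
_GCS_LEVELS = {0: (15, 15), 1: (13, 14), 2: (10, 12), 3: (7, 9), 4: (3, 6)}


class SimConfigError(ValueError):
    pass


@dataclass
class MissingnessRule:
    mechanism: str  # "MCAR" | "MAR"
    rate: float


@dataclass
class SimConfig:
    """Study conditions of the synthetic registries.

    Defaults emulate the published study setting: admissions to adult ICUs
    between 2019-07-01 and 2022-12-31, a male fraction and age distribution in
    the range the two registries report, and APACHE II totals with a median
    around 14-15.
    """

    seed: int = 0
    source_name: str = "src_a"
    dialect: str = "A"
    schema_version: str = "5.3"
    n_registries: int = 1
    icus_per_registry: int = 4
    patients_per_icu: int = 250
    admission_window: tuple[_dt.date, _dt.date] = (
        _dt.date(2019, 7, 1),
        _dt.date(2022, 12, 31),
    )
    age_distribution: dict = field(
        default_factory=lambda: {"type": "normal", "mean": 60.0, "sd": 17.0,
                                 "min": 14, "max": 95}
    )
    male_fraction: float = 0.59
    diagnostic_category_probs: dict[str, float] = field(
        default_factory=lambda: {
            "cardiovascular": 0.18,
            "respiratory": 0.24,
            "gastrointestinal": 0.18,
            "neurologic": 0.14,
            "metabolic_renal": 0.16,
            "sepsis": 0.10,
        }
    )
    elective_postop_prob: float = 0.15
    emergency_postop_prob: float = 0.10
    chronic_prob: float = 0.15
    arf_prob: float = 0.05
    burns_prob: float = 0.01
    underage_handled_by_age_distribution: bool = True
    pre_window_prob: float = 0.01
    missing_reason_prob: float = 0.02
    unmapped_reason_prob: float = 0.01
    readmission_prob: float = 0.05
    distractor_prob: float = 0.25
    smr_multiplier_per_icu: float | list[float] = 1.0
    missingness: dict[str, MissingnessRule] = field(default_factory=dict)
    severity_thresholds: tuple[float, ...] = (-0.126, 0.524, 1.036, 1.645)

    @property
    def n_icus(self) -> int:
        return self.n_registries * self.icus_per_registry

    def multipliers(self) -> np.ndarray:
        m = self.smr_multiplier_per_icu
        arr = (
            np.full(self.n_icus, float(m))
            if np.isscalar(m)
            else np.asarray(m, dtype=float)
        )
        if arr.shape != (self.n_icus,):
            raise SimConfigError(
                f"smr_multiplier_per_icu: expected scalar or {self.n_icus} values"
            )
        return arr

    def validate(self) -> None:
        if self.dialect not in ("A", "B"):
            raise SimConfigError(f"dialect: must be 'A' or 'B', got {self.dialect!r}")
        for name in ("n_registries", "icus_per_registry", "patients_per_icu"):
            if getattr(self, name) < 1:
                raise SimConfigError(f"{name}: must be >= 1")
        if not self.admission_window[0] < self.admission_window[1]:
            raise SimConfigError("admission_window: start must precede end")
        probs = np.array(list(self.diagnostic_category_probs.values()))
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise SimConfigError("diagnostic_category_probs: must be a simplex")
        for name in (
            "male_fraction", "elective_postop_prob", "emergency_postop_prob",
            "chronic_prob", "arf_prob", "burns_prob", "pre_window_prob",
            "missing_reason_prob", "unmapped_reason_prob", "readmission_prob",
            "distractor_prob",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"{name}: must be in [0, 1], got {p}")
        if self.elective_postop_prob + self.emergency_postop_prob > 1.0:
            raise SimConfigError("elective + emergency postoperative probs exceed 1")
        if (self.multipliers() <= 0).any():
            raise SimConfigError("smr_multiplier_per_icu: must be > 0")
        for var, rule in self.missingness.items():
            if rule.mechanism not in ("MCAR", "MAR"):
                raise SimConfigError(f"missingness[{var}]: unknown mechanism")
            if not 0.0 <= rule.rate <= 1.0:
                raise SimConfigError(f"missingness[{var}]: rate must be in [0, 1]")


def simconfig_from_yaml(path) -> SimConfig:
    from pathlib import Path

    raw = yaml.safe_load(Path(path).read_text())
    if "admission_window" in raw:
        raw["admission_window"] = tuple(
            v if isinstance(v, _dt.date) else _dt.date.fromisoformat(str(v))
            for v in raw["admission_window"]
        )
    if "missingness" in raw:
        raw["missingness"] = {
            k: MissingnessRule(v["mechanism"], float(v["rate"]))
            for k, v in raw["missingness"].items()
        }
    return SimConfig(**raw)


# ---------------------------------------------------------------------------
# band sampling machinery
# ---------------------------------------------------------------------------


def _side_level_ranges(definition: ScoringDefinition, var: str):
    """Per (side, severity level 0-4) sampling interval for one variable.

    Level 0 is the normal band; level L on a side is the band with the largest
    point value <= L on that side (falling back toward normal when a side has
    no band at that level).
    """
    vb = definition.variables[var]
    plo, phi = _PLAUSIBLE[var]
    bands = list(vb.bands)
    zero = [i for i, b in enumerate(bands) if b.points == 0][0]

    def clip(b):
        return (max(b.lo, plo), min(b.hi, phi))

    normal = clip(bands[zero])
    low_side = bands[:zero][::-1]  # outward from normal toward low values
    high_side = bands[zero + 1:]
    out = {}
    for side, cands in (("low", low_side), ("high", high_side)):
        lo = np.empty(5)
        hi = np.empty(5)
        for level in range(5):
            best = None
            for b in cands:
                if b.points <= level and (best is None or b.points > best.points):
                    best = b
            rng_ = clip(best) if best is not None and best.points > 0 else normal
            lo[level], hi[level] = rng_
        out[side] = (lo, hi)
    return out


def _round(var: str, x: np.ndarray) -> np.ndarray:
    return np.round(x, _PRECISION[var])


def mar_intercept(score: np.ndarray, rate: float) -> float:
    """Intercept a of P(missing) = expit(a + score) with the given marginal rate.

    Solved on the realised score sample so the marginal missing fraction
    equals ``rate`` exactly in expectation.
    """
    if not 0.0 < rate < 1.0:
        raise ValueError("rate must be in (0, 1) for a MAR link")
    s = np.asarray(score, dtype=float)

    def marginal(a):
        return float(expit(a + s).mean()) - rate

    return brentq(marginal, -40.0, 40.0)


def mar_score(death, los_days) -> np.ndarray:
    """Observed-severity score driving the MAR link.

    Missingness is tied to the stay's *observed* outcome — the ICU death
    indicator and (standardised log) length of stay — exactly the always-
    present variables the imputation protocol conditions on, which makes the
    mechanism missing-at-random for that protocol.  Sicker stays (deaths,
    atypical lengths of stay) lose more laboratory values.
    """
    d = np.asarray(death, dtype=float)
    log_los = np.log(np.asarray(los_days, dtype=float))
    sd = log_los.std()
    l = (log_los - log_los.mean()) / (sd if sd > 0 else 1.0)
    return d + l


# ---------------------------------------------------------------------------
# truth-table simulation
# ---------------------------------------------------------------------------


def simulate_truth(
    config: SimConfig, definition: ScoringDefinition | None = None
) -> pd.DataFrame:
    """Draw the per-admission ground truth (no events materialised).

    One row per ICU admission with identifiers, demographics, latent severity,
    true first-24h extrema per variable, APACHE II score parts, risk, the
    per-ICU SMR multiplier and the realised death.  ``excluded_reason`` is
    non-empty for admissions the cohort-selection rules should drop.
    """
    config.validate()
    definition = definition or load_scoring_definition()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_icus * config.patients_per_icu

    icu_index = np.repeat(np.arange(config.n_icus), config.patients_per_icu)
    registry_index = icu_index // config.icus_per_registry
    care_site_id = 1000 * (registry_index + 1) + (icu_index % config.icus_per_registry) + 1
    registry = np.array(
        [f"{config.source_name}-REG{r + 1:02d}" for r in registry_index]
    )
    icu = np.array(
        [f"ICU{c % 1000:02d}" for c in care_site_id]
    )

    ad = config.age_distribution
    if ad.get("type", "normal") != "normal":
        raise SimConfigError("age_distribution: only type 'normal' is implemented")
    age = np.clip(
        np.round(rng.normal(ad["mean"], ad["sd"], n)), ad["min"], ad["max"]
    ).astype(int)
    male = rng.random(n) < config.male_fraction

    cats = list(config.diagnostic_category_probs)
    category = rng.choice(
        cats, size=n, p=list(config.diagnostic_category_probs.values())
    )
    u = rng.random(n)
    elective = u < config.elective_postop_prob
    emergency = (~elective) & (
        u < config.elective_postop_prob + config.emergency_postop_prob
    )
    chronic = rng.random(n) < config.chronic_prob
    arf = rng.random(n) < config.arf_prob
    burns = rng.random(n) < config.burns_prob

    # admission timing
    start, end = config.admission_window
    span_days = (end - start).days
    day = rng.integers(0, span_days + 1, n)
    pre_window = rng.random(n) < config.pre_window_prob
    day = np.where(pre_window, -rng.integers(1, 180, n), day)
    seconds = rng.integers(0, 86400, n)
    icu_admit = (
        pd.Timestamp(start)
        + pd.to_timedelta(day, unit="D")
        + pd.to_timedelta(seconds, unit="s")
    )
    los_days = np.maximum(0.25, rng.lognormal(np.log(2.0), 0.9, n))
    icu_discharge = icu_admit + pd.to_timedelta(np.round(los_days * 86400), unit="s")

    # latent severity and per-variable worst values
    z = rng.normal(size=n)
    thresholds = np.asarray(config.severity_thresholds)
    wide: dict[str, np.ndarray] = {}
    for var in TWO_SIDED_COMPONENTS:
        latent = (z + rng.normal(size=n)) / np.sqrt(2.0)
        level = np.searchsorted(thresholds, latent)
        high_side = rng.random(n) < _P_HIGH_SIDE[var]
        ranges = _side_level_ranges(definition, var)
        lo = np.where(high_side, ranges["high"][0][level], ranges["low"][0][level])
        hi = np.where(high_side, ranges["high"][1][level], ranges["low"][1][level])
        worst = rng.uniform(lo, hi)
        nlo, nhi = ranges["high"][0][0], ranges["high"][1][0]  # normal band
        other = rng.uniform(nlo, nhi, n)
        v_hi = _round(var, np.maximum(worst, other))
        v_lo = _round(var, np.minimum(worst, other))
        wide[f"{var}_high"] = v_hi
        wide[f"{var}_low"] = v_lo

    # oxygenation: FiO2 rail selects PaO2 vs A-a gradient bands
    fio2_latent = norm.cdf((z + rng.normal(size=n)) / np.sqrt(2.0))
    high_fio2 = fio2_latent > 0.7
    fio2 = np.where(high_fio2, rng.uniform(0.5, 1.0, n), rng.uniform(0.21, 0.45, n))
    wide["fio2_high"] = _round("fio2", fio2)

    ox_latent = (z + rng.normal(size=n)) / np.sqrt(2.0)
    ox_level = np.searchsorted(thresholds, ox_latent)
    pao2_ranges = _side_level_ranges(definition, "pao2")["low"]
    pao2 = np.where(
        high_fio2,
        rng.uniform(70.0, 110.0, n),
        rng.uniform(pao2_ranges[0][ox_level], pao2_ranges[1][ox_level]),
    )
    wide["pao2_low"] = _round("pao2", pao2)
    aado2_ranges = _side_level_ranges(definition, "aado2")["high"]
    aado2 = rng.uniform(aado2_ranges[0][ox_level], aado2_ranges[1][ox_level])
    wide["aado2_high"] = np.where(high_fio2, _round("aado2", aado2), np.nan)

    gcs_latent = (z + rng.normal(size=n)) / np.sqrt(2.0)
    gcs_level = np.searchsorted(thresholds, gcs_latent)
    glo = np.array([_GCS_LEVELS[k][0] for k in range(5)])[gcs_level]
    ghi = np.array([_GCS_LEVELS[k][1] for k in range(5)])[gcs_level]
    wide["gcs_low"] = rng.integers(glo, ghi + 1).astype(float)

    wide_df = pd.DataFrame(wide)
    points = score_components(wide_df, definition, acute_renal_failure=arf)
    totals = compute_totals(points, age, chronic, elective, definition)
    weight = np.array(
        [
            definition.diagnostic_weight(c, postoperative=el or em)
            for c, el, em in zip(category, elective, emergency)
        ]
    )
    risk = np.asarray(
        mortality_risk(totals["total"].to_numpy(), weight, emergency, definition)
    )

    multiplier = config.multipliers()[icu_index]
    death = rng.random(n) < np.minimum(1.0, multiplier * risk)
    death_offset = rng.uniform(0.05, 0.95, n) * los_days
    death_datetime = icu_admit + pd.to_timedelta(
        np.round(death_offset * 86400), unit="s"
    )

    # cohort-exclusion ground truth, in the order cohort selection applies
    missing_reason = rng.random(n) < config.missing_reason_prob
    unmapped = rng.random(n) < config.unmapped_reason_prob
    excluded = np.full(n, "", dtype=object)
    excluded[missing_reason] = "missing_reason"
    excluded[burns] = "burns"
    excluded[age < 17] = "age"
    excluded[pre_window] = "date_window"
    unmappable = unmapped & (excluded == "")
    has_readmission = rng.random(n) < config.readmission_prob

    truth = pd.DataFrame(
        {
            "person_id": np.arange(1, n + 1),
            "visit_occurrence_id": np.arange(10_001, 10_001 + n),
            "visit_detail_id": np.arange(20_001, 20_001 + n),
            "care_site_id": care_site_id,
            "registry": registry,
            "icu": icu,
            "age": age,
            "male": male,
            "year_of_birth": icu_admit.year - age,
            "icu_admit": icu_admit,
            "icu_discharge": icu_discharge,
            "los_days": np.round(los_days * 86400) / 86400.0,
            "admission_type": np.where(
                elective, "elective_postop",
                np.where(emergency, "emergency_postop", "nonoperative"),
            ),
            "elective_postop": elective,
            "emergency_postop": emergency,
            "category": category,
            "chronic": chronic,
            "arf": arf,
            "burns": burns,
            "z": z,
            "multiplier": multiplier,
            "excluded_reason": excluded,
            "reason_unmappable": unmappable,
            "has_readmission": has_readmission,
            "death": death,
            "death_datetime": pd.Series(death_datetime).where(death),
        }
    )
    truth = pd.concat([truth, wide_df, points.add_prefix("pts_"), totals], axis=1)
    truth["diagnostic_weight"] = weight
    truth["risk"] = risk
    truth["in_cohort"] = (truth["excluded_reason"] == "") & ~truth["reason_unmappable"]
    return truth


def unit_truth(truth: pd.DataFrame, level: str = "icu") -> pd.DataFrame:
    """Realised observed/expected deaths per unit among analysable admissions."""
    rows = truth[truth["in_cohort"]]
    key = "care_site_id" if level == "icu" else "registry"
    g = rows.groupby(key)
    out = pd.DataFrame(
        {
            "n_admissions": g.size(),
            "observed": g["death"].sum(),
            "expected": g["risk"].sum(),
            "multiplier": g["multiplier"].first(),
        }
    )
    out["smr"] = out["observed"] / out["expected"]
    return out.reset_index()


# ---------------------------------------------------------------------------
# store materialisation
# ---------------------------------------------------------------------------


def generate_store(
    config: SimConfig, definition: ScoringDefinition | None = None
) -> tuple[OmopStore, pd.DataFrame]:
    """Materialise a synthetic OMOP store and its truth table.

    Identical seeds give byte-identical stores; the dialect only relabels
    concept codes, table placement and the reason vocabulary.
    """
    definition = definition or load_scoring_definition()
    truth = simulate_truth(config, definition)
    rng = np.random.default_rng([config.seed, 1])
    n = len(truth)
    dialect = config.dialect

    person = pd.DataFrame(
        {
            "person_id": truth["person_id"].astype("Int64"),
            "gender_concept_id": pd.array(
                np.where(truth["male"], GENDER_MALE, GENDER_FEMALE), dtype="Int64"
            ),
            "year_of_birth": truth["year_of_birth"].astype("Int64"),
        }
    )
    visit_occurrence = pd.DataFrame(
        {
            "visit_occurrence_id": truth["visit_occurrence_id"].astype("Int64"),
            "person_id": truth["person_id"].astype("Int64"),
            "visit_start_date": truth["icu_admit"].dt.normalize(),
            "visit_end_date": (
                truth["icu_discharge"] + pd.Timedelta(days=2)
            ).dt.normalize(),
            "admitted_from_concept_id": pd.array([pd.NA] * n, dtype="Int64"),
        }
    )
    visit_detail = pd.DataFrame(
        {
            "visit_detail_id": truth["visit_detail_id"].astype("Int64"),
            "visit_occurrence_id": truth["visit_occurrence_id"].astype("Int64"),
            "person_id": truth["person_id"].astype("Int64"),
            "care_site_id": truth["care_site_id"].astype("Int64"),
            "visit_detail_start_datetime": truth["icu_admit"],
            "visit_detail_end_datetime": truth["icu_discharge"],
            "discharged_to_concept_id": pd.array([pd.NA] * n, dtype="Int64"),
        }
    )

    # readmission stays: a later ICU encounter inside the same hospital visit
    re_rows = truth[truth["has_readmission"]]
    if len(re_rows):
        re_start = re_rows["icu_discharge"] + pd.to_timedelta(
            rng.integers(3600, 48 * 3600, len(re_rows)), unit="s"
        )
        re_detail = pd.DataFrame(
            {
                "visit_detail_id": (90_000 + np.arange(len(re_rows))).astype("int64"),
                "visit_occurrence_id": re_rows["visit_occurrence_id"].to_numpy(),
                "person_id": re_rows["person_id"].to_numpy(),
                "care_site_id": re_rows["care_site_id"].to_numpy(),
                "visit_detail_start_datetime": re_start.to_numpy(),
                "visit_detail_end_datetime": (
                    re_start + pd.Timedelta(days=1)
                ).to_numpy(),
            }
        )
        re_detail["discharged_to_concept_id"] = pd.array(
            [pd.NA] * len(re_rows), dtype="Int64"
        )
        for c in ("visit_detail_id", "visit_occurrence_id", "person_id", "care_site_id"):
            re_detail[c] = re_detail[c].astype("Int64")
        visit_detail = pd.concat([visit_detail, re_detail], ignore_index=True)

    # --- measurement events -------------------------------------------------
    meas_parts: list[pd.DataFrame] = []

    def add_events(var: str, per_adm_values: list[np.ndarray], offsets: list[np.ndarray]):
        values = np.concatenate(per_adm_values)
        offs = np.concatenate(offsets)
        reps = np.array([len(v) for v in per_adm_values])
        # per_adm_values entries are aligned with truth rows
        pid = np.repeat(truth["person_id"].to_numpy(), reps)
        vdid = np.repeat(truth["visit_detail_id"].to_numpy(), reps)
        admit = np.repeat(truth["icu_admit"].to_numpy(), reps)
        meas_parts.append(
            pd.DataFrame(
                {
                    "person_id": pid,
                    "visit_detail_id": vdid,
                    "measurement_concept_id": MEASUREMENT_CONCEPTS[var][dialect],
                    "measurement_datetime": admit + offs.astype("timedelta64[s]"),
                    "value_as_number": values,
                    "unit_concept_id": UNIT_CONCEPTS[var],
                }
            )
        )

    def window_offsets(count: int) -> np.ndarray:
        return rng.integers(0, 24 * 3600, count)

    for var in TWO_SIDED_COMPONENTS:
        lo = truth[f"{var}_low"].to_numpy()
        hi = truth[f"{var}_high"].to_numpy()
        n_ev = rng.integers(2, 7, n)
        n_fill = n_ev - 2
        fill = _round(var, rng.uniform(np.repeat(lo, n_fill), np.repeat(hi, n_fill)))
        values = np.concatenate([lo, hi, fill])
        order_pid = np.concatenate([np.arange(n), np.arange(n), np.repeat(np.arange(n), n_fill)])
        # regroup into truth-row order
        idx = np.argsort(order_pid, kind="stable")
        values = values[idx]
        reps = np.full(n, 0)
        np.add.at(reps, order_pid, 1)
        offs = window_offsets(len(values))

        pid = np.repeat(truth["person_id"].to_numpy(), reps)
        vdid = np.repeat(truth["visit_detail_id"].to_numpy(), reps)
        admit = np.repeat(truth["icu_admit"].to_numpy(), reps)
        df = pd.DataFrame(
            {
                "person_id": pid,
                "visit_detail_id": vdid,
                "measurement_concept_id": MEASUREMENT_CONCEPTS[var][dialect],
                "measurement_datetime": admit + offs.astype("timedelta64[s]"),
                "value_as_number": values,
                "unit_concept_id": UNIT_CONCEPTS[var],
            }
        )
        meas_parts.append(df)

        # out-of-window distractor: a more deranged value after the 24 h cut
        room = (truth["los_days"].to_numpy() * 24.0) > 30.0
        pick = room & (rng.random(n) < config.distractor_prob)
        if pick.any():
            plo, phi = _PLAUSIBLE[var]
            extreme = np.where(
                rng.random(pick.sum()) < 0.5,
                np.clip(hi[pick] + 0.15 * (phi - plo), plo, phi),
                np.clip(lo[pick] - 0.15 * (phi - plo), plo, phi),
            )
            meas_parts.append(
                pd.DataFrame(
                    {
                        "person_id": truth["person_id"].to_numpy()[pick],
                        "visit_detail_id": truth["visit_detail_id"].to_numpy()[pick],
                        "measurement_concept_id": MEASUREMENT_CONCEPTS[var][dialect],
                        "measurement_datetime": truth["icu_admit"].to_numpy()[pick]
                        + rng.integers(
                            24 * 3600 + 1, 30 * 3600, pick.sum()
                        ).astype("timedelta64[s]"),
                        "value_as_number": _round(var, extreme),
                        "unit_concept_id": UNIT_CONCEPTS[var],
                    }
                )
            )

    def single_sided(var: str, worst: np.ndarray, fill_lo, fill_hi, present=None):
        present = np.ones(n, bool) if present is None else present
        n_ev = np.where(present, rng.integers(1, 4, n), 0)
        n_fill = np.maximum(n_ev - 1, 0)
        fill = rng.uniform(np.repeat(fill_lo, n_fill), np.repeat(fill_hi, n_fill))
        fill = _round(var, fill) if var in _PRECISION else np.round(fill)
        worst_part = worst[present]
        order = np.concatenate([np.arange(n)[present], np.repeat(np.arange(n), n_fill)])
        values = np.concatenate([worst_part, fill])
        idx = np.argsort(order, kind="stable")
        values = values[idx]
        reps = np.zeros(n, int)
        np.add.at(reps, order, 1)
        offs = window_offsets(len(values))
        meas_parts.append(
            pd.DataFrame(
                {
                    "person_id": np.repeat(truth["person_id"].to_numpy(), reps),
                    "visit_detail_id": np.repeat(
                        truth["visit_detail_id"].to_numpy(), reps
                    ),
                    "measurement_concept_id": MEASUREMENT_CONCEPTS[var][dialect],
                    "measurement_datetime": np.repeat(
                        truth["icu_admit"].to_numpy(), reps
                    )
                    + offs.astype("timedelta64[s]"),
                    "value_as_number": values,
                    "unit_concept_id": UNIT_CONCEPTS[var],
                }
            )
        )

    gcs = truth["gcs_low"].to_numpy()
    single_sided("gcs", gcs, gcs, np.full(n, 15.0))
    pao2 = truth["pao2_low"].to_numpy()
    single_sided("pao2", pao2, pao2, np.minimum(pao2 + 30.0, _PLAUSIBLE["pao2"][1]))
    fio2 = truth["fio2_high"].to_numpy()
    single_sided("fio2", fio2, np.full(n, 0.21), fio2)
    aado2 = truth["aado2_high"].to_numpy()
    has_aado2 = ~np.isnan(aado2)
    single_sided(
        "aado2",
        aado2,
        np.where(has_aado2, np.maximum(aado2 - 150.0, _PLAUSIBLE["aado2"][0]), 0.0),
        np.where(has_aado2, aado2, 1.0),
        present=has_aado2,
    )

    # readmission stays get a couple of unremarkable observations
    if len(re_rows):
        k = len(re_rows)
        meas_parts.append(
            pd.DataFrame(
                {
                    "person_id": re_rows["person_id"].to_numpy(),
                    "visit_detail_id": 90_000 + np.arange(k),
                    "measurement_concept_id": MEASUREMENT_CONCEPTS["temperature"][dialect],
                    "measurement_datetime": re_detail[
                        "visit_detail_start_datetime"
                    ].to_numpy()
                    + rng.integers(0, 24 * 3600, k).astype("timedelta64[s]"),
                    "value_as_number": _round(
                        "temperature", rng.uniform(36.2, 37.8, k)
                    ),
                    "unit_concept_id": UNIT_CONCEPTS["temperature"],
                }
            )
        )

    measurement = pd.concat(meas_parts, ignore_index=True)
    measurement.insert(0, "measurement_id", np.arange(1, len(measurement) + 1))
    for c in (
        "measurement_id", "person_id", "visit_detail_id",
        "measurement_concept_id", "unit_concept_id",
    ):
        measurement[c] = measurement[c].astype("Int64")
    measurement["measurement_datetime"] = pd.to_datetime(
        measurement["measurement_datetime"]
    )

    # --- observations, conditions, death ------------------------------------
    obs_parts: list[pd.DataFrame] = []
    cond_parts: list[pd.DataFrame] = []

    def flag_rows(mask: np.ndarray, concept: int, to: str):
        rows = truth[mask]
        df = pd.DataFrame(
            {
                "person_id": rows["person_id"].to_numpy(),
                "visit_detail_id": rows["visit_detail_id"].to_numpy(),
                "concept_id": concept,
                "datetime": rows["icu_admit"].to_numpy(),
                "value_as_number": np.nan,
            }
        )
        (obs_parts if to == "observation" else cond_parts).append(df)

    has_reason = (truth["excluded_reason"] != "missing_reason").to_numpy()
    codes = np.array(
        [
            (REASON_CODES_A if dialect == "A" else REASON_CODES_B)[c]
            for c in truth["category"]
        ],
        dtype=float,
    )
    codes[truth["reason_unmappable"].to_numpy()] = UNMAPPED_REASON_CODE
    reason_rows = truth[has_reason]
    obs_parts.append(
        pd.DataFrame(
            {
                "person_id": reason_rows["person_id"].to_numpy(),
                "visit_detail_id": reason_rows["visit_detail_id"].to_numpy(),
                "concept_id": REASON_CONCEPT,
                "datetime": reason_rows["icu_admit"].to_numpy(),
                "value_as_number": codes[has_reason],
            }
        )
    )
    if len(re_rows):
        # readmission stays carry a reason too, so deduplication (not the
        # missing-reason rule) is what removes them
        re_mask = truth["has_readmission"].to_numpy()
        obs_parts.append(
            pd.DataFrame(
                {
                    "person_id": re_rows["person_id"].to_numpy(),
                    "visit_detail_id": re_detail["visit_detail_id"].to_numpy(),
                    "concept_id": REASON_CONCEPT,
                    "datetime": re_detail["visit_detail_start_datetime"].to_numpy(),
                    "value_as_number": codes[re_mask],
                }
            )
        )
    flag_rows(truth["elective_postop"].to_numpy(), ELECTIVE_POSTOP_CONCEPT, "observation")
    flag_rows(truth["emergency_postop"].to_numpy(), EMERGENCY_POSTOP_CONCEPT, "observation")
    flag_rows(
        truth["chronic"].to_numpy(),
        CHRONIC_CONCEPT,
        "condition_occurrence" if dialect == "A" else "observation",
    )
    flag_rows(truth["arf"].to_numpy(), ARF_CONCEPT, "condition_occurrence")
    flag_rows(truth["burns"].to_numpy(), BURNS_CONCEPT, "condition_occurrence")

    observation = pd.concat(obs_parts, ignore_index=True).rename(
        columns={"concept_id": "observation_concept_id", "datetime": "observation_datetime"}
    )
    observation.insert(0, "observation_id", np.arange(1, len(observation) + 1))
    condition = (
        pd.concat(cond_parts, ignore_index=True)
        if cond_parts
        else pd.DataFrame(
            columns=["person_id", "visit_detail_id", "concept_id", "datetime",
                     "value_as_number"]
        )
    )
    condition = condition.rename(
        columns={"concept_id": "condition_concept_id", "datetime": "condition_start_datetime"}
    ).drop(columns=["value_as_number"])
    condition.insert(0, "condition_occurrence_id", np.arange(1, len(condition) + 1))
    for df, cols in (
        (observation, ("observation_id", "person_id", "visit_detail_id",
                       "observation_concept_id")),
        (condition, ("condition_occurrence_id", "person_id", "visit_detail_id",
                     "condition_concept_id")),
    ):
        for c in cols:
            df[c] = df[c].astype("Int64")

    dead = truth[truth["death"]]
    death = pd.DataFrame(
        {
            "person_id": dead["person_id"].astype("Int64").to_numpy(),
            "death_datetime": dead["death_datetime"].to_numpy(),
        }
    )
    death["person_id"] = death["person_id"].astype("Int64")

    care_site = pd.DataFrame(
        {
            "care_site_id": pd.array(
                sorted(truth["care_site_id"].unique()), dtype="Int64"
            ),
        }
    )
    names = truth.drop_duplicates("care_site_id").set_index("care_site_id")
    care_site["care_site_name"] = [
        f"{names.at[c, 'registry']}/{names.at[c, 'icu']}"
        for c in care_site["care_site_id"]
    ]

    store = OmopStore(
        person=person,
        visit_occurrence=visit_occurrence,
        visit_detail=visit_detail,
        measurement=measurement,
        observation=observation,
        condition_occurrence=condition,
        death=death,
        care_site=care_site,
        schema_version=config.schema_version,
    )
    if config.missingness:
        store = apply_missingness(
            store, truth, config.missingness, seed=config.seed, dialect=dialect
        )
    return store, truth


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------


def apply_missingness(
    store: OmopStore,
    truth: pd.DataFrame,
    spec: Mapping[str, MissingnessRule],
    seed: int,
    dialect: str = "A",
) -> OmopStore:
    """Delete measurement events per the missingness spec; returns a new store.

    MCAR deletes each event of the target variable independently with the
    given rate.  MAR deletes all of a stay's events for the variable with
    probability ``expit(a + s)`` in the stay's observed-severity score ``s``
    (see :func:`mar_score`), with ``a`` solved so the marginal stay-level
    missing fraction equals the rate.
    """
    rng = np.random.default_rng([seed, 2])
    meas = store.measurement
    drop = np.zeros(len(meas), dtype=bool)
    score = pd.Series(
        mar_score(truth["death"], truth["los_days"]),
        index=truth["visit_detail_id"],
    )
    for var, rule in spec.items():
        if rule.rate == 0:
            continue
        concept = MEASUREMENT_CONCEPTS[var][dialect]
        target = (meas["measurement_concept_id"] == concept).to_numpy()
        if rule.mechanism == "MCAR":
            drop |= target & (rng.random(len(meas)) < rule.rate)
        else:
            a = mar_intercept(score.to_numpy(), rule.rate)
            hit = rng.random(len(score)) < expit(a + score.to_numpy())
            hit_vd = set(score.index[hit])
            drop |= target & meas["visit_detail_id"].isin(hit_vd).to_numpy()
    out = replace(store, measurement=meas[~drop].reset_index(drop=True))
    return out


def mask_wide(
    wide: pd.DataFrame,
    severity_score: np.ndarray,
    spec: Mapping[str, MissingnessRule],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Cell-level missingness on a wide extrema table (both extrema together).

    The stay-variable cell is the unit the downstream imputation must fill;
    MAR uses the same logistic link as :func:`apply_missingness` on the given
    observed-severity score (see :func:`mar_score`).
    """
    out = wide.copy()
    n = len(out)
    s = np.asarray(severity_score, dtype=float)
    for var, rule in spec.items():
        if rule.rate == 0:
            continue
        if rule.mechanism == "MCAR":
            hit = rng.random(n) < rule.rate
        else:
            hit = rng.random(n) < expit(mar_intercept(s, rule.rate) + s)
        for col in (f"{var}_low", f"{var}_high"):
            if col in out.columns:
                out.loc[hit, col] = np.nan
    return out


def truth_wide(truth: pd.DataFrame) -> pd.DataFrame:
    """The wide extrema table implied by a truth table (analysable rows only)."""
    cols = [c for c in truth.columns if c.endswith("_low") or c.endswith("_high")]
    rows = truth[truth["in_cohort"]]
    return rows.set_index("visit_detail_id")[cols]
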
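"""Cohort selection and first-24-hour worst-value extraction.

The extraction layer is deliberately configuration-driven: every variable is
described by a per-source :class:`VariableSpec` naming the concept codes that
encode it, the OMOP table it lives in, and the aggregation to apply.  Two
sources that store the same clinical variable under different vocabularies or
tables are extracted by the same code with different configuration files —
the federated-analysis contract.

Cohort rules (applied in a fixed, reported order): ICU admissions inside the
study date window; age >= 17 at admission; no burns diagnosis; a recorded
reason for admission; first ICU stay per hospital visit only.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .omop_store import OmopStore

AGGREGATIONS = ("highest", "lowest", "both", "presence", "code")

#: variables a config must define exactly once (the APACHE II inputs)
REQUIRED_VARIABLES = (
    "temperature",
    "mean_arterial_pressure",
    "heart_rate",
    "respiratory_rate",
    "pao2",
    "fio2",
    "aado2",
    "arterial_ph",
    "sodium",
    "potassium",
    "creatinine",
    "hematocrit",
    "wbc",
    "gcs",
    "reason_for_admission",
)

_EVENT_COLUMNS = {
    "measurement": ("measurement_concept_id", "measurement_datetime"),
    "observation": ("observation_concept_id", "observation_datetime"),
    "condition_occurrence": ("condition_concept_id", "condition_start_datetime"),
}


class ExtractionError(Exception):
    pass


@dataclass
class VariableSpec:
    name: str
    concept_ids: list[int]
    table: str
    aggregation: str
    unit_concept_id: int | None = None

    def validate(self) -> None:
        if not self.concept_ids:
            raise ExtractionError(f"variable {self.name!r}: empty concept_ids")
        if self.table not in _EVENT_COLUMNS:
            raise ExtractionError(f"variable {self.name!r}: unknown table {self.table!r}")
        if self.aggregation not in AGGREGATIONS:
            raise ExtractionError(
                f"variable {self.name!r}: unknown aggregation {self.aggregation!r}"
            )
        if self.table == "condition_occurrence" and self.aggregation != "presence":
            raise ExtractionError(
                f"variable {self.name!r}: condition_occurrence rows carry no "
                "numeric value; only aggregation=presence is valid"
            )


@dataclass
class ExtractionConfig:
    source_name: str
    variables: list[VariableSpec]
    date_window: tuple[_dt.date, _dt.date]
    gender_male_concept_id: int = 8507
    burns_concept_ids: list[int] = field(default_factory=list)

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise ExtractionError(f"config {self.source_name!r}: no variable {name!r}")

    def has_variable(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    def validate(self) -> None:
        names = [v.name for v in self.variables]
        dupes = {x for x in names if names.count(x) > 1}
        if dupes:
            raise ExtractionError(f"duplicate variable names {sorted(dupes)}")
        missing = [v for v in REQUIRED_VARIABLES if v not in names]
        if missing:
            raise ExtractionError(f"config missing required variables {missing}")
        for v in self.variables:
            v.validate()
        if not self.date_window[0] <= self.date_window[1]:
            raise ExtractionError("date_window start after end")


def load_extraction_config(path: str | Path) -> ExtractionConfig:
    raw = yaml.safe_load(Path(path).read_text())
    variables = [
        VariableSpec(
            name=str(v["name"]),
            concept_ids=[int(c) for c in v["concept_ids"]],
            table=str(v["table"]),
            aggregation=str(v["aggregation"]),
            unit_concept_id=(
                int(v["unit_concept_id"]) if v.get("unit_concept_id") is not None else None
            ),
        )
        for v in raw["variables"]
    ]
    window = tuple(
        d if isinstance(d, _dt.date) else _dt.date.fromisoformat(str(d))
        for d in raw["date_window"]
    )
    cfg = ExtractionConfig(
        source_name=str(raw["source_name"]),
        variables=variables,
        date_window=window,  # type: ignore[arg-type]
        gender_male_concept_id=int(raw.get("gender_male_concept_id", 8507)),
        burns_concept_ids=[int(c) for c in raw.get("burns_concept_ids", [])],
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# event selection
# ---------------------------------------------------------------------------


def _qualifying_events(
    store: OmopStore, cohort: pd.DataFrame, spec: VariableSpec
) -> pd.DataFrame:
    """Events matching concept, table, visit linkage and the 24 h window.

    Linkage: an event attaches to a cohort stay when its visit_detail_id
    matches; events without a visit_detail_id fall back to person identity.
    The timestamp must lie in the half-open window [icu_admit, icu_admit+24h).
    """
    table = getattr(store, spec.table)
    concept_col, dt_col = _EVENT_COLUMNS[spec.table]
    ev = table[table[concept_col].isin(spec.concept_ids)]
    if (
        spec.unit_concept_id is not None
        and spec.table == "measurement"
        and len(ev)
    ):
        wrong = ev["unit_concept_id"].notna() & (
            ev["unit_concept_id"] != spec.unit_concept_id
        )
        if wrong.any():
            warnings.warn(
                f"{spec.name}: dropped {int(wrong.sum())} events with unexpected "
                f"unit_concept_id (no silent conversion)",
                stacklevel=2,
            )
            ev = ev[~wrong]
    if not len(ev):
        return ev.assign(_vd=pd.array([], dtype="Int64")).iloc[:0]

    keys = cohort[["visit_detail_id", "person_id", "icu_admit", "window_end"]]
    linked = ev[ev["visit_detail_id"].notna()].merge(
        keys, on="visit_detail_id", how="inner", suffixes=("", "_c")
    )
    linked["_vd"] = linked["visit_detail_id"]
    unlinked = ev[ev["visit_detail_id"].isna()].drop(columns=["visit_detail_id"]).merge(
        keys, on="person_id", how="inner"
    )
    unlinked["_vd"] = unlinked["visit_detail_id"]
    both = pd.concat([linked, unlinked], ignore_index=True)
    ts = both[dt_col]
    inside = (ts >= both["icu_admit"]) & (ts < both["window_end"])
    return both[inside]


def _extract_numeric(
    store: OmopStore, cohort: pd.DataFrame, spec: VariableSpec
) -> pd.DataFrame:
    if spec.table == "condition_occurrence":
        raise ExtractionError(
            f"variable {spec.name!r}: numeric aggregation over condition rows"
        )
    ev = _qualifying_events(store, cohort, spec)
    out = pd.DataFrame(index=cohort["visit_detail_id"])
    if spec.aggregation in ("highest", "both"):
        agg = ev.groupby("_vd")["value_as_number"].max()
        out[f"{spec.name}_high"] = agg.reindex(out.index)
    if spec.aggregation in ("lowest", "both"):
        agg = ev.groupby("_vd")["value_as_number"].min()
        out[f"{spec.name}_low"] = agg.reindex(out.index)
    return out


def _extract_presence(
    store: OmopStore, cohort: pd.DataFrame, spec: VariableSpec
) -> pd.Series:
    ev = _qualifying_events(store, cohort, spec)
    present = pd.Series(False, index=cohort["visit_detail_id"], name=spec.name)
    present.loc[present.index.isin(set(ev["_vd"].dropna()))] = True
    return present


def _extract_code(
    store: OmopStore, cohort: pd.DataFrame, spec: VariableSpec
) -> pd.Series:
    """Earliest qualifying event's value_as_number, as the source code."""
    ev = _qualifying_events(store, cohort, spec)
    _, dt_col = _EVENT_COLUMNS[spec.table]
    first = (
        ev.sort_values(dt_col, kind="stable").groupby("_vd")["value_as_number"].first()
    )
    return first.reindex(cohort["visit_detail_id"]).rename(spec.name)


# ---------------------------------------------------------------------------
# cohort selection
# ---------------------------------------------------------------------------


def select_cohort(
    store: OmopStore,
    config: ExtractionConfig,
    burns_concept_ids: list[int] | None = None,
    reason_variable: VariableSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the inclusion/exclusion rules; returns (cohort, attrition report).

    Exclusion order (each step counted in the report): date window -> age < 17
    -> burns diagnosis -> missing reason for admission -> later ICU stays
    within the same hospital visit.
    """
    config.validate()
    burns_ids = (
        burns_concept_ids if burns_concept_ids is not None else config.burns_concept_ids
    )
    if reason_variable is None:
        if not config.has_variable("reason_for_admission"):
            raise ExtractionError("config missing the reason-for-admission variable")
        reason_variable = config.variable("reason_for_admission")

    vd = store.visit_detail.rename(
        columns={
            "visit_detail_start_datetime": "icu_admit",
            "visit_detail_end_datetime": "icu_discharge",
        }
    )
    base = vd.merge(
        store.person[["person_id", "gender_concept_id", "year_of_birth"]],
        on="person_id",
        how="left",
    )
    base["age"] = (
        base["icu_admit"].dt.year.astype("Int64") - base["year_of_birth"]
    ).astype("Int64")
    base["sex"] = np.where(
        base["gender_concept_id"] == config.gender_male_concept_id, "M", "F"
    )
    base["window_end"] = base["icu_admit"] + pd.Timedelta(hours=24)

    attrition: list[tuple[str, int, int]] = [("total", 0, len(base))]

    start, end = config.date_window
    admit_date = base["icu_admit"].dt.date
    keep = (admit_date >= start) & (admit_date <= end)
    attrition.append(("date_window", int((~keep).sum()), int(keep.sum())))
    base = base[keep]

    keep = base["age"] >= 17
    attrition.append(("age_under_17", int((~keep).sum()), int(keep.sum())))
    base = base[keep]

    cond = store.condition_occurrence
    burns = cond[cond["condition_concept_id"].isin(burns_ids)]
    burns_vd = set(burns["visit_detail_id"].dropna())
    unlinked = burns[burns["visit_detail_id"].isna()]
    has_burns = base["visit_detail_id"].isin(burns_vd)
    if len(unlinked):
        m = base.merge(
            unlinked[["person_id", "condition_start_datetime"]], on="person_id"
        )
        hit = m[
            (m["condition_start_datetime"] >= m["icu_admit"])
            & (m["condition_start_datetime"] <= m["icu_discharge"])
        ]["visit_detail_id"]
        has_burns |= base["visit_detail_id"].isin(set(hit))
    keep = ~has_burns
    attrition.append(("burns", int((~keep).sum()), int(keep.sum())))
    base = base[keep]

    reason = _extract_code(store, base, reason_variable)
    base = base.set_index("visit_detail_id")
    base["reason_code"] = reason
    keep = base["reason_code"].notna()
    attrition.append(("missing_reason", int((~keep).sum()), int(keep.sum())))
    base = base[keep].reset_index()

    base = base.sort_values(
        ["visit_occurrence_id", "icu_admit", "visit_detail_id"], kind="stable"
    )
    keep_first = ~base.duplicated("visit_occurrence_id", keep="first")
    attrition.append(
        ("icu_readmission", int((~keep_first).sum()), int(keep_first.sum()))
    )
    base = base[keep_first].sort_values("visit_detail_id").reset_index(drop=True)

    # unit (ICU / registry) labels from the optional care_site table
    if store.care_site is not None and "care_site_name" in store.care_site.columns:
        cs = store.care_site.copy()
        parts = cs["care_site_name"].astype(str).str.split("/", n=1, expand=True)
        cs["registry"] = parts[0]
        cs["icu"] = parts[1] if parts.shape[1] > 1 else parts[0]
        base = base.merge(
            cs[["care_site_id", "registry", "icu"]], on="care_site_id", how="left"
        )
    else:
        base["registry"] = config.source_name
        base["icu"] = base["care_site_id"].astype(str)

    # admission-context presence flags used downstream by the scorer
    for flag in ("elective_postop", "emergency_postop"):
        if config.has_variable(flag):
            base[flag] = (
                _extract_presence(store, base, config.variable(flag))
                .reindex(base["visit_detail_id"])
                .to_numpy()
            )
        else:
            base[flag] = False

    cohort = base[
        [
            "person_id",
            "visit_occurrence_id",
            "visit_detail_id",
            "care_site_id",
            "registry",
            "icu",
            "age",
            "sex",
            "icu_admit",
            "icu_discharge",
            "window_end",
            "reason_code",
            "elective_postop",
            "emergency_postop",
        ]
    ].copy()
    report = pd.DataFrame(attrition, columns=["step", "removed", "remaining"])
    return cohort, report


def extract_first24h(
    store: OmopStore, cohort: pd.DataFrame, config: ExtractionConfig
) -> pd.DataFrame:
    """Wide table of first-24h extrema / presence flags, one row per stay."""
    pieces: list[pd.DataFrame | pd.Series] = []
    for spec in config.variables:
        if spec.name == "reason_for_admission":
            continue
        if spec.aggregation == "presence":
            pieces.append(_extract_presence(store, cohort, spec))
        elif spec.aggregation == "code":
            pieces.append(_extract_code(store, cohort, spec))
        else:
            pieces.append(_extract_numeric(store, cohort, spec))
    wide = pd.concat(pieces, axis=1)
    wide.index.name = "visit_detail_id"
    for spec in config.variables:
        lo, hi = f"{spec.name}_low", f"{spec.name}_high"
        if lo in wide.columns and hi in wide.columns:
            bad = wide[lo] > wide[hi]
            if bad.any():
                raise ExtractionError(
                    f"{spec.name}: lowest > highest for stays "
                    f"{wide.index[bad].tolist()[:5]}"
                )
    return wide


def attach_outcome(store: OmopStore, cohort: pd.DataFrame) -> pd.DataFrame:
    """Add icu_death and icu_los_days; flag deaths recorded before admission.

    A stay counts as an ICU death when a death record's timestamp falls in
    the closed interval [icu_admit, icu_discharge]; a later death is a
    hospital death, out of scope here.
    """
    out = cohort.merge(store.death, on="person_id", how="left")
    dd = out["death_datetime"]
    has_end = out["icu_discharge"].notna()
    out["icu_death"] = (
        dd.notna()
        & (dd >= out["icu_admit"])
        & (has_end & (dd <= out["icu_discharge"]) | ~has_end)
    )
    out["icu_los_days"] = (
        (out["icu_discharge"] - out["icu_admit"]).dt.total_seconds() / 86400.0
    )
    out["outcome_flag"] = np.where(
        dd.notna() & (dd < out["icu_admit"]), "death_before_admission", ""
    )
    return out.drop(columns=["death_datetime"])
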
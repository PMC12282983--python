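"""Read, validate and write the OMOP CDM table subset used for ICU benchmarking.

The store holds the seven tables both quality registries populated (person,
visit_occurrence, visit_detail, measurement, observation, condition_occurrence,
death) as pandas DataFrames with a fixed internal column naming.  Each table is
one delimited text file with a header row, ISO-8601 timestamps and the empty
string for an absent value.  CDM 5.3 and 5.4 differ, for the columns this
analysis touches, only in column-name synonyms; both load to the same internal
representation.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_TABLES = (
    "person",
    "visit_occurrence",
    "visit_detail",
    "measurement",
    "observation",
    "condition_occurrence",
    "death",
)

#: tables accepted on load but ignored by every downstream stage
OPTIONAL_TABLES = (
    "care_site",
    "procedure_occurrence",
    "observation_period",
    "drug_exposure",
)

# internal column schema: name -> (id columns, datetime columns, date columns,
# float columns).  Internal names follow CDM 5.4.
_SCHEMA: dict[str, dict[str, tuple[str, ...]]] = {
    "person": {
        "ids": ("person_id", "gender_concept_id", "year_of_birth"),
        "datetimes": (),
        "dates": (),
        "floats": (),
    },
    "visit_occurrence": {
        "ids": ("visit_occurrence_id", "person_id"),
        "datetimes": (),
        "dates": ("visit_start_date", "visit_end_date"),
        "floats": (),
    },
    "visit_detail": {
        "ids": (
            "visit_detail_id",
            "visit_occurrence_id",
            "person_id",
            "care_site_id",
        ),
        "datetimes": ("visit_detail_start_datetime", "visit_detail_end_datetime"),
        "dates": (),
        "floats": (),
    },
    "measurement": {
        "ids": (
            "measurement_id",
            "person_id",
            "visit_detail_id",
            "measurement_concept_id",
            "unit_concept_id",
        ),
        "datetimes": ("measurement_datetime",),
        "dates": (),
        "floats": ("value_as_number",),
    },
    "observation": {
        "ids": (
            "observation_id",
            "person_id",
            "visit_detail_id",
            "observation_concept_id",
        ),
        "datetimes": ("observation_datetime",),
        "dates": (),
        "floats": ("value_as_number",),
    },
    "condition_occurrence": {
        "ids": (
            "condition_occurrence_id",
            "person_id",
            "visit_detail_id",
            "condition_concept_id",
        ),
        "datetimes": ("condition_start_datetime",),
        "dates": (),
        "floats": (),
    },
    "death": {
        "ids": ("person_id",),
        "datetimes": ("death_datetime",),
        "dates": (),
        "floats": (),
    },
    "care_site": {
        "ids": ("care_site_id",),
        "datetimes": (),
        "dates": (),
        "floats": (),
    },
}

# columns that may be absent from the file entirely
_OPTIONAL_COLUMNS = {
    "visit_occurrence": {"visit_end_date", "admitted_from_concept_id"},
    "visit_detail": {
        "visit_detail_end_datetime",
        "care_site_id",
        "discharged_to_concept_id",
    },
    "measurement": {"visit_detail_id", "unit_concept_id"},
    "observation": {"visit_detail_id", "value_as_number"},
    "condition_occurrence": {"visit_detail_id"},
    "care_site": {"care_site_name"},
}

# CDM 5.3 names for columns renamed in 5.4 (none of them used downstream)
_V53_SYNONYMS = {
    "visit_occurrence": {"admitting_source_concept_id": "admitted_from_concept_id"},
    "visit_detail": {"discharge_to_concept_id": "discharged_to_concept_id"},
}

_PASSTHROUGH_COLUMNS = {
    "visit_occurrence": ("admitted_from_concept_id",),
    "visit_detail": ("discharged_to_concept_id",),
    "care_site": ("care_site_name",),
}


class StoreError(Exception):
    """Fatal problem loading or writing an OMOP store."""


@dataclass
class RowError:
    table: str
    row: int
    column: str
    message: str


@dataclass
class Violation:
    """One referential-integrity or invariant violation found by validate_store."""

    table: str
    row: int
    rule: str
    message: str


@dataclass
class OmopStore:
    person: pd.DataFrame
    visit_occurrence: pd.DataFrame
    visit_detail: pd.DataFrame
    measurement: pd.DataFrame
    observation: pd.DataFrame
    condition_occurrence: pd.DataFrame
    death: pd.DataFrame
    care_site: pd.DataFrame | None = None
    schema_version: str = "5.3"
    load_errors: list[RowError] = field(default_factory=list)

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {name: getattr(self, name) for name in REQUIRED_TABLES}
        if self.care_site is not None:
            out["care_site"] = self.care_site
        return out

    def counts(self) -> dict[str, int]:
        return {name: len(df) for name, df in self.tables().items()}

    def equals(self, other: "OmopStore") -> bool:
        """Field-for-field equality of the table contents (row order matters)."""
        mine, theirs = self.tables(), other.tables()
        if set(mine) != set(theirs):
            return False
        for t in mine:
            a = mine[t].reset_index(drop=True)
            b = theirs[t].reset_index(drop=True)
            if sorted(a.columns) != sorted(b.columns):
                return False
            if not a.equals(b[a.columns]):
                return False
        return True


def _empty_table(name: str) -> pd.DataFrame:
    sch = _SCHEMA[name]
    cols: dict[str, pd.Series] = {}
    for c in sch["ids"]:
        cols[c] = pd.Series(dtype="Int64")
    for c in sch["datetimes"] + sch["dates"]:
        cols[c] = pd.Series(dtype="datetime64[ns]")
    for c in sch["floats"]:
        cols[c] = pd.Series(dtype="float64")
    for c in _PASSTHROUGH_COLUMNS.get(name, ()):
        if c not in cols:
            cols[c] = pd.Series(dtype="object")
    return pd.DataFrame(cols)


def _coerce_table(
    name: str, df: pd.DataFrame, errors: list[RowError], on_bad_rows: str
) -> pd.DataFrame:
    sch = _SCHEMA[name]
    df = df.rename(columns=_V53_SYNONYMS.get(name, {}))
    optional = _OPTIONAL_COLUMNS.get(name, set())
    keep = list(sch["ids"]) + list(sch["datetimes"]) + list(sch["dates"]) + list(
        sch["floats"]
    )
    for c in _PASSTHROUGH_COLUMNS.get(name, ()):
        if c not in keep:
            keep.append(c)
    missing = [c for c in keep if c not in df.columns and c not in optional]
    if missing:
        raise StoreError(f"table {name!r}: missing required columns {missing}")
    for c in keep:
        if c not in df.columns:
            df[c] = pd.NA
    df = df[keep].copy()

    bad = pd.Series(False, index=df.index)
    passthrough_ids = [
        c for c in _PASSTHROUGH_COLUMNS.get(name, ()) if c.endswith("_concept_id")
    ]
    for c in list(sch["ids"]) + passthrough_ids:
        df[c] = pd.to_numeric(df[c], errors="coerce").astype("Int64")
    for c in sch["floats"]:
        df[c] = pd.to_numeric(df[c], errors="coerce").astype("float64")
    for c in sch["datetimes"] + sch["dates"]:
        raw = df[c]
        parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
        nonempty = raw.notna() & (raw.astype(str).str.strip() != "")
        failed = nonempty & parsed.isna()
        for idx in df.index[failed]:
            errors.append(RowError(name, int(idx), c, f"unparseable date {raw[idx]!r}"))
        bad |= failed
        df[c] = parsed
    if bad.any():
        if on_bad_rows == "error":
            msgs = "; ".join(
                f"{e.table}[row {e.row}].{e.column}: {e.message}" for e in errors[:10]
            )
            raise StoreError(f"row-level errors while loading {name!r}: {msgs}")
        df = df[~bad]
    return df.reset_index(drop=True)


def load_store(
    path: str | Path, schema_version: str = "5.3", on_bad_rows: str = "error"
) -> OmopStore:
    """Load one directory of delimited table files into an :class:`OmopStore`.

    Parameters
    ----------
    path:
        Directory containing ``person.csv``, ``visit_occurrence.csv``, ... one
        file per table.
    schema_version:
        ``"5.3"`` or ``"5.4"``; controls which column-name synonyms are
        recognised.  Both versions normalise to the same internal naming.
    on_bad_rows:
        ``"error"`` (default) raises on any unparseable date; ``"report"``
        drops the offending rows and records them in ``store.load_errors``.
    """
    path = Path(path)
    if schema_version not in ("5.3", "5.4"):
        raise StoreError(f"unknown schema_version {schema_version!r}")
    if on_bad_rows not in ("error", "report"):
        raise StoreError(f"on_bad_rows must be 'error' or 'report', got {on_bad_rows!r}")
    missing = [t for t in REQUIRED_TABLES if not (path / f"{t}.csv").exists()]
    if missing:
        raise StoreError(f"missing required tables in {path}: {missing}")

    errors: list[RowError] = []
    frames: dict[str, pd.DataFrame] = {}
    for name in REQUIRED_TABLES + ("care_site",):
        f = path / f"{name}.csv"
        if not f.exists():
            continue
        raw = pd.read_csv(f, dtype=str, keep_default_na=True)
        frames[name] = (
            _coerce_table(name, raw, errors, on_bad_rows)
            if len(raw)
            else _empty_table(name)
        )
    return OmopStore(
        person=frames["person"],
        visit_occurrence=frames["visit_occurrence"],
        visit_detail=frames["visit_detail"],
        measurement=frames["measurement"],
        observation=frames["observation"],
        condition_occurrence=frames["condition_occurrence"],
        death=frames["death"],
        care_site=frames.get("care_site"),
        schema_version=schema_version,
        load_errors=errors,
    )


def write_store(store: OmopStore, path: str | Path) -> None:
    """Write the store back to one CSV per table (ISO-8601, empty = absent).

    ``load_store(write_store(s)) == s`` field-for-field on a valid store;
    absent optional values stay absent, never coerced to 0.
    """
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise StoreError(f"cannot create output directory {path}: {exc}") from exc
    for name, df in store.tables().items():
        out = df.copy()
        sch = _SCHEMA[name]
        canonical = [
            c
            for c in (
                list(sch["ids"]) + list(sch["datetimes"]) + list(sch["dates"])
                + list(sch["floats"]) + list(_PASSTHROUGH_COLUMNS.get(name, ()))
            )
            if c in out.columns
        ]
        canonical += [c for c in out.columns if c not in canonical]
        out = out[canonical]
        for c in sch["datetimes"]:
            out[c] = out[c].dt.strftime("%Y-%m-%dT%H:%M:%S")
        for c in sch["dates"]:
            out[c] = out[c].dt.strftime("%Y-%m-%d")
        out.to_csv(path / f"{name}.csv", index=False)


def validate_store(store: OmopStore) -> list[Violation]:
    """Return every invariant violation in the store; ``[]`` iff valid."""
    v: list[Violation] = []
    this_year = _dt.date.today().year

    person = store.person
    dup = person["person_id"].duplicated(keep=False)
    for i in person.index[dup]:
        v.append(Violation("person", int(i), "person_id_unique",
                           f"duplicate person_id {person.at[i, 'person_id']}"))
    bad_year = person["year_of_birth"].notna() & (
        (person["year_of_birth"] < 1900) | (person["year_of_birth"] > this_year)
    )
    for i in person.index[bad_year]:
        v.append(Violation("person", int(i), "year_of_birth_range",
                           f"year_of_birth {person.at[i, 'year_of_birth']}"))

    persons = set(person["person_id"].dropna())
    vo = store.visit_occurrence
    for i in vo.index[~vo["person_id"].isin(persons)]:
        v.append(Violation("visit_occurrence", int(i), "person_fk",
                           f"person_id {vo.at[i, 'person_id']} not in person"))
    bad = (
        vo["visit_end_date"].notna()
        & vo["visit_start_date"].notna()
        & (vo["visit_end_date"] < vo["visit_start_date"])
    )
    for i in vo.index[bad]:
        v.append(Violation("visit_occurrence", int(i), "date_order",
                           "visit_end_date before visit_start_date"))

    visits = set(vo["visit_occurrence_id"].dropna())
    vd = store.visit_detail
    for i in vd.index[~vd["person_id"].isin(persons)]:
        v.append(Violation("visit_detail", int(i), "person_fk",
                           f"person_id {vd.at[i, 'person_id']} not in person"))
    for i in vd.index[~vd["visit_occurrence_id"].isin(visits)]:
        v.append(Violation("visit_detail", int(i), "visit_fk",
                           f"visit_occurrence_id {vd.at[i, 'visit_occurrence_id']} "
                           "not in visit_occurrence"))
    bad = (
        vd["visit_detail_end_datetime"].notna()
        & vd["visit_detail_start_datetime"].notna()
        & (vd["visit_detail_end_datetime"] < vd["visit_detail_start_datetime"])
    )
    for i in vd.index[bad]:
        v.append(Violation("visit_detail", int(i), "datetime_order",
                           "visit_detail end before start"))

    details = set(vd["visit_detail_id"].dropna())
    for name, concept_col, dt_col in (
        ("measurement", "measurement_concept_id", "measurement_datetime"),
        ("observation", "observation_concept_id", "observation_datetime"),
        ("condition_occurrence", "condition_concept_id", "condition_start_datetime"),
    ):
        ev = getattr(store, name)
        for i in ev.index[~ev["person_id"].isin(persons)]:
            v.append(Violation(name, int(i), "person_fk",
                               f"person_id {ev.at[i, 'person_id']} not in person"))
        linked = ev["visit_detail_id"].notna()
        for i in ev.index[linked & ~ev["visit_detail_id"].isin(details)]:
            v.append(Violation(name, int(i), "visit_detail_fk",
                               f"visit_detail_id {ev.at[i, 'visit_detail_id']} "
                               "not in visit_detail"))
        if name == "measurement":
            for i in ev.index[ev["value_as_number"].isna()]:
                v.append(Violation(name, int(i), "measurement_value_present",
                                   "measurement row without value_as_number"))

    death = store.death
    for i in death.index[~death["person_id"].isin(persons)]:
        v.append(Violation("death", int(i), "person_fk",
                           f"person_id {death.at[i, 'person_id']} not in person"))
    dup = death["person_id"].duplicated(keep=False)
    for i in death.index[dup]:
        v.append(Violation("death", int(i), "one_death_per_person",
                           f"multiple death records for person "
                           f"{death.at[i, 'person_id']}"))
    return v
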
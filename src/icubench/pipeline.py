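"""End-to-end federated benchmarking runs.

One :func:`run` executes the same analysis per source — load store, select
cohort, extract first-24h worst values, map reasons, score, resolve missing
data by the source's strategy — and then aggregates **only registry-level
statistics** across sources into the final SMR funnel.  Person-level
intermediates never leave a source's own run subdirectory, mirroring the
privacy contract of a federated analysis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .apache2 import (
    UNMAPPED,
    DiagnosisMap,
    ScoringDefinition,
    compute_totals,
    load_diagnosis_map,
    load_scoring_definition,
    map_reason,
    mortality_risk,
    score_components,
)
from .benchmark import (
    compute_smr,
    demographics_table,
    funnel_limits,
    outlier_table,
    plot_funnel,
    pooled_smr,
)
from .extraction import (
    ExtractionConfig,
    attach_outcome,
    extract_first24h,
    load_extraction_config,
    select_cohort,
)
from .missingness import MiConfig, mi_pmm, normal_fill, score_imputations
from .omop_store import load_store, validate_store

PHYSIOLOGY_WIDE_COLUMNS = [
    "temperature_low", "temperature_high",
    "mean_arterial_pressure_low", "mean_arterial_pressure_high",
    "heart_rate_low", "heart_rate_high",
    "respiratory_rate_low", "respiratory_rate_high",
    "pao2_low", "fio2_high", "aado2_high",
    "arterial_ph_low", "arterial_ph_high",
    "sodium_low", "sodium_high",
    "potassium_low", "potassium_high",
    "creatinine_low", "creatinine_high",
    "hematocrit_low", "hematocrit_high",
    "wbc_low", "wbc_high",
    "gcs_low",
]

#: columns never imputed: FiO2/AaDO2 absence is structural (rail selection)
IMPUTABLE_WIDE_COLUMNS = [
    c for c in PHYSIOLOGY_WIDE_COLUMNS if c not in ("fio2_high", "aado2_high")
]


class PipelineError(Exception):
    pass


def packaged_path(name: str) -> Path:
    return Path(str(resources.files("icubench.data").joinpath(name)))


def packaged_extraction_config(dialect: str) -> ExtractionConfig:
    return load_extraction_config(
        packaged_path(f"synthetic_dialect_{dialect.lower()}_extraction.yaml")
    )


def packaged_diagnosis_map(dialect: str) -> DiagnosisMap:
    return load_diagnosis_map(
        packaged_path(f"synthetic_dialect_{dialect.lower()}_diagnosis_map.yaml")
    )


@dataclass
class SourceConfig:
    name: str
    store_path: str
    extraction_config: str
    diagnosis_map: str
    strategy: str = "normal_fill"  # or "mi_pmm"
    schema_version: str = "5.3"
    mi: MiConfig | None = None

    def validate(self) -> None:
        if self.strategy not in ("normal_fill", "mi_pmm"):
            raise PipelineError(f"source {self.name!r}: unknown strategy {self.strategy!r}")
        for p in (self.store_path, self.extraction_config, self.diagnosis_map):
            if not Path(p).exists():
                raise PipelineError(f"source {self.name!r}: missing file {p}")


@dataclass
class RunConfig:
    output_dir: str
    sources: list[SourceConfig]
    seed: int = 0
    benchmark_level: str = "registry"  # or "icu"
    alpha: float = 0.05
    scoring_definition: str | None = None

    def validate(self) -> None:
        if self.benchmark_level not in ("registry", "icu"):
            raise PipelineError(f"unknown benchmark level {self.benchmark_level!r}")
        if not self.sources:
            raise PipelineError("no sources configured")
        for s in self.sources:
            s.validate()


def runconfig_from_yaml(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    sources = []
    for s in raw["sources"]:
        mi = s.pop("mi", None)
        sources.append(SourceConfig(**s, mi=MiConfig(**mi) if mi else None))
    return RunConfig(
        output_dir=str(raw["output_dir"]),
        sources=sources,
        seed=int(raw.get("seed", 0)),
        benchmark_level=str(raw.get("benchmark_level", "registry")),
        alpha=float(raw.get("alpha", 0.05)),
        scoring_definition=raw.get("scoring_definition"),
    )


# ---------------------------------------------------------------------------
# per-source analysis
# ---------------------------------------------------------------------------


@dataclass
class SourceResult:
    name: str
    cohort: pd.DataFrame  # scored person-level rows (stays inside the source)
    unit_stats: pd.DataFrame  # aggregate only
    pooled: list | None
    counts: dict[str, int] = field(default_factory=dict)


def score_extracted(
    cohort: pd.DataFrame,
    wide: pd.DataFrame,
    dmap,
    definition: ScoringDefinition,
    strategy: str = "normal_fill",
    mi: MiConfig | None = None,
) -> tuple[pd.DataFrame, list[pd.Series] | None, int]:
    """Score an extracted cohort under the source's missing-data strategy.

    Returns (scored cohort with ``total`` and ``risk`` columns, per-imputation
    risk series when strategy is mi_pmm, count of unmapped-reason exclusions).
    """
    cohort = cohort.set_index("visit_detail_id", drop=False)
    wide = wide.reindex(cohort.index)
    cohort["category"] = [map_reason(c, dmap) for c in cohort["reason_code"]]
    mapped = cohort["category"] != UNMAPPED
    n_unmapped = int((~mapped).sum())
    cohort, wide = cohort[mapped], wide[mapped]

    chronic = wide.get("chronic_insufficiency", pd.Series(False, index=wide.index))
    arf = wide.get("acute_renal_failure", pd.Series(False, index=wide.index))
    postop = cohort["elective_postop"] | cohort["emergency_postop"]
    weight = np.array(
        [
            definition.diagnostic_weight(c, postoperative=bool(p))
            for c, p in zip(cohort["category"], postop)
        ]
    )

    risks_per_imp = None
    if strategy == "normal_fill":
        points = normal_fill(wide, definition, acute_renal_failure=arf)
        totals = compute_totals(
            points, cohort["age"], chronic, cohort["elective_postop"], definition
        )
        risk = np.asarray(
            mortality_risk(
                totals["total"].to_numpy(), weight,
                cohort["emergency_postop"].to_numpy(), definition,
            )
        )
        cohort = cohort.assign(total=totals["total"].to_numpy(), risk=risk)
    elif strategy == "mi_pmm":
        mi = mi or MiConfig()
        predictors = pd.get_dummies(
            cohort[["registry"]], drop_first=True, dtype=float
        )
        predictors["icu_death"] = cohort["icu_death"].astype(float).to_numpy()
        predictors["icu_los_days"] = cohort["icu_los_days"].to_numpy()
        imputable = [c for c in IMPUTABLE_WIDE_COLUMNS if c in wide.columns]
        imp = mi_pmm(wide, mi, variables=imputable, predictors=predictors)
        points_list = score_imputations(imp, definition, acute_renal_failure=arf)
        risks_per_imp = []
        totals_list = []
        for pts in points_list:
            totals = compute_totals(
                pts, cohort["age"], chronic, cohort["elective_postop"], definition
            )
            r = np.asarray(
                mortality_risk(
                    totals["total"].to_numpy(), weight,
                    cohort["emergency_postop"].to_numpy(), definition,
                )
            )
            totals_list.append(totals["total"].to_numpy())
            risks_per_imp.append(pd.Series(r, index=cohort.index))
        # per-patient report: mean risk / mean score over the m imputations
        cohort = cohort.assign(
            total=np.mean(totals_list, axis=0),
            risk=np.mean(risks_per_imp, axis=0),
        )
    else:
        raise PipelineError(f"unknown strategy {strategy!r}")
    return cohort, risks_per_imp, n_unmapped


def analyse_source(
    src: SourceConfig,
    definition: ScoringDefinition,
    seed: int,
    out_dir: Path | None = None,
) -> SourceResult:
    """Run the shared analysis script on one source with its own config."""
    store = load_store(src.store_path, schema_version=src.schema_version)
    violations = validate_store(store)
    config = load_extraction_config(src.extraction_config)
    dmap = load_diagnosis_map(src.diagnosis_map)

    cohort, attrition = select_cohort(store, config)
    cohort = attach_outcome(store, cohort)
    wide = extract_first24h(store, cohort, config)

    mi = src.mi or MiConfig()
    if mi.seed == 0:
        mi = MiConfig(m=mi.m, iterations=mi.iterations, donors_k=mi.donors_k,
                      seed=seed, predictors=mi.predictors)
    cohort, risks_per_imp, n_unmapped = score_extracted(
        cohort, wide, dmap, definition, strategy=src.strategy, mi=mi
    )
    wide = wide.reindex(cohort.index)
    pooled = None
    if risks_per_imp is not None:
        pooled = pooled_smr(
            cohort, risks_per_imp, unit_col="registry", death_col="icu_death"
        )

    unit_col = "registry" if "registry" in cohort else "icu"
    unit_stats = compute_smr(cohort, unit_col=unit_col)

    counts = {
        "store_rows": int(sum(store.counts().values())),
        "store_violations": len(violations),
        "cohort": len(cohort),
        "unmapped_reason_excluded": n_unmapped,
        **{f"attrition_{r.step}": int(r.removed) for r in attrition.itertuples()},
    }
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        attrition.to_csv(out_dir / "attrition.csv", index=False)
        cohort.to_csv(out_dir / "cohort_scored.csv", index=False)
        wide.to_csv(out_dir / "wide.csv")
        if pooled is not None:
            from .benchmark import pooled_funnel

            overlays = pooled_funnel(pooled, alpha=0.05)
            for name, limits in overlays.items():
                E = np.array(
                    [
                        {"point": p.pooled.point, "lower95": p.pooled.ci95[0],
                         "upper95": p.pooled.ci95[1]}[name]
                        for p in pooled
                    ]
                )
                keep = E > 0
                stats_df = pd.DataFrame(
                    {
                        "unit": [p.unit for p in pooled],
                        "expected": E,
                        "smr": [p.observed for p in pooled] / np.where(E > 0, E, np.nan),
                    }
                )[keep]
                plot_funnel(
                    stats_df, limits, out_dir / f"funnel_{name}.svg",
                    title=f"Pooled SMR funnel ({name})",
                )
            pd.DataFrame(
                {
                    "unit": [p.unit for p in pooled],
                    "observed": [p.observed for p in pooled],
                    "expected_point": [p.pooled.point for p in pooled],
                    "expected_lo95": [p.pooled.ci95[0] for p in pooled],
                    "expected_hi95": [p.pooled.ci95[1] for p in pooled],
                    "smr_point": [p.smr_point for p in pooled],
                    "smr_lo95": [p.smr_lo95 for p in pooled],
                    "smr_hi95": [p.smr_hi95 for p in pooled],
                }
            ).to_csv(out_dir / "pooled_registry_stats.csv", index=False)
    return SourceResult(
        name=src.name, cohort=cohort, unit_stats=unit_stats, pooled=pooled,
        counts=counts,
    )


def run(config: RunConfig) -> Path:
    """Execute the full federated run; returns the run directory.

    Rerunning with the same configuration reproduces identical numeric
    outputs; only registry-level aggregates cross the source boundary into
    the shared outputs at the top of the run directory.
    """
    config.validate()
    definition = load_scoring_definition(config.scoring_definition)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    results: list[SourceResult] = []
    for src in config.sources:
        try:
            results.append(
                analyse_source(src, definition, config.seed, out_dir=out / src.name)
            )
        except Exception as exc:
            raise PipelineError(f"stage failure in source {src.name!r}: {exc}") from exc

    scored = pd.concat(
        [r.cohort.assign(source=r.name) for r in results], ignore_index=True
    )
    level = config.benchmark_level
    unit_stats = compute_smr(scored, unit_col=level)
    ok = unit_stats["expected"] > 0
    grid = np.linspace(
        max(0.5, unit_stats.loc[ok, "expected"].min() * 0.5),
        unit_stats.loc[ok, "expected"].max() * 1.2,
        200,
    )
    limits = funnel_limits(grid, config.alpha)
    unit_stats.to_csv(out / f"{level}_stats.csv", index=False)
    outlier_table(unit_stats[ok], limits).to_csv(out / "outliers.csv", index=False)
    plot_funnel(unit_stats[ok], limits, out / "funnel.svg",
                title=f"APACHE II SMR per {level}")
    demographics_table(scored).to_csv(out / "demographics.csv")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "benchmark_level": level,
        "config_hash": hashlib.sha256(
            yaml.safe_dump(
                {
                    "seed": config.seed,
                    "benchmark_level": level,
                    "alpha": config.alpha,
                    "sources": [
                        {k: getattr(s, k) for k in
                         ("name", "store_path", "extraction_config",
                          "diagnosis_map", "strategy", "schema_version")}
                        for s in config.sources
                    ],
                },
                sort_keys=True,
            ).encode()
        ).hexdigest(),
        "row_counts": {r.name: r.counts for r in results},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
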
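"""End-to-end orchestration: simulate/read -> graphs -> metrics -> transform -> analyze.

One :class:`PipelineConfig` drives the whole run. Outputs land in
``outdir``: the cohort files (when simulated), ``metrics.csv``,
``merged.csv``, ``table1.csv``, ``table2_<stratum>.csv``,
``table3_<stratum>.csv`` and a ``manifest.json`` recording the seed, every
convention that resolves a definitional ambiguity, stage row counts and the
package version. Reruns with the same config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ClassnetError, ConfigError, IntegrityError
from .generate import Cohort, GeneratorConfig, generate_cohort, write_cohort
from .io import read_cohort, write_cohort_csv
from .metrics import METRIC_COLUMNS, MetricConventions, compute_cohort_metrics, write_metrics_csv
from .stats import (
    DEFAULT_REFERENCES,
    bivariate_scan,
    describe_by_sex,
    multivariate_model,
    results_to_frame,
    screen_predictors,
)
from .transform import transform_table

logger = logging.getLogger(__name__)

SOCIODEMOGRAPHIC_PREDICTORS = ["location", "family_structure", "age", "fas", "apgar"]
STRATA = (("girl", "girls"), ("boy", "boys"))


@dataclass(frozen=True)
class PipelineConfig:
    """Exactly one of ``generator`` or the two input paths must be given."""

    generator: GeneratorConfig | None = None
    students_path: str | None = None
    nominations_path: str | None = None
    conventions: MetricConventions = field(default_factory=MetricConventions)
    transform_vars: tuple[str, ...] = tuple(METRIC_COLUMNS)
    screening_alpha: float = 0.25
    outdir: str = "classnet_out"
    seed: int | None = None  # overrides the generator's seed when simulating
    references: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_REFERENCES))
    equal_var: bool = True
    cov_type: str = "nonrobust"

    def validate(self) -> None:
        has_paths = self.students_path is not None or self.nominations_path is not None
        if self.generator is not None and has_paths:
            raise ConfigError("provide either a generator config or input paths, not both")
        if self.generator is None:
            if self.students_path is None or self.nominations_path is None:
                raise ConfigError("need both students_path and nominations_path (or a generator)")
        if not 0.0 < self.screening_alpha < 1.0:
            raise ConfigError("screening_alpha must be in (0, 1)")
        self.conventions.validate()
        unknown = set(self.transform_vars) - set(METRIC_COLUMNS)
        if unknown:
            raise ConfigError(f"transform_vars not network metrics: {sorted(unknown)}")


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    merged: pd.DataFrame
    table1: pd.DataFrame
    table2: dict[str, pd.DataFrame]
    table3: dict[str, pd.DataFrame]
    screened: dict[str, list[str]]
    model_f2: dict[str, float]
    manifest: dict


def merge_metrics_attributes(
    metrics: pd.DataFrame, students: pd.DataFrame
) -> pd.DataFrame:
    """Inner-join metrics with attributes on student_id; one row per student."""
    overlap = set(metrics["student_id"]) & set(students["student_id"])
    if not overlap:
        raise IntegrityError("merge: no shared student_id between metrics and attributes")
    unmatched = set(metrics["student_id"]) ^ set(students["student_id"])
    if unmatched:
        logger.warning("merge: %d unmatched student_id(s)", len(unmatched))
    merged = metrics.drop(columns=["classroom_id"]).merge(
        students, on="student_id", how="inner", validate="one_to_one"
    )
    return merged


def _students_frame(cohort_students) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "student_id": s.student_id,
                "classroom_id": s.classroom_id,
                "sex": s.sex,
                "age": s.age,
                "ap": s.ap,
                "apgar": s.apgar,
                "fas": s.fas,
                "family_structure": s.family_structure,
                "location": s.location,
            }
            for s in cohort_students
        ]
    )


def _strip_suffix(frame: pd.DataFrame, suffix: str = "_t") -> pd.DataFrame:
    frame = frame.copy()
    frame["predictor"] = [
        p[: -len(suffix)] if p.endswith(suffix) else p for p in frame["predictor"]
    ]
    return frame


def run(config: PipelineConfig) -> PipelineResult:
    """Execute every stage; see the module docstring for outputs."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- stage: acquire cohort -------------------------------------------
    simulated = config.generator is not None
    if simulated:
        gen = config.generator
        if config.seed is not None:
            gen = dataclasses.replace(gen, seed=config.seed)
        cohort = generate_cohort(gen)
        write_cohort(cohort, outdir)
        students_df = _students_frame(cohort.students)
        graphs = read_cohort(outdir / "students.csv", outdir / "nominations.csv")
    else:
        graphs = read_cohort(config.students_path, config.nominations_path)
        students_df = _students_frame(
            [s for g in graphs for s in g.students.values()]
        )

    # --- stage: metrics ----------------------------------------------------
    metrics = compute_cohort_metrics(graphs, config.conventions)
    write_metrics_csv(metrics, outdir / "metrics.csv")

    # --- stage: merge + transform -----------------------------------------
    merged = merge_metrics_attributes(metrics, students_df)
    merged = transform_table(merged, list(config.transform_vars))
    merged.to_csv(outdir / "merged.csv", index=False)

    # --- stage: descriptives ----------------------------------------------
    table1 = describe_by_sex(
        merged,
        continuous=["age", "fas", "apgar", "ap"] + METRIC_COLUMNS,
        categorical=["location", "family_structure"],
        equal_var=config.equal_var,
    )
    table1.to_csv(outdir / "table1.csv", index=False)

    # --- stage: stratified models ------------------------------------------
    network_predictors = [
        v + "_t" if v in config.transform_vars else v for v in METRIC_COLUMNS
    ]
    predictors = SOCIODEMOGRAPHIC_PREDICTORS + network_predictors
    table2, table3, screened_by, f2_by = {}, {}, {}, {}
    for sex_value, label in STRATA:
        sub = merged[merged["sex"] == sex_value]
        bivar = bivariate_scan(
            sub, "ap", predictors, stratum=label,
            references=config.references, cov_type=config.cov_type,
            cluster_col="classroom_id" if config.cov_type == "cluster" else None,
        )
        t2 = _strip_suffix(results_to_frame(bivar))
        t2.to_csv(outdir / f"table2_{label}.csv", index=False)
        table2[label] = t2

        screened = screen_predictors(bivar, alpha=config.screening_alpha)
        screened_by[label] = [
            p[:-2] if p.endswith("_t") else p for p in screened
        ]
        multi, model_f2 = multivariate_model(
            sub, "ap", screened, stratum=label,
            references=config.references, cov_type=config.cov_type,
            cluster_col="classroom_id" if config.cov_type == "cluster" else None,
        )
        t3 = _strip_suffix(results_to_frame(multi))
        t3.to_csv(outdir / f"table3_{label}.csv", index=False)
        table3[label] = t3
        f2_by[label] = model_f2

    manifest = {
        "version": __version__,
        "simulated": simulated,
        "seed": (config.seed if config.seed is not None
                 else (config.generator.seed if simulated else None)),
        "conventions": {
            "friend_set": config.conventions.friend_set,
            "triangle_variant": config.conventions.triangle_variant,
            "density_denominator": "roster_minus_1",
            "homophily_sign": "negated_mean_abs_diff",
            "betweenness": "directed_fractional_unnormalized",
        },
        "screening_alpha": config.screening_alpha,
        "transform_vars": list(config.transform_vars),
        "references": config.references,
        "rows": {
            "students": int(len(students_df)),
            "classrooms": int(len(graphs)),
            "nominations": int(sum(g.graph.number_of_edges() for g in graphs)),
            "metrics": int(len(metrics)),
            "merged": int(len(merged)),
        },
        "screened": screened_by,
        "model_f2": {k: round(v, 10) for k, v in f2_by.items()},
    }
    if simulated:
        manifest["truth"] = cohort.truth.to_dict()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        metrics=metrics,
        merged=merged,
        table1=table1,
        table2=table2,
        table3=table3,
        screened=screened_by,
        model_f2=f2_by,
        manifest=manifest,
    )
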
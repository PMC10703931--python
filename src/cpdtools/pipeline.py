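"""End-to-end orchestration: simulate -> enrich -> compare -> coverage ->
describe -> evaluate, with a JSON manifest and plain files between stages.

Each stage reads only persisted inputs and writes only flat files, so any
stage can be re-run in isolation and a rerun under the same config
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import coverage as cov
from . import descriptives, evaluation, io, nutrients
from .enrichment import EnrichmentConfig, enrich, export_review_queue
from .synthetic import CohortConfig, GroundTruth, generate_cohort, write_cohort
from .types import NUTRIENT_COLUMNS

logger = logging.getLogger("cpdtools")

STAGES = ["simulate", "enrich", "compare-nutrients", "coverage", "describe", "evaluate"]


class CoverageConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    k_groups: int = 20
    subset_sizes: tuple[int, ...] = (1, 2, 4)
    n_individual: int = 10


class RunConfig(BaseModel):
    """One config for the whole workflow."""

    model_config = ConfigDict(frozen=True)

    out_dir: str = "run_output"
    cohort: CohortConfig = CohortConfig()
    enrichment: EnrichmentConfig = EnrichmentConfig()
    coverage: CoverageConfig = CoverageConfig()
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(_listify(self.model_dump()), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    def config_hash(self) -> str:
        canon = json.dumps(_listify(self.model_dump()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage in dependency order; returns the manifest dict.

    The manifest records the config hash, per-stage produced files and
    per-stage counters (rows in/out, flags raised).  On stage failure the
    manifest (with the last successful stage) is written before the
    exception propagates.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "stages": {},
        "last_successful_stage": None,
    }
    manifest_path = out / "manifest.json"
    try:
        _run_stages(config, out, manifest)
    finally:
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return manifest


def _run_stages(config: RunConfig, out: Path, manifest: dict) -> None:
    # stage 1: simulate ------------------------------------------------
    logger.info("stage simulate: generating synthetic cohort")
    data = generate_cohort(config.cohort)
    files = write_cohort(data, out)
    manifest["stages"]["simulate"] = {
        "files": files,
        "counters": {
            "n_lines": data.purchases.n_lines,
            "n_receipts": data.purchases.n_receipts,
            "n_generic_categories": len(data.generic_db),
            **{f"n_{k}": len(v) for k, v in data.specific_dbs.items()},
        },
    }
    manifest["last_successful_stage"] = "simulate"

    # stage 2: enrich --------------------------------------------------
    logger.info("stage enrich: matching %d lines", data.purchases.n_lines)
    result = enrich(data.purchases, data.generic_db, data.specific_dbs, config.enrichment)
    io.write_table(result.match_table, out / "match_table.csv", "csv")
    line_out = result.line_table.copy()
    line_out["purchase_datetime"] = line_out["purchase_datetime"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    io.write_table(line_out, out / "lines_enriched.csv", "csv")
    queue = export_review_queue(result.match_table)
    io.write_table(queue, out / "review_queue.csv", "csv")
    (out / "enrichment_summary.json").write_text(
        json.dumps(result.summary.as_dict(), indent=2, sort_keys=True), encoding="utf-8"
    )
    manifest["stages"]["enrich"] = {
        "files": {
            "match_table": str(out / "match_table.csv"),
            "lines_enriched": str(out / "lines_enriched.csv"),
            "review_queue": str(out / "review_queue.csv"),
            "summary": str(out / "enrichment_summary.json"),
        },
        "counters": {
            "n_unique_products": result.summary.n_unique,
            "n_review_queue": len(queue),
            "n_specific_direct": result.summary.n_specific_direct,
            "n_flagged_excluded": int(result.match_table["flag_excluded_item_number"].sum()),
            "n_flagged_ambiguous": int(result.match_table["flag_ambiguous"].sum()),
            "n_flagged_greedy": int(result.match_table["flag_greedy"].sum()),
        },
    }
    manifest["last_successful_stage"] = "enrich"

    # stage 3: compare-nutrients ---------------------------------------
    logger.info("stage compare-nutrients")
    comparisons = nutrients.compare_nutrients(
        result.match_table, data.generic_db, data.specific_dbs
    )
    io.write_table(comparisons.df, out / "nutrient_comparisons.csv", "csv")
    medians = nutrients.group_medians(comparisons, "energy_kj")
    io.write_table(medians, out / "nutrient_medians.csv", "csv")
    cdf_files = {}
    for nut in NUTRIENT_COLUMNS:
        if not comparisons.for_nutrient(nut).empty:
            cdf = nutrients.cumulative_distribution(comparisons, nut, "unique")
            path = out / f"cdf_{nut}.csv"
            io.write_table(cdf, path, "csv")
            cdf_files[nut] = str(path)
    manifest["stages"]["compare-nutrients"] = {
        "files": {
            "comparisons": str(out / "nutrient_comparisons.csv"),
            "medians": str(out / "nutrient_medians.csv"),
            **cdf_files,
        },
        "counters": {
            "n_comparisons": len(comparisons.df),
            "n_excluded": comparisons.n_excluded,
        },
    }
    manifest["last_successful_stage"] = "compare-nutrients"

    # stage 4: coverage -------------------------------------------------
    logger.info("stage coverage")
    lines = result.line_table
    is_food = {r.group: r.is_food for r in data.generic_db}
    groups = cov.top_food_groups(lines, config.coverage.k_groups, is_food)
    cov_df = cov.coverage_differences(lines, groups)
    io.write_table(cov_df, out / "coverage_differences.csv", "csv")
    disp = cov.dispersion_summary(cov_df)
    io.write_table(disp, out / "coverage_dispersion.csv", "csv")
    pct = cov.percentile_summary(cov_df, subset_sizes=config.coverage.subset_sizes)
    io.write_table(pct, out / "coverage_percentiles.csv", "csv")
    manifest["stages"]["coverage"] = {
        "files": {
            "differences": str(out / "coverage_differences.csv"),
            "dispersion": str(out / "coverage_dispersion.csv"),
            "percentiles": str(out / "coverage_percentiles.csv"),
        },
        "counters": {"n_groups": len(groups), "n_rows": len(cov_df)},
    }
    manifest["last_successful_stage"] = "coverage"

    # stage 5: describe --------------------------------------------------
    logger.info("stage describe")
    summary = descriptives.summarize_cohort(data.purchases)
    (out / "cohort_summary.json").write_text(
        json.dumps(summary.as_dict(), indent=2, sort_keys=True), encoding="utf-8"
    )
    top_n = min(1000, max(1, data.config.n_products // 10))
    concentration = descriptives.purchase_concentration(data.purchases, top_n)
    manifest["stages"]["describe"] = {
        "files": {"summary": str(out / "cohort_summary.json")},
        "counters": {
            "n_participants": summary.n_participants,
            f"concentration_top{top_n}": round(concentration, 6),
        },
    }
    manifest["last_successful_stage"] = "describe"

    # stage 6: evaluate ---------------------------------------------------
    logger.info("stage evaluate")
    ev = evaluation.evaluate_matching(result.match_table, data.truth)
    (out / "evaluation.json").write_text(
        json.dumps(ev.as_dict(), indent=2, sort_keys=True), encoding="utf-8"
    )
    io.write_table(ev.confusion, out / "confusion.csv", "csv")
    recovery = evaluation.evaluate_proportion_recovery(
        _true_group_lines(data.purchases.df, data.truth), data.truth
    )
    io.write_table(recovery, out / "proportion_recovery.csv", "csv")
    manifest["stages"]["evaluate"] = {
        "files": {
            "evaluation": str(out / "evaluation.json"),
            "confusion": str(out / "confusion.csv"),
            "proportion_recovery": str(out / "proportion_recovery.csv"),
        },
        "counters": {
            "n_evaluated": ev.n_evaluated,
            "n_excluded_unmatched": ev.n_excluded_unmatched,
        },
    }
    manifest["last_successful_stage"] = "evaluate"


def _true_group_lines(df: pd.DataFrame, truth: GroundTruth) -> pd.DataFrame:
    group_of = truth.products.set_index("item_number")["group"]
    out = df[["participant_id"]].copy()
    out["group"] = df["item_number"].map(group_of).to_numpy()
    return out
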
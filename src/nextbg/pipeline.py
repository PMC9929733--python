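"""End-to-end orchestration: simulate -> preprocess -> featurize ->
evaluate -> ml-compare -> report.

Every stage reads and writes plain CSV/JSON files under a single output
directory, so any stage can be re-run from the previous stage's outputs.
A reproducibility manifest records the config snapshot, seeds, per-stage
row counts, package version, and timestamps.  All randomness flows from
the seeds in the config, so a rerun produces byte-identical metric
tables.
"""

from __future__ import annotations

import dataclasses
import json
import os
from datetime import datetime, timezone
from typing import Any

import pandas as pd
import yaml

import nextbg
from nextbg.errors import ConfigError, PipelineStageError, ValidationError
from nextbg import evaluation, learners, preprocess, synthetic_cohort, ts_predictors, variability
from nextbg.synthetic_cohort import (
    AdmissionMeanParams,
    BGObservation,
    CohortConfig,
    GapParams,
    ReadingCountParams,
)

RETAINED_EXCLUSIONS = ("none", preprocess.EXCLUSION_NO_TARGET)

ADMISSION_LEVEL_COLUMNS = ("age", "sex", "race", "diabetes_dx", "home_insulin")


# ---------------------------------------------------------------------------
# Config handling
# ---------------------------------------------------------------------------

_COHORT_NESTED = {
    "reading_count_params": ReadingCountParams,
    "gap_mixture_params": GapParams,
    "admission_mean_params": AdmissionMeanParams,
}


def _build_dataclass(cls, data: dict, context: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown config key in {context}: {sorted(unknown)[0]}")
    return cls(**data)


def cohort_config_from_dict(data: dict) -> CohortConfig:
    data = dict(data)
    kwargs: dict[str, Any] = {}
    for key, cls in _COHORT_NESTED.items():
        if key in data:
            sub = data.pop(key)
            if not isinstance(sub, dict):
                raise ConfigError(f"cohort.{key} must be a mapping")
            # YAML lists arrive as lists; dataclasses expect tuples where tuples
            sub = {
                k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()
            }
            kwargs[key] = _build_dataclass(cls, sub, f"cohort.{key}")
    if "stratum_cv_ranges" in data:
        data["stratum_cv_ranges"] = {
            k: tuple(v) for k, v in data["stratum_cv_ranges"].items()
        }
    config = _build_dataclass(CohortConfig, {**data, **kwargs}, "cohort")
    config.validate()
    return config


def experiment_config_from_dict(data: dict) -> learners.ExperimentConfig:
    data = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in dict(data).items()
        if k != "feature_sets"
    }
    return _build_dataclass(learners.ExperimentConfig, data, "learners")


def load_pipeline_config(path: str) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if "cohort" not in config:
        raise ConfigError("missing config key: cohort")
    known = {"cohort", "predictors", "learners", "report"}
    unknown = set(config) - known
    if unknown:
        raise ConfigError(f"unknown config key: {sorted(unknown)[0]}")
    return config


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cohort_config: CohortConfig, cohort_dir: str) -> int:
    admissions = synthetic_cohort.generate_cohort(cohort_config)
    synthetic_cohort.write_cohort(admissions, cohort_dir)
    return sum(len(a.observations) for a in admissions)


def stage_preprocess(cohort_dir: str, out_dir: str) -> preprocess.PreprocessReport:
    """Cohort CSVs -> cleaned observations (with exclusion reasons), pairs, report."""
    os.makedirs(out_dir, exist_ok=True)
    admissions = synthetic_cohort.read_cohort(cohort_dir)
    retained_by_adm, pairs_by_adm, report = preprocess.preprocess_cohort(admissions)

    obs_records = []
    for adm in admissions:
        for o in adm.observations:
            obs_records.append(
                (adm.admission_id, o.t_minutes, o.glucose, o.source, o.block_index, o.exclusion)
            )
    cleaned = pd.DataFrame(
        obs_records,
        columns=["admission_id", "t_minutes", "glucose_mgdl", "source", "block_index", "exclusion"],
    )
    cleaned.to_csv(os.path.join(out_dir, "cleaned_observations.csv"), index=False)

    pair_records = []
    for adm_id, pairs in pairs_by_adm.items():
        for p in pairs:
            pair_records.append(
                (adm_id, p.index_t_minutes, p.index_bg, p.target_t_minutes, p.target_bg, p.gap_hours)
            )
    pd.DataFrame(
        pair_records,
        columns=["admission_id", "index_t_minutes", "index_bg", "target_t_minutes", "target_bg", "target_gap_hours"],
    ).to_csv(os.path.join(out_dir, "prediction_pairs.csv"), index=False)

    with open(os.path.join(out_dir, "preprocess_report.json"), "w") as fh:
        json.dump(vars(report), fh, indent=2, sort_keys=True)
    return report


def _rows_for_admission(
    adm_id: str,
    group: pd.DataFrame,
    predictor_config: ts_predictors.PredictorConfig,
) -> pd.DataFrame:
    """Rebuild retained sequence + pairs from exclusion flags, then featurize."""
    retained_df = group[group["exclusion"].isin(RETAINED_EXCLUSIONS)]
    retained = [
        BGObservation(adm_id, float(r.t_minutes), float(r.glucose_mgdl), str(r.source),
                      exclusion=str(r.exclusion))
        for r in retained_df.itertuples(index=False)
    ]
    pairs = []
    for i in range(len(retained) - 1):
        if retained[i].exclusion == "none":
            pairs.append(
                preprocess.PredictionPair(
                    index_pos=i,
                    target_pos=i + 1,
                    index_t_minutes=retained[i].t_minutes,
                    target_t_minutes=retained[i + 1].t_minutes,
                    index_bg=retained[i].glucose,
                    target_bg=retained[i + 1].glucose,
                )
            )
    rows = ts_predictors.build_prediction_rows(retained, pairs, predictor_config, adm_id)
    rows = variability.annotate_rows(rows, retained, [p.index_pos for p in pairs])
    return rows


def stage_featurize(
    cohort_dir: str,
    preprocessed_dir: str,
    out_path: str,
    predictor_config: ts_predictors.PredictorConfig | None = None,
) -> pd.DataFrame:
    """Cleaned observations -> prediction rows CSV (predictors + CV strata +
    admission-level fields + per-observation covariates when present)."""
    predictor_config = predictor_config or ts_predictors.PredictorConfig()
    cleaned = pd.read_csv(os.path.join(preprocessed_dir, "cleaned_observations.csv"), float_precision="round_trip")
    frames = [
        _rows_for_admission(str(adm_id), group, predictor_config)
        for adm_id, group in cleaned.groupby("admission_id", sort=False)
    ]
    rows = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    adm_path = os.path.join(cohort_dir, "admissions.csv")
    if len(rows) and os.path.exists(adm_path):
        adm = pd.read_csv(adm_path, float_precision="round_trip")
        adm["admission_id"] = adm["admission_id"].astype(str)
        keep = ["admission_id"] + [c for c in ADMISSION_LEVEL_COLUMNS if c in adm.columns]
        rows = rows.merge(adm[keep], on="admission_id", how="left")

    cov_path = os.path.join(cohort_dir, "covariates.csv")
    if len(rows) and os.path.exists(cov_path):
        cov = pd.read_csv(cov_path, float_precision="round_trip")
        cov["admission_id"] = cov["admission_id"].astype(str)
        rows = rows.merge(
            cov.rename(columns={"t_minutes": "index_t_minutes"}),
            on=["admission_id", "index_t_minutes"],
            how="left",
        )
    os.makedirs(os.path.dirname(os.path.abspath(out_path)), exist_ok=True)
    rows.to_csv(out_path, index=False)
    return rows


def featurize_admissions(
    admissions,
    predictor_config: ts_predictors.PredictorConfig | None = None,
) -> pd.DataFrame:
    """In-memory convenience: preprocess + predictor battery + variability.

    Equivalent to running the preprocess and featurize stages without the
    CSV round trip (no covariate/demographic merge).
    """
    predictor_config = predictor_config or ts_predictors.PredictorConfig()
    retained_by_adm, pairs_by_adm, _ = preprocess.preprocess_cohort(admissions)
    frames = []
    for adm in admissions:
        retained = retained_by_adm[adm.admission_id]
        pairs = pairs_by_adm[adm.admission_id]
        rows = ts_predictors.build_prediction_rows(
            retained, pairs, predictor_config, adm.admission_id
        )
        rows = variability.annotate_rows(rows, retained, [p.index_pos for p in pairs])
        frames.append(rows)
    return (
        pd.concat(frames, ignore_index=True)
        if frames
        else ts_predictors.build_prediction_rows([], [], predictor_config)
    )


def stage_evaluate(rows_path: str, out_dir: str, plot: bool = False) -> dict:
    os.makedirs(out_dir, exist_ok=True)
    rows = pd.read_csv(rows_path, float_precision="round_trip")
    labels = [l for l in learners.MODEL_A_COLUMNS if l in rows.columns]
    eval_df, clarke_df = evaluation.evaluate_grid(rows, labels)
    eval_df.to_csv(os.path.join(out_dir, "eval_summaries.csv"), index=False)

    table2 = evaluation.r2_table(eval_df)
    ordered_cols = [c for c in evaluation.EVAL_POPULATIONS if c in table2.columns]
    table2 = table2.reindex(index=labels, columns=ordered_cols)
    table2.to_csv(os.path.join(out_dir, "table2_r2.csv"))

    clarke_df.to_csv(os.path.join(out_dir, "table3_clarke.csv"), index=False)

    overall = eval_df[eval_df["population_label"] == "all"]
    metrics = {
        "n_rows": int(len(rows)),
        "predictors": {
            r["predictor_label"]: {
                "r2": None if pd.isna(r["r2"]) else float(r["r2"]),
                "rmse": float(r["rmse"]),
                "mae": float(r["mae"]),
                "band": r["r2_band"],
            }
            for _, r in overall.iterrows()
        },
    }
    with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)

    if plot and len(rows):
        label = "ma_4h" if "ma_4h" in rows.columns else labels[0]
        sample = rows.sample(min(len(rows), 5000), random_state=0)
        evaluation.plot_error_grid(
            sample["target_bg"], sample[label],
            os.path.join(out_dir, "error_grid.png"),
            title=f"Clarke Error Grid — {label}",
        )
    return metrics


def stage_ml_compare(
    rows_path: str,
    experiment_config: learners.ExperimentConfig,
    out_dir: str,
    feature_sets: tuple[str, ...] = ("model_A", "model_B"),
) -> pd.DataFrame:
    os.makedirs(out_dir, exist_ok=True)
    rows = pd.read_csv(rows_path, float_precision="round_trip")

    capped = min(experiment_config.sample_size, len(rows))
    auto_capped = capped < experiment_config.sample_size
    frames = []
    metadata: dict[str, Any] = {"auto_capped_sample_size": auto_capped, "feature_sets": {}}
    for fs in feature_sets:
        if fs == "model_B" and "age" not in rows.columns:
            metadata["feature_sets"][fs] = {"skipped": "covariates not present in rows"}
            continue
        config = dataclasses.replace(experiment_config, feature_set=fs, sample_size=capped)
        results, meta = learners.run_cv_experiment(rows, config)
        metadata["feature_sets"][fs] = meta
        frames.append(learners.results_frame(results))
    table4 = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    table4.to_csv(os.path.join(out_dir, "table4_learners.csv"), index=False)
    with open(os.path.join(out_dir, "ml_metadata.json"), "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True, default=str)
    return table4


def render_report(out_dir: str) -> str:
    """Assemble a human-readable summary from completed stage outputs."""
    rows_path = os.path.join(out_dir, "prediction_rows.csv")
    if not os.path.exists(rows_path):
        raise ValidationError("cannot render report: prediction_rows.csv missing (run featurize)")
    rows = pd.read_csv(rows_path, float_precision="round_trip")
    if len(rows) == 0:
        raise ValidationError("cannot render report: the cohort produced no prediction rows")

    parts = ["# Next-BG prediction report\n"]
    parts.append(f"Prediction rows: {len(rows)}; admissions: {rows['admission_id'].nunique()}\n")

    t2_path = os.path.join(out_dir, "table2_r2.csv")
    if os.path.exists(t2_path):
        table2 = pd.read_csv(t2_path, index_col=0)
        parts.append("## Predictor R-squared by variability stratum\n")
        parts.append("```\n" + table2.round(4).to_string() + "\n```\n")
        if {"low", "very_high"}.issubset(table2.columns):
            trend = (table2["low"] - table2["very_high"]).mean()
            parts.append(
                f"\nMean R-squared drop from low to very-high variability: {trend:.3f}\n"
            )
    else:
        parts.append("## Predictor R-squared table\n\n*Not available (run evaluate).*\n")

    t3_path = os.path.join(out_dir, "table3_clarke.csv")
    if os.path.exists(t3_path):
        clarke = pd.read_csv(t3_path)
        parts.append("## Clarke Error Grid zone proportions\n")
        cols = ["predictor_label", "population_label", "n"] + [
            f"zone_{z}_prop" for z in evaluation.CLARKE_ZONES
        ]
        parts.append("```\n" + clarke[cols].round(4).to_string(index=False) + "\n```\n")
    else:
        parts.append("## Clarke Error Grid table\n\n*Not available (run evaluate).*\n")

    t4_path = os.path.join(out_dir, "table4_learners.csv")
    if os.path.exists(t4_path):
        table4 = pd.read_csv(t4_path)
        parts.append("## Cross-validated learner comparison\n")
        parts.append("```\n" + table4.round(4).to_string(index=False) + "\n```\n")
    else:
        parts.append("## Cross-validated learner comparison\n\n*Not available (run ml-compare).*\n")

    # Figures: error grid + one example admission predictor overlay.
    figures = []
    if "ma_4h" in rows.columns:
        sample = rows.sample(min(len(rows), 5000), random_state=0)
        grid_path = os.path.join(out_dir, "error_grid.png")
        evaluation.plot_error_grid(
            sample["target_bg"], sample["ma_4h"], grid_path,
            title="Clarke Error Grid — 4-hour moving average",
        )
        figures.append(("Clarke Error Grid (4-hour MA)", "error_grid.png"))

    overlay_path = os.path.join(out_dir, "admission_overlay.png")
    best = rows["admission_id"].value_counts()
    example_id = best.index[0]
    example = rows[rows["admission_id"] == example_id].sort_values("index_t_minutes")
    if len(example) >= 3:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4.5))
        t_h = example["target_t_minutes"] / 60.0
        ax.plot(t_h, example["target_bg"], "ko-", ms=4, label="next BG (actual)")
        for label, style in (("index_bg", "-"), ("ma_2h", "--"), ("ma_24h", ":"), ("recursive", "-.")):
            if label in example.columns:
                ax.plot(t_h, example[label], style, lw=1.2, label=label)
        ax.set_xlabel("Hours since admission")
        ax.set_ylabel("BG (mg/dL)")
        ax.set_title(f"Predictor overlay — admission {example_id}")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(overlay_path, dpi=120)
        plt.close(fig)
        figures.append(("Example admission predictor overlay", "admission_overlay.png"))

    if figures:
        parts.append("## Figures\n")
        for title, fname in figures:
            parts.append(f"- {title}: `{fname}`")
        parts.append("")

    report_path = os.path.join(out_dir, "report.md")
    with open(report_path, "w") as fh:
        fh.write("\n".join(parts))
    return report_path


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------

def run_pipeline(config: dict | str, out_dir: str, with_report: bool = True) -> dict:
    """Execute all stages in order; returns the manifest (also written to disk).

    ``config`` is a path to a YAML file or an already-parsed mapping with
    sections ``cohort`` (required), ``predictors``, ``learners``.
    """
    if isinstance(config, str):
        config = load_pipeline_config(config)
    if "cohort" not in config:
        raise ConfigError("missing config key: cohort")
    os.makedirs(out_dir, exist_ok=True)

    cohort_config = cohort_config_from_dict(config["cohort"])
    predictor_config = _build_dataclass(
        ts_predictors.PredictorConfig,
        {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (config.get("predictors") or {}).items()
        },
        "predictors",
    )
    learner_section = dict(config.get("learners") or {})
    feature_sets = tuple(learner_section.pop("feature_sets", ("model_A", "model_B")))
    experiment_config = experiment_config_from_dict(learner_section)

    manifest: dict[str, Any] = {
        "package_version": nextbg.__version__,
        "config": config,
        "seeds": {"cohort": cohort_config.seed, "learners": experiment_config.seed},
        "started_utc": datetime.now(timezone.utc).isoformat(),
        "stages": {},
    }

    def _fail(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        _write_manifest(manifest, out_dir)
        raise PipelineStageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    cohort_dir = os.path.join(out_dir, "cohort")
    try:
        n_obs = stage_simulate(cohort_config, cohort_dir)
    except Exception as exc:
        _fail("simulate", exc)
    manifest["stages"]["simulate"] = {
        "n_admissions": cohort_config.n_admissions, "n_observations": n_obs
    }

    try:
        report = stage_preprocess(cohort_dir, out_dir)
    except Exception as exc:
        _fail("preprocess", exc)
    manifest["stages"]["preprocess"] = vars(report)

    rows_path = os.path.join(out_dir, "prediction_rows.csv")
    try:
        rows = stage_featurize(cohort_dir, out_dir, rows_path, predictor_config)
    except Exception as exc:
        _fail("featurize", exc)
    manifest["stages"]["featurize"] = {"n_rows": int(len(rows))}
    if len(rows) != report.n_retained_index:
        raise ValidationError(
            f"count mismatch: featurize produced {len(rows)} rows but preprocess "
            f"reported {report.n_retained_index} index observations"
        )

    try:
        metrics = stage_evaluate(rows_path, out_dir)
    except Exception as exc:
        _fail("evaluate", exc)
    manifest["stages"]["evaluate"] = {"n_rows": metrics["n_rows"]}

    try:
        table4 = stage_ml_compare(rows_path, experiment_config, out_dir, feature_sets)
    except Exception as exc:
        _fail("ml_compare", exc)
    manifest["stages"]["ml_compare"] = {"n_results": int(len(table4))}

    if with_report:
        try:
            render_report(out_dir)
        except Exception as exc:
            _fail("report", exc)
        manifest["stages"]["report"] = {"path": "report.md"}

    manifest["finished_utc"] = datetime.now(timezone.utc).isoformat()
    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: str) -> None:
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
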
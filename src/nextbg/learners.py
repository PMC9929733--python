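"""Cross-validated comparison of regression learners on prediction rows.

A random sample of rows (default 10,000) is scored by 5-fold
cross-validation, with identical fold assignments across learners and
feature sets.  Feature set A is the 24 time-series predictor columns;
feature set B adds demographic, medication, and renal covariates
(categoricals one-hot encoded).

Learner registry: linear regression, partial least squares, k-nearest
neighbors, and random forest.  Hyperparameters are selected by inner
3-fold resampling on the training folds over a small fixed grid (k in
{5, 7, 9} for k-NN; components in {2, 5, 10} for PLS); the random forest
uses a fixed tree count with mtry = p/3.  A rule-ensemble (Cubist-style)
slot exists in the registry but has no faithful implementation in this
environment; requesting it records a substitution in the experiment
metadata rather than failing.

Per-fold metrics reuse the evaluation module's r_squared / rmse / mae;
95% CIs are fold mean ± t(0.975, folds-1) · SD/sqrt(folds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GroupKFold, KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from nextbg.errors import ConfigError, SchemaError
from nextbg.evaluation import mae, r_squared, rmse
from nextbg.ts_predictors import PredictorConfig
from nextbg.synthetic_cohort import INSULIN_CLASSES

MODEL_A_COLUMNS: tuple[str, ...] = tuple(PredictorConfig().labels)

COVARIATE_NUMERIC = ("age", "gfr", "hydrocortisone_equiv") + INSULIN_CLASSES
COVARIATE_BINARY = ("npo", "home_insulin", "home_antihyperglycemic")
COVARIATE_CATEGORICAL = {
    "sex": ("F", "M"),
    "race": ("White", "Black", "Other"),
    "diabetes_dx": ("none", "T1D", "T2D", "other"),
}

LEARNER_NAMES = (
    "linear",
    "partial_least_squares",
    "k_nearest_neighbors",
    "random_forest",
    "rule_ensemble_optional",
)


@dataclass
class ExperimentConfig:
    sample_size: int = 10_000
    n_folds: int = 5
    seed: int = 0
    learners: tuple[str, ...] = (
        "linear",
        "partial_least_squares",
        "k_nearest_neighbors",
        "random_forest",
    )
    feature_set: str = "model_A"
    knn_grid: tuple[int, ...] = (5, 7, 9)
    pls_grid: tuple[int, ...] = (2, 5, 10)
    rf_n_estimators: int = 100
    inner_folds: int = 3
    group_by_admission: bool = False

    def validate(self, n_available: int | None = None) -> None:
        if self.n_folds < 2:
            raise ConfigError(f"n_folds must be >= 2, got {self.n_folds}")
        if not self.learners:
            raise ConfigError("learners must be non-empty")
        unknown = set(self.learners) - set(LEARNER_NAMES)
        if unknown:
            raise ConfigError(f"unknown learners: {sorted(unknown)}")
        if self.feature_set not in ("model_A", "model_B"):
            raise ConfigError(f"feature_set must be model_A or model_B, got {self.feature_set}")
        if self.sample_size < self.n_folds:
            raise ConfigError("sample_size must be at least n_folds")
        if n_available is not None and self.sample_size > n_available:
            raise ConfigError(
                f"sample_size {self.sample_size} exceeds available rows {n_available}"
            )


@dataclass
class CVResult:
    learner: str
    feature_set: str
    rmse_mean: float
    rmse_ci: tuple[float, float]
    r2_mean: float
    r2_ci: tuple[float, float]
    mae_mean: float
    mae_ci: tuple[float, float]
    per_fold_metrics: list[dict] = field(default_factory=list)
    hyperparameters: dict = field(default_factory=dict)


def make_feature_matrix(
    rows: pd.DataFrame, feature_set: str = "model_A"
) -> tuple[pd.DataFrame, list[str]]:
    """Deterministically ordered feature matrix for a learner experiment.

    model_A: the 24 time-series predictor columns.  model_B: those plus
    covariates, categoricals expanded into fixed-category indicator
    columns.  Missing columns raise :class:`SchemaError`.
    """
    missing = [c for c in MODEL_A_COLUMNS if c not in rows.columns]
    if missing:
        raise SchemaError(f"missing predictor columns: {missing}")
    parts = [rows[list(MODEL_A_COLUMNS)].astype(float)]
    labels = list(MODEL_A_COLUMNS)
    if feature_set == "model_B":
        needed = list(COVARIATE_NUMERIC) + list(COVARIATE_BINARY) + list(
            COVARIATE_CATEGORICAL
        )
        missing = [c for c in needed if c not in rows.columns]
        if missing:
            raise SchemaError(f"missing model_B covariate columns: {missing}")
        num = rows[list(COVARIATE_NUMERIC) + list(COVARIATE_BINARY)].astype(float)
        parts.append(num)
        labels += list(num.columns)
        for col, categories in COVARIATE_CATEGORICAL.items():
            for cat in categories[1:]:  # first category is the reference level
                name = f"{col}_{cat}"
                parts.append((rows[col] == cat).astype(float).rename(name))
                labels.append(name)
    elif feature_set != "model_A":
        raise ConfigError(f"unknown feature_set {feature_set!r}")
    X = pd.concat(parts, axis=1)
    return X, labels


def _tune(
    factory: Callable[[object], object],
    grid: Sequence,
    X: np.ndarray,
    y: np.ndarray,
    inner_folds: int,
    seed: int,
):
    """Pick the grid value with lowest inner-CV RMSE; returns (value, model)."""
    if len(grid) == 1:
        return grid[0], factory(grid[0])
    inner = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    best_val, best_score = None, np.inf
    for value in grid:
        errs = []
        for tr, va in inner.split(X):
            model = factory(value)
            model.fit(X[tr], y[tr])
            pred = np.asarray(model.predict(X[va])).ravel()
            errs.append(np.sqrt(np.mean((pred - y[va]) ** 2)))
        score = float(np.mean(errs))
        if score < best_score:
            best_val, best_score = value, score
    return best_val, factory(best_val)


def _fit_predict(
    name: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    config: ExperimentConfig,
    fold_seed: int,
) -> tuple[np.ndarray, dict]:
    if name == "linear":
        model = LinearRegression()
        model.fit(X_train, y_train)
        return model.predict(X_test), {}
    if name == "partial_least_squares":
        grid = [c for c in config.pls_grid if c <= min(X_train.shape[1], len(y_train) - 1)]
        factory = lambda c: PLSRegression(n_components=c)
        value, model = _tune(factory, grid or [1], X_train, y_train, config.inner_folds, fold_seed)
        model.fit(X_train, y_train)
        return np.asarray(model.predict(X_test)).ravel(), {"n_components": value}
    if name == "k_nearest_neighbors":
        factory = lambda k: make_pipeline(
            StandardScaler(), KNeighborsRegressor(n_neighbors=k)
        )
        value, model = _tune(
            factory, list(config.knn_grid), X_train, y_train, config.inner_folds, fold_seed
        )
        model.fit(X_train, y_train)
        return model.predict(X_test), {"n_neighbors": value}
    if name == "random_forest":
        model = RandomForestRegressor(
            n_estimators=config.rf_n_estimators,
            max_features=1.0 / 3.0,
            random_state=fold_seed,
            n_jobs=1,
        )
        model.fit(X_train, y_train)
        return model.predict(X_test), {"n_estimators": config.rf_n_estimators}
    raise ConfigError(f"no implementation for learner {name!r}")


def _t_ci(values: np.ndarray) -> tuple[float, float, float]:
    m = float(np.mean(values))
    if len(values) < 2:
        return m, m, m
    half = float(
        stats.t.ppf(0.975, len(values) - 1) * np.std(values, ddof=1) / np.sqrt(len(values))
    )
    return m, m - half, m + half


def run_cv_experiment(
    rows: pd.DataFrame, config: ExperimentConfig
) -> tuple[list[CVResult], dict]:
    """Seeded sampling + k-fold CV of every requested learner.

    Returns the per-learner results and a metadata dict (seed, folds,
    hyperparameters, and any learner substitutions).
    """
    config.validate(n_available=len(rows))
    rng = np.random.default_rng(config.seed)
    pick = rng.choice(len(rows), size=config.sample_size, replace=False)
    pick.sort()
    sample = rows.iloc[pick].reset_index(drop=True)

    X_df, labels = make_feature_matrix(sample, config.feature_set)
    X = X_df.to_numpy(dtype=float)
    y = sample["target_bg"].to_numpy(dtype=float)

    if config.group_by_admission:
        splitter = GroupKFold(n_splits=config.n_folds)
        groups = sample["admission_id"].to_numpy()
        folds = list(splitter.split(X, y, groups=groups))
    else:
        splitter = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
        folds = list(splitter.split(X, y))

    substitutions = []
    learners = []
    for name in config.learners:
        if name == "rule_ensemble_optional":
            substitutions.append(
                {
                    "requested": "rule_ensemble_optional",
                    "action": "skipped",
                    "reason": "no faithful rule-ensemble implementation available",
                }
            )
            continue
        learners.append(name)

    results: list[CVResult] = []
    for name in learners:
        per_fold = []
        for fold_i, (tr, te) in enumerate(folds):
            fold_seed = config.seed * 1000 + fold_i
            pred, hyper = _fit_predict(name, X[tr], y[tr], X[te], config, fold_seed)
            y_te = y[te]
            degenerate = bool(np.std(y_te) == 0 or np.std(pred) == 0)
            per_fold.append(
                {
                    "fold": fold_i,
                    "rmse": rmse(pred, y_te),
                    "r2": float("nan") if degenerate else r_squared(pred, y_te),
                    "mae": mae(pred, y_te),
                    "degenerate": degenerate,
                    "hyperparameters": hyper,
                }
            )
        rm, rl, rh = _t_ci(np.array([f["rmse"] for f in per_fold]))
        r2m, r2l, r2h = _t_ci(np.array([f["r2"] for f in per_fold]))
        mm, ml, mh = _t_ci(np.array([f["mae"] for f in per_fold]))
        results.append(
            CVResult(
                learner=name,
                feature_set=config.feature_set,
                rmse_mean=rm,
                rmse_ci=(rl, rh),
                r2_mean=r2m,
                r2_ci=(r2l, r2h),
                mae_mean=mm,
                mae_ci=(ml, mh),
                per_fold_metrics=per_fold,
                hyperparameters=per_fold[-1]["hyperparameters"],
            )
        )
    metadata = {
        "seed": config.seed,
        "n_folds": config.n_folds,
        "sample_size": config.sample_size,
        "feature_set": config.feature_set,
        "feature_labels": labels,
        "group_by_admission": config.group_by_admission,
        "substitutions": substitutions,
        "hyperparameter_grids": {
            "k_nearest_neighbors": list(config.knn_grid),
            "partial_least_squares": list(config.pls_grid),
            "random_forest": {"n_estimators": config.rf_n_estimators},
        },
    }
    return results, metadata


def results_frame(results: Sequence[CVResult]) -> pd.DataFrame:
    """Flatten CVResults into the learner-comparison table shape."""
    records = []
    for r in results:
        records.append(
            {
                "learner": r.learner,
                "feature_set": r.feature_set,
                "rmse": r.rmse_mean,
                "rmse_ci_low": r.rmse_ci[0],
                "rmse_ci_high": r.rmse_ci[1],
                "r2": r.r2_mean,
                "r2_ci_low": r.r2_ci[0],
                "r2_ci_high": r.r2_ci[1],
                "mae": r.mae_mean,
                "mae_ci_low": r.mae_ci[0],
                "mae_ci_high": r.mae_ci[1],
            }
        )
    return pd.DataFrame(records)


def compare_models(
    cv_results: Sequence[CVResult], baseline_summaries: Sequence
) -> pd.DataFrame:
    """Learner metrics side by side with single-predictor baselines.

    ``baseline_summaries`` are EvalSummary objects for individual
    predictors on the same sample; ``ci_overlaps_best_learner`` marks
    whether the baseline R² falls inside the best learner's 95% CI.
    """
    records = []
    best_ci = None
    for r in cv_results:
        records.append(
            {
                "name": r.learner,
                "kind": "learner",
                "feature_set": r.feature_set,
                "r2": r.r2_mean,
                "r2_ci_low": r.r2_ci[0],
                "r2_ci_high": r.r2_ci[1],
                "rmse": r.rmse_mean,
                "mae": r.mae_mean,
                "ci_overlaps_best_learner": True,
            }
        )
        if best_ci is None or r.r2_mean > best_ci[0]:
            best_ci = (r.r2_mean, r.r2_ci)
    for s in baseline_summaries:
        overlap = (
            bool(best_ci[1][0] <= s.r2 <= best_ci[1][1]) if best_ci is not None else False
        )
        records.append(
            {
                "name": s.predictor_label,
                "kind": "single_predictor",
                "feature_set": "",
                "r2": s.r2,
                "r2_ci_low": float("nan"),
                "r2_ci_high": float("nan"),
                "rmse": s.rmse,
                "mae": s.mae,
                "ci_overlaps_best_learner": overlap,
            }
        )
    return pd.DataFrame(records)
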
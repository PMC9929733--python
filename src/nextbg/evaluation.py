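"""Prediction scoring: squared Pearson correlation, RMSE, median absolute
error, qualitative correlation bands, and Clarke Error Grid analysis.

``r_squared`` is the square of the Pearson product-moment correlation
between prediction and target — deliberately *not* 1 - SSres/SStot, so a
perfectly anti-correlated predictor still scores 1.0.  Bands: good when
R² > 0.75, acceptable in [0.50, 0.75], inadequate below 0.50.

The Clarke Error Grid uses the canonical 1987 piecewise boundaries with
fixed precedence A → E → C → D → B:

    A: reference < 70 and prediction < 70, or |pred - ref| <= 0.2·ref
    E: (ref <= 70 and pred >= 180) or (ref >= 180 and pred <= 70)
    C: (70 <= ref <= 290 and pred >= ref + 110)
       or (130 <= ref <= 180 and pred <= (7/5)·ref - 182)
    D: (ref >= 240 and 70 <= pred <= 180)
       or (ref <= 175/3 and 70 <= pred <= 180)
       or (175/3 <= ref <= 70 and pred >= (6/5)·ref)
    B: everything else
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from nextbg.errors import ContractError, UndefinedMetricError

CLARKE_ZONES = ("A", "B", "C", "D", "E")

EVAL_POPULATIONS = ("all", "low", "medium", "high", "very_high")
CLARKE_POPULATIONS = ("full", "t1d", "t2d_basal")


@dataclass
class EvalSummary:
    predictor_label: str
    population_label: str
    n: int
    r2: float
    rmse: float
    mae: float
    r2_band: str
    empty: bool = False


@dataclass
class ClarkeResult:
    predictor_label: str
    population_label: str
    zone_counts: dict[str, int] = field(default_factory=dict)
    zone_props: dict[str, float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return sum(self.zone_counts.values())


def _as_arrays(pred, target) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ContractError(f"length mismatch: {p.shape} vs {t.shape}")
    return p, t


def r_squared(pred, target) -> float:
    """Square of the Pearson correlation between prediction and target."""
    p, t = _as_arrays(pred, target)
    if len(p) < 2:
        raise ContractError("need at least 2 points for a correlation")
    if np.std(p) == 0 or np.std(t) == 0:
        raise UndefinedMetricError("correlation undefined for zero-variance input")
    r = np.corrcoef(p, t)[0, 1]
    return float(r * r)


def rmse(pred, target) -> float:
    p, t = _as_arrays(pred, target)
    if len(p) == 0:
        raise ContractError("empty input")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def mae(pred, target) -> float:
    """Median of absolute errors."""
    p, t = _as_arrays(pred, target)
    if len(p) == 0:
        raise ContractError("empty input")
    return float(np.median(np.abs(p - t)))


def classify_r2(r2: float) -> str:
    """good > 0.75 >= acceptable >= 0.50 > inadequate."""
    if r2 > 0.75:
        return "good"
    if r2 >= 0.50:
        return "acceptable"
    return "inadequate"


def clarke_zone(reference_bg: float, predicted_bg: float) -> str:
    """Clarke Error Grid zone for one (reference, prediction) pair."""
    return clarke_zones([reference_bg], [predicted_bg])[0]


def clarke_zones(reference, predicted) -> np.ndarray:
    """Vectorized zone assignment with precedence A → E → C → D → B."""
    ref, pred = _as_arrays(reference, predicted)
    if np.any(ref <= 0) or np.any(pred <= 0):
        raise ContractError("glucose values must be positive mg/dL")
    zone_a = ((ref < 70) & (pred < 70)) | (np.abs(pred - ref) <= 0.2 * ref)
    zone_e = ((ref <= 70) & (pred >= 180)) | ((ref >= 180) & (pred <= 70))
    zone_c = ((ref >= 70) & (ref <= 290) & (pred >= ref + 110)) | (
        (ref >= 130) & (ref <= 180) & (pred <= (7.0 / 5.0) * ref - 182.0)
    )
    zone_d = (
        ((ref >= 240) & (pred >= 70) & (pred <= 180))
        | ((ref <= 175.0 / 3.0) & (pred >= 70) & (pred <= 180))
        | ((ref >= 175.0 / 3.0) & (ref <= 70) & (pred >= (6.0 / 5.0) * ref))
    )
    return np.select(
        [zone_a, zone_e, zone_c, zone_d],
        ["A", "E", "C", "D"],
        default="B",
    ).astype("<U1")


def clarke_result(
    reference, predicted, predictor_label: str = "", population_label: str = ""
) -> ClarkeResult:
    zones = clarke_zones(reference, predicted)
    counts = {z: int(np.sum(zones == z)) for z in CLARKE_ZONES}
    n = len(zones)
    props = {z: (counts[z] / n if n else float("nan")) for z in CLARKE_ZONES}
    return ClarkeResult(predictor_label, population_label, counts, props)


def summarize(
    pred, target, predictor_label: str = "", population_label: str = ""
) -> EvalSummary:
    """EvalSummary for one predictor/population cell; flags empty cells."""
    p, t = _as_arrays(pred, target)
    if len(p) < 2 or np.std(p) == 0 or np.std(t) == 0:
        return EvalSummary(
            predictor_label,
            population_label,
            n=len(p),
            r2=float("nan"),
            rmse=rmse(p, t) if len(p) else float("nan"),
            mae=mae(p, t) if len(p) else float("nan"),
            r2_band="undefined",
            empty=len(p) == 0,
        )
    r2 = r_squared(p, t)
    return EvalSummary(
        predictor_label,
        population_label,
        n=len(p),
        r2=r2,
        rmse=rmse(p, t),
        mae=mae(p, t),
        r2_band=classify_r2(r2),
    )


def _population_masks(rows: pd.DataFrame) -> dict[str, np.ndarray]:
    masks: dict[str, np.ndarray] = {"full": np.ones(len(rows), dtype=bool)}
    if "diabetes_dx" in rows.columns:
        masks["t1d"] = (rows["diabetes_dx"] == "T1D").to_numpy()
        t2d = (rows["diabetes_dx"] == "T2D").to_numpy()
        if "insulin_basal" in rows.columns:
            masks["t2d_basal"] = t2d & (rows["insulin_basal"].to_numpy(dtype=float) > 0)
    return masks


def evaluate_grid(
    rows: pd.DataFrame,
    predictor_labels: Sequence[str],
    population_filters: dict[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every predictor overall, by stratum, and by clinical population.

    Returns ``(eval_df, clarke_df)``: one EvalSummary row per predictor ×
    {all + strata}, and one ClarkeResult row per predictor × clinical
    population (full cohort, type 1 diabetes, type 2 diabetes with basal
    insulin on board — the latter two only when the needed columns exist,
    or as supplied via ``population_filters``).
    """
    target = rows["target_bg"].to_numpy(dtype=float)
    strata = rows["stratum"].to_numpy() if "stratum" in rows.columns else None

    eval_records = []
    for label in predictor_labels:
        pred = rows[label].to_numpy(dtype=float)
        for pop in EVAL_POPULATIONS:
            if pop == "all":
                mask = np.ones(len(rows), dtype=bool)
            elif strata is None:
                continue
            else:
                mask = strata == pop
            summary = summarize(pred[mask], target[mask], label, pop)
            eval_records.append(vars(summary))
    eval_df = pd.DataFrame(eval_records)

    masks = population_filters if population_filters is not None else _population_masks(rows)
    clarke_records = []
    for label in predictor_labels:
        pred = rows[label].to_numpy(dtype=float)
        for pop, mask in masks.items():
            if mask.sum() == 0:
                rec = {
                    "predictor_label": label,
                    "population_label": pop,
                    "n": 0,
                    "empty": True,
                }
                rec.update({f"zone_{z}_count": 0 for z in CLARKE_ZONES})
                rec.update({f"zone_{z}_prop": float("nan") for z in CLARKE_ZONES})
                clarke_records.append(rec)
                continue
            res = clarke_result(target[mask], pred[mask], label, pop)
            rec = {
                "predictor_label": label,
                "population_label": pop,
                "n": res.n,
                "empty": False,
            }
            rec.update({f"zone_{z}_count": res.zone_counts[z] for z in CLARKE_ZONES})
            rec.update({f"zone_{z}_prop": res.zone_props[z] for z in CLARKE_ZONES})
            clarke_records.append(rec)
    clarke_df = pd.DataFrame(clarke_records)
    return eval_df, clarke_df


def r2_table(eval_df: pd.DataFrame) -> pd.DataFrame:
    """Wide predictor × population R² table (the stratified correlation view)."""
    return eval_df.pivot(index="predictor_label", columns="population_label", values="r2")


def plot_error_grid(reference, predicted, path: str, title: str = "Clarke Error Grid"):
    """Scatter the (reference, prediction) pairs over the zone boundaries."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref, pred = _as_arrays(reference, predicted)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(ref, pred, s=4, alpha=0.3, linewidths=0)
    lim = 400
    # zone A envelope
    ax.plot([0, lim], [0, lim], "k:", lw=0.8)
    ax.plot([70 / 1.2, lim], [70 / 1.2 * 1.2, lim * 1.2], "k-", lw=0.8)
    ax.plot([70, lim], [70 * 0.8, lim * 0.8], "k-", lw=0.8)
    ax.plot([0, 70], [70, 70], "k-", lw=0.8)
    ax.plot([70, 70], [0, 56], "k-", lw=0.8)
    # C boundaries
    ax.plot([70, 290], [180, 400], "k-", lw=0.8)
    ax.plot([130, 180], [0, 70], "k-", lw=0.8)
    # D / E boundaries
    ax.plot([240, lim], [180, 180], "k-", lw=0.8)
    ax.plot([0, 58.33], [180, 180], "k-", lw=0.8)
    ax.plot([0, 70], [180, 180], "k--", lw=0.5)
    ax.plot([180, lim], [70, 70], "k-", lw=0.8)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("Reference next BG (mg/dL)")
    ax.set_ylabel("Predicted next BG (mg/dL)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
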
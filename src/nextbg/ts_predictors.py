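"""Next-glucose time-series predictor battery.

For every index observation the default battery computes 24 predictors:
14 trailing moving averages (0.5 h ... 72 h), 7 rolling regressions
(last 3 ... 500 observations), recursive regression (all observations
since admission), the index value itself (sample-and-hold), and the
previous retained reading.

Moving averages are unweighted means over a closed time window ending at
the index reading (the index reading is always included; an empty
remainder falls back to the index value).  Rolling regression is an
ordinary least squares fit of glucose on observation position 1..m over
the last ``m = min(n, available)`` retained readings, extrapolated to
position ``m + 1``.  Predictions are floored at 1 mg/dL so that every
emitted value is physically positive.

Scalar functions implement the operation contracts one observation at a
time; the vectorized module internals (prefix-sum based) produce the same
values to floating-point identity and are what the pipeline uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from nextbg.errors import ConfigError, ContractError
from nextbg.preprocess import PredictionPair
from nextbg.synthetic_cohort import BGObservation

PREDICTION_FLOOR = 1.0  # mg/dL; keeps extrapolated regressions physically positive

DEFAULT_MA_WINDOWS_HOURS = (
    0.5, 1.0, 1.5, 2.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 36.0, 48.0, 60.0, 72.0,
)
DEFAULT_RR_ORDERS = (3, 4, 5, 10, 25, 100, 500)

LABEL_RECURSIVE = "recursive"
LABEL_INDEX = "index_bg"
LABEL_PREVIOUS = "prev_bg"


def ma_label(window_hours: float) -> str:
    return f"ma_{window_hours:g}h"


def rr_label(n: int) -> str:
    return f"rr_{n}"


@dataclass
class PredictorConfig:
    ma_windows_hours: tuple[float, ...] = DEFAULT_MA_WINDOWS_HOURS
    rr_orders: tuple[int, ...] = DEFAULT_RR_ORDERS
    include_recursive: bool = True
    include_sample_and_hold: bool = True
    include_previous_bg: bool = True

    def validate(self) -> None:
        w = self.ma_windows_hours
        if any(x <= 0 for x in w) or any(b <= a for a, b in zip(w, w[1:])):
            raise ConfigError("ma_windows_hours must be strictly increasing and positive")
        n = self.rr_orders
        if any(x < 2 for x in n) or any(b <= a for a, b in zip(n, n[1:])):
            raise ConfigError("rr_orders must be strictly increasing integers >= 2")

    @property
    def labels(self) -> list[str]:
        out = [ma_label(w) for w in self.ma_windows_hours]
        out += [rr_label(n) for n in self.rr_orders]
        if self.include_recursive:
            out.append(LABEL_RECURSIVE)
        if self.include_sample_and_hold:
            out.append(LABEL_INDEX)
        if self.include_previous_bg:
            out.append(LABEL_PREVIOUS)
        return out


# ---------------------------------------------------------------------------
# Scalar operation contracts
# ---------------------------------------------------------------------------

def _history_arrays(history: Sequence[BGObservation]) -> tuple[np.ndarray, np.ndarray]:
    if len(history) == 0:
        raise ContractError("history must contain at least the index reading")
    t = np.array([o.t_minutes for o in history], dtype=float)
    v = np.array([o.glucose for o in history], dtype=float)
    return t, v


def moving_average_predict(
    history: Sequence[BGObservation],
    index_obs: BGObservation,
    window_hours: float,
) -> float:
    """Unweighted mean of readings in the closed window ending at the index."""
    t, v = _history_arrays(history)
    t_idx = index_obs.t_minutes
    lo = t_idx - window_hours * 60.0
    mask = (t >= lo) & (t <= t_idx)
    if not mask.any():
        return float(index_obs.glucose)
    return float(v[mask].mean())


def _ols_extrapolate(y: np.ndarray) -> float:
    """OLS of y on positions 1..m, evaluated at m+1 (m = len(y) >= 2)."""
    m = len(y)
    x = np.arange(1, m + 1, dtype=float)
    xbar = (m + 1) / 2.0
    sxx = m * (m * m - 1) / 12.0
    slope = float(((x - xbar) * (y - y.mean())).sum() / sxx)
    return float(y.mean() + slope * ((m + 1) - xbar))


def rolling_regression_predict(
    history: Sequence[BGObservation],
    index_obs: BGObservation,
    n: int,
) -> float:
    """Extrapolate an OLS line over the last min(n, available) readings."""
    if n < 2:
        raise ContractError(f"rolling regression order must be >= 2, got {n}")
    _, v = _history_arrays(history)
    m = min(n, len(v))
    if m < 2:
        return float(index_obs.glucose)
    return max(PREDICTION_FLOOR, _ols_extrapolate(v[-m:]))


def recursive_regression_predict(
    history: Sequence[BGObservation], index_obs: BGObservation
) -> float:
    """Rolling regression with n equal to all available readings."""
    return rolling_regression_predict(history, index_obs, max(2, len(history)))


def sample_and_hold_predict(index_obs: BGObservation) -> float:
    """Predict the next value as exactly the index value."""
    return float(index_obs.glucose)


def previous_bg_predict(
    history: Sequence[BGObservation], index_obs: BGObservation
) -> float:
    """The retained reading immediately before the index; index value if none."""
    _, v = _history_arrays(history)
    return float(v[-2]) if len(v) >= 2 else float(index_obs.glucose)


# ---------------------------------------------------------------------------
# Vectorized internals (prefix sums over one admission)
# ---------------------------------------------------------------------------

def _ma_matrix(
    t: np.ndarray, v: np.ndarray, idx: np.ndarray, window_minutes: float
) -> np.ndarray:
    """Moving-average prediction at each retained position in ``idx``."""
    left = np.searchsorted(t, t[idx] - window_minutes, side="left")
    csum = np.concatenate([[0.0], np.cumsum(v)])
    count = idx - left + 1
    return (csum[idx + 1] - csum[left]) / count


def _rr_matrix(v: np.ndarray, idx: np.ndarray, n: int | None) -> np.ndarray:
    """Rolling-regression prediction at each position in ``idx``.

    ``n`` is the window order in observations; ``None`` means recursive
    (all readings from admission start).  Windows shorter than 2 fall
    back to the index value.
    """
    m_avail = idx + 1
    k = m_avail if n is None else np.minimum(n, m_avail)
    start = idx - k + 1  # 0-based start of the window

    pos = np.arange(1, len(v) + 1, dtype=float)  # global 1-based positions
    c0 = np.concatenate([[0.0], np.cumsum(v)])
    c1 = np.concatenate([[0.0], np.cumsum(v * pos)])

    sy = c0[idx + 1] - c0[start]
    sxy_global = c1[idx + 1] - c1[start]
    # local position of global g is g - start, so sum(x*y) shifts by start*sy
    sxy = sxy_global - start * sy

    kf = k.astype(float)
    xbar = (kf + 1.0) / 2.0
    sxx = kf * (kf * kf - 1.0) / 12.0
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (sxy - xbar * sy) / sxx
        pred = sy / kf + slope * ((kf + 1.0) - xbar)
    pred = np.where(k >= 2, pred, v[idx])
    return np.maximum(PREDICTION_FLOOR, pred)


def predictor_frame(
    retained: Sequence[BGObservation],
    pairs: Sequence[PredictionPair],
    config: PredictorConfig,
) -> pd.DataFrame:
    """Predictor columns (one per label) for each index row of one admission."""
    t = np.array([o.t_minutes for o in retained], dtype=float)
    v = np.array([o.glucose for o in retained], dtype=float)
    idx = np.array([p.index_pos for p in pairs], dtype=int)
    cols: dict[str, np.ndarray] = {}
    for w in config.ma_windows_hours:
        cols[ma_label(w)] = _ma_matrix(t, v, idx, w * 60.0)
    for n in config.rr_orders:
        cols[rr_label(n)] = _rr_matrix(v, idx, n)
    if config.include_recursive:
        cols[LABEL_RECURSIVE] = _rr_matrix(v, idx, None)
    if config.include_sample_and_hold:
        cols[LABEL_INDEX] = v[idx]
    if config.include_previous_bg:
        prev = np.where(idx >= 1, v[np.maximum(idx - 1, 0)], v[idx])
        cols[LABEL_PREVIOUS] = prev
    return pd.DataFrame(cols)


def build_prediction_rows(
    retained: Sequence[BGObservation],
    pairs: Sequence[PredictionPair],
    config: PredictorConfig | None = None,
    admission_id: str | None = None,
) -> pd.DataFrame:
    """Assemble one prediction row per index observation.

    Columns: admission_id, index_t_minutes, index_bg, target_t_minutes,
    target_bg, target_gap_hours, then one column per configured predictor
    label.  Empty pair lists yield an empty (but fully labelled) frame.
    """
    config = config or PredictorConfig()
    config.validate()
    if admission_id is None:
        admission_id = retained[0].admission_id if retained else ""
    base = pd.DataFrame(
        {
            "admission_id": [admission_id] * len(pairs),
            "index_t_minutes": [p.index_t_minutes for p in pairs],
            "index_bg": [p.index_bg for p in pairs],
            "target_t_minutes": [p.target_t_minutes for p in pairs],
            "target_bg": [p.target_bg for p in pairs],
            "target_gap_hours": [p.gap_hours for p in pairs],
        }
    )
    if len(pairs) == 0:
        for label in config.labels:
            if label not in base.columns:
                base[label] = pd.Series(dtype=float)
        return base
    out = pd.concat([base, predictor_frame(retained, pairs, config)], axis=1)
    # the sample-and-hold label coincides with the base index_bg column
    return out.loc[:, ~out.columns.duplicated()]
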
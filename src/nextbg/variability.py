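"""Trailing 24-hour glycemic variability (coefficient of variation) strata.

CV is the sample standard deviation divided by the mean over the retained
readings in the closed 24-hour window ending at (and including) the index
reading.  Band boundaries belong to the lower stratum:

    low        CV <= 0.15
    medium     0.15 < CV <= 0.30
    high       0.30 < CV <= 0.45
    very_high  CV > 0.45

Windows with fewer than two readings have an undefined CV and are labelled
``unclassified``; they appear only in all-observation analyses.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from nextbg.errors import ContractError
from nextbg.synthetic_cohort import BGObservation

WINDOW_MINUTES = 24.0 * 60.0

LOW_MAX = 0.15
MEDIUM_MAX = 0.30
HIGH_MAX = 0.45

STRATUM_ORDER = ("low", "medium", "high", "very_high")
UNCLASSIFIED = "unclassified"


def cv_24h(history: Sequence[BGObservation], index_obs: BGObservation) -> float:
    """Sample CV over the trailing 24 h window; NaN when <2 readings fall in it."""
    t = np.array([o.t_minutes for o in history], dtype=float)
    v = np.array([o.glucose for o in history], dtype=float)
    t_idx = index_obs.t_minutes
    mask = (t >= t_idx - WINDOW_MINUTES) & (t <= t_idx)
    w = v[mask]
    if len(w) < 2:
        return float("nan")
    return float(np.std(w, ddof=1) / np.mean(w))


def assign_stratum(cv: float) -> str:
    """Map a CV value to its variability stratum label."""
    if cv is None or (isinstance(cv, float) and math.isnan(cv)):
        return UNCLASSIFIED
    if cv < 0:
        raise ContractError(f"CV must be non-negative, got {cv}")
    if cv <= LOW_MAX:
        return "low"
    if cv <= MEDIUM_MAX:
        return "medium"
    if cv <= HIGH_MAX:
        return "high"
    return "very_high"


def _cv_vector(t: np.ndarray, v: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Vectorized trailing-24h CV at retained positions ``idx``."""
    left = np.searchsorted(t, t[idx] - WINDOW_MINUTES, side="left")
    c0 = np.concatenate([[0.0], np.cumsum(v)])
    c1 = np.concatenate([[0.0], np.cumsum(v * v)])
    count = (idx - left + 1).astype(float)
    s = c0[idx + 1] - c0[left]
    s2 = c1[idx + 1] - c1[left]
    mean = s / count
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.maximum(0.0, (s2 - count * mean * mean) / (count - 1.0))
        cv = np.sqrt(var) / mean
    return np.where(count >= 2, cv, np.nan)


def annotate_rows(
    rows: pd.DataFrame,
    retained: Sequence[BGObservation],
    index_positions: Sequence[int],
) -> pd.DataFrame:
    """Add ``cv_24h`` and ``stratum`` columns to one admission's rows."""
    if len(rows) == 0:
        rows = rows.copy()
        rows["cv_24h"] = pd.Series(dtype=float)
        rows["stratum"] = pd.Series(dtype=object)
        return rows
    t = np.array([o.t_minutes for o in retained], dtype=float)
    v = np.array([o.glucose for o in retained], dtype=float)
    idx = np.asarray(index_positions, dtype=int)
    cv = _cv_vector(t, v, idx)
    rows = rows.copy()
    rows["cv_24h"] = cv
    rows["stratum"] = [assign_stratum(c) for c in cv]
    return rows
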
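"""Synthetic inpatient glucose cohort generator.

Emits admissions whose statistical structure matches what the downstream
analysis assumes: right-skewed reading counts (median 12, IQR 5-24),
inter-reading gaps with percentiles near 0.58/2.48/3.88/4.88/8.23 hours,
per-admission mean glucose near median 141 (IQR 117-179) mg/dL, a
stationary lag-1 autoregressive glucose process around the admission mean,
and four coefficient-of-variation strata with controllable dispersion.

The glucose process is Gaussian AR(1) truncated to [40, 600] mg/dL; with
lag-1 coefficient ``rho`` the population sample-and-hold ceiling is
``R^2 ~= rho^2``, which downstream property tests exploit.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from nextbg.errors import ConfigError, ParseError, ValidationError

GLUCOSE_FLOOR = 40.0
GLUCOSE_CEIL = 600.0

STRATUM_LABELS = ("low", "medium", "high", "very_high")

#: Default per-stratum target-CV sampling ranges.  Each range sits inside
#: the stratum's CV band with margin so that realized window CVs land in
#: the requested band at high rate despite sampling noise.
DEFAULT_CV_RANGES: dict[str, tuple[float, float]] = {
    "low": (0.06, 0.13),
    "medium": (0.18, 0.27),
    "high": (0.33, 0.42),
    "very_high": (0.50, 0.62),
}

#: Default stratum mix, proportional to the observation counts of the four
#: variability bands in the reference cohort (404,840 / 1,442,328 /
#: 456,584 / 132,476).
DEFAULT_STRATUM_WEIGHTS: dict[str, float] = {
    "low": 0.16617,
    "medium": 0.59203,
    "high": 0.18742,
    "very_high": 0.05438,
}

DIABETES_CATEGORIES = ("none", "T1D", "T2D", "other")
DIABETES_PROBS = (0.6358, 0.0285, 0.3250, 0.0107)
RACE_CATEGORIES = ("White", "Black", "Other")
RACE_PROBS = (0.5661, 0.3191, 0.1148)

INSULIN_CLASSES = (
    "insulin_basal",
    "insulin_combination",
    "insulin_concentrated",
    "insulin_intermediate",
    "insulin_rapid",
    "insulin_regular",
    "insulin_ultralong",
)

COVARIATE_COLUMNS = (
    "npo",
    "gfr",
    "hydrocortisone_equiv",
    "home_antihyperglycemic",
) + INSULIN_CLASSES

OBSERVATION_COLUMNS = ("admission_id", "t_minutes", "glucose_mgdl", "source")


@dataclass
class BGObservation:
    """One timed glucose reading within an admission."""

    admission_id: str
    t_minutes: float
    glucose: float
    source: str = "POC"
    block_index: int | None = None
    exclusion: str = "none"  # none | duplicate_block | adjacency_90min | no_target_gt_10h


@dataclass
class Demographics:
    age: float
    sex: str
    race: str


@dataclass
class Admission:
    """An inpatient stay with its ordered glucose observation stream."""

    admission_id: str
    demographics: Demographics
    diabetes_dx: str
    home_insulin: bool
    observations: list[BGObservation]
    start_minutes: float = 0.0  # wall-clock minutes of admission start (5-min block anchor)
    covariate_series: pd.DataFrame | None = None
    target_stratum: str | None = None  # generator-requested variability stratum
    target_cv: float | None = None

    def validate(self) -> None:
        if len(self.observations) < 4:
            raise ValidationError(
                f"admission {self.admission_id}: fewer than 4 observations"
            )
        t_prev = -math.inf
        for obs in self.observations:
            if not math.isfinite(obs.t_minutes):
                raise ValidationError(
                    f"admission {self.admission_id}: non-finite t_minutes"
                )
            if obs.t_minutes <= t_prev:
                raise ValidationError(
                    f"admission {self.admission_id}: observations not strictly "
                    f"sorted at t={obs.t_minutes}"
                )
            t_prev = obs.t_minutes
            if not obs.glucose > 0:
                raise ValidationError(
                    f"admission {self.admission_id}: non-positive glucose "
                    f"{obs.glucose} at t={obs.t_minutes}"
                )

    @property
    def times(self) -> np.ndarray:
        return np.array([o.t_minutes for o in self.observations], dtype=float)

    @property
    def glucose(self) -> np.ndarray:
        return np.array([o.glucose for o in self.observations], dtype=float)


@dataclass
class ReadingCountParams:
    """Lognormal reading count, rounded and floored (targets median 12, IQR 5-24)."""

    median: float = 12.0
    sigma_log: float = 1.163
    min_count: int = 4


@dataclass
class GapParams:
    """Inter-reading gap distribution in hours.

    kind="lognormal_mixture": weighted lognormal components; the default
    parameters are moment-matched to gap percentiles
    0.58/2.48/3.88/4.88/8.23 h at probabilities 5/25/50/75/95%.
    kind="uniform": Uniform(low_hours, high_hours), handy for building
    exclusion-free test cohorts.
    """

    kind: str = "lognormal_mixture"
    weights: tuple[float, ...] = (0.449265, 0.550735)
    mu_log: tuple[float, ...] = (0.776869, 1.449705)
    sigma_log: tuple[float, ...] = (1.083558, 0.218924)
    low_hours: float = 2.0
    high_hours: float = 6.0


@dataclass
class AdmissionMeanParams:
    """Lognormal per-admission mean BG (targets median 141, IQR 117-179 mg/dL)."""

    median: float = 141.0
    sigma_log: float = 0.3153
    min_bg: float = 70.0
    max_bg: float = 400.0


@dataclass
class CohortConfig:
    n_admissions: int = 100
    seed: int = 0
    reading_count_params: ReadingCountParams = field(default_factory=ReadingCountParams)
    gap_mixture_params: GapParams = field(default_factory=GapParams)
    admission_mean_params: AdmissionMeanParams = field(
        default_factory=AdmissionMeanParams
    )
    stratum_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRATUM_WEIGHTS)
    )
    stratum_cv_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CV_RANGES)
    )
    ar_coefficient: float = 0.7
    covariate_flags: bool = False
    insulin_effect_mgdl_per_unit: float = 0.0
    prop_serum: float = 0.05

    def validate(self) -> None:
        if not (isinstance(self.n_admissions, (int, np.integer)) and self.n_admissions > 0):
            raise ConfigError(f"n_admissions must be a positive integer, got {self.n_admissions}")
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise ConfigError(f"ar_coefficient must be in [0, 1), got {self.ar_coefficient}")
        rc = self.reading_count_params
        if rc.median <= 0 or rc.sigma_log < 0:
            raise ConfigError("reading_count_params: median must be >0 and sigma_log >=0")
        if rc.min_count < 4:
            raise ConfigError("reading_count_params.min_count must be >=4 (inclusion rule)")
        gp = self.gap_mixture_params
        if gp.kind == "lognormal_mixture":
            if not (len(gp.weights) == len(gp.mu_log) == len(gp.sigma_log)):
                raise ConfigError("gap_mixture_params: weights/mu_log/sigma_log length mismatch")
            if abs(sum(gp.weights) - 1.0) > 1e-9:
                raise ConfigError("gap_mixture_params.weights must sum to 1")
            if any(s <= 0 for s in gp.sigma_log):
                raise ConfigError("gap_mixture_params.sigma_log entries must be >0")
        elif gp.kind == "uniform":
            if not (0 < gp.low_hours < gp.high_hours):
                raise ConfigError("gap_mixture_params: need 0 < low_hours < high_hours")
        else:
            raise ConfigError(f"gap_mixture_params.kind unknown: {gp.kind!r}")
        am = self.admission_mean_params
        if am.median <= 0 or am.sigma_log < 0 or not (0 < am.min_bg < am.max_bg):
            raise ConfigError("admission_mean_params: invalid scale or range")
        if set(self.stratum_weights) != set(STRATUM_LABELS):
            raise ConfigError(
                f"stratum_weights must have exactly keys {STRATUM_LABELS}"
            )
        if any(w < 0 for w in self.stratum_weights.values()):
            raise ConfigError("stratum_weights must be non-negative")
        if abs(sum(self.stratum_weights.values()) - 1.0) > 1e-9:
            raise ConfigError("stratum_weights must sum to 1 within 1e-9")
        for label, (lo, hi) in self.stratum_cv_ranges.items():
            if label not in STRATUM_LABELS:
                raise ConfigError(f"stratum_cv_ranges: unknown stratum {label!r}")
            if not (0 <= lo <= hi):
                raise ConfigError(f"stratum_cv_ranges[{label!r}]: need 0 <= lo <= hi")
        if not (0.0 <= self.prop_serum <= 1.0):
            raise ConfigError(f"prop_serum must be in [0, 1], got {self.prop_serum}")
        if self.insulin_effect_mgdl_per_unit < 0:
            raise ConfigError("insulin_effect_mgdl_per_unit must be >=0")


def _draw_gaps_hours(params: GapParams, n: int, rng: np.random.Generator) -> np.ndarray:
    if params.kind == "uniform":
        return rng.uniform(params.low_hours, params.high_hours, n)
    weights = np.asarray(params.weights, dtype=float)
    comp = rng.choice(len(weights), size=n, p=weights)
    mu = np.asarray(params.mu_log, dtype=float)[comp]
    sigma = np.asarray(params.sigma_log, dtype=float)[comp]
    return np.exp(rng.normal(mu, sigma))


def _draw_reading_count(params: ReadingCountParams, rng: np.random.Generator) -> int:
    raw = rng.lognormal(math.log(params.median), params.sigma_log)
    return max(params.min_count, int(round(raw)))


def _clipped_normal_cv(mu: float, s: float, lo: float, hi: float) -> float:
    """CV of clip(N(mu, s), lo, hi) from censored-normal moments."""
    a, b = (lo - mu) / s, (hi - mu) / s
    sqrt2pi = math.sqrt(2.0 * math.pi)
    phi_a, phi_b = math.exp(-0.5 * a * a) / sqrt2pi, math.exp(-0.5 * b * b) / sqrt2pi
    cap_a = 0.5 * (1.0 + math.erf(a / math.sqrt(2.0)))
    cap_b = 0.5 * (1.0 + math.erf(b / math.sqrt(2.0)))
    p = cap_b - cap_a
    ex = lo * cap_a + hi * (1 - cap_b) + mu * p + s * (phi_a - phi_b)
    ex2 = (
        lo * lo * cap_a
        + hi * hi * (1 - cap_b)
        + mu * mu * p
        + 2 * mu * s * (phi_a - phi_b)
        + s * s * (p + a * phi_a - b * phi_b)
    )
    var = max(0.0, ex2 - ex * ex)
    return math.sqrt(var) / ex


def adjusted_sigma_for_cv(
    mean: float, cv_target: float, lo: float = GLUCOSE_FLOOR, hi: float = GLUCOSE_CEIL
) -> float:
    """Generating SD whose [lo, hi]-clipped marginal has CV ``cv_target``.

    Clipping shrinks dispersion, so the naive ``cv_target * mean`` under-
    delivers for high-variability admissions; bisect on the censored-normal
    CV, which is monotone in sigma.
    """
    if cv_target <= 0:
        return 0.0
    s_lo, s_hi = cv_target * mean, 6.0 * cv_target * mean
    if _clipped_normal_cv(mean, s_hi, lo, hi) < cv_target:
        return s_hi
    for _ in range(60):
        s_mid = 0.5 * (s_lo + s_hi)
        if _clipped_normal_cv(mean, s_mid, lo, hi) < cv_target:
            s_lo = s_mid
        else:
            s_hi = s_mid
    return 0.5 * (s_lo + s_hi)


def _ar1_series(
    mean: float, sd: float, rho: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Stationary Gaussian AR(1) around ``mean`` with marginal SD ``sd``."""
    eps = rng.normal(0.0, sd * math.sqrt(max(0.0, 1.0 - rho * rho)), n)
    eps[0] = rng.normal(0.0, sd)  # stationary initialisation
    dev = lfilter([1.0], [1.0, -rho], eps)
    return mean + dev


def _draw_covariates(
    admission: Admission, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    cov = {
        "admission_id": np.repeat(admission.admission_id, n),
        "t_minutes": np.array([o.t_minutes for o in admission.observations]),
        "npo": (rng.random(n) < 0.15).astype(int),
        "gfr": np.clip(rng.lognormal(math.log(75.0), 0.4, n), 5.0, 200.0),
        "hydrocortisone_equiv": np.where(
            rng.random(n) < 0.10, rng.lognormal(math.log(20.0), 0.6, n), 0.0
        ),
        "home_antihyperglycemic": np.repeat(int(rng.random() < 0.30), n),
    }
    # Insulin units on board, by class; mostly zero, heavier basal use in
    # insulin-treated T2D so the T2D-with-basal population is non-empty.
    p_basal = 0.55 if (admission.diabetes_dx == "T2D" and admission.home_insulin) else 0.15
    for cls in INSULIN_CLASSES:
        p = p_basal if cls == "insulin_basal" else 0.12
        units = np.where(rng.random(n) < p, rng.gamma(2.0, 5.0, n), 0.0)
        cov[cls] = np.round(units, 2)
    return pd.DataFrame(cov)


def generate_admission(
    config: CohortConfig,
    rng: np.random.Generator,
    admission_id: str = "adm000001",
) -> Admission:
    """Generate one admission from the configured distributions.

    Draw order is fixed, so identical ``rng`` states yield identical
    admissions.
    """
    n_obs = _draw_reading_count(config.reading_count_params, rng)
    gaps_h = _draw_gaps_hours(config.gap_mixture_params, n_obs - 1, rng)
    t_minutes = np.concatenate([[0.0], np.cumsum(gaps_h) * 60.0])

    labels = list(STRATUM_LABELS)
    weights = np.array([config.stratum_weights[s] for s in labels])
    stratum = labels[rng.choice(len(labels), p=weights / weights.sum())]
    cv_lo, cv_hi = config.stratum_cv_ranges[stratum]
    cv_target = float(rng.uniform(cv_lo, cv_hi))

    am = config.admission_mean_params
    mean_bg = float(
        np.clip(rng.lognormal(math.log(am.median), am.sigma_log), am.min_bg, am.max_bg)
    )
    sigma = adjusted_sigma_for_cv(mean_bg, cv_target)
    glucose = _ar1_series(mean_bg, sigma, config.ar_coefficient, n_obs, rng)
    glucose = np.clip(glucose, GLUCOSE_FLOOR, GLUCOSE_CEIL)

    source = np.where(rng.random(n_obs) < config.prop_serum, "serum", "POC")
    start_minutes = float(rng.integers(0, 1440))

    age = float(np.clip(rng.normal(65.0, 14.0), 18.0, 100.0))
    sex = "M" if rng.random() < 0.5064 else "F"
    race = RACE_CATEGORIES[rng.choice(len(RACE_CATEGORIES), p=RACE_PROBS)]
    diabetes_dx = DIABETES_CATEGORIES[rng.choice(len(DIABETES_CATEGORIES), p=DIABETES_PROBS)]
    home_insulin = bool(rng.random() < (0.8 if diabetes_dx == "T1D" else 0.20))

    admission = Admission(
        admission_id=admission_id,
        demographics=Demographics(age=age, sex=sex, race=race),
        diabetes_dx=diabetes_dx,
        home_insulin=home_insulin,
        observations=[],
        start_minutes=start_minutes,
        target_stratum=stratum,
        target_cv=cv_target,
    )

    if config.covariate_flags:
        admission.observations = [
            BGObservation(admission_id, float(t), float(g), str(s))
            for t, g, s in zip(t_minutes, glucose, source)
        ]
        cov = _draw_covariates(admission, n_obs, rng)
        if config.insulin_effect_mgdl_per_unit > 0:
            # Optional hook: rapid-acting insulin on board lowers glucose.
            effect = config.insulin_effect_mgdl_per_unit * cov["insulin_rapid"].to_numpy()
            glucose = np.clip(glucose - effect, GLUCOSE_FLOOR, GLUCOSE_CEIL)
            for obs, g in zip(admission.observations, glucose):
                obs.glucose = float(g)
        admission.covariate_series = cov
    else:
        admission.observations = [
            BGObservation(admission_id, float(t), float(g), str(s))
            for t, g, s in zip(t_minutes, glucose, source)
        ]

    admission.validate()
    return admission


def generate_cohort(config: CohortConfig) -> list[Admission]:
    """Generate ``config.n_admissions`` admissions, deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    width = max(6, len(str(config.n_admissions)))
    return [
        generate_admission(config, rng, admission_id=f"adm{i:0{width}d}")
        for i in range(1, config.n_admissions + 1)
    ]


# ---------------------------------------------------------------------------
# Delimited-text round trip
# ---------------------------------------------------------------------------

def cohort_to_frames(
    admissions: Sequence[Admission],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Flatten a cohort into (observations, admissions, covariates) tables."""
    obs_records = []
    adm_records = []
    cov_frames = []
    for adm in admissions:
        for o in adm.observations:
            obs_records.append((adm.admission_id, o.t_minutes, o.glucose, o.source))
        adm_records.append(
            {
                "admission_id": adm.admission_id,
                "start_minutes": adm.start_minutes,
                "age": adm.demographics.age,
                "sex": adm.demographics.sex,
                "race": adm.demographics.race,
                "diabetes_dx": adm.diabetes_dx,
                "home_insulin": int(adm.home_insulin),
                "target_stratum": adm.target_stratum or "",
                "target_cv": "" if adm.target_cv is None else adm.target_cv,
            }
        )
        if adm.covariate_series is not None:
            cov_frames.append(adm.covariate_series)
    obs = pd.DataFrame(obs_records, columns=list(OBSERVATION_COLUMNS))
    adm_df = pd.DataFrame(
        adm_records,
        columns=[
            "admission_id",
            "start_minutes",
            "age",
            "sex",
            "race",
            "diabetes_dx",
            "home_insulin",
            "target_stratum",
            "target_cv",
        ],
    )
    cov = pd.concat(cov_frames, ignore_index=True) if cov_frames else None
    return obs, adm_df, cov


def write_cohort(admissions: Sequence[Admission], path: str | os.PathLike) -> None:
    """Write a cohort to ``path`` (a directory) as plain CSV files."""
    os.makedirs(path, exist_ok=True)
    obs, adm_df, cov = cohort_to_frames(admissions)
    obs.to_csv(os.path.join(path, "observations.csv"), index=False)
    adm_df.to_csv(os.path.join(path, "admissions.csv"), index=False)
    if cov is not None:
        cov.to_csv(os.path.join(path, "covariates.csv"), index=False)


def read_cohort(path: str | os.PathLike) -> list[Admission]:
    """Read a cohort written by :func:`write_cohort`; validates on load."""
    obs_path = os.path.join(path, "observations.csv")
    adm_path = os.path.join(path, "admissions.csv")
    try:
        obs = pd.read_csv(obs_path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - depends on pandas message
        raise ParseError(f"cannot parse {obs_path}: {exc}") from exc
    missing = set(OBSERVATION_COLUMNS) - set(obs.columns)
    if missing:
        raise ParseError(f"{obs_path}: missing columns {sorted(missing)}")

    bad = obs.index[~(obs["glucose_mgdl"] > 0)]
    if len(bad):
        row = int(bad[0]) + 2  # 1-based, counting the header line
        raise ValidationError(f"{obs_path}: non-positive glucose at line {row}")

    adm_meta: dict[str, dict] = {}
    if os.path.exists(adm_path):
        adm_df = pd.read_csv(adm_path, float_precision="round_trip")
        adm_meta = {str(r["admission_id"]): r for _, r in adm_df.iterrows()}

    cov_path = os.path.join(path, "covariates.csv")
    cov_groups: dict[str, pd.DataFrame] = {}
    if os.path.exists(cov_path):
        cov = pd.read_csv(cov_path, float_precision="round_trip")
        cov_groups = {str(k): g.reset_index(drop=True) for k, g in cov.groupby("admission_id", sort=False)}

    admissions: list[Admission] = []
    for adm_id, group in obs.groupby("admission_id", sort=False):
        adm_id = str(adm_id)
        t = group["t_minutes"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"{obs_path}: admission {adm_id} timestamps not strictly increasing"
            )
        observations = [
            BGObservation(adm_id, float(r.t_minutes), float(r.glucose_mgdl), str(r.source))
            for r in group.itertuples(index=False)
        ]
        meta = adm_meta.get(adm_id)
        if meta is not None:
            target_cv = meta.get("target_cv")
            admission = Admission(
                admission_id=adm_id,
                demographics=Demographics(
                    age=float(meta["age"]), sex=str(meta["sex"]), race=str(meta["race"])
                ),
                diabetes_dx=str(meta["diabetes_dx"]),
                home_insulin=bool(int(meta["home_insulin"])),
                observations=observations,
                start_minutes=float(meta["start_minutes"]),
                target_stratum=(str(meta["target_stratum"]) or None)
                if isinstance(meta["target_stratum"], str)
                else None,
                target_cv=None if pd.isna(target_cv) or target_cv == "" else float(target_cv),
            )
        else:
            admission = Admission(
                admission_id=adm_id,
                demographics=Demographics(age=float("nan"), sex="", race=""),
                diabetes_dx="none",
                home_insulin=False,
                observations=observations,
            )
        if adm_id in cov_groups:
            admission.covariate_series = cov_groups[adm_id]
        admissions.append(admission)
    return admissions


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    """Return a copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
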
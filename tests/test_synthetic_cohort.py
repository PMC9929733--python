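import dataclasses
import filecmp

import numpy as np
import pandas as pd
import pytest

from nextbg.errors import ConfigError, ValidationError
from nextbg.synthetic_cohort import (
    AdmissionMeanParams,
    CohortConfig,
    GapParams,
    ReadingCountParams,
    cohort_to_frames,
    generate_admission,
    generate_cohort,
    read_cohort,
    write_cohort,
)


def realized_cv_24h_mid(admission):
    """Sample CV of the 24 h window centred on mid-admission."""
    t, v = admission.times, admission.glucose
    mid = t[len(t) // 2]
    w = v[(t >= mid - 1440.0) & (t <= mid)]
    if len(w) < 2:
        return np.nan
    return np.std(w, ddof=1) / np.mean(w)


class TestConfigValidation:
    def test_bad_ar_coefficient_names_field(self):
        with pytest.raises(ConfigError, match="ar_coefficient"):
            CohortConfig(ar_coefficient=1.0).validate()

    def test_bad_stratum_weights_sum(self):
        cfg = CohortConfig(stratum_weights={"low": 0.5, "medium": 0.5, "high": 0.5, "very_high": 0.5})
        with pytest.raises(ConfigError, match="stratum_weights"):
            cfg.validate()

    def test_bad_gap_params(self):
        cfg = CohortConfig(gap_mixture_params=GapParams(kind="uniform", low_hours=5, high_hours=2))
        with pytest.raises(ConfigError, match="gap_mixture_params"):
            cfg.validate()

    def test_nonpositive_scale(self):
        cfg = CohortConfig(reading_count_params=ReadingCountParams(median=-1))
        with pytest.raises(ConfigError, match="reading_count_params"):
            cfg.validate()

    def test_negative_admissions(self):
        with pytest.raises(ConfigError, match="n_admissions"):
            CohortConfig(n_admissions=0).validate()


class TestGeneration:
    def test_seed_reproducibility_byte_identical(self, tmp_path):
        cfg = CohortConfig(n_admissions=20, seed=42, covariate_flags=True)
        write_cohort(generate_cohort(cfg), tmp_path / "a")
        write_cohort(generate_cohort(cfg), tmp_path / "b")
        for name in ("observations.csv", "admissions.csv", "covariates.csv"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)

    def test_different_seeds_differ(self):
        a = generate_cohort(CohortConfig(n_admissions=5, seed=1))
        b = generate_cohort(CohortConfig(n_admissions=5, seed=2))
        assert not np.array_equal(a[0].glucose, b[0].glucose)

    def test_admission_invariants(self):
        for adm in generate_cohort(CohortConfig(n_admissions=50, seed=9)):
            adm.validate()  # sorted, >=4 obs, positive glucose
            assert np.all(adm.glucose >= 40.0) and np.all(adm.glucose <= 600.0)
            assert np.all(np.diff(adm.times) > 0)

    def test_covariate_series_aligned(self):
        cfg = CohortConfig(n_admissions=10, seed=5, covariate_flags=True)
        for adm in generate_cohort(cfg):
            assert adm.covariate_series is not None
            assert len(adm.covariate_series) == len(adm.observations)

    def test_ar_zero_uncorrelated(self, rng):
        cfg = CohortConfig(
            seed=0,
            ar_coefficient=0.0,
            reading_count_params=ReadingCountParams(median=5000, sigma_log=0.0),
            admission_mean_params=AdmissionMeanParams(sigma_log=0.0),
        )
        adm = generate_admission(cfg, np.random.default_rng(7))
        dev = adm.glucose - adm.glucose.mean()
        rho_hat = np.corrcoef(dev[:-1], dev[1:])[0, 1]
        assert abs(rho_hat) < 0.05

    def test_ar_09_recovered_500_readings(self):
        cfg = CohortConfig(
            seed=0,
            ar_coefficient=0.9,
            reading_count_params=ReadingCountParams(median=500, sigma_log=0.0),
            admission_mean_params=AdmissionMeanParams(sigma_log=0.0),
            stratum_weights={"low": 0, "medium": 1.0, "high": 0, "very_high": 0},
        )
        adm = generate_admission(cfg, np.random.default_rng(11))
        dev = adm.glucose - adm.glucose.mean()
        rho_hat = np.corrcoef(dev[:-1], dev[1:])[0, 1]
        assert abs(rho_hat - 0.9) < 0.1

    def test_ar_recovery_within_005_at_5000(self):
        cfg = CohortConfig(
            seed=0,
            ar_coefficient=0.7,
            reading_count_params=ReadingCountParams(median=5000, sigma_log=0.0),
            admission_mean_params=AdmissionMeanParams(sigma_log=0.0),
            stratum_weights={"low": 0, "medium": 1.0, "high": 0, "very_high": 0},
        )
        adm = generate_admission(cfg, np.random.default_rng(3))
        dev = adm.glucose - adm.glucose.mean()
        rho_hat = np.corrcoef(dev[:-1], dev[1:])[0, 1]
        assert abs(rho_hat - 0.7) < 0.05

    def test_admission_mean_concentrated_at_141(self):
        cfg = CohortConfig(
            n_admissions=200,
            seed=2,
            admission_mean_params=AdmissionMeanParams(sigma_log=0.0),
            stratum_weights={"low": 1.0, "medium": 0, "high": 0, "very_high": 0},
        )
        means = [adm.glucose.mean() for adm in generate_cohort(cfg)]
        assert abs(np.median(means) - 141.0) < 10.0


@pytest.fixture(scope="module")
def big_cohort():
    return generate_cohort(CohortConfig(n_admissions=1000, seed=17))


class TestDistributionTargets:

    def test_reading_count_median(self, big_cohort):
        counts = [len(a.observations) for a in big_cohort]
        assert 10 <= np.median(counts) <= 14

    def test_gap_percentiles_within_20pct(self, big_cohort):
        gaps_h = np.concatenate([np.diff(a.times) for a in big_cohort]) / 60.0
        targets = {5: 0.58, 25: 2.48, 50: 3.88, 75: 4.88, 95: 8.23}
        for pct, target in targets.items():
            emp = np.percentile(gaps_h, pct)
            assert abs(emp - target) / target < 0.20, (pct, emp, target)

    def test_admission_mean_distribution(self, big_cohort):
        means = np.array([a.glucose.mean() for a in big_cohort])
        assert 130 < np.median(means) < 152
        q25, q75 = np.percentile(means, [25, 75])
        assert 105 < q25 < 130 and 160 < q75 < 200


class TestStratumControl:
    dense = dict(
        reading_count_params=ReadingCountParams(median=60, sigma_log=0.1),
        gap_mixture_params=GapParams(kind="uniform", low_hours=0.8, high_hours=1.2),
        ar_coefficient=0.0,
    )

    def test_low_stratum_hit_rate_90pct(self):
        cfg = CohortConfig(
            n_admissions=200, seed=4,
            stratum_weights={"low": 1.0, "medium": 0, "high": 0, "very_high": 0},
            **self.dense,
        )
        cvs = np.array([realized_cv_24h_mid(a) for a in generate_cohort(cfg)])
        assert np.mean(cvs <= 0.15) >= 0.90

    @pytest.mark.parametrize(
        "stratum,lo,hi",
        [("low", 0.0, 0.15), ("medium", 0.15, 0.30), ("high", 0.30, 0.45), ("very_high", 0.45, np.inf)],
    )
    def test_each_stratum_hit_rate_80pct(self, stratum, lo, hi):
        weights = {s: 0.0 for s in ("low", "medium", "high", "very_high")}
        weights[stratum] = 1.0
        cfg = CohortConfig(n_admissions=150, seed=8, stratum_weights=weights, **self.dense)
        cvs = np.array([realized_cv_24h_mid(a) for a in generate_cohort(cfg)])
        hit = np.mean((cvs > lo) & (cvs <= hi)) if np.isfinite(hi) else np.mean(cvs > lo)
        assert hit >= 0.80, (stratum, hit)


class TestRoundTrip:
    def test_empty_cohort(self, tmp_path):
        write_cohort([], tmp_path / "c")
        assert read_cohort(tmp_path / "c") == []

    def test_three_admission_round_trip_field_identical(self, tmp_path):
        cohort = generate_cohort(CohortConfig(n_admissions=3, seed=13, covariate_flags=True))
        write_cohort(cohort, tmp_path / "c")
        back = read_cohort(tmp_path / "c")
        assert len(back) == 3
        for orig, rt in zip(cohort, back):
            assert rt.admission_id == orig.admission_id
            assert rt.start_minutes == orig.start_minutes
            assert rt.diabetes_dx == orig.diabetes_dx
            assert rt.home_insulin == orig.home_insulin
            assert rt.demographics == orig.demographics
            assert rt.target_stratum == orig.target_stratum
            assert rt.target_cv == pytest.approx(orig.target_cv, abs=0)
            assert [o.t_minutes for o in rt.observations] == [o.t_minutes for o in orig.observations]
            assert [o.glucose for o in rt.observations] == [o.glucose for o in orig.observations]
            assert [o.source for o in rt.observations] == [o.source for o in orig.observations]
            pd.testing.assert_frame_equal(rt.covariate_series, orig.covariate_series)

    def test_negative_glucose_names_row(self, tmp_path):
        cohort = generate_cohort(CohortConfig(n_admissions=1, seed=1))
        write_cohort(cohort, tmp_path / "c")
        path = tmp_path / "c" / "observations.csv"
        lines = path.read_text().splitlines()
        parts = lines[3].split(",")
        parts[2] = "-5.0"
        lines[3] = ",".join(parts)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValidationError, match="line 4"):
            read_cohort(tmp_path / "c")

    def test_unsorted_times_rejected(self, tmp_path):
        cohort = generate_cohort(CohortConfig(n_admissions=1, seed=1))
        write_cohort(cohort, tmp_path / "c")
        path = tmp_path / "c" / "observations.csv"
        lines = path.read_text().splitlines()
        lines[1], lines[2] = lines[2], lines[1]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValidationError, match="not strictly increasing"):
            read_cohort(tmp_path / "c")


def test_insulin_effect_hook_lowers_glucose():
    base = CohortConfig(n_admissions=40, seed=21, covariate_flags=True)
    hooked = dataclasses.replace(base, insulin_effect_mgdl_per_unit=3.0)
    g_base = np.concatenate([a.glucose for a in generate_cohort(base)])
    g_hook = np.concatenate([a.glucose for a in generate_cohort(hooked)])
    assert g_hook.mean() < g_base.mean()
    assert np.all(g_hook <= g_base + 1e-9)
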
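import numpy as np
import pytest

from nextbg.errors import ConfigError, ContractError
from nextbg.preprocess import preprocess_admission
from nextbg.synthetic_cohort import BGObservation
from nextbg.ts_predictors import (
    LABEL_INDEX,
    LABEL_PREVIOUS,
    LABEL_RECURSIVE,
    PREDICTION_FLOOR,
    PredictorConfig,
    build_prediction_rows,
    ma_label,
    moving_average_predict,
    recursive_regression_predict,
    rolling_regression_predict,
    rr_label,
    sample_and_hold_predict,
)

from conftest import make_admission, random_admission


def series(times, values):
    return [BGObservation("a", float(t), float(v)) for t, v in zip(times, values)]


# --- independent oracles -----------------------------------------------------

def brute_ma(times, values, i, window_hours):
    """Explicit mean over the closed trailing window."""
    sel = [
        v
        for t, v in zip(times[: i + 1], values[: i + 1])
        if times[i] - window_hours * 60.0 <= t <= times[i]
    ]
    return sum(sel) / len(sel) if sel else values[i]


def brute_rr(values, i, n):
    """Explicit normal-equations OLS on positions 1..m, evaluated at m+1."""
    m = min(n, i + 1)
    if m < 2:
        return values[i]
    y = np.asarray(values[i - m + 1 : i + 1], dtype=float)
    x = np.arange(1, m + 1, dtype=float)
    A = np.array([[m, x.sum()], [x.sum(), (x * x).sum()]])
    b = np.array([y.sum(), (x * y).sum()])
    intercept, slope = np.linalg.solve(A, b)
    return max(PREDICTION_FLOOR, intercept + slope * (m + 1))


# --- scalar contract examples ------------------------------------------------

class TestMovingAverage:
    def test_two_reading_mean(self):
        hist = series([0.0, 180.0], [100.0, 120.0])
        assert moving_average_predict(hist, hist[-1], 4.0) == pytest.approx(110.0)

    def test_lone_reading_falls_back_to_index(self):
        hist = series([0.0, 600.0], [90.0, 130.0])
        assert moving_average_predict(hist, hist[-1], 0.5) == 130.0

    def test_constant_series_fixpoint(self):
        hist = series([0, 100, 200, 300], [141.0] * 4)
        for w in PredictorConfig().ma_windows_hours:
            assert moving_average_predict(hist, hist[-1], w) == pytest.approx(141.0)

    def test_empty_history_contract(self):
        with pytest.raises(ContractError):
            moving_average_predict([], BGObservation("a", 0, 100), 1.0)

    def test_window_is_closed_at_boundary(self):
        hist = series([0.0, 240.0], [100.0, 120.0])
        # reading exactly window-length away is included
        assert moving_average_predict(hist, hist[-1], 4.0) == pytest.approx(110.0)


class TestRollingRegression:
    def test_three_point_line(self):
        hist = series([0, 60, 120], [100.0, 110.0, 120.0])
        assert rolling_regression_predict(hist, hist[-1], 3) == pytest.approx(130.0)

    def test_constant_series(self):
        hist = series([0, 60, 120, 180], [95.0] * 4)
        for n in (2, 3, 4, 10):
            assert rolling_regression_predict(hist, hist[-1], n) == pytest.approx(95.0)

    def test_two_point_extrapolation(self):
        hist = series([0, 60], [100.0, 90.0])
        assert rolling_regression_predict(hist, hist[-1], 2) == pytest.approx(80.0)

    def test_order_below_2_rejected(self):
        hist = series([0, 60], [100.0, 90.0])
        with pytest.raises(ContractError):
            rolling_regression_predict(hist, hist[-1], 1)

    def test_floor_applied_to_negative_extrapolation(self):
        hist = series([0, 60, 120], [200.0, 100.0, 45.0])
        pred = rolling_regression_predict(hist, hist[-1], 3)
        assert pred >= PREDICTION_FLOOR


class TestRecursive:
    def test_equals_rr3_on_three_readings(self):
        hist = series([0, 60, 120], [100.0, 104.0, 111.0])
        assert recursive_regression_predict(hist, hist[-1]) == pytest.approx(
            rolling_regression_predict(hist, hist[-1], 3)
        )

    def test_equals_rr40_on_forty_readings(self, rng):
        v = rng.uniform(60, 300, 40)
        hist = series(np.arange(40) * 200.0, v)
        assert recursive_regression_predict(hist, hist[-1]) == pytest.approx(
            rolling_regression_predict(hist, hist[-1], 40), rel=1e-12
        )

    def test_equals_rr500_when_under_500_readings(self, rng):
        # mirrors the published table where the 500-observation window row
        # and the recursive row carry identical values
        for _ in range(5):
            n = int(rng.integers(4, 60))
            hist = series(np.arange(n) * 200.0, rng.uniform(50, 400, n))
            assert recursive_regression_predict(hist, hist[-1]) == pytest.approx(
                rolling_regression_predict(hist, hist[-1], 500), rel=1e-12
            )


class TestSampleAndHold:
    @pytest.mark.parametrize("value", [141.0, 54.0])
    def test_identity(self, value):
        assert sample_and_hold_predict(BGObservation("a", 0, value)) == value

    def test_equals_30min_ma_when_window_empty(self):
        hist = series([0.0, 300.0], [90.0, 130.0])
        idx = hist[-1]
        assert moving_average_predict(hist, idx, 0.5) == sample_and_hold_predict(idx)


class TestBuildRows:
    def test_shape_24_predictors(self):
        adm = make_admission(np.arange(5) * 240.0, [100, 110, 105, 120, 115])
        retained, pairs, _ = preprocess_admission(adm)
        rows = build_prediction_rows(retained, pairs)
        assert len(rows) == 4
        labels = PredictorConfig().labels
        assert len(labels) == 24
        assert all(l in rows.columns for l in labels)

    def test_first_row_prev_bg_falls_back_to_index(self):
        adm = make_admission(np.arange(5) * 240.0, [100, 110, 105, 120, 115])
        retained, pairs, _ = preprocess_admission(adm)
        rows = build_prediction_rows(retained, pairs)
        assert rows[LABEL_PREVIOUS].iloc[0] == rows[LABEL_INDEX].iloc[0]
        assert rows[LABEL_PREVIOUS].iloc[1] == rows[LABEL_INDEX].iloc[0]

    def test_empty_pairs(self):
        rows = build_prediction_rows([], [])
        assert len(rows) == 0
        assert LABEL_RECURSIVE in rows.columns

    def test_target_gap_invariant(self, rng):
        adm = random_admission(rng)
        retained, pairs, _ = preprocess_admission(adm)
        rows = build_prediction_rows(retained, pairs)
        if len(rows):
            assert ((rows["target_gap_hours"] > 0) & (rows["target_gap_hours"] <= 10)).all()
            assert np.isfinite(rows[PredictorConfig().labels].to_numpy(float)).all()
            assert (rows[PredictorConfig().labels].to_numpy(float) > 0).all()

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            PredictorConfig(ma_windows_hours=(2.0, 1.0)).validate()
        with pytest.raises(ConfigError):
            PredictorConfig(rr_orders=(1, 3)).validate()


class TestOracleEquivalence:
    """Vectorized battery vs explicit brute-force recomputation."""

    def test_random_admissions_match_brute_force(self, rng):
        config = PredictorConfig()
        for k in range(25):
            adm = random_admission(rng, n_min=4, n_max=60, admission_id=f"adm{k}")
            retained, pairs, _ = preprocess_admission(adm)
            rows = build_prediction_rows(retained, pairs, config)
            t = [o.t_minutes for o in retained]
            v = [o.glucose for o in retained]
            for row_i, p in enumerate(pairs):
                i = p.index_pos
                for w in config.ma_windows_hours:
                    expected = brute_ma(t, v, i, w)
                    assert rows[ma_label(w)].iloc[row_i] == pytest.approx(expected, rel=1e-9)
                for n in config.rr_orders:
                    expected = brute_rr(v, i, n)
                    assert rows[rr_label(n)].iloc[row_i] == pytest.approx(expected, rel=1e-9)
                assert rows[LABEL_RECURSIVE].iloc[row_i] == pytest.approx(
                    brute_rr(v, i, i + 1), rel=1e-9
                )

    def test_nesting_monotonicity(self, rng):
        # enlarging the MA window never shrinks the averaged set: the
        # window-w mean over k readings and window-w' (w'>w) mean over k'
        # readings satisfy k' >= k
        adm = random_admission(rng, n_min=10, n_max=40)
        retained, pairs, _ = preprocess_admission(adm)
        t = np.array([o.t_minutes for o in retained])
        for p in pairs:
            counts = [
                np.sum((t >= t[p.index_pos] - w * 60.0) & (t <= t[p.index_pos]))
                for w in PredictorConfig().ma_windows_hours
            ]
            assert counts == sorted(counts)

    def test_constant_admission_all_predictors_constant(self):
        adm = make_admission(np.arange(8) * 240.0, np.full(8, 141.0))
        retained, pairs, _ = preprocess_admission(adm)
        rows = build_prediction_rows(retained, pairs)
        values = rows[PredictorConfig().labels].to_numpy(dtype=float)
        assert np.allclose(values, 141.0)
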
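"""Windowed summaries, static features and the automated functional catalog."""

import numpy as np
import pandas as pd
import pytest

from vacpred import (
    MissingnessPolicy,
    PredictionSample,
    SimConfig,
    WindowSpec,
    automated_features,
    generate_cohort,
    manual_features,
    static_features,
)
from vacpred.features import PREDICTIVE_VARIABLES, extract_matrix, subwindow_blocks
from vacpred.preprocess import compute_training_means, preprocess_window
from vacpred.records import HOUR


class TestPartition:
    def test_twelve_hour_blocks_cover_35h_backward(self):
        blocks = subwindow_blocks(35, 12)
        assert blocks == [(23, 35), (11, 23), (0, 11)]  # earliest truncated to 11 h

    def test_three_hour_blocks(self):
        blocks = subwindow_blocks(35, 3)
        assert len(blocks) == 12
        assert blocks[0] == (32, 35) and blocks[-1] == (0, 2)
        covered = sorted(i for lo, hi in blocks for i in range(lo, hi))
        assert covered == list(range(35))


def _window(values_by_var, counts_by_var=None):
    idx = pd.Timestamp("2021-01-01") + pd.to_timedelta(np.arange(35), unit="h")
    hourly = pd.DataFrame(values_by_var, index=idx)
    if counts_by_var is None:
        counts_by_var = {v: np.ones(35) for v in values_by_var}
    counts = pd.DataFrame(counts_by_var, index=idx)
    return hourly, counts


class TestManual:
    def test_constant_series_summaries(self):
        hourly, counts = _window({"HR": np.full(35, 7.0)})
        f = manual_features(hourly, counts)
        for i in range(3):
            assert f[f"HR__w12_{i}__mean"] == 7.0
            assert f[f"HR__w12_{i}__variance"] == 0.0
            assert f[f"HR__w12_{i}__min"] == 7.0
            assert f[f"HR__w12_{i}__max"] == 7.0
            assert f[f"HR__w12_{i}__range"] == 0.0

    def test_small_subwindow_arithmetic(self):
        x = np.zeros(35)
        x[32:35] = [1.0, 3.0, 5.0]  # most recent 3 h block
        hourly, counts = _window({"HR": x})
        f = manual_features(hourly, counts)
        assert f["HR__w3_0__mean"] == 3.0
        assert f["HR__w3_0__range"] == 4.0

    def test_observation_count_of_fully_charted_block(self):
        hourly, counts = _window({"HR": np.arange(35.0)})
        f = manual_features(hourly, counts)
        assert f["HR__w12_0__count"] == 12.0
        assert f["HR__w12_2__count"] == 11.0  # truncated earliest block
        assert f["HR__w3_11__count"] == 2.0

    def test_range_equals_max_minus_min_everywhere(self):
        rng = np.random.default_rng(3)
        hourly, counts = _window({"HR": rng.normal(80, 10, 35),
                                  "RR": rng.normal(18, 4, 35)})
        f = manual_features(hourly, counts)
        for name in f.index:
            if name.endswith("__range"):
                stem = name[: -len("__range")]
                assert f[name] == pytest.approx(f[f"{stem}__max"] - f[f"{stem}__min"])

    def test_feature_count_formula(self):
        rng = np.random.default_rng(0)
        cols = {v: rng.normal(size=35) for v in ("HR", "RR", "SBP")}
        hourly, counts = _window(cols)
        f = manual_features(hourly, counts)
        assert len(f) == 3 * 6 * (3 + 12)


class TestStatic:
    def _record_and_sample(self):
        cfg = SimConfig(n_patients=2, seed=4, missing_rate=0, outlier_rate=0,
                        vent_duration_hours=(120, 120))
        records, _ = generate_cohort(cfg)
        rec = records[0]
        sample = PredictionSample(rec.patient_id, rec.vent_start + 60 * HOUR, 0)
        return rec, sample

    def test_shock_index_is_mean_hr_over_mean_sbp(self):
        rec, sample = self._record_and_sample()
        hourly, counts = _window({"HR": np.full(35, 90.0),
                                  "SBP": np.full(35, 120.0)})
        f = static_features(rec, sample, hourly, counts)
        assert f["static__shock_index"] == pytest.approx(0.75)

    def test_time_since_admission_in_hours(self):
        rec, sample = self._record_and_sample()
        hourly, counts = _window({"HR": np.full(35, 90.0),
                                  "SBP": np.full(35, 120.0)})
        f = static_features(rec, sample, hourly, counts)
        expected = (sample.decision_time - rec.icu_admit_time) / HOUR
        assert f["static__hours_since_admission"] == pytest.approx(expected)

    def test_measurement_count_totals_raw_observations(self):
        rec, sample = self._record_and_sample()
        counts = {"HR": np.full(35, 2.0), "SBP": np.ones(35)}
        hourly, cdf = _window({"HR": np.full(35, 90.0),
                               "SBP": np.full(35, 120.0)}, counts)
        f = static_features(rec, sample, hourly, cdf)
        assert f["static__measurement_count"] == 35 * 3


class TestAutomated:
    def test_constant_series_has_zero_variance_and_no_off_dc_power(self):
        f = automated_features({"HR": np.full(64, 5.0)})
        assert f["HR__auto__variance"] == 0.0
        for k in range(1, 6):
            assert f[f"HR__auto__fft_abs__coeff_{k}"] == 0.0
        assert f["HR__auto__fft_abs__coeff_0"] == pytest.approx(5.0)

    def test_pure_sine_dominates_its_fft_coefficient(self):
        n = 64
        x = np.sin(2 * np.pi * 3 * np.arange(n) / n)
        # independent oracle: direct DFT
        dft = np.abs(np.array([np.sum(x * np.exp(-2j * np.pi * k *
                                                 np.arange(n) / n))
                               for k in range(6)])) / n
        assert np.argmax(dft) == 3
        f = automated_features({"HR": x})
        coeffs = [f[f"HR__auto__fft_abs__coeff_{k}"] for k in range(6)]
        assert np.argmax(coeffs) == 3
        assert coeffs[3] == pytest.approx(dft[3], rel=1e-9)

    def test_identical_windows_give_identical_vectors(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        a = automated_features({"HR": x})
        b = automated_features({"HR": x.copy()})
        pd.testing.assert_series_equal(a, b)

    def test_time_reversal_moves_trend_but_not_order_statistics(self):
        rng = np.random.default_rng(2)
        x = np.cumsum(rng.normal(size=50)) + np.linspace(0, 5, 50)
        f = automated_features({"HR": x})
        r = automated_features({"HR": x[::-1].copy()})
        assert f["HR__auto__linear_trend__slope"] == pytest.approx(
            -r["HR__auto__linear_trend__slope"]
        )
        assert f["HR__auto__mean_change"] == pytest.approx(
            -r["HR__auto__mean_change"]
        )
        for stat in ("mean", "minimum", "maximum", "range"):
            assert f[f"HR__auto__{stat}"] == pytest.approx(r[f"HR__auto__{stat}"])

    def test_degenerate_inputs_use_sentinel_not_nan(self):
        f = automated_features({"HR": np.full(30, 1.0)})
        assert not f.isna().any()
        assert f["HR__auto__autocorrelation__lag_1"] == 0.0
        assert f["HR__auto__skewness"] == 0.0


class TestMatrix:
    def test_matrix_shape_and_determinism(self, clean_cohort):
        records, truth = clean_cohort
        from vacpred import build_samples

        samples = build_samples(records, truth.positives(), seed=0)[:6]
        policy = MissingnessPolicy(
            training_means=compute_training_means(records, PREDICTIVE_VARIABLES)
        )
        X1, y1, info = extract_matrix(records, samples, policy)
        X2, y2, _ = extract_matrix(records, samples, policy)
        pd.testing.assert_frame_equal(X1, X2)
        V = len(PREDICTIVE_VARIABLES)
        assert X1.shape == (6, V * 6 * 15 + 6)
        assert not X1.isna().any().any()
        assert info["provenance"]["features"]["static__age"]["kind"] == "static"

    def test_highfreq_channel_flows_through_auto_mode(self):
        cfg = SimConfig(n_patients=2, seed=6, missing_rate=0, outlier_rate=0,
                        vent_duration_hours=(120, 120), hf_channels=("HR",))
        records, _ = generate_cohort(cfg)
        rec = records[0]
        sample = PredictionSample(rec.patient_id, rec.vent_start + 60 * HOUR, 0)
        policy = MissingnessPolicy(
            training_means=compute_training_means(records, ("HR", "SBP"))
        )
        hourly, counts, hf = preprocess_window(
            rec, sample.window_start, 35, ("HR", "SBP"), policy
        )
        assert "HR" in hf
        assert len(hf["HR"]) == 35 * 12  # 5-min bins
        assert hf["HR"].notna().all()
        X, y, _ = extract_matrix(records, [sample], policy, ("HR", "SBP"),
                                 mode="auto")
        assert X.shape[0] == 1 and not X.isna().any().any()
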
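"""Heart-rate extraction, error metrics and the clinical utilities."""

import numpy as np
import pytest

from axisppg.metrics import (HRSeries, VitalsRecord, classify_band,
                             estimate_hr_series, hr_mae, hr_rmse,
                             pearson_r_concat, ews_score)
from axisppg.synthetic import synthesize_ppg


class TestEstimateHR:
    def test_pure_sinusoid_recovered_within_a_bin(self):
        fs, f = 30.0, 1.5
        t = np.arange(int(60 * fs)) / fs
        series = estimate_hr_series(np.sin(2 * np.pi * f * t), fs)
        assert len(series) == 51  # floor((60-10)/1)+1
        assert np.all(np.abs(series.bpm - 90.0) < 1.0)

    @pytest.mark.parametrize("bpm", [50, 70, 90, 120])
    def test_noise_free_synthetic_ppg_recovered(self, bpm):
        ppg = synthesize_ppg(bpm, 0.0, 30, 30, seed=0)
        series = estimate_hr_series(ppg.samples, 30)
        assert np.all(np.abs(series.bpm - bpm) < 1.0)

    def test_constant_signal_yields_nan_windows(self):
        series = estimate_hr_series(np.ones(600), 30.0)
        assert np.isnan(series.bpm).all()

    def test_short_signal_gives_empty_series(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="axisppg.metrics"):
            series = estimate_hr_series(np.ones(30), 30.0)
        assert len(series) == 0 and caplog.records


class TestErrorMetrics:
    def test_identical_series_score_zero(self, rng):
        x = rng.uniform(50, 120, 20)
        assert hr_mae(x, x) == 0.0
        assert hr_rmse(x, x) == 0.0

    def test_constant_offset_reproduced_exactly(self, rng):
        x = rng.uniform(50, 120, 20)
        assert abs(hr_mae(x + 3.0, x) - 3.0) < 1e-12
        assert abs(hr_rmse(x - 4.0, x) - 4.0) < 1e-12

    def test_matches_elementwise_oracle_and_jensen(self, rng):
        a, b = rng.uniform(40, 180, 20), rng.uniform(40, 180, 20)
        assert abs(hr_mae(a, b) - np.abs(a - b).mean()) < 1e-12
        assert abs(hr_rmse(a, b) - np.sqrt(((a - b) ** 2).mean())) < 1e-12
        assert hr_rmse(a, b) >= hr_mae(a, b)

    def test_nan_pairs_dropped(self):
        a = np.array([60.0, np.nan, 80.0])
        b = np.array([61.0, 70.0, np.nan])
        assert hr_mae(a, b) == 1.0
        with pytest.raises(ValueError):
            hr_mae(np.array([np.nan]), np.array([1.0]))


class TestPearsonConcat:
    def test_perfect_and_anti_correlation(self, rng):
        pairs = [(rng.standard_normal(50),) * 2 for _ in range(3)]
        assert abs(pearson_r_concat([(g, g) for g, _ in pairs]) - 1.0) < 1e-12
        assert abs(pearson_r_concat([(g, -g) for g, _ in pairs]) + 1.0) < 1e-12

    def test_concatenation_breaks_per_person_perfection(self, rng):
        """Two persons, each r=1 but at different affine scales: the
        concatenated correlation is computed over the joined signal and is
        generally lower than 1."""
        g1, g2 = rng.standard_normal(50), rng.standard_normal(50)
        pairs = [(g1, 5.0 * g1 + 10.0), (g2, 0.2 * g2 - 3.0)]
        concat_g = np.concatenate([g1, g2])
        concat_i = np.concatenate([5.0 * g1 + 10.0, 0.2 * g2 - 3.0])
        expected = np.corrcoef(concat_g, concat_i)[0, 1]
        got = pearson_r_concat(pairs)
        assert abs(got - expected) < 1e-12
        assert got < 0.999

    def test_constant_concatenation_rejected(self):
        with pytest.raises(ValueError):
            pearson_r_concat([(np.ones(10), np.arange(10.0))])


class TestEWS:
    @pytest.mark.parametrize("hr,score", [
        (35, 2), (40, 1), (50, 1), (51, 0), (75, 0), (100, 0),
        (101, 1), (110, 1), (111, 2), (130, 2), (131, 3), (135, 3)])
    def test_heart_rate_bands(self, hr, score):
        total, sub = ews_score(VitalsRecord(hr, 120, 12, 37.0, "alert"))
        assert sub["heart_rate"] == score

    @pytest.mark.parametrize("sbp,score", [
        (65, 3), (70, 2), (80, 2), (81, 1), (100, 1), (101, 0),
        (160, 0), (161, 1), (200, 1), (201, 2)])
    def test_systolic_bands(self, sbp, score):
        _, sub = ews_score(VitalsRecord(75, sbp, 12, 37.0, "alert"))
        assert sub["systolic_bp"] == score

    @pytest.mark.parametrize("rr,score", [
        (8, 2), (9, 0), (14, 0), (15, 1), (20, 1), (21, 2), (30, 2), (31, 3)])
    def test_respiratory_bands(self, rr, score):
        _, sub = ews_score(VitalsRecord(75, 120, rr, 37.0, "alert"))
        assert sub["respiratory_rate"] == score

    @pytest.mark.parametrize("temp,score", [
        (34.5, 2), (35.0, 1), (36.0, 1), (36.1, 0), (37.5, 0), (37.6, 1)])
    def test_temperature_bands(self, temp, score):
        _, sub = ews_score(VitalsRecord(75, 120, 12, temp, "alert"))
        assert sub["temperature"] == score

    @pytest.mark.parametrize("level,score", [
        ("alert", 0), ("voice", 1), ("pain", 2), ("unresponsive", 3)])
    def test_consciousness_levels(self, level, score):
        _, sub = ews_score(VitalsRecord(75, 120, 12, 37.0, level))
        assert sub["consciousness"] == score

    def test_every_integer_hr_maps_to_exactly_one_band(self):
        for hr in range(30, 181):
            _, sub = ews_score(VitalsRecord(hr, 120, 12, 37.0, "alert"))
            assert sub["heart_rate"] in (0, 1, 2, 3)

    def test_total_is_sum_of_subscores(self):
        total, sub = ews_score(VitalsRecord(135, 65, 31, 34.0, "unresponsive"))
        assert total == sum(sub.values()) == 14


class TestFrequencyBands:
    @pytest.mark.parametrize("freq,band", [
        (0.001, "ULF"), (0.003, "ULF"), (0.01, "out_of_range"),
        (0.033, "VLF"), (0.039, "VLF"), (0.04, "LF"), (0.1, "LF"),
        (0.15, "HF"), (0.2, "HF"), (0.4, "HF"), (0.5, "out_of_range")])
    def test_band_edges(self, freq, band):
        assert classify_band(freq) == band

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            classify_band(-0.1)
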
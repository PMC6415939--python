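"""Correlogram, peak location, RI/RS arithmetic and period estimation."""

import numpy as np
import pytest

from flysleep.core import Correlogram
from flysleep.rhythmicity import (
    ConstantSeriesError,
    analyze_rhythm,
    autocorrelogram,
    locate_peaks,
    rhythm_statistics,
)
from flysleep.synthetic_data import simulate_arrhythmic_trace, simulate_rhythmic_trace


def _sinusoid(period_h=24.0, days=10, bin_min=30, phase=0.0):
    t = np.arange(days * 24 * 60 // bin_min) * bin_min / 60.0
    return np.cos(2 * np.pi * (t - phase) / period_h), bin_min * 60


class TestAutocorrelogram:
    def test_lag_zero_is_exactly_one(self):
        x, bs = _sinusoid()
        corr = autocorrelogram(x, bs)
        assert corr.coefficients[0] == pytest.approx(1.0)

    def test_pure_sinusoid_matches_closed_form_with_taper(self):
        # the normalized-correlogram estimator carries a (1 - k/N) taper, so
        # the closed-form cosine autocorrelation predicts (1-k/N)*cos(2*pi*k/P)
        x, bs = _sinusoid()
        corr = autocorrelogram(x, bs)
        n = corr.n_observations
        k24 = 48  # 24 h at 30-min bins
        assert corr.coefficients[k24] == pytest.approx((1 - k24 / n), abs=0.02)
        k12 = 24  # half period: trough
        assert corr.coefficients[k12] == pytest.approx(-(1 - k12 / n), abs=0.02)

    def test_white_noise_stays_inside_null_band(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=480)
        corr = autocorrelogram(x, 1800)
        band = 3 / np.sqrt(corr.n_observations)
        frac = np.mean(np.abs(corr.coefficients[1:]) <= band)
        assert frac >= 0.99

    def test_constant_series_flagged(self):
        with pytest.raises(ConstantSeriesError):
            autocorrelogram(np.full(480, 7.0), 1800)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            autocorrelogram(np.arange(100.0), 1800)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(3.0, 480).astype(float)
        c1 = autocorrelogram(x, 1800).coefficients
        c2 = autocorrelogram(250.0 * x, 1800).coefficients
        np.testing.assert_allclose(c1, c2, atol=1e-12)


class TestLocatePeaks:
    def test_24h_sinusoid_peaks_at_multiples(self):
        x, bs = _sinusoid(24.0)
        corr = autocorrelogram(x, bs)
        pk = locate_peaks(corr)
        assert pk.indices[0] == 0
        assert pk.period_hours == pytest.approx(24.0, abs=0.5)
        assert pk.third_peak_index * 0.5 == pytest.approx(48.0, abs=1.0)

    def test_20h_sinusoid_period(self):
        x, bs = _sinusoid(20.0)
        pk = locate_peaks(autocorrelogram(x, bs))
        assert pk.period_hours == pytest.approx(20.0, abs=0.5)

    def test_monotone_decay_has_no_period(self):
        lags = np.arange(289) * 30.0
        coef = np.exp(-np.arange(289) / 40.0)
        corr = Correlogram(lags_min=lags, coefficients=coef, n_observations=480, bin_seconds=1800)
        pk = locate_peaks(corr)
        assert pk.period_hours is None and pk.third_peak_index is None

    def test_insufficient_span_rejected(self):
        corr = Correlogram(
            lags_min=np.arange(49) * 30.0, coefficients=np.ones(49) * 0.1,
            n_observations=480, bin_seconds=1800,
        )
        with pytest.raises(ValueError, match="span"):
            locate_peaks(corr)


class TestRhythmStatistics:
    def test_rs_arithmetic_from_stated_formula(self):
        # RI = 0.5, N = 14400 -> RS = 0.5 * sqrt(14400)/2 = 0.5 * 120/2 = 30
        corr = Correlogram(
            lags_min=np.arange(4) * 30.0,
            coefficients=np.array([1.0, 0.2, 0.5, 0.1]),
            n_observations=14400,
            bin_seconds=1800,
        )
        pk_like = type("P", (), {"third_peak_index": 2, "period_hours": 24.0})
        res = rhythm_statistics(corr, pk_like)
        assert res.rhythmicity_index == 0.5
        assert res.rhythmic_statistic == pytest.approx(30.0)
        assert res.is_rhythmic

    def test_absent_period_gives_zero_ri(self):
        corr = Correlogram(
            lags_min=np.arange(4) * 30.0,
            coefficients=np.array([1.0, 0.2, 0.5, 0.1]),
            n_observations=14400,
            bin_seconds=1800,
        )
        pk_like = type("P", (), {"third_peak_index": None, "period_hours": None})
        res = rhythm_statistics(corr, pk_like)
        assert res.rhythmic_statistic == 0.0 and not res.is_rhythmic

    def test_rs_grows_as_sqrt_n_for_fixed_ri(self):
        rs = []
        for n in (900, 3600, 14400):
            corr = Correlogram(
                lags_min=np.arange(4) * 30.0,
                coefficients=np.array([1.0, 0.2, 0.4, 0.1]),
                n_observations=n,
                bin_seconds=1800,
            )
            pk_like = type("P", (), {"third_peak_index": 2, "period_hours": 24.0})
            rs.append(rhythm_statistics(corr, pk_like).rhythmic_statistic)
        assert rs[1] / rs[0] == pytest.approx(2.0) and rs[2] / rs[1] == pytest.approx(2.0)


class TestAnalyzeRhythm:
    def test_poisson_modulated_rhythm_detected(self):
        t = simulate_rhythmic_trace(rng=3)
        res = analyze_rhythm(t)
        assert res.is_rhythmic and res.period_hours == pytest.approx(24.0, abs=0.5)

    def test_white_noise_not_rhythmic(self):
        t = simulate_arrhythmic_trace(rng=3)
        res = analyze_rhythm(t)
        assert res.rhythmic_statistic < 1.0 and not res.is_rhythmic

    def test_constant_trace_arrhythmic_without_error(self):
        t = simulate_arrhythmic_trace(rng=3).with_values(np.zeros(14400))
        res = analyze_rhythm(t)
        assert not res.is_rhythmic and res.rhythmic_statistic == 0.0

    def test_entrained_day_excluded_from_window(self):
        t = simulate_rhythmic_trace(n_days=12, rng=4)
        res = analyze_rhythm(t, skip_initial_hours=24.0)
        # 11 days remain at 30-min bins
        assert res.n_observations == 11 * 48
        assert res.is_rhythmic
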
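"""Autocorrelogram rhythmicity analysis of multi-day activity.

The strength of circadian rhythmicity is read off the normalized
autocorrelogram of a fly's activity series.  Counting the lag-0 maximum as
the first peak, the second peak's lag estimates the free-running period and
the height of the **third** peak (near twice the period) is the
rhythmicity index RI.  The rhythmic statistic scales RI by the
correlogram's 95% confidence bound,

    RS = RI / (2/sqrt(N)) = RI * sqrt(N) / 2,

where N is the number of observations at the analysis sampling; a fly is
called rhythmic when a period was identified and RS >= 1.

The correlogram uses the classic normalized (biased) estimator, whose
null variance ~1/N underlies the 2/sqrt(N) band; peak finding runs on a
boxcar-smoothed copy while RI is always read from the raw coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.ndimage import uniform_filter1d
from statsmodels.tsa.stattools import acf

from .core import ActivityTrace, Correlogram, RhythmResult
from .io_formats import rebin_activity

__all__ = [
    "autocorrelogram",
    "locate_peaks",
    "rhythm_statistics",
    "analyze_rhythm",
    "CorrelogramPeaks",
    "ConstantSeriesError",
    "DEFAULT_ANALYSIS_BIN_MIN",
]

#: activity is summed into bins of this width before the correlogram
DEFAULT_ANALYSIS_BIN_MIN = 30
DEFAULT_MAX_LAG_HOURS = 72.0
MIN_PERIOD_HOURS = 14.0
MAX_PERIOD_HOURS = 34.0
SMOOTH_HOURS = 2.0
#: peak 3 must lie within this relative window of twice peak 2's lag
HARMONIC_TOL = 0.20


class ConstantSeriesError(ValueError):
    """Zero-variance activity: no correlogram is defined."""


def autocorrelogram(
    values: np.ndarray,
    bin_seconds: int,
    max_lag_hours: float = DEFAULT_MAX_LAG_HOURS,
) -> Correlogram:
    """Normalized autocorrelation of a mean-subtracted activity series.

    Coefficients are returned for lags 0 .. ``max_lag_hours``;
    ``n_observations`` is the series length at this sampling.
    """
    x = np.asarray(values, dtype=float)
    n_lags = int(round(max_lag_hours * 3600 / bin_seconds))
    if x.size < 2 * n_lags:
        raise ValueError(
            f"series too short ({x.size} bins) for max lag {max_lag_hours} h "
            f"({n_lags} bins): need >= {2 * n_lags}"
        )
    if np.ptp(x) == 0:
        raise ConstantSeriesError("constant activity series has no correlogram")
    coef = acf(x - x.mean(), nlags=n_lags, adjusted=False, fft=True)
    lags_min = np.arange(n_lags + 1) * (bin_seconds / 60.0)
    return Correlogram(
        lags_min=lags_min,
        coefficients=coef,
        n_observations=int(x.size),
        bin_seconds=bin_seconds,
    )


@dataclass(frozen=True)
class CorrelogramPeaks:
    """Ordered correlogram peaks; the lag-0 maximum is peak 1."""

    indices: tuple[int, ...]  # bin indices into the correlogram, ascending
    period_hours: float | None  # refined lag of peak 2
    third_peak_index: int | None


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-bin peak location by quadratic interpolation around index i."""
    if i <= 0 or i >= y.size - 1:
        return float(i)
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return float(i)
    return i + 0.5 * (a - c) / denom


def locate_peaks(
    correlogram: Correlogram,
    min_period_hours: float = MIN_PERIOD_HOURS,
    max_period_hours: float = MAX_PERIOD_HOURS,
    smooth_hours: float = SMOOTH_HOURS,
) -> CorrelogramPeaks:
    """Find ordered correlogram peaks and the implied period.

    Local maxima are found on a boxcar-smoothed copy of the coefficients,
    requiring peaks at least ``min_period_hours`` apart (ties resolve to
    the smaller lag).  Peak 2 must fall in [min_period, max_period] hours
    and peak 3 within +-20% of twice peak 2's lag; otherwise the period is
    absent and RI will be taken as 0.
    """
    bin_h = correlogram.bin_seconds / 3600.0
    if correlogram.lags_hours[-1] < 2 * max_period_hours:
        raise ValueError("correlogram must span at least twice the maximum period")
    coef = np.asarray(correlogram.coefficients, dtype=float)
    width = max(1, int(round(smooth_hours / bin_h)) | 1)  # odd boxcar
    smoothed = uniform_filter1d(coef, size=width, mode="nearest")
    dist = max(1, int(round(min_period_hours / bin_h)))
    idx, _ = find_peaks(smoothed, distance=dist)
    idx = idx[idx >= dist]  # enforce spacing from the lag-0 peak as well
    indices = (0, *map(int, idx))
    if len(indices) < 3:
        return CorrelogramPeaks(indices=indices, period_hours=None, third_peak_index=None)

    p2 = indices[1]
    period_h = _parabolic_refine(smoothed, p2) * bin_h
    if not (min_period_hours <= period_h <= max_period_hours):
        return CorrelogramPeaks(indices=indices, period_hours=None, third_peak_index=None)
    # a period counts as identified only if the period peak itself clears
    # the correlogram's 95% confidence band
    if coef[p2] < correlogram.confidence_bound:
        return CorrelogramPeaks(indices=indices, period_hours=None, third_peak_index=None)
    lo, hi = 2 * period_h * (1 - HARMONIC_TOL), 2 * period_h * (1 + HARMONIC_TOL)
    third = next(
        (i for i in indices[2:] if lo <= i * bin_h <= hi),
        None,
    )
    if third is None:
        return CorrelogramPeaks(indices=indices, period_hours=None, third_peak_index=None)
    return CorrelogramPeaks(indices=indices, period_hours=float(period_h), third_peak_index=third)


def rhythm_statistics(
    correlogram: Correlogram, peaks: CorrelogramPeaks, fly_id: str = ""
) -> RhythmResult:
    """RI, RS and the rhythmicity verdict from located peaks.

    RI is the raw coefficient at the third peak (0 when no period was
    identified); RS = RI*sqrt(N)/2; rhythmic iff a period is present and
    RS >= 1.
    """
    n = correlogram.n_observations
    if n < 4:
        raise ValueError("need at least 4 observations")
    if peaks.third_peak_index is None or peaks.period_hours is None:
        ri = 0.0
        period = None
    else:
        ri = float(correlogram.coefficients[peaks.third_peak_index])
        period = peaks.period_hours
    rs = ri / correlogram.confidence_bound
    return RhythmResult(
        fly_id=fly_id,
        rhythmicity_index=ri,
        rhythmic_statistic=float(rs),
        period_hours=period,
        is_rhythmic=bool(period is not None and rs >= 1.0),
        n_observations=n,
    )


def analyze_rhythm(
    trace: ActivityTrace,
    analysis_bin_min: int = DEFAULT_ANALYSIS_BIN_MIN,
    max_lag_hours: float = DEFAULT_MAX_LAG_HOURS,
    skip_initial_hours: float = 0.0,
    min_period_hours: float = MIN_PERIOD_HOURS,
    max_period_hours: float = MAX_PERIOD_HOURS,
) -> RhythmResult:
    """Full per-fly rhythmicity analysis.

    Activity is summed into ``analysis_bin_min`` bins (N is counted at this
    sampling), optionally discarding an initial entrained stretch — the
    standard free-running protocol records one light:dark day followed by
    eleven days of constant dark and excludes the entrained day
    (``skip_initial_hours=24``).  Constant (zero-variance) series are
    returned as arrhythmic with RI = RS = 0.
    """
    binned = rebin_activity(trace, analysis_bin_min * 60)
    values = binned.values
    if skip_initial_hours:
        skip = int(round(skip_initial_hours * 60 / analysis_bin_min))
        values = values[skip:]
    try:
        corr = autocorrelogram(values, binned.bin_seconds, max_lag_hours)
    except ConstantSeriesError:
        return RhythmResult(
            fly_id=trace.fly_id,
            rhythmicity_index=0.0,
            rhythmic_statistic=0.0,
            period_hours=None,
            is_rhythmic=False,
            n_observations=int(values.size),
        )
    peaks = locate_peaks(corr, min_period_hours, max_period_hours)
    return rhythm_statistics(corr, peaks, fly_id=trace.fly_id)
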
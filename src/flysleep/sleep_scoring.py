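"""Sleep-bout calling and per-fly sleep metrics.

Sleep is scored from a binary per-minute inactivity series:

* a DAM minute is inactive iff it records zero beam crosses;
* a DART minute is inactive iff **every** constituent window moved strictly
  less than 3 mm (a single window at or above 3 mm makes the minute active).

A sleep bout is a maximal run of at least 5 consecutive inactive minutes;
shorter runs contribute no sleep.  Metrics are computed per analysis day,
with bout minutes attributed to day/night minute-by-minute (a bout spanning
lights-off is split), bout *counts* assigned to the phase of bout onset,
and a 48-bin daily profile of minutes asleep per 30-min ZT interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DAY, NIGHT, ActivityTrace, PhaseAnnotation, SleepBout, SleepMetrics

__all__ = [
    "DART_DISTANCE_THRESHOLD_MM",
    "MIN_BOUT_MIN",
    "inactivity_series",
    "detect_bouts",
    "asleep_mask",
    "sleep_metrics",
    "sleep_profile",
    "waking_velocity",
    "WakingVelocity",
]

#: a DART 5-s window below this distance (mm) counts as immobile (strict <)
DART_DISTANCE_THRESHOLD_MM = 3.0
#: minimum run of inactive minutes constituting a sleep bout
MIN_BOUT_MIN = 5
PROFILE_BINS = 48  # 30-min bins per 24 h


def inactivity_series(
    trace: ActivityTrace, distance_threshold_mm: float = DART_DISTANCE_THRESHOLD_MM
) -> np.ndarray:
    """Binary per-minute inactivity from an activity trace.

    Returns a boolean array, one element per minute, True = inactive.
    DAM traces must already be on the 1-min grid; DART traces must have a
    bin width dividing 60 s, and a minute is inactive only if all its
    windows are sub-threshold.
    """
    if trace.modality == "DAM":
        if trace.bin_seconds != 60:
            raise ValueError(
                f"DAM trace must be on the 1-min grid (got {trace.bin_seconds}s bins); "
                "rebin first"
            )
        return trace.values == 0
    if 60 % trace.bin_seconds != 0:
        raise ValueError(f"DART bin width {trace.bin_seconds}s does not divide 60 s")
    per_min = 60 // trace.bin_seconds
    n_min = trace.n_bins // per_min
    if n_min == 0:
        raise ValueError("trace shorter than one minute")
    windows = trace.values[: n_min * per_min].reshape(n_min, per_min)
    return np.all(windows < distance_threshold_mm, axis=1)


def detect_bouts(inactive: np.ndarray, min_bout_min: int = MIN_BOUT_MIN) -> list[SleepBout]:
    """Maximal runs of inactive minutes with length >= ``min_bout_min``.

    Offsets are exclusive; minutes adjacent to a bout are active by
    maximality.
    """
    if min_bout_min < 1:
        raise ValueError("min_bout_min must be >= 1")
    inactive = np.asarray(inactive, dtype=bool)
    if inactive.size < 1:
        raise ValueError("empty inactivity series")
    padded = np.concatenate(([False], inactive, [False])).astype(int)
    diff = np.diff(padded)
    onsets = np.nonzero(diff == 1)[0]
    offsets = np.nonzero(diff == -1)[0]
    return [
        SleepBout(onset_bin=int(a), offset_bin=int(b))
        for a, b in zip(onsets, offsets)
        if b - a >= min_bout_min
    ]


def asleep_mask(n_minutes: int, bouts: list[SleepBout]) -> np.ndarray:
    """Boolean per-minute mask of minutes lying inside a detected bout."""
    mask = np.zeros(n_minutes, dtype=bool)
    for b in bouts:
        mask[b.onset_bin : b.offset_bin] = True
    return mask


def _window_bouts(
    bouts: list[SleepBout], lo: int, hi: int, min_bout_min: int
) -> list[SleepBout]:
    """Clip bouts to the half-open minute window [lo, hi).

    A bout truncated by the window edge is kept only if its within-window
    run still reaches ``min_bout_min``; untruncated bouts always qualify.
    """
    out = []
    for b in bouts:
        a, z = max(b.onset_bin, lo), min(b.offset_bin, hi)
        if z <= a:
            continue
        truncated = (a != b.onset_bin) or (z != b.offset_bin)
        if truncated and z - a < min_bout_min:
            continue
        out.append(SleepBout(onset_bin=a, offset_bin=z, phase_at_onset=b.phase_at_onset))
    return out


def sleep_profile(asleep: np.ndarray, annotation: PhaseAnnotation) -> np.ndarray:
    """Minutes asleep per 30-min ZT bin over one full analysis day.

    ``asleep`` marks minutes inside detected bouts only.  Raises if the
    annotation does not cover a complete 1440-min day.
    """
    if annotation.bin_seconds != 60:
        raise ValueError("profile requires a minute-level annotation")
    if len(annotation) != 1440 or len(np.asarray(asleep)) != 1440:
        raise ValueError("sleep_profile requires exactly one full day (1440 min)")
    bins = np.minimum((np.asarray(annotation.zt_hours) / 0.5).astype(int), PROFILE_BINS - 1)
    profile = np.bincount(bins[np.asarray(asleep, dtype=bool)], minlength=PROFILE_BINS)
    return profile.astype(float)


def sleep_metrics(
    bouts: list[SleepBout],
    annotation: PhaseAnnotation,
    day_index: int,
    fly_id: str = "",
    min_bout_min: int = MIN_BOUT_MIN,
    mean_waking_velocity_mm_s: float | None = None,
) -> SleepMetrics:
    """Per-fly sleep metrics restricted to one analysis day.

    Sleep minutes are attributed to day/night minute-by-minute; each bout is
    counted once, in the phase of its (within-window) onset.
    """
    if annotation.bin_seconds != 60:
        raise ValueError("sleep metrics require a minute-level annotation")
    in_day = np.nonzero(annotation.day_mask(day_index))[0]
    if in_day.size == 0:
        raise ValueError(f"day_index {day_index} not covered by the recording")
    lo, hi = int(in_day[0]), int(in_day[-1]) + 1
    phase = np.asarray(annotation.phase)
    windowed = _window_bouts(bouts, lo, hi, min_bout_min)

    day_min = night_min = 0.0
    counts = {DAY: 0, NIGHT: 0}
    lengths = []
    for b in windowed:
        ph = phase[b.onset_bin : b.offset_bin]
        d = int(np.sum(ph == DAY))
        day_min += d
        night_min += b.duration_min - d
        counts[str(phase[b.onset_bin])] += 1
        lengths.append(b.duration_min)

    if hi - lo == 1440:
        sub = PhaseAnnotation(
            zt_hours=np.asarray(annotation.zt_hours)[lo:hi],
            phase=phase[lo:hi],
            analysis_day_index=np.asarray(annotation.analysis_day_index)[lo:hi],
            bin_seconds=60,
        )
        day_sleep = asleep_mask(hi - lo, _shift_bouts(windowed, lo))
        profile = sleep_profile(day_sleep, sub)
    else:  # partial day at the recording edge: profile undefined bins stay 0
        profile = np.zeros(PROFILE_BINS)
        for b in windowed:
            zt = np.asarray(annotation.zt_hours)[b.onset_bin : b.offset_bin]
            bins = np.minimum((zt / 0.5).astype(int), PROFILE_BINS - 1)
            profile += np.bincount(bins, minlength=PROFILE_BINS)

    return SleepMetrics(
        fly_id=fly_id,
        day_index=day_index,
        day_sleep_min=day_min,
        night_sleep_min=night_min,
        total_sleep_min=day_min + night_min,
        bout_count_day=counts[DAY],
        bout_count_night=counts[NIGHT],
        bout_lengths_min=tuple(lengths),
        profile_30min=profile,
        mean_waking_velocity_mm_s=mean_waking_velocity_mm_s,
    )


def _shift_bouts(bouts: list[SleepBout], offset: int) -> list[SleepBout]:
    return [
        SleepBout(b.onset_bin - offset, b.offset_bin - offset, b.phase_at_onset)
        for b in bouts
    ]


@dataclass(frozen=True)
class WakingVelocity:
    """Mean locomotor speed over awake minutes (DART only)."""

    mean_mm_s: float  # NaN if the fly never wakes
    per_bin_mm_s: np.ndarray | None = None  # 48 values, NaN where never awake


def waking_velocity(
    trace: ActivityTrace,
    asleep: np.ndarray,
    annotation: PhaseAnnotation | None = None,
    day_index: int | None = None,
) -> WakingVelocity:
    """Average mm/s across minutes classified awake (outside any bout).

    With an annotation and day index, also returns the 48-bin 30-min
    profile; bins in which the fly never wakes are NaN.
    """
    if trace.modality != "DART":
        raise ValueError("waking velocity is defined for DART traces only")
    per_min = 60 // trace.bin_seconds
    n_min = len(asleep)
    dist = trace.values[: n_min * per_min].reshape(n_min, per_min).sum(axis=1)
    speed = dist / 60.0  # mm/s per minute
    awake = ~np.asarray(asleep, dtype=bool)

    sel = np.ones(n_min, dtype=bool)
    profile = None
    if annotation is not None and day_index is not None:
        sel = annotation.day_mask(day_index)[:n_min]
        zt = np.asarray(annotation.zt_hours)[:n_min]
        bins = np.minimum((zt / 0.5).astype(int), PROFILE_BINS - 1)
        profile = np.full(PROFILE_BINS, np.nan)
        for k in range(PROFILE_BINS):
            m = sel & awake & (bins == k)
            if m.any():
                profile[k] = speed[m].mean()
    m = sel & awake
    mean = float(speed[m].mean()) if m.any() else float("nan")
    return WakingVelocity(mean_mm_s=mean, per_bin_mm_s=profile)
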
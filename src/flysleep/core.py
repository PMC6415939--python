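"""Core domain types shared by every analysis stage.

The package operates on per-fly locomotor activity time series recorded by
one of two acquisition modalities:

* **DAM** — infrared beam-break monitors reporting beam-cross *counts* per
  bin (canonically one minute), and
* **DART** — video tracking reporting *distance moved* (mm) per short fixed
  window (canonically 5 s).

A :class:`LightRegime` maps calendar time onto Zeitgeber Time (ZT, hours
since lights-on) or, under constant conditions, onto subjective phase
anchored to the prior entrainment cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, time, timedelta
from typing import Sequence

import numpy as np

__all__ = [
    "ActivityTrace",
    "LightRegime",
    "PhaseAnnotation",
    "SleepBout",
    "SleepMetrics",
    "StimulusEvent",
    "ArousalResult",
    "Correlogram",
    "RhythmResult",
    "DAY",
    "NIGHT",
]

DAY = "day"
NIGHT = "night"

SECONDS_PER_DAY = 86400


@dataclass(frozen=True)
class ActivityTrace:
    """One fly's activity on a uniform time grid.

    ``values`` holds beam-cross counts per bin (DAM, integers) or distance
    moved in mm per bin (DART, non-negative reals).
    """

    fly_id: str
    modality: str  # "DAM" | "DART"
    start_time: datetime
    bin_seconds: int
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("values must be a non-empty 1-D sequence")
        if np.any(vals < 0):
            raise ValueError(f"negative activity values for fly {self.fly_id}")
        if self.modality not in ("DAM", "DART"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "DAM" and not np.allclose(vals, np.round(vals)):
            raise ValueError("DAM counts must be integers")
        if self.bin_seconds <= 0 or SECONDS_PER_DAY % self.bin_seconds != 0:
            raise ValueError("bin_seconds must be positive and divide 86400")
        object.__setattr__(self, "values", vals)

    @property
    def n_bins(self) -> int:
        return int(self.values.size)

    @property
    def duration_hours(self) -> float:
        return self.n_bins * self.bin_seconds / 3600.0

    def bin_start(self, i: int) -> datetime:
        """Calendar timestamp at which bin ``i`` begins."""
        return self.start_time + timedelta(seconds=int(i) * self.bin_seconds)

    def with_values(self, values: np.ndarray, **changes) -> "ActivityTrace":
        return replace(self, values=np.asarray(values), **changes)


@dataclass(frozen=True)
class LightRegime:
    """Photoperiod specification.

    ``mode`` is one of ``"LD"``, ``"DD"``, ``"LL"``.  Under LD, ``ZT0`` is
    lights-on and the day phase spans ``[ZT0, ZT light_hours)``.  Under
    constant conditions (DD/LL) subjective time is anchored to
    ``entrainment_anchor`` (the lights-on time of the prior entrainment
    cycle) and the day/night split reuses ``entrainment_light_hours``.
    """

    mode: str
    lights_on_clock: time | None = None
    light_hours: float | None = None
    entrainment_anchor: time | None = None
    entrainment_light_hours: float = 12.0

    def __post_init__(self) -> None:
        if self.mode == "LD":
            if self.lights_on_clock is None:
                raise ValueError("LD regime requires lights_on_clock")
            if self.light_hours is None:
                raise ValueError("LD regime requires light_hours")
            if not 0 < self.light_hours < 24:
                raise ValueError("light_hours must lie in (0, 24)")
        elif self.mode in ("DD", "LL"):
            if self.entrainment_anchor is None:
                raise ValueError(f"{self.mode} regime requires entrainment_anchor")
            if not 0 < self.entrainment_light_hours < 24:
                raise ValueError("entrainment_light_hours must lie in (0, 24)")
        else:
            raise ValueError(f"unknown regime mode {self.mode!r}")

    @property
    def anchor(self) -> time:
        """Clock time mapped to ZT0 (lights-on or subjective lights-on)."""
        return self.lights_on_clock if self.mode == "LD" else self.entrainment_anchor

    @property
    def day_hours(self) -> float:
        """Length of the (subjective) day phase in hours."""
        return self.light_hours if self.mode == "LD" else self.entrainment_light_hours


@dataclass(frozen=True)
class PhaseAnnotation:
    """Per-bin Zeitgeber/Circadian time, day/night phase and day index.

    ``analysis_day_index`` is 1-based and increments at each (subjective)
    ZT0 crossing; the partial day containing the first bin is day 1.
    """

    zt_hours: np.ndarray
    phase: np.ndarray  # array of "day"/"night" strings
    analysis_day_index: np.ndarray
    bin_seconds: int

    def __post_init__(self) -> None:
        n = len(self.zt_hours)
        if not (len(self.phase) == len(self.analysis_day_index) == n):
            raise ValueError("annotation arrays must have equal length")

    def __len__(self) -> int:
        return len(self.zt_hours)

    def day_mask(self, day_index: int) -> np.ndarray:
        return np.asarray(self.analysis_day_index) == day_index


@dataclass(frozen=True)
class SleepBout:
    """One maximal inactivity run of at least the bout threshold.

    ``onset_bin``/``offset_bin`` index the per-minute inactivity series;
    the offset is exclusive.
    """

    onset_bin: int
    offset_bin: int
    phase_at_onset: str | None = None

    @property
    def duration_min(self) -> int:
        return self.offset_bin - self.onset_bin

    def __post_init__(self) -> None:
        if self.offset_bin <= self.onset_bin:
            raise ValueError("bout offset must exceed onset")


@dataclass(frozen=True)
class SleepMetrics:
    """Per-fly, per-day sleep and locomotion summary."""

    fly_id: str
    day_index: int
    day_sleep_min: float
    night_sleep_min: float
    total_sleep_min: float
    bout_count_day: int
    bout_count_night: int
    bout_lengths_min: tuple[int, ...]
    profile_30min: np.ndarray  # 48 values, minutes asleep per 30-min ZT bin
    mean_waking_velocity_mm_s: float | None = None


@dataclass(frozen=True)
class StimulusEvent:
    """A vibration startle stimulus: a train of short pulses.

    Defaults encode the standard paradigm of five 200 ms, 50 Hz pulses
    separated by 800 ms gaps, spanning 4800 ms in total.
    """

    time: datetime
    zt_hours: float | None = None
    pulse_count: int = 5
    pulse_ms: int = 200
    pulse_gap_ms: int = 800
    frequency_hz: float = 50.0

    @property
    def span_ms(self) -> int:
        return self.pulse_count * self.pulse_ms + (self.pulse_count - 1) * self.pulse_gap_ms


@dataclass(frozen=True)
class ArousalResult:
    """Responder tally for one group at one stimulus."""

    group_id: str
    n_sleeping: int
    n_responding: int
    low_n_flag: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.n_responding <= self.n_sleeping:
            raise ValueError("0 <= n_responding <= n_sleeping violated")
        if self.n_sleeping == 0:
            raise ValueError("empty group: no sleeping flies")

    @property
    def proportion(self) -> float:
        return self.n_responding / self.n_sleeping


@dataclass(frozen=True)
class Correlogram:
    """Normalized autocorrelation of an activity series across lags."""

    lags_min: np.ndarray
    coefficients: np.ndarray
    n_observations: int
    bin_seconds: int

    def __post_init__(self) -> None:
        if len(self.lags_min) != len(self.coefficients):
            raise ValueError("lags and coefficients must align")

    @property
    def lags_hours(self) -> np.ndarray:
        return np.asarray(self.lags_min, dtype=float) / 60.0

    @property
    def confidence_bound(self) -> float:
        """Half-width of the 95% confidence band, 2/sqrt(N)."""
        return 2.0 / np.sqrt(self.n_observations)


@dataclass(frozen=True)
class RhythmResult:
    """Correlogram-derived rhythmicity verdict for one fly.

    ``rhythmicity_index`` (RI) is the correlogram's third-peak height and
    ``rhythmic_statistic`` RS = RI / (2/sqrt(N)); the fly is called rhythmic
    when a period was identified and RS >= 1.
    """

    fly_id: str
    rhythmicity_index: float
    rhythmic_statistic: float
    period_hours: float | None
    is_rhythmic: bool
    n_observations: int = 0
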
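"""Synthetic fly-activity cohorts with known ground truth.

Virtual flies alternate between wake and sleep as a two-state
alternating-renewal (semi-Markov) process whose parameters depend on the
(subjective) photoperiod phase: bout durations follow a discrete
log-normal law (minimum 1 min), and the per-phase stationary asleep
fraction is set by the programmed mean day/night sleep.  Each phase
segment is simulated with a burn-in so the process enters the segment in
its stationary regime: the expected scored sleep then equals the
programmed value up to the (negligible, documented) 5-min censoring bound.

Group effects: ``night_sleep_reduction_fraction`` r rescales the night
stationary asleep fraction to (1-r) x baseline, implemented as both
shorter night sleep bouts (scaled by sqrt(1-r)) and more frequent brief
awakenings (shorter wake gaps are *not* used — gaps lengthen so the
fraction drops); ``day_sleep_effect`` is the signed fractional change of
day sleep.

Emissions: wake minutes emit at least one beam cross (DAM, shifted Poisson
with crepuscular morning/evening rate peaks) or at least one
supra-threshold 5-s window (DART, gamma distances); sleep minutes emit
zeros (DAM) or sub-threshold jitter < 3 mm (DART).  A waking minute is by
definition a moving minute, which keeps the scheduled-vs-scored closed
loop exact.

Under DD the subjective day repeats with ``free_running_period_hours``;
under LL phase structure is abolished (one blended parameter set, no
crepuscular modulation), producing behaviorally arrhythmic flies.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from datetime import datetime, time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import DAY, NIGHT, ActivityTrace, LightRegime, StimulusEvent
from .io_formats import write_dam_monitor, write_dart_velocity
from .sleep_scoring import MIN_BOUT_MIN, detect_bouts

__all__ = [
    "GroupSpec",
    "Baseline",
    "SimulationParams",
    "simulate_activity_trace",
    "simulate_experiment",
    "simulate_cohort",
    "inject_startle_responses",
    "simulate_rhythmic_trace",
    "simulate_arrhythmic_trace",
    "default_regime_8L16D",
]

DART_WINDOWS_PER_MIN = 12  # 5-s windows
#: burn-in (min) run before every phase segment so it starts stationary
BURN_IN_MIN = 1440


def default_regime_8L16D() -> LightRegime:
    return LightRegime(mode="LD", lights_on_clock=time(9, 0), light_hours=8.0)


@dataclass(frozen=True)
class GroupSpec:
    """One genotype/condition in a simulated experiment."""

    id: str
    night_sleep_reduction_fraction: float = 0.0
    day_sleep_effect: float = 0.0  # signed fractional change of day sleep
    startle_response_prob_day: float = 0.8
    startle_response_prob_night: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.night_sleep_reduction_fraction < 1.0:
            raise ValueError("night_sleep_reduction_fraction must lie in [0, 1)")
        for p in (self.startle_response_prob_day, self.startle_response_prob_night):
            if not 0.0 <= p <= 1.0:
                raise ValueError("response probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class Baseline:
    """Control-fly behavioral parameters.

    Sleep means are per (subjective) phase and day; bout medians are the
    log-normal medians in minutes with log-sd ``bout_length_shape``.
    """

    mean_night_sleep_min: float = 700.0
    mean_day_sleep_min: float = 250.0
    night_bout_median_min: float = 45.0
    day_bout_median_min: float = 20.0
    bout_length_shape: float = 0.5
    waking_rate_counts_per_min: float = 2.0
    mm_per_window: float = 6.0
    crepuscular_peak_amplitude: float = 0.8


@dataclass(frozen=True)
class SimulationParams:
    regime: LightRegime = field(default_factory=default_regime_8L16D)
    n_flies_per_group: int = 40
    groups: tuple[GroupSpec, ...] = (GroupSpec(id="control"),)
    baseline: Baseline = field(default_factory=Baseline)
    n_days: int = 1
    modality: str = "DAM"
    free_running_period_hours: float = 24.0
    rng_seed: int = 0
    start_date: str = "2018-01-01"  # calendar anchor; lights-on sets the clock


@dataclass(frozen=True)
class _PhaseLaw:
    """Alternating-renewal parameters of one phase."""

    sleep_mu: float  # log-median of sleep bout (min)
    wake_mu: float  # log-median of wake bout (min)
    sigma: float


def _phase_law(asleep_frac: float, bout_median: float, sigma: float) -> _PhaseLaw:
    if not 0.0 < asleep_frac < 1.0:
        raise ValueError(f"stationary asleep fraction {asleep_frac:.3f} out of (0, 1)")
    mean_sleep = bout_median * np.exp(sigma**2 / 2)
    mean_wake = mean_sleep * (1.0 / asleep_frac - 1.0)
    return _PhaseLaw(
        sleep_mu=np.log(bout_median),
        wake_mu=np.log(mean_wake) - sigma**2 / 2,
        sigma=sigma,
    )


def _group_laws(params: SimulationParams, group: GroupSpec) -> dict[str, _PhaseLaw]:
    b = params.baseline
    day_min = params.regime.day_hours * 60.0
    night_min = 1440.0 - day_min
    r = group.night_sleep_reduction_fraction
    f_night = (b.mean_night_sleep_min / night_min) * (1.0 - r)
    f_day = np.clip(
        (b.mean_day_sleep_min / day_min) * (1.0 + group.day_sleep_effect), 1e-3, 0.98
    )
    night_median = b.night_bout_median_min * np.sqrt(1.0 - r)
    if params.regime.mode == "LL":
        # constant light abolishes phase structure: one blended law
        f = (f_day * day_min + f_night * night_min) / 1440.0
        median = float(np.sqrt(night_median * b.day_bout_median_min))
        law = _phase_law(f, median, b.bout_length_shape)
        return {DAY: law, NIGHT: law}
    return {
        DAY: _phase_law(float(f_day), b.day_bout_median_min, b.bout_length_shape),
        NIGHT: _phase_law(f_night, night_median, b.bout_length_shape),
    }


def _subjective_phase_minutes(params: SimulationParams, n_min: int) -> np.ndarray:
    """Per-minute day/night labels from ZT0, honoring DD free-running period."""
    minutes = np.arange(n_min)
    if params.regime.mode == "DD":
        tau_min = params.free_running_period_hours * 60.0
        ct = np.mod(minutes, tau_min) / tau_min * 24.0
    else:
        ct = np.mod(minutes / 60.0, 24.0)
    return np.where(ct < params.regime.day_hours, DAY, NIGHT), ct


def _simulate_states_segment(rng: np.random.Generator, law: _PhaseLaw, n_min: int) -> np.ndarray:
    """Stationary wake(0)/sleep(1) minute sequence of one phase segment."""
    total = BURN_IN_MIN + n_min
    out = np.empty(total, dtype=np.int8)
    pos = 0
    state = 0  # burn-in start; forgotten by stationarity
    while pos < total:
        mu = law.sleep_mu if state else law.wake_mu
        dur = max(1, int(round(np.exp(rng.normal(mu, law.sigma)))))
        out[pos : pos + dur] = state
        pos += dur
        state ^= 1
    return out[BURN_IN_MIN : BURN_IN_MIN + n_min]


def _crepuscular_rate(params: SimulationParams, ct: np.ndarray) -> np.ndarray:
    """Per-minute DAM wake rate with morning/evening activity peaks."""
    b = params.baseline
    if params.regime.mode == "LL":
        return np.full(ct.shape, b.waking_rate_counts_per_min)
    width = 1.5  # h
    bump = np.zeros_like(ct, dtype=float)
    for center in (0.0, params.regime.day_hours):
        d = np.minimum(np.abs(ct - center), 24.0 - np.abs(ct - center))
        bump += np.exp(-0.5 * (d / width) ** 2)
    return b.waking_rate_counts_per_min * (1.0 + b.crepuscular_peak_amplitude * bump)


def _start_time(params: SimulationParams) -> datetime:
    d = datetime.strptime(params.start_date, "%Y-%m-%d")
    anchor = params.regime.anchor
    return d.replace(hour=anchor.hour, minute=anchor.minute)


def simulate_activity_trace(
    params: SimulationParams,
    group: GroupSpec,
    fly_index: int,
    rng: np.random.Generator | None = None,
    modality: str | None = None,
) -> tuple[ActivityTrace, np.ndarray]:
    """One fly's trace plus its true per-minute sleep state (1 = asleep).

    The recording starts at (subjective) ZT0 and spans ``n_days`` full
    days.  With no explicit ``rng``, the stream is derived from
    ``(rng_seed, group id, fly_index)`` so cohorts are reproducible
    fly-by-fly.
    """
    if rng is None:
        rng = _fly_rng(params, group, fly_index)
    modality = modality or params.modality
    n_min = params.n_days * 1440
    phase, ct = _subjective_phase_minutes(params, n_min)
    laws = _group_laws(params, group)

    states = np.empty(n_min, dtype=np.int8)
    # contiguous equal-phase segments, each simulated in its stationary regime
    boundaries = np.flatnonzero(np.diff(phase != DAY)) + 1
    for lo, hi in zip(np.r_[0, boundaries], np.r_[boundaries, n_min]):
        states[lo:hi] = _simulate_states_segment(rng, laws[str(phase[lo])], hi - lo)

    wake = states == 0
    if modality == "DAM":
        rate = _crepuscular_rate(params, ct)
        counts = np.zeros(n_min)
        counts[wake] = 1 + rng.poisson(rate[wake])
        values, bin_seconds = counts, 60
    elif modality == "DART":
        values = _dart_emissions(rng, wake, params.baseline.mm_per_window)
        bin_seconds = 5
    else:
        raise ValueError(f"unknown modality {modality!r}")
    trace = ActivityTrace(
        fly_id=f"{group.id}_{fly_index:03d}",
        modality=modality,
        start_time=_start_time(params),
        bin_seconds=bin_seconds,
        values=values,
    )
    return trace, states


def _dart_emissions(
    rng: np.random.Generator, wake: np.ndarray, mm_per_window: float
) -> np.ndarray:
    n_min = wake.size
    win = np.empty((n_min, DART_WINDOWS_PER_MIN))
    sleep_rows = ~wake
    win[sleep_rows] = rng.uniform(0.0, 1.5, size=(int(sleep_rows.sum()), DART_WINDOWS_PER_MIN))
    n_wake = int(wake.sum())
    gam = rng.gamma(2.0, mm_per_window / 2.0, size=(n_wake, DART_WINDOWS_PER_MIN))
    # a waking minute must register movement: force one window supra-threshold
    sub = np.all(gam < 3.0, axis=1)
    if sub.any():
        cols = rng.integers(0, DART_WINDOWS_PER_MIN, size=int(sub.sum()))
        gam[np.flatnonzero(sub), cols] = 3.0 + rng.exponential(3.0, size=int(sub.sum()))
    win[wake] = gam
    return win.reshape(-1)


def _fly_rng(params: SimulationParams, group: GroupSpec, fly_index: int) -> np.random.Generator:
    key = zlib.crc32(group.id.encode())  # stable across processes, unlike hash()
    return np.random.default_rng(
        np.random.SeedSequence(entropy=params.rng_seed, spawn_key=(key, fly_index))
    )


def _true_sleep_row(
    states: np.ndarray, phase: np.ndarray, min_bout_min: int = MIN_BOUT_MIN
) -> dict[str, float]:
    """Ground-truth scheduled sleep, applying the same >= 5-min rule."""
    bouts = detect_bouts(states == 1, min_bout_min)
    day_min = night_min = 0.0
    for b in bouts:
        ph = phase[b.onset_bin : b.offset_bin]
        d = float(np.sum(ph == DAY))
        day_min += d
        night_min += b.duration_min - d
    scheduled = float(np.sum(states == 1))
    return {
        "true_day_sleep_min": day_min,
        "true_night_sleep_min": night_min,
        "true_total_sleep_min": day_min + night_min,
        "scheduled_sleep_min": scheduled,
        "n_true_bouts": float(len(bouts)),
    }


def simulate_experiment(
    params: SimulationParams,
) -> tuple[list[ActivityTrace], dict[str, np.ndarray], pd.DataFrame]:
    """Simulate every fly of every group in memory.

    Returns the traces, the true per-minute sleep states keyed by fly id,
    and a ground-truth table (per fly: group, programmed effects, true
    day/night/total scheduled sleep under the 5-min rule).
    """
    traces: list[ActivityTrace] = []
    states: dict[str, np.ndarray] = {}
    rows = []
    n_min = params.n_days * 1440
    phase, _ = _subjective_phase_minutes(params, n_min)
    for group in params.groups:
        for i in range(params.n_flies_per_group):
            trace, st = simulate_activity_trace(params, group, i)
            traces.append(trace)
            states[trace.fly_id] = st
            rows.append(
                {
                    "fly_id": trace.fly_id,
                    "group": group.id,
                    "night_sleep_reduction_fraction": group.night_sleep_reduction_fraction,
                    **_true_sleep_row(st, phase),
                }
            )
    return traces, states, pd.DataFrame(rows)


def inject_startle_responses(
    traces: Sequence[ActivityTrace],
    states: dict[str, np.ndarray],
    stimuli: Sequence[StimulusEvent],
    groups: Sequence[GroupSpec],
    rng_seed: int = 0,
    response_window_s: int = 60,
    immobility_window_min: int = 5,
    day_hours: float = 8.0,
) -> tuple[list[ActivityTrace], pd.DataFrame]:
    """Insert Bernoulli startle responses for flies asleep at each stimulus.

    For every fly whose true state is asleep throughout the pre-stimulus
    immobility window, a draw with the group's phase-appropriate response
    probability decides whether supra-threshold movement is inserted with
    onset inside the response window; non-responders are forced to remain
    immobile through the window.  Returns modified traces and the draw
    table (the assay's ground truth).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=rng_seed, spawn_key=(77,)))
    by_group = {g.id: g for g in groups}
    out = []
    rows = []
    for trace in traces:
        group = by_group[trace.fly_id.rsplit("_", 1)[0]]
        st = states[trace.fly_id]
        values = trace.values.copy()
        per_min = 60 // trace.bin_seconds
        for stim in stimuli:
            off_s = (stim.time - trace.start_time).total_seconds()
            stim_min = int(off_s // 60)
            lo = stim_min - immobility_window_min
            if lo < 0 or (off_s + response_window_s) / 60 + 1 > st.size:
                raise ValueError(f"stimulus at {stim.time} outside recording")
            if not np.all(st[lo:stim_min] == 1):
                continue  # awake fly: not part of the assay
            zt = stim.zt_hours if stim.zt_hours is not None else (off_s / 3600.0) % 24.0
            is_day = zt < day_hours
            p = group.startle_response_prob_day if is_day else group.startle_response_prob_night
            responded = bool(rng.random() < p)
            first_bin = int(off_s // trace.bin_seconds)
            win_bins = response_window_s // trace.bin_seconds
            if responded:
                onset = first_bin + 1 + int(rng.integers(0, max(1, win_bins - 1)))
                burst = slice(onset, onset + max(1, per_min // 4))
                if trace.modality == "DAM":
                    values[burst] = 1 + rng.poisson(3.0, size=len(range(*burst.indices(values.size))))
                else:
                    values[burst] = 4.0 + rng.gamma(2.0, 2.0, size=len(range(*burst.indices(values.size))))
            else:
                quiet = slice(first_bin, first_bin + win_bins + per_min)
                values[quiet] = 0.0 if trace.modality == "DAM" else rng.uniform(
                    0.0, 1.5, size=len(range(*quiet.indices(values.size)))
                )
                st = st.copy()
                st[stim_min : stim_min + response_window_s // 60 + 1] = 1
            rows.append(
                {
                    "fly_id": trace.fly_id,
                    "group": group.id,
                    "stimulus_time": stim.time,
                    "zt_hours": zt,
                    "was_asleep": True,
                    "responded": responded,
                }
            )
        out.append(trace.with_values(values))
        states[trace.fly_id] = st
    return out, pd.DataFrame(rows)


def simulate_cohort(params: SimulationParams, outdir: str | Path) -> dict[str, list[Path]]:
    """Simulate an experiment and write it in the native file dialects.

    Writes one DAM monitor file (or DART CSV) per group, the experiment
    config YAML, and the ground-truth CSV; returns the written paths.
    Identical seeds give byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traces, _, truth = simulate_experiment(params)
    written: dict[str, list[Path]] = {"activity": [], "truth": [], "config": []}
    channel_rows = []
    for gi, group in enumerate(params.groups):
        gtraces = [t for t in traces if t.fly_id.startswith(f"{group.id}_")]
        if params.modality == "DAM":
            for j in range(0, len(gtraces), 32):
                p = outdir / f"Monitor{gi + 1}_{j // 32 + 1}.txt"
                chunk = gtraces[j : j + 32]
                write_dam_monitor(chunk, p)
                written["activity"].append(p)
                channel_rows += [
                    {"monitor_file": p.name, "channel": ch + 1, "fly_id": t.fly_id, "group": group.id}
                    for ch, t in enumerate(chunk)
                ]
        else:
            p = outdir / f"dart_{group.id}.csv"
            write_dart_velocity(gtraces, p)
            written["activity"].append(p)
    if channel_rows:
        cm_path = outdir / "channel_map.csv"
        pd.DataFrame(channel_rows).to_csv(cm_path, index=False)
        written["config"].append(cm_path)
    truth_path = outdir / "ground_truth.csv"
    truth.to_csv(truth_path, index=False)
    written["truth"].append(truth_path)
    config_path = outdir / "experiment.yaml"
    regime = params.regime
    with open(config_path, "w") as fh:
        yaml.safe_dump(
            {
                "regime": {
                    "mode": regime.mode,
                    "lights_on": regime.anchor.strftime("%H:%M"),
                    "light_hours": regime.day_hours,
                },
                "analysis_day": 1,
                "groups": {
                    g.id: {"n_flies": params.n_flies_per_group} for g in params.groups
                },
                "modality": params.modality,
                "rng_seed": params.rng_seed,
            },
            fh,
            sort_keys=True,
        )
    written["config"].append(config_path)
    return written


def simulate_rhythmic_trace(
    fly_id: str = "rhythmic",
    n_days: int = 10,
    period_hours: float = 24.0,
    mean_rate_per_min: float = 1.5,
    modulation_depth: float = 0.8,
    rng: np.random.Generator | int | None = None,
) -> ActivityTrace:
    """Poisson activity with a sinusoidally modulated rate (1-min bins).

    The canonical rhythmic test signal: counts ~ Poisson(rate(t)) with
    rate(t) = m(1 + depth*cos(2*pi*t/period)).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    t_h = np.arange(n_days * 1440) / 60.0
    rate = mean_rate_per_min * (1.0 + modulation_depth * np.cos(2 * np.pi * t_h / period_hours))
    counts = rng.poisson(np.clip(rate, 0.0, None))
    return ActivityTrace(
        fly_id=fly_id,
        modality="DAM",
        start_time=datetime(2018, 1, 1, 9, 0),
        bin_seconds=60,
        values=counts.astype(float),
    )


def simulate_arrhythmic_trace(
    fly_id: str = "arrhythmic",
    n_days: int = 10,
    mean_rate_per_min: float = 1.5,
    rng: np.random.Generator | int | None = None,
) -> ActivityTrace:
    """Constant-rate Poisson activity: white noise, no circadian structure."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    counts = rng.poisson(mean_rate_per_min, size=n_days * 1440)
    return ActivityTrace(
        fly_id=fly_id,
        modality="DAM",
        start_time=datetime(2018, 1, 1, 9, 0),
        bin_seconds=60,
        values=counts.astype(float),
    )
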
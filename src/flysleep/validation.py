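"""End-to-end validation studies run by the test suite and reporting script.

Each function recomputes one pipeline-level property from scratch on
freshly simulated data: bout-caller exhaustiveness, sleep conservation,
scoring-definition fidelity, rhythmicity sensitivity/specificity,
night-sleep effect recovery with the nonparametric statistics, the
startle-assay closed loop, test calibration under the null, and file
round-trips.  All randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import itertools
import tempfile
from datetime import timedelta
from pathlib import Path

import numpy as np
from scipy import stats

from .arousal_assay import (
    arousal_summary,
    binomial_vs_proportion,
    classify_startle,
    compare_arousal,
    select_asleep_at_stimulus,
)
from .core import StimulusEvent
from .group_stats import kruskal_wallis_dunn, mann_whitney_u
from .io_formats import annotate_phase, read_dam_monitor, read_dart_velocity, write_dam_monitor, write_dart_velocity
from .rhythmicity import analyze_rhythm, rhythm_statistics, Correlogram, CorrelogramPeaks
from .sleep_scoring import detect_bouts, inactivity_series, sleep_metrics
from .synthetic_data import (
    GroupSpec,
    SimulationParams,
    inject_startle_responses,
    simulate_arrhythmic_trace,
    simulate_cohort,
    simulate_experiment,
    simulate_rhythmic_trace,
)


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1000 + k) % (2**31 - 1)


# ---------------------------------------------------------------- bout caller

def bout_caller_exhaustive_agreement(length: int = 12, thresholds=range(1, 7)) -> dict:
    """Compare the bout caller with brute-force maximal-run enumeration
    over every binary minute-string of the given length."""

    def brute(bits, thr):
        runs, start = [], None
        for i, v in enumerate(bits + (False,)):
            if v and start is None:
                start = i
            elif not v and start is not None:
                if i - start >= thr:
                    runs.append((start, i))
                start = None
        return runs

    n_cases = agree = 0
    for bits in itertools.product((False, True), repeat=length):
        arr = np.asarray(bits)
        for thr in thresholds:
            got = [(b.onset_bin, b.offset_bin) for b in detect_bouts(arr, thr)]
            agree += got == brute(bits, thr)
            n_cases += 1
    return {"agreement_rate": agree / n_cases, "n": n_cases}


# --------------------------------------------------------------- conservation

def conservation_check(n_flies: int = 500, seed: int = 0) -> dict:
    """day + night = total and sum(30-min profile) = total, exactly."""
    params = SimulationParams(
        rng_seed=_sub_seed(seed, 1),
        n_flies_per_group=n_flies,
        groups=(GroupSpec(id="mix", night_sleep_reduction_fraction=0.15),),
    )
    traces, _, _ = simulate_experiment(params)
    ann = annotate_phase(traces[0], params.regime)
    violations = 0
    for t in traces:
        m = sleep_metrics(detect_bouts(inactivity_series(t)), ann, 1, fly_id=t.fly_id)
        if m.day_sleep_min + m.night_sleep_min != m.total_sleep_min:
            violations += 1
        elif m.profile_30min.sum() != m.total_sleep_min:
            violations += 1
    return {"violations": violations, "n": n_flies}


# ------------------------------------------------------- definition fidelity

def definition_checks() -> dict:
    """The core scoring definitions checked directly: a DAM minute is
    inactive iff zero counts, a DART window is inactive iff < 3 mm
    (strict), a 4-min run yields no sleep and a 5-min run one bout."""
    from datetime import datetime

    from .core import ActivityTrace

    t0 = datetime(2018, 1, 1, 9, 0)
    dam = ActivityTrace("d", "DAM", t0, 60, np.array([0.0, 0.0, 1.0, 0.0]))
    dam_ok = list(inactivity_series(dam)) == [True, True, False, True]
    dart_in = ActivityTrace("v", "DART", t0, 5, np.full(12, 2.9))
    dart_edge = ActivityTrace("v", "DART", t0, 5, np.r_[np.full(11, 2.9), 3.0])
    dart_ok = bool(inactivity_series(dart_in)[0]) and not bool(inactivity_series(dart_edge)[0])
    four = detect_bouts(np.ones(4, dtype=bool))
    five = detect_bouts(np.ones(5, dtype=bool))
    bout_ok = len(four) == 0 and len(five) == 1 and five[0].duration_min == 5
    return {
        "dam_definition_ok": float(dam_ok),
        "dart_definition_ok": float(dart_ok),
        "bout_threshold_ok": float(bout_ok),
        "n": 4,
    }


# ---------------------------------------------------------------- rhythmicity

def rhythm_recovery_study(n_per_class: int = 100, seed: int = 0) -> dict:
    """Sensitivity on 24-h Poisson-modulated flies, specificity on noise."""
    rng = np.random.default_rng(_sub_seed(seed, 2))
    rhythmic = [analyze_rhythm(simulate_rhythmic_trace(rng=rng)) for _ in range(n_per_class)]
    noise = [analyze_rhythm(simulate_arrhythmic_trace(rng=rng)) for _ in range(n_per_class)]
    period_ok = np.mean(
        [r.period_hours is not None and abs(r.period_hours - 24.0) <= 0.5 for r in rhythmic]
    )
    rs_ok = np.mean([r.rhythmic_statistic >= 1.0 for r in rhythmic])
    noise_ok = np.mean([r.rhythmic_statistic < 1.0 for r in noise])
    # RS arithmetic at the stated numbers: RI=0.5, N=14400 -> RS=30
    corr = Correlogram(
        lags_min=np.arange(4) * 30.0,
        coefficients=np.array([1.0, 0.2, 0.5, 0.1]),
        n_observations=14400,
        bin_seconds=1800,
    )
    peaks = CorrelogramPeaks(indices=(0, 1, 2), period_hours=24.0, third_peak_index=2)
    rs_check = rhythm_statistics(corr, peaks).rhythmic_statistic
    return {
        "rhythmic_period_within_half_hour": float(period_ok),
        "rhythmic_rs_ge_1": float(rs_ok),
        "noise_rs_lt_1": float(noise_ok),
        "rs_for_ri_half_n14400": float(rs_check),
        "n": n_per_class,
    }


# ------------------------------------------------------------ effect recovery

def effect_recovery_study(
    n_reps: int = 100, n_per_group: int = 40, reduction: float = 0.3, seed: int = 0
) -> dict:
    """Simulated knockdown experiment: 30% night-sleep loss, day unchanged.

    Per replicate: three groups (two controls, one experimental), scored
    through the full pipeline, compared with Kruskal-Wallis + Dunn
    (experimental vs each control, Bonferroni over the two comparisons).
    """
    groups = (
        GroupSpec(id="driver-ctrl"),
        GroupSpec(id="rnai-ctrl"),
        GroupSpec(id="kd", night_sleep_reduction_fraction=reduction),
    )
    comparisons = [("kd", "driver-ctrl"), ("kd", "rnai-ctrl")]
    deficits, night_hits, day_rejects = [], 0, 0
    for rep in range(n_reps):
        params = SimulationParams(
            rng_seed=_sub_seed(seed, 100 + rep), n_flies_per_group=n_per_group, groups=groups
        )
        traces, _, _ = simulate_experiment(params)
        ann = annotate_phase(traces[0], params.regime)
        night = {g.id: [] for g in groups}
        day = {g.id: [] for g in groups}
        for t in traces:
            m = sleep_metrics(detect_bouts(inactivity_series(t)), ann, 1, fly_id=t.fly_id)
            gid = t.fly_id.rsplit("_", 1)[0]
            night[gid].append(m.night_sleep_min)
            day[gid].append(m.day_sleep_min)
        ctrl_mean = np.mean(night["driver-ctrl"] + night["rnai-ctrl"])
        deficits.append(1.0 - np.mean(night["kd"]) / ctrl_mean)
        _, post_n = kruskal_wallis_dunn(night, comparisons)
        night_hits += all(p.p_adjusted < 0.05 for p in post_n)
        _, post_d = kruskal_wallis_dunn(day, comparisons)
        day_rejects += any(p.p_adjusted < 0.05 for p in post_d)
    return {
        "mean_recovered_deficit": float(np.mean(deficits)),
        "programmed_deficit": reduction,
        "night_detection_rate": night_hits / n_reps,
        "day_rejection_rate": day_rejects / n_reps,
        "n": n_reps,
    }


# ------------------------------------------------------------- arousal assay

def arousal_pattern_study(
    n_reps: int = 100, n_sleeping: int = 30, seed: int = 0, n_flies: int = 60
) -> dict:
    """Closed-loop startle experiment reproducing the day/night pattern.

    Control flies respond with probability 0.8 by day and 0.3 by night;
    mutants respond with 0.8 at both times.  Per replicate the full
    pipeline runs (simulate DART traces, inject responses, select sleeping
    flies capped at the programmed cohort size, classify, compare with the
    Bonferroni-corrected binomial).  Success = night difference detected
    (mutant vs control, adjusted p < 0.05) and day difference not.
    """
    groups = (
        GroupSpec(id="ctrl", startle_response_prob_day=0.8, startle_response_prob_night=0.3),
        GroupSpec(id="mut", startle_response_prob_day=0.8, startle_response_prob_night=0.8),
    )
    pattern = night_detect = day_reject = 0
    for rep in range(n_reps):
        rs = _sub_seed(seed, 300 + rep)
        params = SimulationParams(rng_seed=rs, n_flies_per_group=n_flies, groups=groups, modality="DART")
        traces, states, _ = simulate_experiment(params)
        start = traces[0].start_time
        stims = {
            "day": StimulusEvent(time=start + timedelta(hours=4), zt_hours=4.0),
            "night": StimulusEvent(time=start + timedelta(hours=16), zt_hours=16.0),
        }
        traces, _ = inject_startle_responses(
            traces, states, list(stims.values()), groups, rng_seed=rs
        )
        by_id = {t.fly_id: t for t in traces}
        results = {}
        for g in groups:
            gtraces = [t for t in traces if t.fly_id.startswith(f"{g.id}_")]
            for phase, stim in stims.items():
                sleeping = select_asleep_at_stimulus(gtraces, stim)[:n_sleeping]
                responses = [classify_startle(by_id[f], stim) for f in sleeping]
                results[f"{g.id}_{phase}"] = arousal_summary(f"{g.id}_{phase}", responses)
        cmp = compare_arousal(
            results, [("mut_night", "ctrl_night"), ("mut_day", "ctrl_day")]
        )
        night_p = cmp.loc[cmp.group_a == "mut_night", "p_binomial_adj"].iloc[0]
        day_p = cmp.loc[cmp.group_a == "mut_day", "p_binomial_adj"].iloc[0]
        night_detect += night_p < 0.05
        day_reject += day_p < 0.05
        pattern += (night_p < 0.05) and (day_p >= 0.05)
    return {
        "pattern_rate": pattern / n_reps,
        "night_detection_rate": night_detect / n_reps,
        "day_rejection_rate": day_reject / n_reps,
        "n": n_reps,
    }


# ----------------------------------------------------------- test calibration

def type1_error_study(n_sims: int = 1000, n: int = 30, seed: int = 0) -> dict:
    """Rejection rates at alpha = 0.05 when every group shares one
    distribution (Mann-Whitney, Kruskal-Wallis) or the null proportion is
    true (exact binomial, p0 = 0.5)."""
    rng = np.random.default_rng(_sub_seed(seed, 4))
    mwu = kw = binom = 0
    for _ in range(n_sims):
        a, b, c = rng.normal(size=(3, n))
        mwu += mann_whitney_u(a, b).p_raw < 0.05
        omni, _ = kruskal_wallis_dunn({"a": a, "b": b, "c": c}, comparisons=[])
        kw += omni.p_raw < 0.05
        k = rng.binomial(n, 0.5)
        binom += binomial_vs_proportion(k, n, 0.5) < 0.05
    return {
        "mwu_type1_rate": mwu / n_sims,
        "kw_type1_rate": kw / n_sims,
        "binomial_type1_rate": binom / n_sims,
        "n": n_sims,
    }


def mwu_enumeration_agreement(max_n: int = 6, seed: int = 0) -> dict:
    """Exact Mann-Whitney p vs full enumeration for tie-free samples."""
    rng = np.random.default_rng(_sub_seed(seed, 5))
    checked = agree = 0
    for n in range(2, max_n + 1):
        for _ in range(10):
            pooled = rng.choice(10_000, size=2 * n, replace=False).astype(float)
            a, b = pooled[:n], pooled[n:]
            got = mann_whitney_u(list(a), list(b)).p_raw
            # enumerate all rank assignments
            ranks = stats.rankdata(np.concatenate([a, b]))
            u_obs = ranks[:n].sum() - n * (n + 1) / 2
            us = np.array(
                [sum(c) - n * (n + 1) / 2 for c in itertools.combinations(range(1, 2 * n + 1), n)]
            )
            expected = min(1.0, 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs)))
            agree += abs(got - expected) < 1e-12
            checked += 1
    return {"agreement_rate": agree / checked, "n": checked}


def binomial_tail_agreement(max_n: int = 10, seed: int = 0) -> dict:
    """Exact binomial tails vs closed-form pmf sums for n <= 10."""
    from math import comb

    rng = np.random.default_rng(_sub_seed(seed, 6))
    checked = agree = 0
    for n in range(1, max_n + 1):
        for k in range(n + 1):
            p0 = float(rng.uniform(0.05, 0.95))
            pmf = [comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(n + 1)]
            expected = min(1.0, 2 * min(sum(pmf[: k + 1]), sum(pmf[k:])))
            agree += abs(binomial_vs_proportion(k, n, p0) - expected) < 1e-9
            checked += 1
    return {"agreement_rate": agree / checked, "n": checked}


# -------------------------------------------------------------- i/o integrity

def io_roundtrip_study(seed: int = 0, workdir: str | Path | None = None) -> dict:
    """Write->read losslessness in both dialects plus seed determinism."""
    with tempfile.TemporaryDirectory() as tmp:
        base = Path(workdir) if workdir else Path(tmp)
        params = SimulationParams(rng_seed=_sub_seed(seed, 7), n_flies_per_group=8, n_days=1)
        traces, _, _ = simulate_experiment(params)
        dam_path = base / "monitor_rt.txt"
        write_dam_monitor(traces, dam_path)
        back = read_dam_monitor(dam_path, channel_map=[t.fly_id for t in traces] + [f"pad{i}" for i in range(32 - len(traces))])
        dam_ok = all(
            np.array_equal(a.values, b.values) and a.fly_id == b.fly_id
            for a, b in zip(traces, back)
        )
        dparams = SimulationParams(
            rng_seed=_sub_seed(seed, 8), n_flies_per_group=3, modality="DART"
        )
        dtraces, _, _ = simulate_experiment(dparams)
        dart_path = base / "dart_rt.csv"
        write_dart_velocity(dtraces, dart_path)
        dback = read_dart_velocity(dart_path)
        dart_ok = all(
            np.allclose(a.values, b.values) and a.fly_id == b.fly_id
            for a, b in zip(dtraces, dback)
        )
        cparams = SimulationParams(rng_seed=_sub_seed(seed, 9), n_flies_per_group=4)
        w1 = simulate_cohort(cparams, base / "c1")
        w2 = simulate_cohort(cparams, base / "c2")
        identical = all(
            f1.read_bytes() == f2.read_bytes()
            for f1, f2 in zip(sum(w1.values(), []), sum(w2.values(), []))
        )
    return {
        "dam_roundtrip_lossless": float(dam_ok),
        "dart_roundtrip_lossless": float(dart_ok),
        "seed_determinism": float(identical),
        "n": len(traces) + len(dtraces),
    }
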
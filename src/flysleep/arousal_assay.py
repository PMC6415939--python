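"""Vibration-startle arousal-threshold assay.

The assay probes how deeply flies sleep: at a scheduled time a vibration
stimulus (by default five 200 ms, 50 Hz pulses with 800 ms gaps) is
delivered, flies that had been immobile for the full five minutes before
the stimulus are selected as "sleeping", and each selected fly is scored in
a binary manner — responder if any supra-threshold movement starts within
the response window after the stimulus.  Group responder proportions are
compared with an exact binomial test, Bonferroni-corrected over the
requested comparison family.

The binomial comparison tests group A's responder count against a null
proportion equal to group B's *observed* proportion; two-sided p is twice
the smaller exact tail, capped at 1.  Fisher's exact test on the 2x2 table
is reported alongside as an alternative construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ActivityTrace, ArousalResult, StimulusEvent
from .sleep_scoring import DART_DISTANCE_THRESHOLD_MM, inactivity_series

__all__ = [
    "select_asleep_at_stimulus",
    "classify_startle",
    "arousal_summary",
    "binomial_vs_proportion",
    "compare_arousal",
]

#: groups with fewer sleeping flies than this are flagged in summaries
MIN_GROUP_N = 10


def _stim_offset_seconds(trace: ActivityTrace, stimulus: StimulusEvent) -> float:
    return (stimulus.time - trace.start_time).total_seconds()


def select_asleep_at_stimulus(
    traces: Iterable[ActivityTrace],
    stimulus: StimulusEvent,
    immobility_window_min: int = 5,
    distance_threshold_mm: float = DART_DISTANCE_THRESHOLD_MM,
) -> list[str]:
    """Fly ids immobile for every minute of the pre-stimulus window.

    The window is the ``immobility_window_min`` whole minutes ending at the
    minute containing the stimulus.
    """
    selected = []
    for trace in traces:
        off = _stim_offset_seconds(trace, stimulus)
        stim_min = int(off // 60)
        lo = stim_min - immobility_window_min
        if lo < 0 or off < 0:
            raise ValueError(
                f"pre-stimulus window starts before the recording for fly {trace.fly_id}"
            )
        inactive = inactivity_series(trace, distance_threshold_mm)
        if stim_min > inactive.size:
            raise ValueError(f"stimulus falls outside the recording for fly {trace.fly_id}")
        if np.all(inactive[lo:stim_min]):
            selected.append(trace.fly_id)
    return selected


def classify_startle(
    trace: ActivityTrace,
    stimulus: StimulusEvent,
    response_window_s: int = 60,
    distance_threshold_mm: float = DART_DISTANCE_THRESHOLD_MM,
) -> bool:
    """Binary startle call: did movement start within the response window?

    A responder has at least one active bin (DART distance >= threshold, or
    DAM count > 0) whose onset lies in ``(stimulus, stimulus +
    response_window_s]``.
    """
    off = _stim_offset_seconds(trace, stimulus)
    end = off + response_window_s
    if end > trace.n_bins * trace.bin_seconds:
        raise ValueError(
            f"response window extends past the recording for fly {trace.fly_id}"
        )
    onsets = np.arange(trace.n_bins) * trace.bin_seconds
    in_window = (onsets > off) & (onsets <= end)
    if trace.modality == "DAM":
        active = trace.values > 0
    else:
        active = trace.values >= distance_threshold_mm
    return bool(np.any(active & in_window))


def arousal_summary(
    group_id: str, responses: Sequence[bool], min_group_n: int = MIN_GROUP_N
) -> ArousalResult:
    """Tally responders among the sleeping flies of one group."""
    responses = list(responses)
    if not responses:
        raise ValueError(f"group {group_id!r} has no sleeping flies")
    return ArousalResult(
        group_id=group_id,
        n_sleeping=len(responses),
        n_responding=int(sum(bool(r) for r in responses)),
        low_n_flag=len(responses) < min_group_n,
    )


def binomial_vs_proportion(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value of count k/n against null p0.

    Two-sided by doubling the smaller exact tail, capped at 1.  Degenerate
    nulls are handled exactly: under p0 = 0 any k > 0 has probability 0
    (p = 0), and symmetrically for p0 = 1.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("null proportion must lie in [0, 1]")
    if p0 == 0.0:
        return 1.0 if k == 0 else 0.0
    if p0 == 1.0:
        return 1.0 if k == n else 0.0
    lower = stats.binom.cdf(k, n, p0)  # P(K <= k)
    upper = stats.binom.sf(k - 1, n, p0)  # P(K >= k)
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass(frozen=True)
class ArousalComparison:
    group_a: str
    group_b: str
    n_a: int
    k_a: int
    null_proportion: float
    p_binomial: float
    p_binomial_adj: float
    p_fisher: float
    p_fisher_adj: float


def compare_arousal(
    results: Sequence[ArousalResult] | Mapping[str, ArousalResult],
    comparisons: Sequence[tuple[str, str]],
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Pairwise responder-proportion comparisons with Bonferroni correction.

    For each (A, B) pair, group A's responder count is tested against a
    null proportion equal to group B's observed proportion (exact binomial,
    doubling rule); Fisher's exact test of the 2x2 responder table is
    reported side by side.  Adjusted p-values multiply by the number of
    requested comparisons, capped at 1.  Note the binomial construction is
    not symmetric in (A, B); Fisher's is.
    """
    if correction != "bonferroni":
        raise ValueError(f"unsupported correction {correction!r}")
    if isinstance(results, Mapping):
        by_id = dict(results)
    else:
        by_id = {r.group_id: r for r in results}
    m = len(comparisons)
    if m == 0:
        raise ValueError("no comparisons requested")
    rows = []
    for a_id, b_id in comparisons:
        a, b = by_id[a_id], by_id[b_id]
        p_bin = binomial_vs_proportion(a.n_responding, a.n_sleeping, b.proportion)
        table = [
            [a.n_responding, a.n_sleeping - a.n_responding],
            [b.n_responding, b.n_sleeping - b.n_responding],
        ]
        _, p_fis = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            ArousalComparison(
                group_a=a_id,
                group_b=b_id,
                n_a=a.n_sleeping,
                k_a=a.n_responding,
                null_proportion=b.proportion,
                p_binomial=p_bin,
                p_binomial_adj=min(1.0, p_bin * m),
                p_fisher=float(p_fis),
                p_fisher_adj=min(1.0, float(p_fis) * m),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
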
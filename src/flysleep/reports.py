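"""Tabular report builders: per-fly metrics, bout, rhythm and stats tables."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import PhaseAnnotation, RhythmResult, SleepBout, SleepMetrics
from .group_stats import GroupComparison


def metrics_table(metrics: Iterable[SleepMetrics]) -> pd.DataFrame:
    """One row per fly x day with all sleep metrics (profile as 48 columns)."""
    rows = []
    for m in metrics:
        row = {
            "fly_id": m.fly_id,
            "day_index": m.day_index,
            "day_sleep_min": m.day_sleep_min,
            "night_sleep_min": m.night_sleep_min,
            "total_sleep_min": m.total_sleep_min,
            "bout_count_day": m.bout_count_day,
            "bout_count_night": m.bout_count_night,
            "mean_bout_length_min": float(np.mean(m.bout_lengths_min)) if m.bout_lengths_min else 0.0,
            "mean_waking_velocity_mm_s": m.mean_waking_velocity_mm_s,
        }
        row.update({f"profile_zt{k * 0.5:04.1f}": v for k, v in enumerate(m.profile_30min)})
        rows.append(row)
    return pd.DataFrame(rows)


def bout_table(
    fly_id: str, bouts: Sequence[SleepBout], annotation: PhaseAnnotation
) -> pd.DataFrame:
    """Long-format bout table with onset/offset in ZT hours."""
    zt = np.asarray(annotation.zt_hours)
    rows = [
        {
            "fly_id": fly_id,
            "onset_zt": float(zt[b.onset_bin]),
            "offset_zt": float(zt[min(b.offset_bin, len(zt) - 1)]),
            "duration_min": b.duration_min,
            "phase_at_onset": str(annotation.phase[b.onset_bin]),
        }
        for b in bouts
    ]
    return pd.DataFrame(rows, columns=["fly_id", "onset_zt", "offset_zt", "duration_min", "phase_at_onset"])


def rhythm_table(results: Iterable[RhythmResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fly_id": r.fly_id,
                "rhythmicity_index": r.rhythmicity_index,
                "rhythmic_statistic": r.rhythmic_statistic,
                "period_hours": r.period_hours,
                "is_rhythmic": r.is_rhythmic,
            }
            for r in results
        ]
    )


def stats_table(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    """Statistics report with the legend-style significance stars."""
    return pd.DataFrame(
        [
            {
                "test": c.test_name,
                "comparison": " vs ".join(c.comparison),
                "statistic": c.statistic,
                "p_raw": c.p_raw,
                "p_adjusted": c.p_adjusted,
                "stars": c.stars,
                "n": "/".join(map(str, c.n_per_group)),
            }
            for c in comparisons
        ]
    )
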
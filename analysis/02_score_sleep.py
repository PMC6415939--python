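#!/usr/bin/env python
"""Score sleep from the simulated recordings through the full I/O path.

Reads the DAM monitor files written by 01_simulate_cohort.py, excludes dead
flies, scores sleep bouts (>= 5 min of inactivity) on the final recorded
day, and writes the per-fly metrics and long-format bout tables.
"""

from pathlib import Path

import pandas as pd

from flysleep.io_formats import annotate_phase, flag_dead_flies, read_dam_monitor
from flysleep.sleep_scoring import detect_bouts, inactivity_series, sleep_metrics
from flysleep.reports import bout_table, metrics_table
from flysleep.synthetic_data import default_regime_8L16D

BASE = Path(__file__).resolve().parent.parent / "results"
COHORT = BASE / "cohort"
ANALYSIS_DAY = 3  # the third day of the regime

regime = default_regime_8L16D()
channel_map = pd.read_csv(COHORT / "channel_map.csv")
all_metrics, bout_frames = [], []
for monitor in sorted(COHORT.glob("Monitor*.txt")):
    loaded = channel_map[channel_map.monitor_file == monitor.name]
    ids = dict(zip(loaded.channel, loaded.fly_id))
    traces = read_dam_monitor(monitor, channel_map=ids)
    traces = [t for t in traces if t.fly_id in set(loaded.fly_id)]  # drop padded channels
    dead = flag_dead_flies(traces)
    traces = [t for t in traces if not dead[t.fly_id]]
    for t in traces:
        ann = annotate_phase(t, regime)
        bouts = detect_bouts(inactivity_series(t))
        all_metrics.append(sleep_metrics(bouts, ann, ANALYSIS_DAY, fly_id=t.fly_id))
        bout_frames.append(bout_table(t.fly_id, bouts, ann))

mt = metrics_table(all_metrics)
mt.to_csv(BASE / "sleep_metrics.csv", index=False)
pd.concat(bout_frames, ignore_index=True).to_csv(BASE / "sleep_bouts.csv", index=False)

print(f"scored {len(mt)} flies on day {ANALYSIS_DAY}")
print(
    mt[["day_sleep_min", "night_sleep_min", "total_sleep_min"]]
    .describe()
    .loc[["mean", "50%"]]
    .round(1)
)
print(f"tables: {BASE/'sleep_metrics.csv'}, {BASE/'sleep_bouts.csv'}")
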
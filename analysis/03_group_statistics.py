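#!/usr/bin/env python
"""Compare day and night sleep across genotypes.

Kruskal-Wallis omnibus with Dunn's post-hoc (experimental vs each control,
Bonferroni over the two requested pairs), mirroring how knockdown sleep
phenotypes are reported.  Writes results/sleep_stats.csv.
"""

from pathlib import Path

import pandas as pd

from flysleep.group_stats import kruskal_wallis_dunn
from flysleep.reports import stats_table

BASE = Path(__file__).resolve().parent.parent / "results"

metrics = pd.read_csv(BASE / "sleep_metrics.csv")
metrics["group"] = metrics.fly_id.str.rsplit("_", n=1).str[0]
comparisons = [("kd", "driver-ctrl"), ("kd", "rnai-ctrl")]

rows = []
for phase, col in (("day", "day_sleep_min"), ("night", "night_sleep_min")):
    groups = {g: sub[col].to_list() for g, sub in metrics.groupby("group")}
    omnibus, posthoc = kruskal_wallis_dunn(groups, comparisons)
    print(f"{phase} sleep: KW H = {omnibus.statistic:.2f}, p = {omnibus.p_raw:.2g}")
    for c in posthoc:
        print(
            f"  {c.comparison[0]} vs {c.comparison[1]}: z = {c.statistic:.2f}, "
            f"adjusted p = {c.p_adjusted:.2g} {c.stars}"
        )
    tab = stats_table([omnibus, *posthoc])
    tab.insert(0, "phase", phase)
    rows.append(tab)

medians = metrics.groupby("group")[["day_sleep_min", "night_sleep_min"]].median()
print("\ngroup medians (min):")
print(medians.round(0))

pd.concat(rows, ignore_index=True).to_csv(BASE / "sleep_stats.csv", index=False)
print(f"\ntable: {BASE/'sleep_stats.csv'}")
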
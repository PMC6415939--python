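#!/usr/bin/env python
"""Simulate the baseline experiment: three genotypes under 8L:16D.

Generates a cohort mirroring the knockdown design — two control groups and
one experimental group with a 30% night-sleep reduction — and writes the
native-format recordings (DAM monitor files), the experiment config and the
per-fly ground truth under results/cohort/.
"""

from pathlib import Path

from flysleep.synthetic_data import GroupSpec, SimulationParams, simulate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20180101

params = SimulationParams(
    rng_seed=SEED,
    n_flies_per_group=40,
    n_days=3,
    groups=(
        GroupSpec(id="driver-ctrl"),
        GroupSpec(id="rnai-ctrl"),
        GroupSpec(id="kd", night_sleep_reduction_fraction=0.3),
    ),
)

written = simulate_cohort(params, OUT)
n_files = sum(len(v) for v in written.values())
print(f"wrote {n_files} files to {OUT}")
for kind, paths in written.items():
    for p in paths:
        print(f"  [{kind}] {p.name}")
print(
    f"cohort: {len(params.groups)} groups x {params.n_flies_per_group} flies x "
    f"{params.n_days} days under 8L:16D; experimental night-sleep reduction 30%"
)
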
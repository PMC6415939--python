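# flysleep

Sleep, arousal and circadian-rhythmicity analysis for *Drosophila*
locomotor recordings, built as a tested, reusable pipeline with a synthetic
cohort generator so every stage can be validated end to end without raw
recordings.

## Who this is for

Fly sleep labs score sleep from two kinds of recordings: **DAM** monitors
(TriKinetics infrared beam-break counters, one count column per tube, one
row per minute) and **DART**-style video tracking (distance moved in mm per
short window, canonically 5 s). This package ingests both, applies the
field-standard sleep definition, and runs the downstream analyses those
recordings feed: day/night sleep partitioning under arbitrary photoperiods,
a vibration-startle arousal-threshold assay, an autocorrelogram rhythmicity
statistic for free-running conditions, and the nonparametric group
statistics used to compare genotypes.

## The definitions and statistics at its core

* **Sleep bout** — ≥ 5 consecutive minutes of inactivity, where a DAM
  minute is inactive iff it records zero beam crosses and a DART minute is
  inactive iff every 5-s window moved < 3 mm (strict). Runs shorter than
  5 min contribute no sleep.
* **Day/night partition** — Zeitgeber Time (ZT) from lights-on; day is
  [ZT0, ZT *L*) under an *L*L:(24−*L*)D cycle; under DD/LL, subjective
  phase is anchored to the prior entrainment. Bout minutes are attributed
  to phases minute-by-minute; bout counts follow the onset phase.
* **Arousal threshold** — flies immobile for the 5 min before a vibration
  stimulus (five 200 ms, 50 Hz pulses, 800 ms gaps) are "sleeping"; a
  responder shows movement onset within the response window (default
  60 s). Group proportions are compared with an exact binomial test of one
  group's count against the other's observed proportion (two-sided by
  doubling the smaller tail), Bonferroni-corrected; Fisher's exact test is
  reported alongside.
* **Rhythmicity** — on 30-min binned activity, the rhythmicity index RI is
  the height of the third peak of the normalized autocorrelogram (counting
  the lag-0 maximum as peak 1, so peak 2's lag is the period and peak 3
  sits near twice the period), and the rhythmic statistic is

      RS = RI / (2/√N),

  with N the number of observations; a fly is rhythmic when a period is
  identified and RS ≥ 1.
* **Group statistics** — Mann-Whitney U (exact for small tie-free
  samples), Kruskal-Wallis with Dunn's post-hoc z on pooled tie-corrected
  ranks, Bonferroni over the requested comparison family.

## Worked example

The `analysis/` scripts run a complete simulated experiment; each writes
its tables under `results/`. `01_simulate_cohort.py` generates three
genotypes (two controls, one "knockdown" with a programmed 30% night-sleep
reduction), 40 flies each, three days of 8L:16D, written as native DAM
monitor files. `02_score_sleep.py` reads them back through the parser,
drops dead flies and scores day 3; `03_group_statistics.py` compares the
groups:

```
day sleep: KW H = 2.41, p = 0.3
  kd vs driver-ctrl: z = -0.05, adjusted p = 1 ns
  kd vs rnai-ctrl: z = 1.32, adjusted p = 0.38 ns
night sleep: KW H = 80.22, p = 3.8e-18
  kd vs driver-ctrl: z = -7.25, adjusted p = 8.6e-13 ***
  kd vs rnai-ctrl: z = -8.18, adjusted p = 5.6e-16 ***

group medians (min):
             day_sleep_min  night_sleep_min
driver-ctrl          259.0            691.0
kd                   256.0            486.0
rnai-ctrl            247.0            700.0
```

The knockdown group loses night sleep (486 vs ~695 min median, Dunn
adjusted p < 0.001 against both controls) while day sleep is unchanged —
the night-specific phenotype the simulation programs. `04_arousal_assay.py`
runs the startle assay closed loop (controls respond 0.8 by day / 0.3 by
night, mutants 0.8 at both times):

```
ctrl@ZT4: 22/26 responding (85%)
ctrl@ZT16: 10/45 responding (22%)
mut@ZT4: 21/25 responding (84%)
mut@ZT16: 32/39 responding (82%)
```

with the mutant-vs-control difference significant at ZT16 and not at ZT4.
`05_rhythmicity.py` analyzes a free-running DD cohort (programmed 23.5-h
period, one entrained day excluded) and an LL cohort:

```
DD (free-running): 100% rhythmic, median period 23.48 h (programmed 23.5 h)
LL (constant light): 0% rhythmic (no periods identified)
```

## Layout

```
src/flysleep/      library: io_formats, sleep_scoring, arousal_assay,
                   rhythmicity, group_stats, synthetic_data, validation
analysis/          numbered driver scripts (simulate → score → compare)
tests/             pytest suite (unit, property and end-to-end tests)
scripts/           acceptance.py
docs/methods.md    model, parameters and design notes
```
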
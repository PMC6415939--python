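# Methods

## Scope and data model

The pipeline operates on per-fly activity time series from two
acquisition modalities: DAM beam-cross counts (1-min bins, integers) and
DART video-tracking distances (mm per 5-s window). Both are carried as
`ActivityTrace` objects on a uniform time grid; a `LightRegime` maps
calendar time to Zeitgeber/Circadian Time and a day/night phase. All
sleep scoring happens on a per-minute inactivity series so the two
modalities share one downstream path.

## Sleep scoring

A minute is inactive iff it records zero beam crosses (DAM) or every
constituent 5-s window moved strictly less than 3 mm (DART; a window at
exactly 3.0 mm counts as movement). A sleep bout is a maximal run of at
least 5 inactive minutes; shorter runs contribute no sleep. Design
choices where the convention is genuinely open:

* **DART minute aggregation.** The bout definition concatenates sixty
  5-s judgments; we call a minute inactive only if *all* its windows are
  sub-threshold. This is the strictest composition and the one that makes
  DAM and DART minutes commensurable.
* **Phase boundaries.** Half-open: day = [ZT0, ZT *L*), bins labeled by
  start time. Bouts spanning lights-off are split minute-by-minute for
  sleep totals (preserving day + night = total exactly) but counted once,
  in the phase of their onset.
* **Window truncation.** A bout clipped by the analysis-day boundary is
  counted only if its within-window run still reaches 5 min, so short
  analysis windows are not dominated by censoring artifacts.
* **Dead flies.** A fly whose activity is zero from some point through
  the end of the recording for ≥ 24 h (configurable) is excluded
  entirely; the recordings give no principled way to keep its pre-death
  days without biasing group means.
* **Analysis day.** Experiments conventionally analyze the third day of
  a regime (config default); the simulation drivers score the last
  simulated day.

The daily profile is minutes asleep per 30-min ZT bin (48 bins); waking
velocity (DART only) averages mm/s over minutes outside any bout, with
bins in which a fly never wakes flagged undefined rather than zero.

## Arousal assay

Flies whose inactivity series is inactive for every one of the 5 whole
minutes preceding the stimulus are "sleeping"; a responder has an active
bin whose onset lies in (stimulus, stimulus + window]. The window default
is 60 s (configurable to 300 s, the span over which responses are usually
plotted); the classification is monotone in the window by construction.

The named comparison, "binomial test with Bonferroni correction", is
underdetermined: we test group A's responder count against a null
proportion equal to group B's *observed* proportion, two-sided by
doubling the smaller exact tail (capped at 1), Bonferroni over the
user-supplied comparison list. This construction is asymmetric in (A, B)
and anti-conservative, because it treats B's proportion as known: at
n = 30 per group and a true shared proportion of 0.8 its exact type-I
error is 0.090 rather than 0.05 (computable by direct enumeration over
both binomials). Fisher's exact test on the 2×2 table — symmetric and
correctly calibrated — is always reported alongside. Against its own
fixed null the doubled-tail binomial is exact and conservative (size
0.043 at n = 30, p₀ = 0.5).

## Rhythmicity

Activity is summed into 30-min bins (N, the number of observations, is
counted at this sampling) and the normalized autocorrelogram computed to
a 72-h maximum lag after mean subtraction. We use the classic biased
(1/N) normalization: its null variance ≈ 1/N is what the 95% confidence
bound 2/√N presumes. It carries a (1 − k/N) taper, so a pure 24-h
sinusoid over 10 days peaks at ≈ 0.9 at lag 24 h, not 1.0; the tests
assert against the taper-corrected closed form.

Peaks are local maxima of a boxcar-smoothed copy (2-h window), at least
the minimum period (14 h) apart, ties toward smaller lags; the lag-0
maximum is peak 1. Peak 2's lag — refined by parabolic interpolation for
sub-bin resolution — is the period estimate and must lie in [14, 34] h;
peak 3 must fall within ±20% of twice the period (harmonic consistency)
and supplies RI, read from the *raw* coefficients. A period counts as
identified only when the period peak itself clears the 2/√N band —
without this gate, peak selection alone lets ~9% of white-noise flies
through with RS ≥ 1; with it, specificity on constant-rate Poisson noise
is effectively complete while sensitivity on modulated flies is
unaffected. RS = RI·√N/2; rhythmic ⇔ period identified and RS ≥ 1.
Constant (zero-variance) series are returned arrhythmic with RI = RS = 0.
The standard free-running protocol (one 12L:12D day then eleven DD days)
is analyzed with the entrained day excluded (`skip_initial_hours=24`).

## Group statistics

Mann-Whitney U uses the exact null for pooled n ≤ 16 without ties, else
the tie-corrected normal approximation with continuity correction.
Kruskal-Wallis uses the tie-corrected H against χ²; Dunn's post-hoc z is
computed on pooled ranks with the tie term Σ(t³−t)/(12(N−1)), Bonferroni
over only the requested pairs (experimental vs each control by default),
since that is the family experimenters report. Stars: * < 0.05,
** < 0.01, *** < 0.001.

## Synthetic cohorts

Each virtual fly alternates wake and sleep as a two-state
alternating-renewal process with phase-specific parameters; bout
durations are discrete log-normal (log-sd 0.5, minimum 1 min). Baseline
targets under 8L:16D: 700 min night sleep (of 960), 250 min day sleep
(of 480), night bout median 45 min, day 20 min — consolidated night
sleep with crepuscular activity peaks, the standard wild-type pattern.
Every phase segment is simulated after a 24-h virtual burn-in with that
phase's parameters, so the process enters each segment in its stationary
regime and the expected asleep fraction equals the programmed value
essentially exactly; with these bout medians the probability of a
sub-5-min sleep bout is ≲ 10⁻³, so the ≥5-min censoring bias on mean
sleep is negligible (< 0.1%).

A programmed night-sleep reduction r rescales the night stationary
asleep fraction to (1−r)× baseline, implemented as shorter night bouts
(median × √(1−r)) with correspondingly longer/more frequent awakenings —
fragmentation plus loss, not a uniform dilation. Wake minutes emit 1 +
Poisson counts with a sinusoidally bumped rate (peaks at lights-on and
lights-off), or DART gamma distances with at least one window forced
supra-threshold — a waking minute is by definition a moving minute, which
makes scheduled and pipeline-scored sleep agree exactly and is the basis
of the closed-loop tests. Sleep minutes emit zeros (DAM) or sub-threshold
jitter (DART). Under DD the subjective day repeats with the programmed
free-running period; under LL the phase structure and modulation are
abolished, yielding behaviorally arrhythmic flies. Startle responses are
injected as Bernoulli draws for flies genuinely asleep through the
pre-stimulus window; responders get a movement burst with onset inside
the response window, non-responders are held immobile through it, and
every draw is recorded as ground truth.

What the generator does *not* emulate: positional information, bout-level
temporal correlations beyond the renewal structure, homeostatic rebound
after deprivation, inter-fly variability in baseline parameters, and
sensor artifacts other than the dropout/error rows the parser tests
construct. Passing closed-loop tests therefore demonstrates correctness
of the scoring/statistics machinery under the stated behavioral model,
not robustness to every pathology of real recordings.

## Validation studies and problem sizes

`flysleep.validation` (driven by `tests/test_acceptance.py` and
`scripts/acceptance.py`) uses: exhaustive bout enumeration over all 4096
length-12 binary strings at thresholds 1–6; 500 flies for conservation;
100 rhythmic + 100 noise flies (10 days, 1-min bins, 30-min analysis
bins) for rhythmicity; 100 replicate experiments of 3 × 40 flies for
effect recovery; 100 replicate startle experiments with cohorts of 60
flies per group capped at 30 sleeping flies per time point; 1000
simulations at n = 30 for type-I calibration (binomial null p₀ = 0.5,
where the doubled-tail test's exact size is 0.043). These sizes make each
study's Monte-Carlo error small relative to the property being asserted.

A calibration note on the startle closed loop: with the
comparator-proportion binomial prescribed above, the exact probability
that one replicate detects the night difference (0.8 vs 0.3) and not the
day difference (0.8 vs 0.8) at n = 30/30 with Bonferroni m = 2 is 0.904
(= 0.993 power × (1 − 0.090) type-I). A 100-replicate run therefore
hovers at the 90% mark by construction; the per-component rates (night
detection ≈ 0.99, day false-positive ≈ 0.09) are the stable quantities.
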
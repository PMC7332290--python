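# Methods

`mesocage` re-creates, in software, the data flow of an automated home-cage
in which group-housed mice voluntarily head-fix themselves under a
mesoscale imaging camera and perform a vibration-cued go/no-go licking
task. Everything the physical cage prints to its text logs — entries,
licks, fixations, LED marks, cues, outcomes — is modelled, so the entire
analysis chain can be exercised and validated against ground truth without
hardware or data downloads.

## Event logs and sessions

The native log dialect is one record per line,
`timestamp<TAB>tag<TAB>event<TAB>payload`, with timestamps as unix-style
seconds printed with shortest-round-trip float formatting so a
write→read→write cycle is byte-identical. The event vocabulary is closed
(entry, exit, lick, fix_loose/fix_tight/fix_release, reward_entrance,
reward_task, cue_go/cue_nogo, tone_feedback, BrainLEDON/BrainLEDOFF,
outcome, weight, alert). Deposited archives use a different layout; a
pluggable `Dialect` (delimiter, field order, event-name map) adapts them,
and must be calibrated against the archive itself since its exact line
format is not standardized.

Session parsing turns the stream into `HeadfixSession` objects: every
fixation…release pair of one tag is a fixed session; a beam-break episode
that switches the imaging LED on without fixation is a no-fix session
running from LED-on to exit (the boundary for no-fix sessions is a
package convention — the episode has no mechanical start marker). A
fixation with no release before the visit ends is retained and flagged
`truncated` rather than dropped, keeping participation counts
conservative. Licks and trials attach to the unique enclosing session of
the same tag.

The 30 Hz timebase for movies is anchored on the LED on/off events:
`align_timebase` linearly interpolates drifting camera timestamps onto an
exact 30 Hz grid between the marks.

## Task state machine

One chamber visit runs: entry → entrance reward → Bernoulli(`p_fix`)
fixation (never 1.0, as a safety property) → LED on 3 s after fixation →
repeated trials → LED off → release 3 s later → exit. Each trial draws a
lick-withhold interval (base 0.5–2 s plus an exponential jitter of mean
0.5 s — exponential because its memorylessness prevents the mouse from
timing the cue; the distribution is a package choice, only the mean is
prescribed), presents a go or no-go vibration cue, imposes a self-timed
delay (0.3–1.1 s over training), and scores the response:

| first lick            | go   | no-go |
|-----------------------|------|-------|
| within the delay      | −4   | −3    |
| in [delay, delay+1.25]| +2   | −1    |
| none / later          | −2   | +1    |

Boundary conventions (not specified by the protocol, fixed here): a lick
at exactly t = 0 counts as within the delay; ties at `delay` and at
`delay + window` fall into the response window. Rewards for +2 are
delivered at `delay + response_window` after the cue; the last trial of a
fixation is allowed to finish. Early licks (and sub-1 s inter-lick
intervals in the lick-suppression stage) trigger a feedback tone. Daily
advancement raises the delay by 50–100 ms toward a 1.1 s cap and the
withhold base toward 2 s. The 15 % weight-loss supplementation rule is a
pure function: flag when weight ≤ 0.85 × baseline (mice must stay *above*
the limit, so the boundary itself is flagged).

## Synthetic colony

`simulate_colony` is the study-conditions generator, not a tuning knob.
Chamber-entry bursts follow an inhomogeneous Poisson process with a
two-level day/night intensity (lights on 07:00, 12 h cycle) whose 24 h
mean matches `entry_rate` (default 1.5 entries/h) and whose dark-phase
share matches `night_bias` (default 0.69, the observed nocturnal
fraction). Each burst is a geometric number of back-to-back visits (mean
3) separated by exponential re-entry gaps (mean 8 s), reproducing the
short same-mouse re-fixation mode (< 30 s) seen in real cages.
Participation (default 0.8), hit rate (0.75), false-alarm rate (0.3), and
an early-lick rate (0.1) define the stochastic lick policy; because the
early-lick draw precedes the hit/false-alarm draw, the conditional rates
among scored trials equal the configured values, which is what makes d′
recovery exact in expectation. Sessions are simulated sequentially per
mouse; chamber contention between mice is not modelled (it would only
perturb timing, not counts).

Because sessions arrive in bursts, the sampling variance of colony-level
fractions (e.g. the night fraction) carries a cluster design effect of
E[K²]/E[K] = 5 for the geometric burst size at mean 3; tests use this
corrected standard error rather than the naive binomial one.

## Behavioral statistics

* **KDE clustering** — each headfix start is a unit Gaussian of σ = 50 s
  (the typical duration of one headfix including entry/exit); the summed
  density is thresholded at 5 % of an isolated peak. Analytically the
  isolated peak crosses the threshold at √(2 ln 20) ≈ 2.45 σ and two
  isolated events merge iff their gap is below 2σ√(2 ln 40) ≈ 271.6 s,
  i.e. clusters break after 4–5 min without a headfix. The implementation
  evaluates density only inside inter-event gaps (0.25 s step, 6 σ
  neighborhood) and is tested for exact agreement with a brute-force 1 s
  global grid.
* **d′** — z(hit) − z(FA) with hit = (+2)/((+2)+(−2)) and
  FA = (−1)/((−1)+(+1)); early-lick trials (−4/−3) are excluded because
  they demonstrate detection. Extreme rates are clamped to
  [1/(2n), 1 − 1/(2n)] (the standard correction; the protocol is silent
  on extremes).
* **Intervals** — same-mouse intervals default to release-to-next-start
  gaps (the re-fixation latency, which is what makes the short mode
  visible); start-to-start is selectable. Cross-mouse intervals run from
  each session start to the next start by a different tag. Group
  summaries are means of per-mouse medians.
* **Summary table** — per-day columns divide by days-with-headfixation;
  the go success rate is +2 over all go outcomes in the last 5 days that
  contain headfixed go trials (the denominator convention is a package
  choice); aggregates are the arithmetic mean, the n−1 standard
  deviation, and plain column sums; mice under 20 min total fixation are
  excluded as poor performers.
* **Timing uniformity** — Anderson–Darling on times-of-day; the normal
  reference delegates to scipy, the uniform reference uses the
  fully-specified-distribution A² formula with its case-0 critical
  values.

## Imaging pipeline

Frames are registered by FFT cross-correlation against a reference frame
(integer pixel by default, subpixel optional); shifts estimated on the
green channel are applied to both. dF/F₀ is computed per pixel and per
channel; F₀ defaults to the per-pixel mean over the recording (the
baseline definition is a package choice, recorded in the output;
percentile and pre-trial-window baselines are selectable). Hemodynamic
correction subtracts the blue-reflectance dF/F from the green dF/F with
unit weight — valid because the artifact is multiplicative with equal
fractional amplitude in both channels, which is exactly how the synthetic
generator injects it (smooth two-frequency oscillation, default amplitude
10 % of the peak neural signal, within the < 20 % regime observed with a
440 nm isosbestic reference). The reported blue/green amplitude ratio
uses per-pixel temporal SDs with the fast frame-to-frame noise floor
subtracted, taking the maximum pixel per channel.

With additive sensor noise of SD `noise_sd` per channel, the corrected
signal deviates from the neural truth by independent noise of SD
√2·`noise_sd` per sample; recovery is therefore asserted on the per-pixel
temporal RMS (bounded by 3× the per-sample noise SD), since the maximum
over millions of Gaussian samples necessarily exceeds any fixed multiple
of σ. Noiseless movies recover truth to the second-order
(signal × artifact) floor, below 10⁻³ dF/F.

Seed-pixel maps are plain Pearson correlation images, optionally after
global signal regression (spatial-mean time course projected out of every
pixel; idempotent, with a guarded degenerate branch). Behavioral-video
movement is the mean absolute frame-to-frame difference per ROI, min–max
scaled jointly across ROIs. Trial averaging aligns on cues, requires the
full window inside the recording, and optionally drops trials whose mean
pre-cue movement exceeds 0.4 SD across trials (the low-movement filter
that stabilizes pre-stimulus baselines). Group brain–behavior analysis
z-scores per-mouse trial averages, correlates each mouse's averaged
calcium trace with its own and with every other mouse's averaged
behavior trace, and compares correct vs mismatched pairings with a
Wilcoxon signed-rank test (mice with < 20 trials excluded, ≥ 3 mice
required).

Default geometry: 64×64 pixels over an 8.2×8.2 mm window
(0.128 mm/pixel), bregma at pixel (24, 32), eight bilateral ROIs (ALM,
M2, M1, FL, HL, BC, RS, V1) at approximate dorsal-projection coordinates,
0.7×0.7 mm boxes for region averaging.

## Outcome decoder

Per frame, a ridge model y = β₀ + Xβ (intercept unpenalized, closed-form
solution) predicts +1 correct vs −1 error from the 8 region traces,
z-scored per region over all trials and frames. The penalty λ is chosen
per frame from 25 log-spaced values (10⁻³–10³) by stratified inner CV on
the training folds; accuracy is the held-out sign agreement averaged over
repeated stratified 3-fold CV (50 runs at full scale). Ties in λ
selection break toward the stronger penalty; ŷ = 0 classifies as +1.
Region contributions come from reduced models: −region permutes one
region's trial assignment (consistently across frames), +region permutes
all others; importance is the drop in maximum accuracy relative to the
full model (maximum over frames of the run-averaged accuracy). A
label-permutation null calibrates chance at the majority-class rate.
The λ-path is computed through one eigendecomposition of XᵀX per training
set, which keeps the per-frame × runs × folds × λ-grid sweep cheap.

## Problem sizes

Config defaults keep the full protocol (50 CV runs, 1000 permutation
iterations); the shipped tests and the acceptance script run the same
code at smaller, explicitly-passed scales chosen as the package's
standard desk-scale analysis: colonies of 2–8 mice over 1–14 days,
12-trial synthetic movies at 64×64×30 Hz, decoders with 2–6 runs and
3–6 permutation iterations on 120 trials. d′ recovery uses 500-trial
grids (3 SE tolerance) plus a 40 000-trial run against the normal-quantile
oracle.

## What the generators do and do not emulate

The synthetic colony reproduces clustered, diurnally biased entries,
participation heterogeneity, and stage-dependent lick policies, but not
social interaction at the chamber, satiety dynamics, or drift in
motivation across weeks. The synthetic movie reproduces epoch-locked
regional transients (single-exponential calcium kernel, τ = 1 s,
GCaMP6s-like; a stand-in, not a fitted indicator model), a shared
multiplicative hemodynamic component, and additive sensor noise — but not
vascular spatial structure, wavelength-dependent path-length effects,
photobleaching, or true behavioral video (ROI movement traces are
generated directly). Passing tests therefore demonstrate correctness of
the algorithms under the stated model assumptions, not performance on
real recordings; the optional `scripts/archive_stats.py` applies the same
code to a locally downloaded cage archive.

## Known limitations

* Unit-weight reflectance subtraction is exact only when the artifact is
  identical in both channels; a fitted per-pixel weight is left as an
  extension hook.
* The no-fix session boundary and the F₀ definition are package
  conventions; both are recorded in outputs so they can be revisited.
* The KDE cluster oracle equivalence is established for event sets ≤ 50
  and gaps sampled over hours; extremely dense inputs fall back to the
  same gap-wise evaluation but are not separately validated.
* The decoder pools trials across mice into one design; a per-mouse
  option exists but cross-mouse generalization is not measured.
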
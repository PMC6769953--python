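# Methods

This note documents the models, defaults, and design choices behind
`socialgaze`: what the estimators assume, what the synthetic generator does
and does not emulate, and where the design was genuinely open.

## Event classification

Gaze samples arrive at a nominal 60 Hz with per-eye ordinal validity codes
0–4 (0 best). A sample is *usable* when at least one eye is at or below the
validity threshold (default 1) and its coordinates are finite; it is
*invalid* otherwise — the rationale being that the head turns that produce
purposeful gaze aversion lose both eyes at once, so requiring both eyes to
fail before declaring a sample invalid would miss exactly the behaviour of
interest. Events are half-open intervals `[start, end)` in integer
milliseconds; each sample covers the span up to the next sample (the last
extends one median inter-sample interval), which makes the event list tile
the stream span exactly — an invariant asserted in tests.

**I-VT.** Angular velocity between successive *valid* samples is the visual
angle `atan(chord_mm / viewing_distance_mm)` divided by the true elapsed
time, assigned to the later sample. Computing across invalid gaps matters: a
single dropped sample at the moment of a saccade would otherwise hide the
cross-AOI jump and let gap-filling weld two different fixations together
(this failure mode was observed during development on synthetic data and is
covered by a regression-style recovery test). Defaults: velocity threshold
30°/s, minimum fixation 100 ms, gap interpolation up to 75 ms — conventional
values for infant screen data; the upstream literature delegates these to
external classifiers without printing them, so they are explicit, logged
parameters here rather than claims about any particular study.

**Offscreen looks.** A maximal run of invalid samples spanning more than
500 ms is one *offscreen* event. Detection runs before gap-filling so an
aversion can never be interpolated away; gap events overlapping a detected
offscreen run are split at its boundaries. Shorter invalid runs stay gaps.

**Calibration offset.** Infant calibrations drift by a constant translation.
The estimator exploits the moving stimuli: over a bounded coarse-to-fine
grid (±60 px, 4 px then 1 px steps) it minimises the mean distance from
fixation centroids to the nearest time-matched AOI centre. It is
deterministic, translation-equivariant (tested), and recovers injected
offsets within ±3 px on synthetic streams. The returned value is the offset
*present in the data*; correct with its negation.

## AOIs and scanpaths

Characters are ellipse AOIs (~110 × 140 px) with 20 px padding per side
(≈ the 40–50 px one-degree margin across both supported geometries:
17″ 1280×1024 and 23″ 1920×1080 at 550 mm viewing distance), keyframed and
linearly interpolated over time. Fixations are attributed by hit-testing the
centroid at the fixation's temporal midpoint — robust to edge jitter and
cheaper than per-sample majority voting; overlapping padded shapes resolve
to the nearest centre. Consecutive same-AOI fixations collapse into visits;
offscreen events become visits to a virtual `Offscreen` AOI; fixations on no
AOI are counted but emit no visit.

Pattern templates over visits come in two flavours: *ordered* templates
match as leftmost, non-overlapping subsequences whose first and last matched
visits start within `max_span_ms` (default 4,000 ms — the A→B→A synchrony
patterns of interest play out within a few seconds; the source material
gives event-relative timeframes, not a number, so this is a declared
operationalisation); *unordered* templates match when every step set is
visited inside a time window. The matcher is verified against exhaustive
subsequence enumeration on short sequences. "Group" steps accept any of
gatekeeper and the two other group members.

The offscreen-aversion contingency is the count of offscreen visits whose
immediately preceding visit was on a given AOI (the gatekeeper), per trial;
the between-condition comparison is the ratio of these rates, flagged
undefined (NaN) rather than raised when the divisor is zero.

## Transition matrices and entropy

Transition counts are over adjacent visit pairs; collapsing makes the
diagonal structurally zero, which is worth stating because it lowers entropy
relative to sample-level matrices. Pooling trials sums counts without
bridging the last visit of one trial to the first of the next. The on-screen
analysis removes `Offscreen` visits first and re-collapses, so an
A → offscreen → A excursion contributes no transition; the aversion analysis
includes them by flag.

Standardized entropy is the stationary-weighted conditional Shannon entropy
`H = −Σ_i π_i Σ_j p_ij log2 p_ij` normalised by `log2` of the visited-state
count, giving `H_norm ∈ [0, 1]` with 0 for a deterministic cycle and 1 iff
all rows are uniform. The 0–1 standardization is cited in the gaze
literature without a formula; this stationary-weighted definition is the
standard gaze-transition-entropy choice and is stated here explicitly.
`π` solves `πP = π` by power iteration (tolerance 1e-10) on the
visited-state submatrix when that chain is irreducible (checked via strongly
connected components); otherwise — common in short infant trials that wander
off and never return — the weights fall back to empirical visit frequencies,
which is also available as an explicit `weighting="empirical"` variant.
Trials with fewer than two visited states have undefined entropy and are
dropped with a log entry.

## Looking-time metrics

Fixation-duration proportions divide an AOI's in-window fixation time by the
total on-AOI fixation time in the window (fixations straddling the boundary
contribute their in-window part only), removing between-infant differences
in overall attention. Infants with zero on-AOI time in a window are flagged
missing and excluded from group means. Group tables report n, mean, SD and a
normal-approximation 95% CI of the mean.

First looks are sample-level: the earliest valid sample hitting any AOI in
the window wins, so a saccadic sweep counts; the hit is labelled by whether
it falls inside a classified fixation.

VOE looking time starts at the scripted arrival event (24,000 ms into the
test scene). Observation ends at the trial end or at the *onset* of the
third offscreen look after the reference point, whichever is first — the
design allows two looks away; onset rather than offset is used because the
observation window should not include the terminating aversion itself
(the source is silent on this; onset is the declared choice). Offscreen time
inside the span is subtracted and the remainder log-transformed — natural
log by default, base-10 available, as only "log value" is specified
upstream.

## Outcome statistics and inclusion

Two binomial methods are always available and reported side by side: exact
tail sums of the pmf (two-sided = twice the smaller tail, capped at 1) and
the normal approximation with ±0.5 continuity correction. The package
convention — continuity-corrected one-sided for pre-registered directional
predictions, exact two-sided for non-directional controls — is the
combination that reproduces every published p-value computable from printed
counts (0.04, 0.048, 0.415, 0.71, 0.05, 0.65).

Group contrasts use a two-sided permutation test (add-one corrected) and a
percentile bootstrap 95% CI, both reproducible from a recorded seed. These
replace unnamed CI/p machinery and small-sample ANOVA F tests by design:
with per-cell n of 3–12, resampling inference is transparent and valid where
normal-theory assumptions are doubtful. The reported F statistics of the
original analyses are real-data-dependent and out of scope.

The inclusion filter is a pure function of the session record: at least four
familiarization trials, at least two exclusion trials with the critical
event attended, plus coder flags (fussiness, technical error, reach-task
errors, reported colour preference). In the anticipatory-looking design,
missing the test trial's critical window ("no expectation") excludes the
infant from the outcome analysis only; they remain in the gaze analyses.

## Synthetic cohorts

The generator emulates the study conditions, not arbitrary gaze. Scenes are
deterministic scripts: 48 s familiarization scenes at 1280 × 720 with the
scripted event order (group bounce, entry, approach, call-response, push or
ignore at 13 s, retreat, group synchrony), an 8 s two-character end scene,
and a 40 s test scene whose neutral character descends from 6 s and arrives —
with a bell — at 24,000 ms. Event order and timing anchors are fixed;
trajectories between markers are piecewise-linear inventions, since the
original stimulus kinematics are unavailable.

Gaze is a semi-Markov itinerary: visits drawn iid from a per-scene dwell
distribution (iid rather than no-repeat by design — a "never repeat the
previous AOI" kernel would make realised time shares diverge from the dwell
weights, destroying the recovery target), with log-normal durations (median
400 ms, σ = 0.45, clipped to 200–3,000 ms — plausible infant dwells,
declared not derived), 1–3 sample saccade transits, offscreen episodes of
600–1,500 ms with per-visit hazard 0.015 multiplied by 1.8 after a
gatekeeper visit in the explicit condition, AR(1) oculomotor/tracker noise
(sd 6 px, ρ = 0.6 — white noise of realistic amplitude would sit at the I-VT
threshold and shred fixations; correlated noise matches how tracker error
actually behaves), sporadic single-sample dropout (rate 0.01), and an
optional constant calibration offset. Condition dwell profiles are seeded
from the published per-condition means (excluded/gatekeeper 0.439/0.268
implicit, 0.338/0.351 explicit); outcome models use the published
frequencies (choice 0.75/0.77, anticipation to group 0.545/0.727); the
entry synchrony pattern is embedded with probability 0.747. Every stream is
paired with a ground-truth itinerary log, and on noise-free, dropout-free
streams the classify → extract pipeline reproduces that itinerary exactly
(tested).

What the generator does **not** emulate: main-sequence saccade dynamics,
drift and microsaccades, smooth pursuit as a distinct class, per-eye
disparity, luminance-driven pupil artefacts, or systematic condition
differences in data quality. Passing recovery tests therefore shows the
*estimators* are consistent under realistic sampling, noise and dropout —
not that real infant data meets these assumptions.

Two recovery experiments use controlled rather than naturalistic profiles,
because the naturalistic conditions do not identify the parameter:

* **Aversion ratio.** With condition-specific dwell profiles the per-trial
  rate ratio confounds the hazard multiplier with gatekeeper visit
  frequency, so the recovery experiment holds dwell fixed across the two
  simulated groups and varies only the multiplier (1.8 vs 1.0).
* **Synchrony fraction.** Under naturalistic dwell the individual → group →
  individual trigram occurs by chance in almost every 48 s trial, so the
  embedded fraction is recovered under a controlled dwell in which the
  individual character is never visited spontaneously; the pipeline estimate
  is compared against the generator's own bookkeeping of which trials
  contain the pattern.

## Problem sizes and determinism

Test-suite recovery runs use 24–120 simulated trials per experiment and
outcome-model checks of 4,000 draws per condition; the acceptance script
uses 60–200 trials and 5,000 draws, completing in about a minute. These
sizes put the Monte-Carlo standard error of each recovered quantity well
inside the tolerance asserted for it; every tolerance in the tests is stated
as a multiple of that standard error. All randomness flows from explicit
seeds through `numpy.random.SeedSequence` spawning, so cohorts, analyses and
report bundles are bit-reproducible; stochastic inference results record
their seed and replicate count.

## Known limitations

* Eye selection averages the two eyes implicitly by using the combined gaze
  point; per-eye streams are not modelled separately.
* `estimate_offset` assumes a constant translation; rotations, scale errors
  and time-varying drift are out of scope.
* The entropy normaliser uses the visited-state count, so trials visiting
  different numbers of AOIs are compared on slightly different scales; the
  per-trial state count is available in the report for sensitivity checks.
* The pattern matcher's leftmost-greedy, non-overlapping semantics is one of
  several defensible conventions; it is pinned down by the exhaustive-oracle
  test rather than by any external specification.
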
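# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `gazecontrast`. Everything stated here is computed by the
package's test suite or by `scripts/acceptance.py`; nothing is quoted from
external data.

## Data model and canonical frame

All analyses operate on pre-parsed fixation events, not raw gaze samples.
Coordinates are continuous degrees of visual angle in a **canonical face
frame**: origin at the per-face *reference point* — the point equidistant
from the centres of the nearest eye, the nearest half of the nose rectangle
and the nearest half of the mouth rectangle (its y-coordinate is where the
pre-stimulus start dot sits) — with x rightward and y increasing downward.
The reference point is the circumcentre of the three feature centres and is
recomputed per face. Registration from recorded screen coordinates is a
similarity transform (translation + isotropic scale + optional horizontal
mirror); mirroring twice is the identity and the transform is invertible to
1e-9°. Pixelation happens only at density-mapping time, so tracker
resolution and analysis resolution are decoupled. Timing is trial-relative
(stimulus onset = 0 ms).

## Synthetic sessions

The generator emulates a two-phase old/new recognition experiment: a study
phase of two 24-trial blocks (one per presentation time, 1 s or 5 s) and a
test phase of four 24-trial blocks (12 old + 12 new each). The four
study/test block-time orders are counterbalanced across participants;
within each phase, presentation time × start side × face gender is fully
crossed, and an old face reappears on its study-phase side. All randomness
flows from one seed through per-participant substreams, so datasets are
bit-reproducible and invariant to participant order.

**Responses** follow an equal-variance Gaussian signal-detection model:
evidence ~ N(d′, 1) on old trials, N(0, 1) on new trials, response "old"
iff evidence > c + d′/2 — with this threshold parameterization the standard
estimators recover (d′, c) without structural bias. Defaults: short-study
cells (d′ = 1.0, c = 0.25), long-study cells (1.67, 0.0) — a 0.67
discrimination gap and a 0.25 criterion gap by study time, the magnitudes
the analysis chain is designed to detect. Participant-level offsets
(SD 0.3 on d′, 0.15 on c) provide realistic between-subject dispersion.
Reaction times are log-normal (median 1400 ms, σ = 0.3), capped at the 5 s
response window.

**Scan paths.** Each trial has a first-saccade latency (log-normal; study
median 290 ms, test 230 ms, σ = 0.35 — a 60 ms phase step, constant within
phase), a 30 ms saccade transit, and successive fixation durations
(log-normal, σ = 0.55; medians 220 ms for the first fixation, 200 ms
otherwise, 150 ms for the second fixation of 1 s study trials). Fixations
are generated until the trial ends (stimulus offset, or the response in the
test phase); the last one may span the offset and is flagged
`interrupted`. These values were calibrated once so that 1 s study trials
yield ~2.4 uninterrupted fixations and ~12% interrupted second fixations
while 5 s study trials yield essentially none — the regime in which the
interruption-exclusion machinery matters.

**Locations** are drawn from per-(phase × time × ordinal) Gaussian mixtures
anchored to facial features. Defaults: first fixations land just below the
eyes in both phases; second fixations sit slightly eye-ward during study
and shift toward the lower face during test; third-and-later fixations are
markedly more dispersed (SD up to 2.3°, extra mouth weight). The late
dispersion is what makes dwell proportions window-dependent (see AOI
below). A `null_config` collapses every cell to one shared spatial,
temporal and SDT parameterization for calibration runs.

**What the generator does not emulate:** calibration/drift error, saccade
kinematics (amplitude–velocity main sequence), saliency- or
identity-dependent scan paths, within-trial sequential dependencies beyond
the ordinal-group mixtures, and response–gaze coupling. Passing tests
therefore validate the *analysis machinery* under a plausible data model,
not claims about real observers.

## Behavioral scoring

False-alarm rates are paired with their hit rates at the block level: new
faces belong to no study-time condition, so each (study-time × test-time)
cell's FA/CR counts come from the new trials of the same test block(s) that
held the cell's old trials. Rates at 0 or 1 are replaced by 1/(2n) and
1 − 1/(2n) (flags record when this fires); the replacement constant is a
package decision, since only the existence of a correction is prescribed by
the source analyses. d′ and c use the probit transform; requesting them on
uncorrected extreme rates is an error, not a silent fix.

At 12-trial cells the corrected estimator is biased upward: its exact
expectation (binomial enumeration) is 1.075 at true d′ = 1.0 and 1.780 at
true 1.67, because the floor/ceiling replacements overshoot the probit of
moderately extreme rates. The recovery tests therefore assert the
replicate-averaged mean, and single-experiment d′ values should be read
with this bias in mind.

The 2×2 within-subject ANOVA is computed from sums of squares with
participant-interaction error terms; two-level factors need no sphericity
correction, and three-level comparisons are exposed as paired t-tests
instead. Missing cells drop a participant listwise for that test. Paired
t-tests report bias-corrected Hedges' g; one-sample tests report Cohen's d;
zero-variance inputs return an explicit infinite-t flag rather than NaN.

## Density maps and profiles

A condition map is the sum of unit-mass isotropic Gaussian kernels
(σ = 0.26°) at the selected fixations of one ordinal, evaluated
analytically at pixel centres and truncated at 5σ; durations carry no
weight. Default grid: x ∈ [−8, 8]°, y ∈ [−8, 10]° at 0.05°/px, covering a
10°-forehead face with ≥3σ margins; interior kernels conserve mass to
better than 1% at the default resolution (0.01% at 0.01°/px), and off-grid
mass is reported as a clip fraction, never an error. The vertical profile
is the exact row sum of the 2D map. Group averages are means of
per-participant maps with optional scales; a pooled condition with twice
the trials is scaled by ½ so densities stay comparable. Densities are
dimensionless and only interpreted relative to one another.

## Permutation contrasts

Null hypothesis: within each participant, fixation locations of the
analysed ordinal are exchangeable between the contrasted conditions. Since
exactly one ordinal enters a map, fixation-level and trial-level exchange
coincide for this design. Each iteration reassigns every participant's
pooled fixations to the two conditions uniformly at random with counts
preserved, and the scaled group difference map is recomputed. Because the
kernel is separable, each fixation's profile contribution is exactly the
row sum of its 2D kernel patch; both bases receive the same relabelling
coefficients, so profile nulls are identically the horizontal sums of the
2D nulls (asserted in tests by retaining small iteration stacks).

p-values are **directional**: for an observed positive pixel, the fraction
of iterations at least as large; for a negative one, at least as small;
zero observed difference gives p = 1. The estimator is the literal
count/n, floored at 1/n (conservative). Comparisons against the observed
value use a 1e-9 scale-relative tolerance so that exact ties — the identity
relabelling always reproduces the observed map — are counted consistently
regardless of floating-point summation order. A `two_sided` flag doubles
the directional p (capped at 1): under the null the directional p is
uniform on (0, ~0.5) by construction (the direction is chosen by the
observed sign), and only the doubled variant is calibrated against
Uniform(0, 1) — calibration checks must use it.

Significance is Benjamini–Hochberg FDR at q = 0.05 pooled over all pixels
of all maps sharing a `family_id` (Benjamini–Yekutieli by flag). One
master seed drives deterministic per-chunk substreams, making results
reproducible and independent of fixation row order and participant order.
Iterations are streamed in chunks with per-pixel tail counts, so the
default 39,000 iterations never materialize full map stacks; an option
retains stacks for oracle tests. An exact-enumeration oracle exhausts all
within-participant assignments (refusing above 10⁶ combinations) and the
Monte Carlo path matches it to binomial accuracy.

Interpretation note: under a pure location shift, relative differences in
the far low-density tail are large, so minimum-p rows can sit outside the
displayed face region; localization statements are made over rows carrying
at least a few percent of the maximum profile density, which is also the
region profile plots display.

## Temporal dynamics

Latency to first saccade prefers the `saccade_onset_ms` column and falls
back to ordinal-1 start minus the configured mean transit (30 ms) —
fixation-only tables cannot express saccade onset exactly. Outlier
screening flags participants more than 2.5 group SDs (conventional
mean-centred SD) from the group *median*, per condition, in a single pass
(no iterative re-screening). Duration analyses keep a fixation iff
`end ≤ min(presentation window, response time)` and report excluded
fractions per phase × time cell; exclusions weakly increase as the window
shortens. The trial-position series averages latencies across participants
per trial position; block means exclude each block's first trial (task
re-engagement inflates it) and equal the plain mean of the retained trials.

## AOI analysis

AOIs are axis-aligned, half-open rectangles (min edge inside, max edge
outside) drawn per face; left eye, bridge and right eye merge into one
"eyes" region, anything else is "other". Dwell inside an analysis window is
`min(end, window, trial end) − start` for fixations starting inside it;
dwell never extends past stimulus offset or the response. Proportions are
normalized per trial then averaged across trials per participant (default;
pooled-milliseconds by flag — the averaging convention is not dictated by
the source analyses, so both are implemented). Absolute dwell is monotone
in window length; proportions are not — comparing a 5 s window against the
same trials truncated to 1 s flips apparent feature preferences (eyes and
nose down, "other" up), the time-window artefact the truncation contrast
quantifies with paired t-tests per AOI.

## Pipeline, sizes and determinism

`gazecontrast report` (or `pipeline.run_pipeline`) chains simulate →
validate → behavior → temporal → density → permutation battery → AOI and
writes CSV/TSV/JSON/PNG outputs plus a manifest with SHA-256 hashes; reruns
with the same seed are bit-identical for all tables. The shipped contrast
battery mirrors the design's natural comparisons: study vs pooled test
within each time (test scaled ½), short vs long within each phase, the two
crossed phase × time contrasts, and old vs new within test, each family
sharing one FDR correction.

Test-suite problem sizes are chosen for desk-scale runtimes: calibration
uses 16-participant null experiments at 2,000 iterations (50 replicates),
recovery/power use the full 31-participant design (40 and 200 behavioral
replicates), localization uses 20 replicates, and the oracle comparison
uses a 2-participant instance where enumeration (4,900 assignments) is
exact. The full suite runs in a few minutes on one CPU; the acceptance
script in well under a minute.

## Known limitations

* The 2D permutation path holds a dense per-fixation basis and refuses
  grids beyond a memory guard; full-resolution 2D maps at 39,000 iterations
  are out of desk scope (profiles are the primary statistical object).
* The directional p-value is intentionally literal (sign-selected,
  one-sided, count/n with floor); it is anti-conservative by about a factor
  of two if misread as a two-sided p — use `two_sided=True` for calibrated
  error rates.
* Small-cell d′/c estimates carry the floor/ceiling-correction bias
  quantified above; group-level *differences* between cells are much less
  affected.
* The generator's ordinal-group mixtures are stationary within a trial
  beyond the third fixation and ignore inter-fixation correlations.
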
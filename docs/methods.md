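# Methods

## Scope and data model

The package operates on touch-event streams: integer-millisecond
timestamps, device-pixel coordinates (origin top-left, y down), and a phase
per event forming the regular language `(down move* up)*` for a single
pointer. Multi-touch is rejected; the paradigm is single-finger writing.
Sessions whose last event exceeds the 180 s task limit are flagged invalid
and excluded from feature extraction — never truncated — mirroring the
paradigm's exclusion rule. Times are converted to seconds only at the
biomarker boundary; files carry integers so round-trips are bit-exact
(floats are written in shortest-repr form and parsed with round-trip
precision).

## Biomarker definitions and reconciliations

Strokes are the down→up segments; gaps are up→next-down intervals; the
initial pause runs from session start to the first down. The decomposition
`total = initial + Σ durations + Σ gaps` is exact by construction.

Several published formulae for these features are internally inconsistent
(index bounds, a time where a length is required, a max-of-sum with mixed
units). The package follows the verbal definitions and the printed units
throughout:

* total/maximum/average stroke trajectory length are computed over all `J`
  strokes from each stroke's own points;
* per-stroke mean speed is `v_j = D_j / t_j` (0 for zero-duration strokes;
  a zero-duration stroke with positive length is excluded from speed
  statistics and logged);
* all coefficients of variation use the population standard deviation
  (divide by the number of values), matching the gap-variability formula's
  `J − 1` denominator over `J − 1` gaps;
* speed variability is the CV of `{v_j}` about the mean speed;
* the pause count (IPSDB_10) counts maximal runs of consecutive identical
  coordinates within strokes. The raw duplicate-pair definition is
  recovered with `min_pause_ms = 0`; the default threshold of 50 ms
  decouples the count from the device sampling rate (60 Hz here). Run
  durations sit exactly on the threshold for 3-frame runs, so the
  comparison carries a 1 µs guard against float round-off.

Single-stroke sessions have no gaps: the gap statistics are returned as
NaN (flagged missing, never 0) and excluded pairwise downstream.

### Task score (EFDB_1)

The score has two binary components. *Count*: the number of detected
characters equals the required repetitions (10). *Order*: every character
has exactly six strokes and, after similarity-normalizing the character to
the unit box, each stroke's nearest template stroke (mean distance between
16-point arc-length resamplings) is its own rank — i.e. the
nearest-template assignment is the identity permutation. Characters are
detected by scanning strokes in time order and starting a new group when a
stroke's centroid departs from the running group centroid by more than
0.8 × the median glyph width (estimated from stroke extents, then refined
from provisional character boxes). The true clinical rubric is not
recoverable from its description; this rubric is the simplest testable one
with the observed 0/1-valued score medians, and it is isolated behind
`score_task` so it can be swapped.

## Cohort statistics

* **Routing.** Shapiro–Wilk per group at α = 0.05 (a conventional choice
  for n < 50; the source names no normality test). Both arms normal →
  pooled-variance t test, descriptives mean ± SD; otherwise Mann–Whitney,
  descriptives median(IQR). Categorical columns use the Pearson chi-square
  *without* continuity correction — the uncorrected statistic reproduces
  the published sex-table p (0.738) exactly, the Yates-corrected one does
  not.
* **Mann–Whitney.** Exact tie-aware enumeration of all group assignments
  when both arms have ≤ 7 subjects; tie- and continuity-corrected normal
  approximation otherwise.
* **Stepwise logistic.** Bidirectional, likelihood-ratio p-values,
  p_enter = 0.05 / p_remove = 0.10 (the conventional defaults of the
  statistical software the pipeline emulates; the original direction of
  stepping is unstated). Candidates are z-standardized internally, making
  selection invariant to affine rescaling; the final model is refit on the
  original scale. Perfect separation triggers a flagged ridge-stabilized
  (L2, C = 1) fit instead of divergent coefficients. Note that entering
  the minimum-p candidate at p_enter gives a familywise entry probability
  of `1 − (1 − α)^k` for k noise candidates (≈ 18% at k = 4), which is the
  expected type-I behavior of this classical algorithm, not a defect.
* **ROC/AUC.** AUC is pairwise concordance (ties ½), computed via
  midranks; the 95% CI uses DeLong structural components. Single-marker
  ROCs are auto-oriented (scores negated when AUC < ½, flip recorded),
  since markers can differ in either direction; the joint-model ROC uses
  the logistic probabilities with MCI as the positive class.
* **Sample size.** Smallest integer per-group n whose two-sample t power,
  evaluated with the noncentral-t distribution, reaches the target. For
  d = 0.7, α = 0.05, power = 0.8, ratio 1, two-tailed this gives 34 per
  group (power 0.812; 33 gives 0.7997), total 68.
* **Multiplicity.** Marker selection uses raw p < 0.05, as the pipeline
  being reproduced does; Benjamini–Hochberg q-values are emitted in the
  battery table for information only.

## Synthetic sessions

Each subject draws latent factors, then the session is rendered at 60 Hz
with 1 px coordinate jitter:

* **Pauses.** Initial pause, a gap scale and a within-session gap CV, each
  log-normal between subjects; gaps are log-normal within the session.
* **Tempo.** A total on-screen move time plus a tempo-allocation exponent
  β: stroke j's moving time ∝ `(D_j/D_ref)^β` below the reference length
  and `(D_j/D_ref)^(β+δ)` above it. β = 1 is constant speed, β = 0
  isochrony; the long-stroke surcharge δ caps the maximum stroke speed
  near twice the mean, as real handwriting does. Because the allocation
  conserves total time, β moves the mean per-stroke speed *without*
  moving the writing time — the lever that decouples the two in
  calibration (Chebyshev's sum inequality bounds `mean_j v_j` by
  `ΣD/Σt` for β ∈ (0,1)). One-sided log-normal "hesitation" noise slows
  random strokes, feeding the slow tail of the speed distribution.
* **Stationary episodes.** A per-subject episode count (per 60 strokes),
  episode duration, and a spread fraction choosing how many strokes carry
  them; episodes are emitted as exact coordinate repeats ≥ 3 frames, so
  they register under the 50 ms pause threshold.
* **Production errors.** Per character: stroke merges (fluent connection
  of adjacent strokes), splits (mid-stroke lifts with a ~55 ms micro-gap),
  skipped dots, order scrambles; per session: writing 9 or 11 characters
  instead of 10. These drive the stroke-count and task-score contrasts.
* **Geometry.** A glyph scale with a large between-subject size multiplier
  (log-SD ≈ 0.25): people write at very different sizes, which is what the
  published trajectory-length SDs (~25–30% of the mean) imply. Size
  variation also spreads the speed levels without touching any time
  marker.

Cohort generation spawns one child seed per subject from the master seed
(plus one for demographics), so sessions are byte-identical across
platforms given (params, group, seed). Demographics carry no group effect
(the source cohorts did not differ); the MMSE/MoCA scales do.

## Calibration

`calibrate` adjusts one generator parameter per targeted marker by damped
proportional updates, probing each group with a fixed common-random-number
seed set per sweep so the iteration converges to a fixed point rather than
chasing Monte-Carlo noise; the final report re-probes with fresh seeds and
lists every target's achieved median, including infeasible
observation-only targets (never silently dropped).

The default target set is the twelve jointly feasible published medians:
writing time, initial pause, mean gap, gap CV, pause count and mean stroke
length, per group. Two published blocks are *provably* not jointly
reachable by any generative model and are therefore represented
structurally rather than as targets:

* the maximum-gap and gap-CV rows together would require a far heavier
  gap tail than any two-parameter distribution provides (a median max of
  1.0 s over ~59 gaps with CV 0.11); the gap CV is calibrated and the max
  gap inherits the direction;
* the speed block: a mean stroke speed of ~594 px/s sits at the
  mathematical minimum of `mean_j D_j/t_j` given the published writing
  time and trajectory lengths, so no room is left for the published speed
  CV (~0.85) — the variability rows print CV × 100 — or the printed
  max/mean ratio. The defaults preserve the speed block's directions and
  its significance pattern (mean speed and max speed non-significant,
  speed CV significant) instead of absolute levels.

The published total-task-time row contradicts the running text's stated
direction of the group difference and the row-wise sum decomposition; the
default calibration follows the text direction, and a columns-as-printed
target mode exists that carries the printed row as an observation-only
target, which then appears in the failure report.

Between-subject dispersions are set from the published IQR/SD where those
are consistent with the published p-values, and otherwise from the
dispersion the published p implies at n = 38/34 — the two columns
disagree for several markers, and the significance pattern is the
property the generator exists to reproduce. The shipped
`default_params()` are the calibrated fixed point of this procedure.

## What the generator does and does not emulate

It reproduces the marginal biomarker distributions, their group contrasts
and the resulting significance pattern. It does not attempt
biomechanically realistic trajectories (no jerk minimization, no curvature
–speed power law within strokes), no fatigue or learning across the ten
repetitions, no correlation between demographics and kinematics, and no
device artifacts beyond Gaussian jitter. Passing tests therefore validate
the *pipeline* — segmentation, feature algebra, statistics, selection —
under realistic distributional conditions; they say nothing about clinical
discriminative performance on real patients, and the published clinical
AUCs (joint 0.918) are deliberately not reproduction targets: on synthetic
cohorts the pause-variability contrast is strong enough that the joint
model often approaches AUC 1.

## Problem sizes and numerical choices

Stochastic checks use 50 replicate 38/34 cohorts for the battery-count
criterion, 500 probe sessions per group for calibration recovery, 60 null
cohorts (both arms from the HC generator) for the false-positive rate,
100 seeded simulations at n = 200 for selection sanity, and 300 bi-normal
simulations for DeLong coverage; identities run on 1000 sessions. Exact
identities are asserted at relative 1e-12; oracle equivalence at 1e-9.
Degenerate inputs: empty sessions and single-class cohorts raise typed
errors naming the failing stage; J = 1 sessions propagate NaN gap
statistics; zero-variance marker columns are routed to Mann–Whitney (the
normality test is undefined on constants).
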
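# Methods

## The test being modelled

The Box and Block Test (BBT) measures unilateral gross manual dexterity:
150 one-inch cubes sit in one compartment of a divided box, and the
score is the number of cubes the subject carries over the partition and
releases in the other compartment within 60 seconds. The augmented-
reality variant keeps the protocol but replaces the physical apparatus
with virtual blocks overlaid on a selfie-view camera image; a
hand-tracking model provides 21 landmarks per frame (wrist = 0, thumb
tip = 4, index fingertip = 8) and a thumb–index pinch substitutes for
grasping. This package implements the game logic, timing, scoring, and
validation statistics of such a test as a deterministic, headless
engine; the tracking backend itself (a palm detector plus landmark
regressor) is out of scope and enters only through the provider
contract: anything that yields time-ordered landmark frames.

## Engine model and assumptions

**Coordinates.** Pixel origin top-left, x rightward, y downward.
Rectangles are half-open `[x0,x1)×[y0,y1)` for containment tests and
closed for clamping and overlap, stated once and used everywhere.
Streams are assumed already mirrored (selfie view); `flip_horizontal`
and the `mirror_consistency` score (minimum mean absolute difference
over horizontal shifts after un-flipping) are provided as preprocessing
diagnostics, not game logic.

**Pinch.** The pinch aperture is the Euclidean distance between the
thumb-tip and index-tip landmarks in pixel space, so thresholds have a
physical reading at the calibrated ~50 cm camera distance. A pinch
closes when the aperture falls *strictly below* the grab threshold and
reopens only at the release threshold (default 64 px / 80 px at a
1280-wide frame, i.e. grab = 5% of frame width, release = 1.25 × grab).
The hysteresis band absorbs frame-to-frame tracking jitter; without it
an aperture fluctuating around a single threshold would toggle the grip
every few frames. Closure is monotone in the threshold and the state
never toggles while the aperture stays inside the open band — both are
property-tested.

**Hand selection.** One hand moves blocks. The first hand detected is
tracked by its handedness label until lost (an empty detection); only
then does a new first detection take over. Frames with no hand freeze
the arena while the trial clock keeps running, matching a timed test in
which the hand briefly leaves the camera view.

**Arena.** The box spans the full frame. The divider is a vertical band
(default 24 px wide) centred on the midline, rising from the box floor
to 55% of the box height; the compartments are the full-height regions
either side of the band, and the source compartment is the one adjacent
to the assessed hand. Blocks are axis-aligned squares (half-size 30 px
at 720p ≈ one inch at ~50 cm). One block is active at a time: grabbing
requires *both* fingertips inside the block with the pinch closed; a
carried block sits at the fingertip midpoint, clamped into the box
(component-wise, idempotent); any closed-rectangle overlap with the
divider voids the block (it vanishes and the next spawns immediately);
releasing with the centre inside the target compartment scores a point
and settles the block on the compartment floor, where it persists;
releasing anywhere else drops the block where it is, still grabbable.
Spawn positions are seeded-uniform in the source compartment shrunk by
a 40 px margin, colors seeded-uniform over four; `spawn_mode="center"`
pins spawns to the compartment centre for exactly reproducible scripted
scenarios. Since the divider band spans the full height of the gap
between compartments below its top, the only scoring route is over the
top — as in the physical test.

**Trials and protocol.** The clock is driven by frame timestamps, not
frame counts, so variable processing latency does not distort the 60-s
window. A frame at or past the trial duration ends the trial without
being applied; a block still grabbed at cutoff counts as an unfinished
grab, never a point. The protocol runs five familiarization trials and
one assessment trial; only the assessment score is reported. Per-trial
seeds derive from (session seed, trial index), so spawn sequences
differ between trials but reproduce exactly across runs. The event
sequence is frame-rate independent provided every state-changing
geometric condition persists at least two frames at the lower rate
(tested at 60 vs 30 fps).

**Kinematics.** Per scored transfer (last grab to score): path length
as the sum of successive carry-point displacements (≥ the straight-line
distance), peak per-frame speed, transfer duration, and mean pinch
aperture over the carried span. These are the quantities a camera-based
test can add to the plain score.

## The synthetic subject

The closed-loop simulator emulates a seated subject performing the
test. It reads only the arena's published observation (active block id,
state, position, layout, score) and controls a hand point with:

- `reach_speed` (px/s): straight-line speed toward the current goal
  (default 700 for an unimpaired profile; 450 in the impaired profile);
- `tremor_sd` (px): white Gaussian positional noise added rigidly to
  the whole hand each frame — the simplest falsifiable noise model,
  deliberately without autocorrelation, documented so an oscillatory
  tremor model can be swapped in;
- `pinch_close_reliability`: probability that a commanded pinch
  registers closed on a given frame; failures while carrying release
  the block mid-air;
- `reaction_lag` (s): delay before moving toward a newly spawned block;
- `regrip_delay` (s, default 0.25): recovery time after a failed grasp
  attempt or an involuntary drop before the next attempt — grasp
  attempts are discrete single-frame closures, not per-frame retries,
  because a real subject perceives a miss and re-aims rather than
  re-closing 60 times a second;
- `carry_height_fraction`: the height at which blocks are carried; the
  controller lifts vertically to this height, traverses through an apex
  over the divider, and descends to the target-compartment centre. A
  fraction below the divider-top fraction cannot clear the divider, and
  every such attempt ends in a collision — a deliberate failure mode
  used in testing.

The 19 non-tip landmarks come from a fixed synthetic hand template
rigidly translated with the carry point; only the tips carry behavioral
meaning, since the engine reads nothing else. The `impaired_subject`
profile (tremor 8 px, reliability 0.92, 450 px/s, 0.25 s lag) is
calibrated so simulated 60-s scores land in the low teens, the range
reported for hemiplegic stroke patients on virtual block-transfer
tests; the unimpaired default scores in the mid-20s.

What the simulator does *not* model: landmark estimation error
structure (occlusion, depth ambiguity, identity switches), hand
rotation and articulation, fatigue or learning across trials, and any
block physics beyond settling. Passing tests therefore demonstrate the
correctness and determinism of the engine and the qualitative response
of the score to impairment — not the behavior of any particular
tracking backend on real video.

An open-loop `ScriptedPlan` gives exact frame-level control for unit
tests. The ideal transfer plan executes one transfer per `cycle_time`
seconds against a centre-pinned spawn, releasing at 85% of each cycle,
so a trial of duration D scores exactly `floor(D / cycle_time)`
whenever `frac(D / cycle_time) ≤ 0.85` — the closed-form oracle used in
the acceptance checks.

## Statistics

**Sample size for a correlation.** The a priori requirement to detect a
correlation ρ₁ at two-sided level α with power 1−β uses the Fisher
variance-stabilizing transform z = atanh r, z ~ N(atanh ρ, 1/(n−3)):

n = ((z₁₋α/tails + z_power) / atanh ρ₁)² + 3,

rounded to the *nearest* integer. At conventional design points the
Fisher approximation slightly understates power (its analytic power at
the moderate-correlation design point of ρ=0.5, α=0.05, 80% power is
0.7998 at n=29, while the exact rejection rate of the t-test on r under
bivariate-normal sampling is ≈0.813), so always rounding up would
overshoot the n that exact-power software reports; nearest-integer
rounding reproduces those exact results (29, and 38 at 90% power, 85 at
ρ=0.3) and the Monte-Carlo check (`monte_carlo_power`, vectorized
simulation of the t-test on the sample correlation) verifies that the
returned n actually brackets the target.

**Correlation and effect size.** Product-moment r with
t = r√(n−2)/√(1−r²), two-tailed p on n−2 df, and Cohen's classes for
|r|: ≥0.5 large, ≥0.3 medium, ≥0.1 small, below that "negligible".
Zero-variance inputs are rejected by name. A known quirk of the source
study this toolkit mirrors: it prints p = 0.000008 next to r = 0.918 at
n = 31, while the t-based two-tailed p at that r and df = 29 is on the
order of 10⁻¹²; this package reports the t-based value.

**Paired decrease.** Differences x−y tested with a paired t by default
and Wilcoxon signed-rank as the selectable alternative (the underlying
study does not name its test, so both are exposed); all-zero
differences short-circuit to p = 1 with a degenerate flag, and the
direction label reports the sign of the mean difference.

**Cohort filter.** Inclusion: hemorrhagic-stroke etiology, Ashworth ≤ 3,
≤ 6 months since the incident. Exclusion labels are matched against
comorbidity strings. A record with several reasons is tallied under the
first match in a fixed, documented order — neurological comorbidity,
rheumatoid arthritis, joint stiffness, Ashworth, time since incident,
etiology — chosen so the tally reproduces disjoint per-reason counts.
Filtering conserves records and is idempotent on its included output.

**Likert summaries.** Four response levels per item; per-level and
collapsed agree/disagree percentages are computed from raw counts and
rounded to one decimal, half away from zero (29/31 → 93.5%). Collapsing
happens before rounding.

**Synthetic paired scores.** Seeded draws from a bivariate normal with
specified means, SDs and ρ, optionally rounded to non-negative integers
(block counts). The reference moments — AR-BBT 11.90 ± 2.11, BBT
36.64 ± 6.14, ρ = 0.918, n = 31 — define the parameter-recovery study:
integerization attenuates the observable correlation slightly (rounding
adds ~1/12 of variance per margin), which is why recovery is asserted
as Fisher-CI coverage of the generating ρ rather than point equality.

## Problem sizes and tolerances

The test suite and acceptance script use: 10,000 Monte-Carlo studies
for the power cross-check (band 0.80 ± 0.02); 1,000 replicates for
parameter recovery (CI coverage ≥ 93%, paired-decrease detection
> 99%); full 60-s trials at 60 fps for closed-form and determinism
checks and 20–30-s trials for behavioral properties; impairment grids
of 2–9 cells with 3–4 replicates. Monotonicity assertions use a
two-standard-error margin on the replicate means. Floating-point
determinism is asserted at byte level on serialized JSONL (Python float
repr round-trips exactly); statistical oracles are asserted against
closed-form computations at 1e-6 relative tolerance or better.

## Known limitations

- The engine consumes landmarks; nothing here validates a tracking
  model, and depth (z) is carried but unused by the grab logic, whose
  gating is purely 2-D — as in the screen-space test it implements.
- The divider band's width and height and the block size are
  interpretation choices (the protocol's source material gives no
  pixel geometry); they are configuration, not constants.
- The simulator's tremor is white noise and its grasp policy is a
  simple finite-state controller; it is a test harness for the engine
  and a qualitative impairment model, not a biomechanical hand.
- Scores from the synthetic cohort generator reproduce moments and
  correlation structure, not the empirical distribution of any real
  patient population.
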
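# Methods

## Display model

A trial is a sequence of `round(duration × rate / 1000)` frames (180 at the
default 3000 ms / 60 Hz). Four visible dots (1° diameter) move at a constant
14.5°/s; positions and headings are stored in degrees of visual angle with
the origin at display center, heading 0 = +x, counterclockwise.

Motion follows two rules:

* **Random dots** resample their heading uniformly within a 120° full
  window centered on the current heading, at update events spaced
  `round(0.170 × rate)` = 10 frames apart. Each dot carries an independent
  uniform phase offset so updates are not lock-stepped across dots.
* **The wolf** samples, at its update events after a 170 ms onset delay,
  a heading uniformly within ±*s* (the chasing subtlety) of the bearing
  from its current position to the sheep's current position. Before onset
  it follows the random-dot rule, so early motion looks like everyone
  else's. In chase-absent trials its target is a fifth, invisible dot
  governed by the random-dot rule and the same collision constraints.

Within a frame dots advance sequentially — the wolf's target first, the
wolf last — so every constraint is evaluated against the positions the
display actually shows on that frame. The bearing used at a wolf update is
therefore taken from the wolf's pre-step position to the sheep's position
on that frame; the analysis helpers (`Trajectory.wolf_update_deviations`)
measure deviations against the same geometry. Between updates the heading
is held, so the *instantaneous* deviation can exceed *s* as the sheep moves;
the window guarantee is defined at update events, which is also how the
tests and acceptance scans measure it.

### Constraints

Two hard rules hold on every frame: wolf–sheep center distance ≥ 5° and no
pair of dots closer than one dot diameter. When a sampled (or held) heading
would violate a rule on the next frame, the dot keeps its previous heading
instead (the display's documented behavior); if that also violates, it
steers directly away from the nearest offender, and as a last resort takes
the heading on a 1° grid with the largest worst-case constraint margin.
Only the wolf enforces the 5° floor in its steering. Because the sheep's
random walk is not constrained by the floor, a wall-pinned wolf can very
rarely (≈0.3% of trials) still be cornered below it; such trajectories are
discarded and regenerated from a deterministically derived retry seed, so
every emitted trajectory satisfies both rules on every frame. This
generate-and-verify step conditions the trial ensemble on constraint
satisfaction; its rejection rate is too small to measurably distort the
kinematics.

### Arena and boundaries

The display's physical bounds are not part of the paradigm's published
constants, so the arena is configurable; the default is 48 × 30° (a 24-inch
16:10 monitor at 57 cm) with specular reflection at the walls (position and
velocity mirrored; a `resample` mode that redraws an inward heading is
available). A reflection bends the dot's within-frame path: the path length
still equals `speed/frame_rate`, but the straight-line displacement on that
frame is shorter. Reflection frames are logged (`reflect_log`) and excluded
when tests assert exact per-frame displacement.

### Emergent behavior worth knowing

Heat-seeking pursuit plus a distance floor produces *orbiting*: the wolf
closes to ~5–6° within the first second and then rides the floor, its
sampled headings frequently rejected, its held heading tangential to the
sheep. Consequently the full-trial mean of cos(heading − bearing) for the
true pair is far below 1 (≈0.5–0.6 at s = 15°) even though every accepted
update heading lies within the subtlety window. Summaries of chase evidence
should expect this attenuation; the window guarantee itself is unaffected.

## Cue model

Gaze is an orientation signal per visible dot: the wolf's gaze equals the
instantaneous wolf→sheep bearing on chase-present social trials; every
other dot (and the wolf on absent trials) gazes along its own heading, so
absent trials carry no gaze trace of the invisible target. Luminance is an
abstract signal `A sin(2πft + φ)` in [−1, 1]; mapping to screen color is
out of scope. On present trials wolf and sheep share 3 Hz with a 0.15 rad
phase offset and the two distractors run at 0.5 Hz with independent random
phases; on absent trials the wolf is paired at 3 Hz with one randomly
chosen visible distractor, so counting 3 Hz dots cannot by itself reveal
chase absence. Note the spectral granularity of a 3 s window is 1/3 Hz:
3 Hz falls exactly on a bin, 0.5 Hz resolves to within one bin — the two
frequency classes are always separable, but a 0.5 Hz track's periodogram
peak sits at 1/3 or 2/3 Hz.

## Trial design

Each participant completes three blocks in an order cycled through the six
permutations of {baseline, social, nonsocial} in participant order (a
balanced assignment; the original assignment scheme is not published). Each
block holds 6 practice trials (one present and one absent per subtlety)
followed by 75 test trials (3 subtleties × 20 present + 5 absent) in a
seeded uniform shuffle. Every row carries a unique sub-seed below 2³¹ for
trajectory generation.

## Generative observer model

Accuracy is Bernoulli with a logit linear in Group (ASD = 1, TD = 0), Age
(raw years), Trial type (present = 1), Subtlety (raw degrees), condition
dummies against baseline, Group × Subtlety, plus a participant random
intercept u ~ N(0, σ_u²). The default fixed effects are the published
estimates of the final accuracy model; this coding is forced by the
published signs (the positive interaction with ASD = 1 makes the ASD
group's accuracy flatter in subtlety, crossing the TD group between 15°
and 75°). σ_u is not published; the default 0.8 logits is a typical
between-participant spread for tasks of this kind and is configurable.
Ages are drawn from group-specific normals (ASD 14.08 ± 1.47, TD
14.33 ± 1.27 years) truncated to 12–16.5.

`correct` is generated directly by this model, matching the trial-by-trial
accuracy analysis; `response_present` is derived from `correct` and the
trial's true presence rather than modelled separately, and the quadrant
click is uniform bookkeeping that no analysis consumes. What passing tests
show is therefore that the *statistical structure the analysis assumes* is
recovered end to end — not that human observers behave like the generator:
the parametric path contains no perceptual front end, no lapses or response
bias, and its random intercept is exactly normal.

The heuristic observer implements the item-by-item search account: for all
12 ordered visible pairs it computes (a) heading alignment, the full-trial
mean of cos(candidate-wolf heading − bearing to candidate sheep); (b)
proximity, the negative linear slope of pair distance over time normalized
by mean distance; (c) cue consistency (mean gaze–bearing cosine, or
magnitude-squared coherence of the two luminance tracks at 3 Hz), combines
them with configurable weights, and reports "chase" when the maximum plus
Gaussian noise exceeds a criterion. It is a qualitative tool: it reproduces
the direction of the subtlety effect and the benefit of informative cues,
and no attempt is made to fit its parameters to human accuracies.

## Mixed-model estimation

The random-intercept logistic likelihood integrates u out per participant.
The integral is evaluated by adaptive Gauss–Hermite quadrature: a
step-clipped Newton search (globally convergent, since the per-participant
posterior in u is strictly concave) finds each posterior mode and
curvature, and the Gauss–Hermite rule (default order 9; order 1 recovers
the Laplace approximation) is applied on the re-centered, re-scaled grid.
The marginal likelihood is maximized over (β, σ_u) with L-BFGS-B, σ_u
bounded at 0. Covariates are standardized internally for conditioning and
estimates mapped back to raw units. If σ̂_u reaches the boundary the
profile is exactly the ordinary logistic model, and the plain-logistic
solution is returned for the fixed effects. Standard errors come from the
observed information (central-difference Hessian of the marginal negative
log-likelihood); Wald Z = estimate/SE, p = 2Φ(−|Z|), CI = estimate ±
1.96·SE, with p below 0.001 reported as "<0.001". Complete separation is
detected on the fixed-effects screen and raised explicitly. The fitter is
cross-checked in the test suite against `lme4::glmer` (adaptive quadrature,
nAGQ = 9) to < 0.01 on all coefficients and σ_u.

Only the final accuracy model is implemented (with a generic `terms`
argument to drop or add fixed effects); model-selection searches, mixed
ANOVAs and Bayesian alternatives are out of scope.

## Signal-detection summaries

Hit and false-alarm rates are computed per participant per
(group, condition, subtlety) cell. With only 5 absent trials per cell the
raw FA rate is often 0, so d′ = z(H) − z(FA) supports the log-linear
correction ((k+0.5)/(n+1)) and the half-count correction (0 → 1/(2n),
1 → 1 − 1/(2n)); `none` leaves rates untouched and can produce infinite d′.
Cell summaries average per-participant values; SEM = SD/√n with SD of a
single value defined as 0 (the cell's participant count is reported so the
degenerate case is visible).

## Problem sizes and tolerances used in the checks

Geometric scans use 500 trials per subtlety (250 present + 250 absent);
parameter recovery uses 20 replicate studies of 48 participants × 225
trials; CI coverage uses 200 replicates that keep the full 48-participant
cohort (which sets the degrees of freedom of the between-participant
coefficients) with a stratified subsample of 81 test trials per participant
(7 present + 2 absent per condition-subtlety cell);
the observer comparison uses 100 present + 100 absent trials per subtlety
with a criterion calibrated at the pooled median score. Angular assertions
use 1e-9 absolute slack over exact window bounds; the mixed-fit/logistic
boundary equivalence is asserted at 1e-3, and Monte-Carlo assertions use
2–4 standard-error bands as stated in each test. The wolf-vs-distractor
turn-angle similarity check uses a KS threshold of 0.35 calibrated on the
generator at 75° subtlety (measured ≈0.25): the invisible-target wolf's
turn distribution is the self-convolution of its subtlety window and is
genuinely wider than the distractors' uniform window, so the similarity is
partial by construction — consistent with the display's documented intent
that the wolf's visible motion differ from the other dots' only in its
amount of direction changes.

## Known limitations

* The arena geometry and boundary rule are design choices; published
  constants do not pin them down.
* Only the wolf's steering enforces the 5° floor; the rare cornered
  trajectory is regenerated rather than re-steered (see above).
* The parametric and heuristic observers are not calibrated to human data;
  claims about them are qualitative or structural.
* The marginal-likelihood optimizer uses finite-difference gradients;
  estimates are reproducible to ~1e-3, which bounds how tightly structural
  identities (e.g. group-recoding invariance) can be asserted.
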
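# Methods

This note documents the models implemented in `teamintercept`, their
assumptions and default parameters, the design choices made where the
original task description left details open, and what the synthetic
pipeline does and does not establish.

## Game model

The arena is the closed unit disc; all lengths are in arena radii and
all times in seconds. Defaults (all configurable through `GameConfig`):

| parameter | default | rationale |
|---|---|---|
| `arena_radius` | 1.0 | unit of length |
| `avatar_speed` | 0.25 /s | a radius crossing takes ~4 s, so a 180 s round yields several dozen interceptions per team |
| `tick_dt` | 0.05 s | 20 Hz; one movement step (0.0125) is well under the capture diameter, so proximity capture cannot tunnel |
| `capture_radius` | 0.03 | 3% of the radius; small relative to typical inter-target spacing |
| `spawn_cone_half_angle` | π/4 | the original task constrains headings to "a cone"; ±45° around the inward normal guarantees inward motion with varied chord lengths |
| `target_density` | 5 (or 15) | the two study conditions |
| `round_duration` | 180 s | one round |
| target speed | U(0.50, 0.99) × avatar speed | targets 1–50% slower than the avatar |
| value | floor(16·u), u ~ Beta(1, 2), clamped to 15 | equal-width binning; bin masses are exactly (31 − 2k)/256 |

Coordinates have the arena center at the origin, angles in radians
counterclockwise. Avatars start at (±0.2, 0) (human left), halted.

**Interception.** A click solves the pursuit quadratic
`(|v|² − s²)t² + 2(d·v)t + |d|² = 0` and sends the avatar to the meeting
point, clipped to the boundary when the point lies outside the arena (the
avatar then halts at the edge until re-directed; avatars never
re-navigate on their own). Because targets are strictly slower than
avatars, exactly one non-negative root exists. Any active target within
the capture radius of an avatar at the end of a tick is intercepted —
marked targets as deliberate captures, everything else as incidental;
this proximity rule subsumes "targets on the interception path are also
collected" without needing a separate sweep geometry. If both avatars
are in range in the same tick, the nearer one is credited, with the human
winning exact ties; each target is intercepted at most once.

**Ghost paths and respawning.** An intercepted target's straight-line
path keeps counting toward the density until it would have reached the
perimeter; only then does a replacement spawn. This makes the spawn
process independent of player skill and keeps the unexpired-path count
exactly at the density on every tick (a tested invariant).

**Randomness.** One master seed feeds named substreams (spawn position,
heading, speed, value, human policy, likert, choice, experiment) via
`SeedSequence` spawn keys, so changing the AI policy does not perturb the
spawn sequence and all artifacts are bit-reproducible given (seed,
config, policies).

**Path intersections** are tested per tick between the two players'
position→destination segments (orientation test; a halted avatar has a
degenerate segment and never intersects) and counted at onsets
(false→true transitions) so the count does not scale with `tick_dt`.

## Agents

All five policies share the sequence search: every ordered sequence of up
to three distinct targets from the consideration set, each leg solved
from the previous leg's meeting point and time; a leg whose target path
expires before interception or whose meeting point falls outside the
arena prunes the sequence there. The plan objective is total (planning)
value, ties broken by earlier completion, then lexicographic target ids;
a value-per-second objective is available behind `rate_objective`. At
density 15 the search is evaluated with batched quadratic solves
(`search_best_plan`), tested equal to the explicit enumeration.

Policy defaults: `replan_period` 0.5 s (the agent also replans
immediately when its pursued target disappears or leaves its
consideration set), `max_sequence_length` 3, `ema_window` 5,
`ema_alpha` 1/3, `initial_delay` 0.5 s.

Open details resolved as package design choices:

- **Human "path" for omission**: the segment from the human's position to
  its destination, swept with the capture radius, at current target
  positions.
- **Divide's half-plane test** uses the target's *interception point*
  (from the AI's position), not its current position; the dividing line
  passes through the center orthogonal to the center→human vector. A
  human exactly at the center leaves the line undefined: the previous
  line is reused, else the omit set is used unchanged.
- **Delay's EMA** honors both the "exponential moving average" and the
  "previous five" clauses: weights (1 − α)^age over a hard window of 5.
  A human response time is the gap between a deliberate human
  interception and the next human click. The delay applies only after
  the agent's own deliberate interceptions.
- **Bottom-Feeder** plans under 15 − v (kept non-negative rather than
  negated; identical ordering for single legs); scoring always uses real
  values.
- **Back-off rule**: when a replan was forced because the pursued target
  left the consideration set (typically: the human just marked it) and no
  feasible alternative plan exists, the agent clicks the center token.
  Without this, its cross-hair and path would linger on the human's
  target and produce spurious "steals"; with it, omit-family steals drop
  to ~1 per 180 s round (virtually all incidental or same-tick races)
  versus ~30 for the ignorant agent.

## Synthetic humans and the synthetic study

The synthetic human is a test fixture, not a cognitive model. After each
completed action it waits a lognormal reaction time (median 0.8 s,
σ_log = 0.4), then softmax-picks among catchable targets by
(value + N(0, 1)) / time-to-intercept at temperature 1, with a 0.1 /s
hazard of spontaneous retargeting. These values were chosen once to give
a plausibly slower-than-AI, mostly-greedy player; they are not fit to
human data.

`simulate_experiment` reproduces the study structure: per participant,
two blocks (densities 5 and 15, order counterbalanced) of two rounds (the
two assigned agents, order counterbalanced and reversed across blocks);
eight 7-point Likert ratings per agent per block; one pairwise choice per
block. The full counterbalancing cycle is 80 cells (10 agent pairs × 2
density orders × 2 agent orders × 2 survey/choice orders).

Ratings are latent means per (item, agent) plus N(0, 1.2) noise, rounded
and clamped to 1–7 — the simplest generative model sufficient to test the
subjective-feature pipeline. Choices are Bernoulli draws from the
logistic Bradley–Terry model over the *realized* feature differences of
the two rounds, under a reference ground truth with order bias 0.3,
inequality aversion (β = −6 on relative score-inequality differences),
steal aversion (β = −0.25 per steal), and teaming-flavored Likert effects
(q1, q4, q8); all other coefficients zero. Generating choices from
realized differences keeps coefficient recovery well-posed.

What the synthetic cohort does *not* emulate: human skill heterogeneity,
learning across rounds, rating responses driven by the actual gameplay a
participant experienced (ratings depend on the agent's identity, not the
realized round), or attrition. Consequently, passing tests show that the
pipeline measures and recovers what it is pointed at — not that human
players behave like the fixture. The synthetic cohort is also more
internally consistent than human data, so its choice-prediction
accuracies run higher than one should expect from participants.

## Preference model

Coefficients are estimated on standardized (z-scored) feature
differences, scalers refit on each training split; constant columns get
scale 1. Priors are independent Normal(0, 2.5²) on all coefficients
including the order bias — a documented, reproducible weakly-informative
choice in place of the bespoke g-prior machinery of point-and-click
Bayesian GLM tools; every summary records the prior actually used.

Inference is the posterior mode (Newton/IRLS, tolerance 1e-10) with a
Laplace approximation for 95% credible intervals. Inclusion Bayes factors
are ratios of Laplace marginal likelihoods, full model vs drop-one —
simpler than model-averaged inclusion probabilities and stated as such in
the output metadata. The Laplace BF is tested within a factor of 2 of
dense-grid numerical integration on a small problem. Perfectly separable
data leave the posterior proper under the Gaussian prior; a warning is
raised when coefficients run past 10 on the standardized scale. A
non-positive-definite Hessian raises rather than silently reporting an
unstable approximation.

Cross-validation uses a seeded uniform random 10-fold partition without
stratification; held-out choices are predicted "first" iff p > 0.5, with
exact ties counted incorrect for conservatism. Choice matrices pool the
two presentation orders; each cell's evidence against 50% is a
beta-binomial Bayes factor with a uniform prior
(`BF10 = B(k+1, n−k+1)/0.5ⁿ`), flagged at BF > 10.

Steals are defined by the human's cross-hair at the interception instant
(unambiguous from the log); a first-marker variant is available behind a
flag. Scores entering the preference model are relative (fraction of the
total value spawned), including the inequality feature.

## Problem sizes and numerics

The test suite validates the interception solver against a dt = 1e-4
time-stepping oracle (200 instances), the planner against exhaustive
re-simulation with bracketed root-finding (100 boards of ≤6 targets),
engine invariants over 20 full-length rounds, policy invariants over 20
rounds, the directional agent orderings over 50 rounds per agent at
density 5, and coefficient recovery over 20 replicates of 600 choices
(300 participants × 2 blocks each). `scripts/acceptance.py` uses a
160-participant cohort (two full counterbalancing cycles) at full-length
rounds. The Bottom-Feeder value-minimality property is checked on
single-leg plans, where it is well-defined; with longer sequences the
planner legitimately orders its chosen low-value set by travel time.

Known limitations: constant-velocity targets make the interception point
click-time-invariant, which the agents exploit by not re-clicking a
pursued target — a real client with latency would behave slightly
differently; proximity capture approximates path-sweep incidental
collection; and the Laplace approximation can understate tail mass for
very small samples (the quadrature cross-check bounds this on a toy
problem, not in general).
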
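# Methods

## The task and its physics

Two agents (one person using both hands, or a dyad with one hand each) hold
the two ends of a virtual board through stiff spring-damper grips and must
roll a ball along the frictionless board into a target area, keeping it
there for 1.5 s.  The board hangs from a soft central spring; the ball's
only actuation is gravity along the tilted board.

The simulator integrates the standard small-model equations of this
apparatus.  Hand forces are

    F_side = k_h (z_side − z_P,side) + c_h (ż_side − ż_P,side),
    z_P,L = z_board − l sin θ,   z_P,R = z_board + l sin θ,

with the control-point velocities obtained by differentiating the
control-point heights (ż_P,L/R = ż_board ∓ l cos θ · θ̇).  The board and
ball obey

    F_s = −k_s z_board,
    M z̈_board = F_L + F_R − M g − m g cos²θ + F_s,
    I θ̈ = (F_R − F_L) l cos θ − m g x_ball cos θ,
    ẍ_ball = −g sin θ.

The `m g cos²θ` normal-load term is a deliberate simplification that keeps
the ball glued to the board; exact contact mechanics are out of scope.
Positive θ is counterclockwise (right end up) and drives the ball in the
negative x direction.

Default constants: board mass M = 0.01 kg, ball mass m = 0.15 kg (the
five-condition dyadic setting; `ModelParams.light_ball()` switches to the
0.05 kg ball), g = 9.81 m/s², k_h = 200 N/m, c_h = 2 N·s/m,
k_s = 140 N/m, l = 0.25 m, I = 4·10⁻⁴ kg·m².

**Integrator.** One-millisecond steps (matching the 1 kHz recording rate):
velocities are advanced first with the current accelerations (the stable,
symplectic order for the stiff hand springs, ω ≈ 250 rad/s, ω·dt ≈ 0.25),
and positions then move with the average of the old and new velocity.  The
averaged position update reproduces constant-acceleration kinematics
exactly, so a frozen-tilt ball roll tracks the closed form
x₀ − ½ g sin θ t² to well below 0.1 mm over a second; plain velocity-first
Euler would err by ~0.5 mm there.

**Haptic conditions.** Rendered feedback per side: Without → 0;
Full → −F_side; Partner → ½F_s (the central spring carries the partner's
action); Environment → −F_side − ½F_s.  Partner and Environment sum to Full
by construction.  Unrelated replays a pre-recorded force-pair profile
indexed by trial time; when a trial outlasts the profile, each wrap blends
linearly from the held final value into the restarted samples over 100 ms,
so the rendered force never steps.

**Trial protocol.** The ball starts clamped at one target centre and is
released at t = 0.  Success fires when the ball has stayed inside the goal
target continuously for the hold duration (1.5 s); the recorded completion
time includes that hold.  Rolling past a board end is failure; a safety cap
(60 s default) marks a distinct timeout failure.  Target centres at
±0.15 m with half-width 0.03 m are configurable defaults — the task
geometry is not uniquely determined by the apparatus, only constrained to
lie on the board.  The inter-trial "hold the board level" reset lives in
the session runner and never counts toward completion time.

## Synthetic dyads

No human data ships with the package, so the `agents` module generates
dyadic sessions with exact ground truth.  The controller is deliberately
simple and is **our** model of an operator, not something the analysis
assumes: a shared intermittent planner fires whenever both hands are idle
and the ball is outside a 1 cm error deadband (or still faster than
2 cm/s).  It maps ball error and velocity to a desired tilt through a
bounded PD rule (P = 0.25 rad/m, D = 0.4 rad·s/m, |θ| ≤ 0.04 rad — chosen
once to give stable, human-like completion times around 4.5 s), converts
the tilt to the differential hand displacement that realises it (including
a feed-forward term cancelling the board's sag under the ball's weight),
and issues one minimum-jerk submovement per side (0.3 s default).

Role structure is imposed by construction, which is what makes recovery
testable:

* **gain share** — each side executes a fixed fraction of every
  differential displacement; shares sum to 1 across the dyad;
* **reaction delay** — the follower's submovement onsets lag by a fixed
  delay.  The follower *catches up*: its movement is compressed so that it
  ends together with the leader's.  Without catch-up the two movements
  overlap so little that board rotations are dominated by single-sided
  samples and the aligned-delay analysis has almost nothing to measure —
  which says something true about strongly lagged dyads but leaves the
  delay estimator untested;
* **motor noise** — additive Gaussian perturbation of submovement
  amplitudes (0.5 mm default);
* **sensor noise** — 0.2 mm / 0.2 mrad white noise added to the recorded
  (not simulated) kinematics, emulating encoder noise.  This matters for
  the segmenter: perfectly noise-free commanded trajectories are *exactly*
  constant between submovements, and a Gaussian-emission HMM then collapses
  its stationary state onto a near-zero-variance spike and separates states
  by scale instead of direction.

What the generator does **not** emulate: learning across blocks, reactions
to the haptic feedback itself (the controller is state-feedback only, so
haptic condition does not causally affect synthetic behaviour), visual or
neuromotor delays beyond the single reaction-delay parameter, and
game-theoretic partner modelling.  Passing recovery tests therefore shows
the *estimators* are correct, not that human dyads behave like these
agents.

## Preprocessing and segmentation

All analysis channels are low-pass filtered with a 10th-order Butterworth
(20 Hz cutoff, second-order-section form) applied forward and backward:
zero phase lag, squared magnitude (amplitude ½ at the cutoff), with
odd-reflection padding of 3× the order.  Velocities are central
differences (one-sided at the ends).

Movement segmentation fits one three-state Gaussian-emission HMM per
channel class per dyad session (left hand, right hand, board) on the
pooled successful-trial velocities, EM with 5 restarts (best likelihood
kept, 50 iterations, per-restart k-means initialisation, variance floor
1e-7), capped at 50 000 pooled samples for fitting; decoding is Viterbi on
full trials.  States are relabelled by ascending emission mean to
down/stationary/up (hands) or cw/stationary/ccw (board).  Segments shorter
than 50 ms are merged into the neighbouring state with the higher mean
posterior over the segment, shortest first.  Near-constant input is
rejected as degenerate rather than fitted.

## Metrics

* **Interaction dynamics** — per sample: opposite hand directions =
  aligned (same board rotation), same direction = opposed, one mover =
  single, none = stationary.  Each sample stands for the interval to the
  next sample, so category durations sum exactly to completion time.
* **Delay** — for every board-rotation segment whose plurality category is
  aligned, each hand contributes its closest direction-consistent movement
  onset within ±0.5 s of the board onset; delay = onset_L − onset_R
  (positive ⇒ the right side moved first).  The ±0.5 s window and the
  direction-consistency requirement reject spurious pairings.
* **Movement ratio** — ordinary least squares of z_L on −θ and z_R on θ at
  board-segment endpoints (the hand positions when the board has just
  stopped rotating), pooled per block, at least 5 points;
  p_L = k_L/(k_L + k_R).  A non-positive gain sum leaves the ratio
  undefined and flagged.
* **Corrective movement** — mean absolute deviation of each hand from its
  trailing 200 ms moving average (window truncated at trial start,
  current sample included); the ratio flags an all-but-unmoved dyad
  (total below 1e-12) and reports 0.5/0.5.
* **Unilateral manipulation** — path length (Σ|Δz|) of the moving hand
  over single-category samples, per side; share of the grand total.
* **MTTA** — hand trajectories in a window 0.5 s before to 1 s after each
  board-rotation onset, shifted to zero at onset, left side sign-flipped,
  normalised by the required total movement
  L_req = 2l(sin θ_end − sin θ_start), averaged per role × condition.
  Windows crossing trial boundaries are dropped, as are segments with
  |L_req| < 0.1 mm.
* **Leader call** — the movement-ratio side is primary; when its share is
  within 0.05 of ½ *and* the four metrics disagree, no leader is declared.
* **Dyadic improvement** — x = 1 − T_partner/T, y = 1 − T_dyad/T from
  stable-phase completion times.

## Statistics

`compare_conditions` runs a one-way repeated-measures ANOVA over the
haptic conditions on per-subject condition means (complete designs only,
no imputation), reporting the uncorrected F alongside the
Greenhouse-Geisser-corrected p, plus all pairwise paired t-tests with Holm
step-down adjustment.  Degenerate designs with no condition effect and no
error variance report the null result (F = 0, p = 1) rather than 0/0.
Mixed-effects analyses of partially crossed designs are deliberately not
implemented; the tidy per-trial tables are the intended hand-off to
dedicated statistical software.

## Problem sizes and determinism

The shipped tests and the acceptance script use 20-trial sessions per
recovery dyad (5 blocks × 4 trials covering all five conditions) and a
2-dyad × 5-block × 2-trial study for the end-to-end determinism check;
these sizes were chosen as the smallest at which every estimator has
enough observations (≈200 movement-ratio endpoints, ≈120 delay
observations per dyad).  Every random draw descends from one seed through
`numpy.random.default_rng`; recordings and metric tables are written with
`%.17g` formatting and reread with round-trip float parsing, so repeated
runs are byte-identical.

## Known limitations

* The generator's controller is not fitted to human data; absolute values
  of coordination ratios or completion times are properties of the
  controller, not predictions about people.
* HMM segmentation quality depends on the velocity distribution; extremely
  asymmetric or movement-free sessions are rejected rather than segmented.
* The delay estimator carries a small onset-detection bias (movement
  amplitude affects when velocity crosses the state boundary); with the
  default dyads it stays well under the 20 ms recovery tolerance.
* The Unrelated condition affects only what force is rendered, not the
  synthetic agents' behaviour.
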
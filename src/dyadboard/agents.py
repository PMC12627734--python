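"""Synthetic dyads: intermittent discrete-movement controllers with known roles.

Human operators of the board-ball task act through short, discrete hand
movements rather than continuous tracking.  The generator emulates this with
a shared intermittent planner: whenever both hands are idle and the ball is
off target (or still moving), the planner maps the ball error to a desired
board tilt through a bounded proportional-derivative rule, converts the tilt
into a differential hand displacement, and issues one minimum-jerk
submovement per side.  Leader-follower asymmetry is imposed by construction:
each side executes a fixed share of the differential displacement
(``gain_share``) and the follower's submovement onsets are delayed by its
``reaction_delay``.  Because the asymmetry is built in, every downstream role
metric has an exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .simulator import (
    CONDITION_LABELS,
    BoardBallState,
    HandInput,
    HapticCondition,
    ModelParams,
    TrialConfig,
    TrialRecording,
    UnrelatedProfile,
    equilibrium_height,
    simulate_trial,
)

__all__ = [
    "AgentParams",
    "DyadSpec",
    "DyadGroundTruth",
    "MinJerkSegment",
    "desired_angle",
    "plan_submovement",
    "IntermittentDyadPolicy",
    "make_condition_schedule",
    "make_unrelated_profile",
    "generate_dyad_dataset",
]


@dataclass(frozen=True)
class AgentParams:
    """One agent's control style.

    gain_share : fraction of the required differential displacement this side
        produces (the two shares of a dyad must sum to 1).
    reaction_delay : s added to every submovement onset (0 for the leader).
    motor_noise_sd : m, additive Gaussian noise on submovement amplitude.
    trigger_threshold : m, ball-error deadband below which no new submovement
        is planned (provided the ball is also slow).
    submovement_duration : s, duration of each minimum-jerk submovement.
    angle_p_gain / angle_d_gain : rad per m and rad per (m/s), the PD map from
        ball error and velocity to the desired board tilt.
    max_angle : rad, bound on the commanded tilt.
    """

    gain_share: float = 0.5
    reaction_delay: float = 0.0
    motor_noise_sd: float = 0.0005
    trigger_threshold: float = 0.01
    submovement_duration: float = 0.3
    angle_p_gain: float = 0.25
    angle_d_gain: float = 0.4
    max_angle: float = 0.04

    def __post_init__(self) -> None:
        if not 0.0 <= self.gain_share <= 1.0:
            raise ValueError("gain_share must lie in [0, 1]")
        if self.reaction_delay < 0:
            raise ValueError("reaction_delay must be >= 0")
        if self.submovement_duration <= 0:
            raise ValueError("submovement_duration must be > 0")

    def as_dict(self) -> dict:
        return {
            "gain_share": self.gain_share,
            "reaction_delay": self.reaction_delay,
            "motor_noise_sd": self.motor_noise_sd,
            "trigger_threshold": self.trigger_threshold,
            "submovement_duration": self.submovement_duration,
            "angle_p_gain": self.angle_p_gain,
            "angle_d_gain": self.angle_d_gain,
            "max_angle": self.max_angle,
        }


@dataclass(frozen=True)
class DyadSpec:
    """A pair of agents; shares must sum to 1."""

    left: AgentParams = field(default_factory=AgentParams)
    right: AgentParams = field(default_factory=AgentParams)
    dyad_id: str = "dyad0"
    pairing: str = "dyadic"

    def __post_init__(self) -> None:
        if abs(self.left.gain_share + self.right.gain_share - 1.0) > 1e-9:
            raise ValueError(
                "gain shares must sum to 1 "
                f"(got {self.left.gain_share} + {self.right.gain_share})"
            )

    @property
    def true_leader(self) -> str:
        if self.left.gain_share > self.right.gain_share:
            return "L"
        if self.right.gain_share > self.left.gain_share:
            return "R"
        return "none"

    @property
    def true_follower_delay(self) -> float:
        leader = self.true_leader
        if leader == "L":
            return self.right.reaction_delay
        if leader == "R":
            return self.left.reaction_delay
        return max(self.left.reaction_delay, self.right.reaction_delay)


@dataclass
class DyadGroundTruth:
    """What the generator actually imposed, for parameter-recovery tests."""

    dyad_id: str
    true_leader: str
    true_gain_share: tuple[float, float]
    true_follower_delay: float
    condition_schedule: list[str]
    agents: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "dyad_id": self.dyad_id,
            "true_leader": self.true_leader,
            "true_gain_share": list(self.true_gain_share),
            "true_follower_delay": self.true_follower_delay,
            "condition_schedule": list(self.condition_schedule),
            "agents": self.agents,
        }


def desired_angle(
    x_ball: float,
    x_ball_dot: float,
    x_target: float,
    p_gain: float,
    d_gain: float,
    max_angle: float,
) -> float:
    """Bounded PD map from ball error to target board tilt.

    A ball left of its target (negative error) needs a negative tilt, which
    accelerates it rightward; the derivative term brakes an approaching ball.
    """
    raw = p_gain * (x_ball - x_target) + d_gain * x_ball_dot
    return max(-max_angle, min(max_angle, raw))


@dataclass(frozen=True)
class MinJerkSegment:
    """Minimum-jerk point-to-point hand movement; rest-to-rest by construction."""

    onset: float
    duration: float
    z_start: float
    z_end: float

    @property
    def end_time(self) -> float:
        return self.onset + self.duration

    def position(self, t: float) -> float:
        if t <= self.onset:
            return self.z_start
        if t >= self.end_time:
            return self.z_end
        tau = (t - self.onset) / self.duration
        s = tau * tau * tau * (10.0 + tau * (-15.0 + 6.0 * tau))
        return self.z_start + (self.z_end - self.z_start) * s

    def velocity(self, t: float) -> float:
        if t <= self.onset or t >= self.end_time:
            return 0.0
        tau = (t - self.onset) / self.duration
        ds = tau * tau * (30.0 + tau * (-60.0 + 30.0 * tau))
        return (self.z_end - self.z_start) * ds / self.duration


def plan_submovement(
    current_z: float, target_z: float, duration: float, onset: float
) -> MinJerkSegment:
    """A minimum-jerk segment from the current to the target height."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    return MinJerkSegment(onset=onset, duration=duration, z_start=current_z, z_end=target_z)


class _HandTrack:
    """One side's submovement queue; position is continuous across segments."""

    def __init__(self, z0: float) -> None:
        self.segments: list[MinJerkSegment] = []
        self.rest = z0

    @property
    def busy_until(self) -> float:
        return self.segments[-1].end_time if self.segments else 0.0

    @property
    def final_z(self) -> float:
        return self.segments[-1].z_end if self.segments else self.rest

    def push(self, amplitude: float, duration: float, onset: float) -> None:
        onset = max(onset, self.busy_until)
        z0 = self.final_z
        self.segments.append(plan_submovement(z0, z0 + amplitude, duration, onset))
        # segments older than the active one never matter again
        if len(self.segments) > 4:
            del self.segments[:-4]

    def sample(self, t: float) -> tuple[float, float]:
        z, v = self.rest, 0.0
        for seg in self.segments:
            if t >= seg.end_time:
                z, v = seg.z_end, 0.0
            elif t > seg.onset:
                return seg.position(t), seg.velocity(t)
            else:
                break
        return z, v


class IntermittentDyadPolicy:
    """Shared intermittent planner driving both hands of a dyad.

    The planner wakes whenever both hands have finished their queued
    submovements.  If the ball error exceeds the trigger deadband or the ball
    is still moving faster than ``velocity_trigger``, it computes the desired
    tilt, the differential hand displacement that realises it (including a
    feed-forward term that cancels the board's sag under the ball's gravity
    torque), splits the displacement by the two gain shares, perturbs each
    amplitude with motor noise, and queues one submovement per side, the
    follower's delayed by its reaction delay.
    """

    def __init__(
        self,
        spec: DyadSpec,
        params: ModelParams,
        goal_x: float,
        rng: np.random.Generator,
        velocity_trigger: float = 0.02,
    ) -> None:
        self.spec = spec
        self.params = params
        self.goal_x = goal_x
        self.rng = rng
        self.velocity_trigger = velocity_trigger
        z_eq = equilibrium_height(params)
        self.left = _HandTrack(z_eq)
        self.right = _HandTrack(z_eq)
        self.n_plans = 0

    def _plan(self, t: float, state: BoardBallState) -> None:
        p = self.params
        sl, sr = self.spec.left, self.spec.right
        theta_star = desired_angle(
            state.x_ball,
            state.x_ball_dot,
            self.goal_x,
            sl.angle_p_gain,
            sl.angle_d_gain,
            sl.max_angle,
        )
        # differential displacement for the tilt, plus feed-forward for the
        # tilt the ball's weight induces through the finite hand stiffness
        sag = p.ball_mass * p.gravity * state.x_ball / (p.hand_stiffness * p.half_length)
        d_star = 2.0 * p.half_length * math.sin(theta_star) + sag
        d_now = self.right.final_z - self.left.final_z
        delta = d_star - d_now
        if abs(delta) < 1e-4:
            return
        amp_l = -sl.gain_share * delta
        amp_r = sr.gain_share * delta
        if sl.motor_noise_sd > 0:
            amp_l += self.rng.normal(0.0, sl.motor_noise_sd)
        if sr.motor_noise_sd > 0:
            amp_r += self.rng.normal(0.0, sr.motor_noise_sd)
        # a delayed side compresses its movement to finish with its partner
        # ("catch-up"): the onset lag equals the reaction delay while the
        # movement endpoints stay synchronised
        dur_l = max(sl.submovement_duration - sl.reaction_delay, 0.5 * sl.submovement_duration)
        dur_r = max(sr.submovement_duration - sr.reaction_delay, 0.5 * sr.submovement_duration)
        self.left.push(amp_l, dur_l, t + sl.reaction_delay)
        self.right.push(amp_r, dur_r, t + sr.reaction_delay)
        self.n_plans += 1

    def __call__(
        self, t: float, state: BoardBallState, feedback: tuple[float, float]
    ) -> HandInput:
        if t >= self.left.busy_until and t >= self.right.busy_until:
            err = abs(state.x_ball - self.goal_x)
            if (
                err > self.spec.left.trigger_threshold
                or abs(state.x_ball_dot) > self.velocity_trigger
            ):
                self._plan(t, state)
        zl, vl = self.left.sample(t)
        zr, vr = self.right.sample(t)
        return HandInput(z_left=zl, z_right=zr, z_left_dot=vl, z_right_dot=vr)


def make_condition_schedule(
    n_blocks: int, rng: np.random.Generator, conditions: Sequence[str] = CONDITION_LABELS
) -> list[str]:
    """Blocks organised into sets covering every condition in shuffled order."""
    if n_blocks <= 0:
        raise ValueError("n_blocks must be > 0")
    schedule: list[str] = []
    while len(schedule) < n_blocks:
        block_set = list(conditions)
        rng.shuffle(block_set)
        schedule.extend(block_set)
    return schedule[:n_blocks]


def make_unrelated_profile(
    spec: DyadSpec,
    params: ModelParams,
    config: TrialConfig,
    seed: int,
    ramp_duration: float = 0.1,
) -> UnrelatedProfile:
    """Record the feedback channel of one Full-condition run as a replay profile."""
    rng = np.random.default_rng(seed)
    policy = IntermittentDyadPolicy(spec, params, config.target_positions[1], rng)
    rec = simulate_trial(
        policy,
        HapticCondition("Full"),
        config,
        params,
        start_side="left",
        seed=seed,
        dyad_id=spec.dyad_id,
    )
    return UnrelatedProfile(rec.FB_L, rec.FB_R, dt=params.dt, ramp_duration=ramp_duration)


def generate_dyad_dataset(
    spec: DyadSpec,
    n_blocks: int,
    trials_per_block: int,
    seed: int,
    *,
    condition_schedule: Sequence[str] | None = None,
    params: ModelParams | None = None,
    config: TrialConfig | None = None,
    max_retries_per_block: int | None = None,
    measurement_noise_sd: float = 2e-4,
) -> tuple[list[TrialRecording], DyadGroundTruth]:
    """Simulate a block-structured session for one synthetic dyad.

    Returns every recording (failed trials are repeated until the block's
    quota of successes is met, and the failures are kept in the list with
    their outcome marked) plus the ground truth that generated them.  The
    whole run is reproducible from ``seed``.

    ``measurement_noise_sd`` is white sensor noise (m for the hand channels,
    rad for the board angle) added to the recorded kinematics, emulating
    encoder noise of the haptic devices; it does not feed back into the
    dynamics.
    """
    params = params or ModelParams()
    config = config or TrialConfig()
    if trials_per_block <= 0:
        raise ValueError("trials_per_block must be > 0")
    rng = np.random.default_rng(seed)
    if condition_schedule is None:
        condition_schedule = make_condition_schedule(n_blocks, rng)
    else:
        condition_schedule = list(condition_schedule)
        if len(condition_schedule) != n_blocks:
            raise ValueError("condition_schedule length must equal n_blocks")
        for label in condition_schedule:
            if label not in CONDITION_LABELS:
                raise ValueError(f"unknown condition {label!r}")

    profile: UnrelatedProfile | None = None
    if "Unrelated" in condition_schedule:
        profile_seed = int(rng.integers(2**31))
        profile = make_unrelated_profile(spec, params, config, profile_seed)

    if max_retries_per_block is None:
        max_retries_per_block = 5 * trials_per_block

    recordings: list[TrialRecording] = []
    trial_counter = 0
    start_side = "left"
    for block, label in enumerate(condition_schedule):
        condition = HapticCondition(label, profile if label == "Unrelated" else None)
        successes = 0
        attempts = 0
        while successes < trials_per_block:
            if attempts >= trials_per_block + max_retries_per_block:
                break  # pathological spec; keep whatever was produced
            trial_seed = int(rng.integers(2**31))
            policy_rng = np.random.default_rng(trial_seed)
            goal_x = (
                config.target_positions[1]
                if start_side == "left"
                else config.target_positions[0]
            )
            policy = IntermittentDyadPolicy(spec, params, goal_x, policy_rng)
            rec = simulate_trial(
                policy,
                condition,
                config,
                params,
                start_side=start_side,
                seed=trial_seed,
                dyad_id=spec.dyad_id,
                pairing=spec.pairing,  # type: ignore[arg-type]
                block=block,
                trial=trial_counter,
            )
            if measurement_noise_sd > 0:
                n = rec.n_samples
                rec.z_L = rec.z_L + policy_rng.normal(0.0, measurement_noise_sd, n)
                rec.z_R = rec.z_R + policy_rng.normal(0.0, measurement_noise_sd, n)
                rec.theta = rec.theta + policy_rng.normal(0.0, measurement_noise_sd, n)
            recordings.append(rec)
            trial_counter += 1
            attempts += 1
            if rec.outcome == "success":
                successes += 1
                start_side = "right" if start_side == "left" else "left"
            # failed trials are repeated from the same start side

    truth = DyadGroundTruth(
        dyad_id=spec.dyad_id,
        true_leader=spec.true_leader,
        true_gain_share=(spec.left.gain_share, spec.right.gain_share),
        true_follower_delay=spec.true_follower_delay,
        condition_schedule=list(condition_schedule),
        agents={"left": spec.left.as_dict(), "right": spec.right.as_dict()},
    )
    return recordings, truth

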
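"""Virtual board-ball task: rigid-body dynamics, haptic feedback, trial protocol.

The task is a two-person (or bimanual) ball-and-beam problem.  A light board
is suspended at its centre by a soft vertical spring and held at its two ends
through stiff spring-damper "hands".  A ball rolls without friction along the
board; tilting the board accelerates the ball.  The goal of a trial is to
slide the ball from one target area to the other and keep it there for a hold
period.

Coordinate conventions: ``z`` is up, ``theta`` is the board rotation about the
x-axis with counterclockwise positive, and ``x_ball`` is the ball position
along the board with 0 at the board centre.  With ``theta > 0`` the *right*
control point (``z_board + l sin(theta)``) is raised and the ball accelerates
in the negative x direction (``x_ball'' = -g sin(theta)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "BoardBallState",
    "HandInput",
    "HapticCondition",
    "UnrelatedProfile",
    "TrialConfig",
    "TrialRecording",
    "SuccessMonitor",
    "control_points",
    "control_point_velocities",
    "hand_forces",
    "spring_force",
    "step_dynamics",
    "feedback_forces",
    "simulate_trial",
    "monitor_events",
    "equilibrium_height",
    "CONDITION_LABELS",
    "CHANNEL_NAMES",
]

CONDITION_LABELS = ("Without", "Full", "Partner", "Environment", "Unrelated")

CHANNEL_NAMES = (
    "t",
    "z_L",
    "z_R",
    "F_L",
    "F_R",
    "FB_L",
    "FB_R",
    "z_board",
    "theta",
    "x_ball",
)


@dataclass(frozen=True)
class ModelParams:
    """Physical constants of the board-ball model plus the integration step.

    Defaults are the constants of the dyadic experiment (heavy 0.15 kg ball);
    :meth:`light_ball` gives the 0.05 kg variant used in the two-condition
    experiment.

    Units: masses kg, gravity m/s^2, stiffnesses N/m, damping N s/m, lengths
    m, inertia kg m^2, ``dt`` s.
    """

    board_mass: float = 0.01
    ball_mass: float = 0.15
    gravity: float = 9.81
    hand_stiffness: float = 200.0
    hand_damping: float = 2.0
    spring_stiffness: float = 140.0
    half_length: float = 0.25
    inertia: float = 0.0004
    dt: float = 0.001

    def __post_init__(self) -> None:
        for name in (
            "board_mass",
            "ball_mass",
            "gravity",
            "hand_stiffness",
            "hand_damping",
            "spring_stiffness",
            "half_length",
            "inertia",
            "dt",
        ):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"ModelParams.{name} must be finite and > 0, got {value!r}")

    @classmethod
    def light_ball(cls, **overrides) -> "ModelParams":
        """Parameters with the 0.05 kg ball."""
        overrides.setdefault("ball_mass", 0.05)
        return cls(**overrides)

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt

    def as_dict(self) -> dict:
        return {
            "board_mass": self.board_mass,
            "ball_mass": self.ball_mass,
            "gravity": self.gravity,
            "hand_stiffness": self.hand_stiffness,
            "hand_damping": self.hand_damping,
            "spring_stiffness": self.spring_stiffness,
            "half_length": self.half_length,
            "inertia": self.inertia,
            "dt": self.dt,
        }


@dataclass
class BoardBallState:
    """Instantaneous state of board (height, tilt) and ball."""

    z_board: float = 0.0
    z_board_dot: float = 0.0
    theta: float = 0.0
    theta_dot: float = 0.0
    x_ball: float = 0.0
    x_ball_dot: float = 0.0

    def is_finite(self) -> bool:
        return all(
            math.isfinite(v)
            for v in (
                self.z_board,
                self.z_board_dot,
                self.theta,
                self.theta_dot,
                self.x_ball,
                self.x_ball_dot,
            )
        )

    def copy(self) -> "BoardBallState":
        return replace(self)


@dataclass
class HandInput:
    """Commanded hand heights and vertical velocities for the two sides."""

    z_left: float = 0.0
    z_right: float = 0.0
    z_left_dot: float = 0.0
    z_right_dot: float = 0.0


def equilibrium_height(params: ModelParams) -> float:
    """Static rest height of the board centre, ``-(M + m) g / k_s``.

    With the ball centred and the hands holding this same height, every force
    in the vertical balance cancels and the board is in equilibrium.
    """
    return -(params.board_mass + params.ball_mass) * params.gravity / params.spring_stiffness


def control_points(state: BoardBallState, params: ModelParams) -> tuple[float, float]:
    """Heights of the two control points: ``z -/+ l sin(theta)`` (left, right)."""
    offset = params.half_length * math.sin(state.theta)
    return (state.z_board - offset, state.z_board + offset)


def control_point_velocities(state: BoardBallState, params: ModelParams) -> tuple[float, float]:
    """Vertical velocities of the control points, by differentiating their heights."""
    term = params.half_length * math.cos(state.theta) * state.theta_dot
    return (state.z_board_dot - term, state.z_board_dot + term)


def hand_forces(hands: HandInput, state: BoardBallState, params: ModelParams) -> tuple[float, float]:
    """Forces the two hands exert on the board through the spring-damper grips.

    ``F_side = k_h (z_side - z_P,side) + c_h (z_side' - z_P,side')`` where
    ``z_P`` is the control-point height on that side.
    """
    zp_l, zp_r = control_points(state, params)
    vp_l, vp_r = control_point_velocities(state, params)
    f_l = params.hand_stiffness * (hands.z_left - zp_l) + params.hand_damping * (
        hands.z_left_dot - vp_l
    )
    f_r = params.hand_stiffness * (hands.z_right - zp_r) + params.hand_damping * (
        hands.z_right_dot - vp_r
    )
    return (f_l, f_r)


def spring_force(state: BoardBallState, params: ModelParams) -> float:
    """Restoring force of the central suspension spring, ``F_s = -k_s z_board``."""
    return -params.spring_stiffness * state.z_board


def accelerations(
    state: BoardBallState, f_left: float, f_right: float, params: ModelParams
) -> tuple[float, float, float]:
    """Instantaneous (z_board'', theta'', x_ball'') for the given hand forces.

    Vertical: the board carries its own weight, the ball's normal load
    (simplified to ``m g cos^2(theta)`` so the ball never leaves the board),
    the central spring and the two hand forces.  Rotation: the differential
    hand force acts at the lever arm ``l cos(theta)`` against the ball's
    gravity torque.  The ball is a frictionless point mass on an incline.
    """
    cos_t = math.cos(state.theta)
    f_s = spring_force(state, params)
    az = (
        f_left
        + f_right
        - params.board_mass * params.gravity
        - params.ball_mass * params.gravity * cos_t * cos_t
        + f_s
    ) / params.board_mass
    ath = (
        (f_right - f_left) * params.half_length * cos_t
        - params.ball_mass * params.gravity * state.x_ball * cos_t
    ) / params.inertia
    ax = -params.gravity * math.sin(state.theta)
    return (az, ath, ax)


def step_dynamics(
    state: BoardBallState, f_left: float, f_right: float, params: ModelParams
) -> BoardBallState:
    """Advance the state by one ``dt``.

    Semi-implicit (symplectic) Euler on the velocities with a trapezoidal
    position update: velocities are advanced first with the current
    accelerations, positions then move with the average of old and new
    velocity.  For a constant acceleration this reproduces the exact
    ``x0 + v0 t + a t^2 / 2`` kinematics, which keeps the frictionless ball
    roll accurate to well under 0.1 mm over a second at the 1 ms step, while
    retaining the stability of the velocity-first update for the stiff hand
    springs.
    """
    if not (math.isfinite(f_left) and math.isfinite(f_right)):
        raise ValueError(f"non-finite hand forces ({f_left!r}, {f_right!r})")
    dt = params.dt
    az, ath, ax = accelerations(state, f_left, f_right, params)
    vz = state.z_board_dot + az * dt
    vth = state.theta_dot + ath * dt
    vx = state.x_ball_dot + ax * dt
    return BoardBallState(
        z_board=state.z_board + 0.5 * (state.z_board_dot + vz) * dt,
        z_board_dot=vz,
        theta=state.theta + 0.5 * (state.theta_dot + vth) * dt,
        theta_dot=vth,
        x_ball=state.x_ball + 0.5 * (state.x_ball_dot + vx) * dt,
        x_ball_dot=vx,
    )


@dataclass
class UnrelatedProfile:
    """Pre-recorded feedback force pair replayed in the Unrelated condition.

    When a trial outlasts the profile it is replayed; each wrap is bridged by
    a linear ramp of ``ramp_duration`` seconds from the profile's final value
    into its restarted samples, so the rendered force never jumps.
    """

    fb_left: np.ndarray
    fb_right: np.ndarray
    dt: float = 0.001
    ramp_duration: float = 0.1

    def __post_init__(self) -> None:
        self.fb_left = np.asarray(self.fb_left, dtype=float)
        self.fb_right = np.asarray(self.fb_right, dtype=float)
        if self.fb_left.ndim != 1 or self.fb_left.shape != self.fb_right.shape:
            raise ValueError("feedback profiles must be 1-D arrays of equal length")
        if self.fb_left.size == 0:
            raise ValueError("feedback profile is empty")
        if not (np.isfinite(self.fb_left).all() and np.isfinite(self.fb_right).all()):
            raise ValueError("feedback profile contains non-finite values")
        if self.ramp_duration <= 0:
            raise ValueError("ramp_duration must be > 0")

    @property
    def duration(self) -> float:
        return self.fb_left.size * self.dt

    def at(self, t: float) -> tuple[float, float]:
        """Profile value at time ``t >= 0`` with ramped looping."""
        period = self.duration
        n = self.fb_left.size
        tau = t % period
        idx = min(int(round(tau / self.dt)), n - 1)
        raw_l = float(self.fb_left[idx])
        raw_r = float(self.fb_right[idx])
        if t < period or tau >= self.ramp_duration:
            return (raw_l, raw_r)
        # first ramp_duration seconds of a replay: blend from the held final
        # value into the restarted profile
        w = tau / self.ramp_duration
        end_l = float(self.fb_left[-1])
        end_r = float(self.fb_right[-1])
        return ((1.0 - w) * end_l + w * raw_l, (1.0 - w) * end_r + w * raw_r)


@dataclass
class HapticCondition:
    """One of the five feedback conditions; Unrelated carries a replay profile."""

    label: str
    profile: UnrelatedProfile | None = None

    def __post_init__(self) -> None:
        if self.label not in CONDITION_LABELS:
            raise ValueError(f"unknown haptic condition {self.label!r}; expected one of {CONDITION_LABELS}")
        if self.label == "Unrelated" and self.profile is None:
            raise ValueError("Unrelated condition requires a replay profile")


def feedback_forces(
    f_left: float,
    f_right: float,
    f_spring: float,
    condition: HapticCondition,
    t: float = 0.0,
) -> tuple[float, float]:
    """Force rendered to each hand under the given haptic condition.

    Without: nothing.  Full: the reaction of the applied force.  Partner: only
    the central-spring force, split equally (the component that carries the
    partner's action).  Environment: the remainder, i.e. Full minus Partner.
    Unrelated: a replayed profile indexed by trial time.  By construction
    Partner + Environment == Full, elementwise.
    """
    label = condition.label
    if label == "Without":
        return (0.0, 0.0)
    if label == "Full":
        return (-f_left, -f_right)
    if label == "Partner":
        half = 0.5 * f_spring
        return (half, half)
    if label == "Environment":
        half = 0.5 * f_spring
        return (-f_left - half, -f_right - half)
    # Unrelated; profile presence enforced by HapticCondition
    assert condition.profile is not None
    return condition.profile.at(t)


@dataclass(frozen=True)
class TrialConfig:
    """Trial protocol: target geometry, hold criterion, reset phase, safety cap."""

    target_positions: tuple[float, float] = (-0.15, 0.15)
    target_half_width: float = 0.03
    hold_duration: float = 1.5
    reset_hold: float = 1.0
    reset_angle_tol: float = 0.02
    max_duration: float = 60.0

    def __post_init__(self) -> None:
        if self.hold_duration <= 0:
            raise ValueError("hold_duration must be > 0")
        if self.target_half_width <= 0:
            raise ValueError("target_half_width must be > 0")
        if self.max_duration <= 0:
            raise ValueError("max_duration must be > 0")

    def validate_against(self, params: ModelParams) -> None:
        for x in self.target_positions:
            if abs(x) + self.target_half_width >= params.half_length:
                raise ValueError(
                    f"target at {x} m with half-width {self.target_half_width} m "
                    f"extends beyond the board (half-length {params.half_length} m)"
                )


@dataclass
class TrialRecording:
    """One trial: multichannel 1 kHz time series plus metadata.

    Channels (all numpy arrays of equal length): ``t, z_L, z_R, F_L, F_R,
    FB_L, FB_R, z_board, theta, x_ball``, SI units.
    """

    t: np.ndarray
    z_L: np.ndarray
    z_R: np.ndarray
    F_L: np.ndarray
    F_R: np.ndarray
    FB_L: np.ndarray
    FB_R: np.ndarray
    z_board: np.ndarray
    theta: np.ndarray
    x_ball: np.ndarray
    dyad_id: str = "dyad0"
    pairing: Literal["bimanual", "dyadic"] = "dyadic"
    condition: str = "Without"
    block: int = 0
    trial: int = 0
    start_side: Literal["left", "right"] = "left"
    outcome: Literal["success", "failure"] = "success"
    failure_reason: str | None = None
    completion_time: float = float("nan")
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in CHANNEL_NAMES:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def channels(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in CHANNEL_NAMES}

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else float("nan")

    def metadata(self) -> dict:
        return {
            "dyad_id": self.dyad_id,
            "pairing": self.pairing,
            "condition": self.condition,
            "block": self.block,
            "trial": self.trial,
            "start_side": self.start_side,
            "outcome": self.outcome,
            "failure_reason": self.failure_reason,
            "completion_time": self.completion_time,
            "seed": self.seed,
            "params": self.params,
        }

    def validate(self) -> None:
        n = self.t.size
        if n < 2:
            raise ValueError("recording must contain at least two samples")
        for name in CHANNEL_NAMES:
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"channel {name} has shape {arr.shape}, expected ({n},)")
        steps = np.diff(self.t)
        if not np.all(steps > 0):
            raise ValueError("time channel must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("time channel must be uniformly sampled")
        if self.pairing not in ("bimanual", "dyadic"):
            raise ValueError(f"unknown pairing {self.pairing!r}")
        if self.condition not in CONDITION_LABELS:
            raise ValueError(f"unknown condition label {self.condition!r}")
        if self.outcome not in ("success", "failure"):
            raise ValueError(f"unknown outcome {self.outcome!r}")


class SuccessMonitor:
    """Tracks in-target dwell, roll-off and timeout over a state stream.

    Feed one ball position per sample via :meth:`update`; events are strings
    ``enter``, ``exit``, ``success``, ``failure``.  Failure (roll-off) takes
    precedence over everything else at the sample where it occurs.  Success
    fires at the first sample whose continuous dwell time reaches the hold
    duration (dwell is measured from the entry sample, so entry itself counts
    as dwell 0).
    """

    def __init__(
        self,
        config: TrialConfig,
        goal_x: float,
        half_length: float,
        dt: float,
    ) -> None:
        self.config = config
        self.goal_x = goal_x
        self.half_length = half_length
        self.dt = dt
        self._enter_index: int | None = None
        self._index = -1
        self.done: str | None = None  # "success" | "failure" | "timeout"

    def update(self, x_ball: float) -> list[str]:
        if self.done is not None:
            return []
        self._index += 1
        i = self._index
        events: list[str] = []
        if abs(x_ball) > self.half_length:
            self.done = "failure"
            return ["failure"]
        inside = abs(x_ball - self.goal_x) <= self.config.target_half_width
        if inside and self._enter_index is None:
            self._enter_index = i
            events.append("enter")
        elif not inside and self._enter_index is not None:
            self._enter_index = None
            events.append("exit")
        if self._enter_index is not None:
            dwell = (i - self._enter_index) * self.dt
            if dwell >= self.config.hold_duration - 1e-12:
                self.done = "success"
                events.append("success")
        if self.done is None and i * self.dt >= self.config.max_duration:
            self.done = "timeout"
            events.append("timeout")
        return events


def monitor_events(
    x_ball: Sequence[float],
    config: TrialConfig,
    goal_x: float,
    half_length: float,
    dt: float,
) -> list[tuple[int, str]]:
    """Run :class:`SuccessMonitor` over a recorded ball trajectory.

    Returns ``(sample_index, event)`` pairs; stops after a terminal event.
    """
    monitor = SuccessMonitor(config, goal_x, half_length, dt)
    out: list[tuple[int, str]] = []
    for i, x in enumerate(x_ball):
        for ev in monitor.update(float(x)):
            out.append((i, ev))
        if monitor.done is not None:
            break
    return out


DyadPolicy = Callable[[float, BoardBallState, tuple[float, float]], HandInput]


def simulate_trial(
    policy: DyadPolicy,
    condition: HapticCondition,
    config: TrialConfig,
    params: ModelParams,
    *,
    start_side: Literal["left", "right"] = "left",
    seed: int | None = None,
    dyad_id: str = "dyad0",
    pairing: Literal["bimanual", "dyadic"] = "dyadic",
    block: int = 0,
    trial: int = 0,
) -> TrialRecording:
    """Run one trial of the protocol under ``policy`` and record every channel.

    The ball starts clamped at the centre of the start target and is released
    at ``t = 0``; the board starts at its static rest height with hands
    holding it level.  The trial ends in success when the ball has remained
    continuously inside the goal target for the hold duration (the recorded
    completion time includes that hold), in failure when the ball passes a
    board end, or in a timeout failure at ``max_duration``.

    ``policy(t, state, (FB_L, FB_R)) -> HandInput`` is queried every step with
    the current state and the feedback forces just rendered.
    """
    config.validate_against(params)
    if start_side not in ("left", "right"):
        raise ValueError(f"start_side must be 'left' or 'right', got {start_side!r}")
    start_x = config.target_positions[0] if start_side == "left" else config.target_positions[1]
    goal_x = config.target_positions[1] if start_side == "left" else config.target_positions[0]

    dt = params.dt
    z_eq = equilibrium_height(params)
    state = BoardBallState(z_board=z_eq, x_ball=start_x)
    monitor = SuccessMonitor(config, goal_x, params.half_length, dt)

    n_cap = int(math.ceil(config.max_duration / dt)) + 2
    cols: dict[str, list[float]] = {name: [] for name in CHANNEL_NAMES}
    append = {name: cols[name].append for name in CHANNEL_NAMES}

    t = 0.0
    completion_time = float("nan")
    outcome = "failure"
    failure_reason: str | None = None
    last_fb = (0.0, 0.0)  # one-sample sensory latency on rendered feedback
    for i in range(n_cap):
        hands = policy(t, state, last_fb)
        f_l, f_r = hand_forces(hands, state, params)
        f_s = spring_force(state, params)
        fb_l, fb_r = feedback_forces(f_l, f_r, f_s, condition, t)
        last_fb = (fb_l, fb_r)

        append["t"](t)
        append["z_L"](hands.z_left)
        append["z_R"](hands.z_right)
        append["F_L"](f_l)
        append["F_R"](f_r)
        append["FB_L"](fb_l)
        append["FB_R"](fb_r)
        append["z_board"](state.z_board)
        append["theta"](state.theta)
        append["x_ball"](state.x_ball)

        monitor.update(state.x_ball)
        if monitor.done == "success":
            outcome = "success"
            completion_time = t
            break
        if monitor.done == "failure":
            outcome = "failure"
            failure_reason = "roll_off"
            break
        if monitor.done == "timeout":
            outcome = "failure"
            failure_reason = "timeout"
            break

        state = step_dynamics(state, f_l, f_r, params)
        t += dt

    return TrialRecording(
        **{name: np.asarray(cols[name]) for name in CHANNEL_NAMES},
        dyad_id=dyad_id,
        pairing=pairing,
        condition=condition.label,
        block=block,
        trial=trial,
        start_side=start_side,
        outcome=outcome,
        failure_reason=failure_reason,
        completion_time=completion_time,
        seed=seed,
        params=params.as_dict(),
    )
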
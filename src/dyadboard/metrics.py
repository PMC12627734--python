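"""Coordination and leader-follower metrics for segmented dyadic recordings.

All measures operate on three-state label sequences (see
:mod:`dyadboard.signals`) and the raw channels of a trial:

* interaction dynamics — per-sample classification of the joint hand state
  into aligned / opposed / single / stationary, and per-trial time ratios;
* delay — per board-rotation onset, the lag between the two hands' movement
  onsets within aligned rotations (positive = right side moved first);
* movement ratio — each side's share of board-angle control from the linear
  maps ``z_L = -k_L theta + b_L`` and ``z_R = k_R theta + b_R`` fitted at
  board-segment endpoints;
* corrective movement ratio — each side's share of the cumulative deviation
  of its hand from the trailing 200 ms moving average;
* unilateral manipulation ratio — each side's share of path length travelled
  while the other side was stationary;
* motion-triggered trajectory averaging (MTTA) — onset-aligned hand
  trajectories normalised by the total displacement a rotation requires;
* relative dyadic improvement of one participant against their solo baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .signals import Segment, SegmentSequence

__all__ = [
    "CATEGORY_LABELS",
    "InteractionTimeline",
    "DelayObservation",
    "MovementRatioFit",
    "CorrectiveResult",
    "UnilateralResult",
    "MTTACurve",
    "ImprovementPoint",
    "LeadershipSummary",
    "classify_interaction",
    "coordination_ratios",
    "aligned_delays",
    "segment_endpoints",
    "movement_ratio_from_points",
    "movement_ratio",
    "corrective_movement",
    "corrective_ratio",
    "unilateral_ratio",
    "mtta",
    "dyadic_improvement",
    "leadership_summary",
]

CATEGORY_LABELS = ("aligned", "opposed", "single", "stationary")
ALIGNED, OPPOSED, SINGLE, STATIONARY = range(4)


@dataclass
class InteractionTimeline:
    """Per-sample four-category classification of the dyad's joint state."""

    categories: np.ndarray  # int codes indexing CATEGORY_LABELS
    dt: float

    def __post_init__(self) -> None:
        self.categories = np.asarray(self.categories, dtype=int)

    @property
    def n_samples(self) -> int:
        return self.categories.size

    def durations(self) -> dict[str, float]:
        """Time per category.  Each sample stands for the interval up to the
        next sample, so the final sample contributes none: a trial recorded
        from 0 to T at step dt has T/dt + 1 samples and total duration T."""
        counts = np.bincount(self.categories[:-1], minlength=4)
        return {lab: float(c * self.dt) for lab, c in zip(CATEGORY_LABELS, counts)}


def classify_interaction(
    labels_left: SegmentSequence | np.ndarray,
    labels_right: SegmentSequence | np.ndarray,
    dt: float | None = None,
) -> InteractionTimeline:
    """Classify each sample of the two hand label streams jointly.

    Opposite vertical directions rotate the board the same way (aligned);
    the same vertical direction fights over the rotation (opposed); one
    moving hand is a single manipulation; neither moving is stationary.
    """
    sl, dl = _states_and_dt(labels_left)
    sr, dr = _states_and_dt(labels_right)
    if sl.shape != sr.shape:
        raise ValueError(f"label streams differ in length ({sl.size} vs {sr.size})")
    dt = dt if dt is not None else (dl or dr or 0.001)
    left_moving = sl != 1
    right_moving = sr != 1
    cats = np.full(sl.shape, STATIONARY, dtype=int)
    both = left_moving & right_moving
    cats[both & (sl != sr)] = ALIGNED
    cats[both & (sl == sr)] = OPPOSED
    cats[left_moving ^ right_moving] = SINGLE
    return InteractionTimeline(categories=cats, dt=dt)


def _states_and_dt(obj: SegmentSequence | np.ndarray) -> tuple[np.ndarray, float | None]:
    if isinstance(obj, SegmentSequence):
        return obj.states, obj.dt
    return np.asarray(obj, dtype=int), None


def coordination_ratios(
    timeline: InteractionTimeline, completion_time: float
) -> dict[str, float]:
    """Time share of each interaction category, relative to completion time."""
    if not (completion_time > 0):
        raise ValueError("completion_time must be > 0")
    durations = timeline.durations()
    return {lab: durations[lab] / completion_time for lab in CATEGORY_LABELS}


@dataclass(frozen=True)
class DelayObservation:
    """Onset lag of one aligned board-rotation episode.

    ``delay = onset_L - onset_R`` in seconds: positive means the right hand
    started first (led), negative means the left hand led.
    """

    board_segment: int
    onset_left: float
    onset_right: float

    @property
    def delay(self) -> float:
        return self.onset_left - self.onset_right

    @property
    def abs_delay(self) -> float:
        return abs(self.delay)


# hand states required for each board rotation direction:
# ccw (board state 2): left hand moves down (0), right hand up (2); cw mirrored
_CONSISTENT_HAND = {2: (0, 2), 0: (2, 0)}


def aligned_delays(
    board_seq: SegmentSequence,
    hand_left: SegmentSequence,
    hand_right: SegmentSequence,
    *,
    window: float = 0.5,
) -> tuple[list[DelayObservation], int]:
    """Delay observations for board segments dominated by aligned movement.

    For every non-stationary board segment whose plurality interaction
    category is aligned, each hand contributes its closest direction-
    consistent movement onset within ``window`` seconds of the board onset.
    Segments where either hand has no such onset are skipped; the second
    return value counts them.
    """
    if not (board_seq.states.size == hand_left.states.size == hand_right.states.size):
        raise ValueError("board and hand label streams must have equal length")
    dt = board_seq.dt
    timeline = classify_interaction(hand_left, hand_right, dt=dt)
    observations: list[DelayObservation] = []
    skipped = 0
    for i, seg in enumerate(board_seq.moving_segments()):
        cats = timeline.categories[seg.start : seg.stop]
        counts = np.bincount(cats, minlength=4)
        if counts.argmax() != ALIGNED:
            continue
        want_left, want_right = _CONSISTENT_HAND[seg.state]
        onset_l = _closest_onset(hand_left, want_left, seg.start, window / dt)
        onset_r = _closest_onset(hand_right, want_right, seg.start, window / dt)
        if onset_l is None or onset_r is None:
            skipped += 1
            continue
        observations.append(
            DelayObservation(
                board_segment=i,
                onset_left=onset_l * dt,
                onset_right=onset_r * dt,
            )
        )
    return observations, skipped


def _closest_onset(
    hand: SegmentSequence, state: int, board_onset: int, max_lag: float
) -> int | None:
    best: int | None = None
    for seg in hand.segments:
        if seg.state != state:
            continue
        lag = abs(seg.start - board_onset)
        if lag <= max_lag and (best is None or lag < abs(best - board_onset)):
            best = seg.start
    return best


@dataclass
class MovementRatioFit:
    """OLS fits of the two angle-to-hand maps and the derived control shares."""

    k_left: float
    k_right: float
    b_left: float
    b_right: float
    r2_left: float
    r2_right: float
    n_points: int

    @property
    def defined(self) -> bool:
        return self.k_left + self.k_right > 0

    @property
    def p_left(self) -> float:
        if not self.defined:
            return float("nan")
        return self.k_left / (self.k_left + self.k_right)

    @property
    def p_right(self) -> float:
        if not self.defined:
            return float("nan")
        return self.k_right / (self.k_left + self.k_right)

    @property
    def leader(self) -> str:
        if not self.defined or math.isnan(self.p_left):
            return "none"
        if self.p_left > 0.5:
            return "L"
        if self.p_right > 0.5:
            return "R"
        return "none"


def segment_endpoints(board_seq: SegmentSequence) -> np.ndarray:
    """Sample index of the last sample of every non-stationary board segment."""
    return np.asarray([s.stop - 1 for s in board_seq.moving_segments()], dtype=int)


def movement_ratio_from_points(
    theta: np.ndarray, z_left: np.ndarray, z_right: np.ndarray, min_points: int = 5
) -> MovementRatioFit:
    """Fit ``z_L = -k_L theta + b_L`` and ``z_R = k_R theta + b_R`` by OLS.

    Points are board-segment endpoint samples, possibly pooled over several
    trials of one block.  Shares follow from the two gains; a nonpositive
    gain sum leaves the ratio undefined (NaN shares, leader "none").
    """
    theta = np.asarray(theta, dtype=float)
    z_left = np.asarray(z_left, dtype=float)
    z_right = np.asarray(z_right, dtype=float)
    if not (theta.size == z_left.size == z_right.size):
        raise ValueError("theta and hand endpoint arrays must have equal length")
    if theta.size < min_points:
        raise ValueError(f"need at least {min_points} endpoint samples, got {theta.size}")
    slope_l, intercept_l, r2_l = _ols(theta, z_left)
    slope_r, intercept_r, r2_r = _ols(theta, z_right)
    return MovementRatioFit(
        k_left=-slope_l,
        k_right=slope_r,
        b_left=intercept_l,
        b_right=intercept_r,
        r2_left=r2_l,
        r2_right=r2_r,
        n_points=theta.size,
    )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0.0:
        raise ValueError("degenerate fit: board angle endpoints have zero variance")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    syy = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / syy if syy > 0 else 1.0
    return slope, intercept, r2


def movement_ratio(
    board_seq: SegmentSequence,
    theta: np.ndarray,
    z_left: np.ndarray,
    z_right: np.ndarray,
    min_points: int = 5,
) -> MovementRatioFit:
    """Movement-ratio fit from a single trial's board segmentation."""
    idx = segment_endpoints(board_seq)
    theta = np.asarray(theta, dtype=float)
    return movement_ratio_from_points(
        theta[idx], np.asarray(z_left, float)[idx], np.asarray(z_right, float)[idx], min_points
    )


def corrective_movement(z: np.ndarray, k: int = 200) -> float:
    """Mean absolute deviation of a hand from its trailing moving average.

    The window holds the current sample and the ``min(k, t) - 1`` preceding
    ones, truncated at the start of the trial.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    if n == 0:
        raise ValueError("empty series")
    cumsum = np.concatenate([[0.0], np.cumsum(z)])
    t = np.arange(1, n + 1)
    widths = np.minimum(k, t)
    moving_avg = (cumsum[t] - cumsum[t - widths]) / widths
    return float(np.mean(np.abs(z - moving_avg)))


@dataclass(frozen=True)
class CorrectiveResult:
    c_left: float
    c_right: float
    flagged: bool  # True when neither side moved (ratio defaulted)

    @property
    def cr_left(self) -> float:
        if self.flagged:
            return 0.5
        return self.c_left / (self.c_left + self.c_right)

    @property
    def cr_right(self) -> float:
        return 1.0 - self.cr_left

    @property
    def leader(self) -> str:
        if self.flagged or self.cr_left == 0.5:
            return "none"
        return "L" if self.cr_left > 0.5 else "R"


def corrective_ratio(z_left: np.ndarray, z_right: np.ndarray, k: int = 200) -> CorrectiveResult:
    """Cumulative corrective movement per side and each side's share.

    When neither side moved (total corrective movement at floating-point
    rounding level) the ratio is reported as 0.5 / 0.5 with the
    ``flagged`` marker set.
    """
    c_l = corrective_movement(z_left, k)
    c_r = corrective_movement(z_right, k)
    return CorrectiveResult(c_left=c_l, c_right=c_r, flagged=(c_l + c_r) <= 1e-12)


@dataclass(frozen=True)
class UnilateralResult:
    path_left: float
    path_right: float
    defined: bool

    @property
    def ratio_left(self) -> float:
        total = self.path_left + self.path_right
        return float("nan") if not self.defined or total == 0 else self.path_left / total

    @property
    def ratio_right(self) -> float:
        r = self.ratio_left
        return float("nan") if math.isnan(r) else 1.0 - r

    @property
    def leader(self) -> str:
        r = self.ratio_left
        if math.isnan(r) or r == 0.5:
            return "none"
        return "L" if r > 0.5 else "R"


def unilateral_ratio(
    timeline: InteractionTimeline,
    hand_left: SegmentSequence,
    hand_right: SegmentSequence,
    z_left: np.ndarray,
    z_right: np.ndarray,
) -> UnilateralResult:
    """Each side's share of path length over the single-manipulation samples."""
    z_left = np.asarray(z_left, dtype=float)
    z_right = np.asarray(z_right, dtype=float)
    n = timeline.n_samples
    if not (n == z_left.size == z_right.size):
        raise ValueError("timeline and position series must have equal length")
    single = timeline.categories == SINGLE
    if not single.any():
        return UnilateralResult(0.0, 0.0, defined=False)
    # per-sample displacement attributed to the sample where it starts
    moving_left = hand_left.states != 1
    step_idx = np.flatnonzero(single[:-1])
    dl = np.abs(np.diff(z_left))[step_idx]
    dr = np.abs(np.diff(z_right))[step_idx]
    left_mask = moving_left[step_idx]
    path_l = float(np.sum(dl[left_mask]))
    path_r = float(np.sum(dr[~left_mask]))
    return UnilateralResult(path_l, path_r, defined=True)


@dataclass
class MTTACurve:
    """Mean normalised trajectory around board-rotation onsets for one group."""

    time: np.ndarray  # seconds relative to onset (onset at 0)
    nt: np.ndarray
    n_segments: int
    l_req: list[float] = field(default_factory=list)
    role: str = ""
    condition: str = ""


def mtta(
    trials: Iterable[tuple[np.ndarray, np.ndarray, np.ndarray, SegmentSequence]],
    half_length: float,
    *,
    roles: Mapping[str, str] = {"L": "leader", "R": "follower"},
    condition: str = "",
    dt: float = 0.001,
    pre: float = 0.5,
    post: float = 1.0,
    min_l_req: float = 1e-4,
) -> dict[str, MTTACurve]:
    """Motion-triggered trajectory averages pooled over trials.

    Each trial is ``(theta, z_L, z_R, board_seq)``.  For every non-stationary
    board segment whose window ``[-pre, +post]`` lies inside the trial, the
    required total displacement is ``L_req = 2 l (sin theta_end - sin
    theta_start)``; each hand's window is shifted to zero at the onset,
    the left side sign-flipped, and both divided by ``L_req``.  Curves are
    averaged per role, so with ``roles`` mapping sides to "leader" and
    "follower" the output has one curve per role.
    """
    n_pre = int(round(pre / dt))
    n_post = int(round(post / dt))
    time = np.arange(-n_pre, n_post + 1) * dt
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    lreqs: dict[str, list[float]] = {}
    for theta, z_left, z_right, board_seq in trials:
        theta = np.asarray(theta, dtype=float)
        z_left = np.asarray(z_left, dtype=float)
        z_right = np.asarray(z_right, dtype=float)
        n = theta.size
        for seg in board_seq.moving_segments():
            onset = seg.start
            if onset - n_pre < 0 or onset + n_post >= n:
                continue
            l_req = 2.0 * half_length * (
                math.sin(theta[seg.stop - 1]) - math.sin(theta[seg.start])
            )
            if abs(l_req) < min_l_req:
                continue
            window = slice(onset - n_pre, onset + n_post + 1)
            tr_l = -(z_left[window] - z_left[onset]) / l_req
            tr_r = (z_right[window] - z_right[onset]) / l_req
            for side, tr in (("L", tr_l), ("R", tr_r)):
                role = roles.get(side)
                if role is None:
                    continue
                if role not in sums:
                    sums[role] = np.zeros(time.size)
                    counts[role] = 0
                    lreqs[role] = []
                sums[role] += tr
                counts[role] += 1
                lreqs[role].append(l_req)
    return {
        role: MTTACurve(
            time=time.copy(),
            nt=sums[role] / counts[role],
            n_segments=counts[role],
            l_req=lreqs[role],
            role=role,
            condition=condition,
        )
        for role in sums
    }


@dataclass(frozen=True)
class ImprovementPoint:
    """Relative dyadic performance of one participant.

    ``x = 1 - T_partner / T`` compares the partner's solo skill with one's
    own; ``y = 1 - T_dyad / T`` compares dyadic with solo performance
    (positive = the dyad beat the participant's own solo time).
    """

    x: float
    y: float


def dyadic_improvement(t_solo: float, t_partner: float, t_dyad: float) -> ImprovementPoint:
    """Improvement point from stable-phase completion times (all > 0)."""
    for name, val in (("t_solo", t_solo), ("t_partner", t_partner), ("t_dyad", t_dyad)):
        if not (val > 0 and math.isfinite(val)):
            raise ValueError(f"{name} must be positive and finite, got {val!r}")
    return ImprovementPoint(x=1.0 - t_partner / t_solo, y=1.0 - t_dyad / t_solo)


@dataclass
class LeadershipSummary:
    """The four role metrics and the combined leader call for one unit."""

    fit: MovementRatioFit
    mean_delay: float
    mean_abs_delay: float
    n_delays: int
    corrective: CorrectiveResult
    unilateral: UnilateralResult
    ambiguity_threshold: float = 0.05

    @property
    def delay_leader(self) -> str:
        if self.n_delays == 0 or self.mean_delay == 0:
            return "none"
        # positive delay: right side moved first
        return "R" if self.mean_delay > 0 else "L"

    def metric_leaders(self) -> dict[str, str]:
        return {
            "movement_ratio": self.fit.leader,
            "delay": self.delay_leader,
            "corrective_ratio": self.corrective.leader,
            "unilateral_ratio": self.unilateral.leader,
        }

    @property
    def leader(self) -> str:
        """Combined call: the movement-ratio leader, unless the share is near
        0.5 and the four metrics disagree, in which case no leader."""
        primary = self.fit.leader
        votes = set(self.metric_leaders().values())
        ambiguous = (
            not self.fit.defined
            or abs(self.fit.p_left - 0.5) < self.ambiguity_threshold
        )
        if ambiguous and len(votes - {"none"}) != 1:
            return "none"
        if primary == "none" and len(votes - {"none"}) == 1:
            return (votes - {"none"}).pop()
        return primary


def leadership_summary(
    board_seq: SegmentSequence,
    hand_left: SegmentSequence,
    hand_right: SegmentSequence,
    theta: np.ndarray,
    z_left: np.ndarray,
    z_right: np.ndarray,
    *,
    window_samples: int = 200,
    delay_window: float = 0.5,
    ambiguity_threshold: float = 0.05,
) -> LeadershipSummary:
    """Compute all four leadership metrics for one trial (or pooled unit)."""
    fit = movement_ratio(board_seq, theta, z_left, z_right)
    obs, _ = aligned_delays(board_seq, hand_left, hand_right, window=delay_window)
    delays = np.asarray([o.delay for o in obs])
    timeline = classify_interaction(hand_left, hand_right, dt=board_seq.dt)
    return LeadershipSummary(
        fit=fit,
        mean_delay=float(delays.mean()) if delays.size else float("nan"),
        mean_abs_delay=float(np.abs(delays).mean()) if delays.size else float("nan"),
        n_delays=delays.size,
        corrective=corrective_ratio(z_left, z_right, k=window_samples),
        unilateral=unilateral_ratio(timeline, hand_left, hand_right, z_left, z_right),
        ambiguity_threshold=ambiguity_threshold,
    )
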
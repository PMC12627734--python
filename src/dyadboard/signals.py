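"""Preprocessing and three-state movement segmentation of velocity profiles.

Hand and board kinematics are low-pass filtered (zero-phase Butterworth),
differentiated, and segmented into three states — moving down / stationary /
moving up for hands, clockwise / stationary / counterclockwise for the board
— with a Gaussian-emission hidden Markov model fitted by EM.  The HMM is
preferred over plain thresholding because its transition structure suppresses
label chatter around the velocity zero-crossings of noisy data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from hmmlearn.hmm import GaussianHMM
from scipy import signal as sp_signal

__all__ = [
    "FilterSpec",
    "Segment",
    "SegmentSequence",
    "SegmenterModel",
    "DegenerateSignalError",
    "zero_phase_filter",
    "estimate_velocity",
    "fit_segmenter",
    "decode_segments",
    "threshold_segments",
    "HAND_LABELS",
    "BOARD_LABELS",
]

HAND_LABELS = ("down", "stationary", "up")
BOARD_LABELS = ("cw", "stationary", "ccw")


class DegenerateSignalError(ValueError):
    """Raised when a velocity collection has too little variation to segment."""


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth design applied forward-backward (zero phase).

    The dual pass squares the magnitude response, so the single-pass order
    is what is specified here and the effective attenuation is doubled;
    at the cutoff the amplitude ratio is 1/2 instead of 1/sqrt(2).
    """

    order: int = 10
    cutoff: float = 20.0
    sample_rate: float = 1000.0
    mode: Literal["dual-pass"] = "dual-pass"

    def __post_init__(self) -> None:
        if self.order <= 0 or self.order % 2:
            raise ValueError("order must be a positive even integer")
        if not 0 < self.cutoff < self.sample_rate / 2:
            raise ValueError("cutoff must lie in (0, sample_rate / 2)")

    @property
    def padlen(self) -> int:
        # odd-reflection padding of 3x the filter order on each end
        return 3 * self.order


def zero_phase_filter(series: np.ndarray, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Forward-backward Butterworth filtering; same length, zero phase lag."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if x.size <= 3 * spec.order:
        raise ValueError(
            f"series of length {x.size} is too short for order-{spec.order} "
            f"dual-pass filtering (need > {3 * spec.order} samples)"
        )
    sos = sp_signal.butter(spec.order, spec.cutoff, fs=spec.sample_rate, output="sos")
    return sp_signal.sosfiltfilt(sos, x, padtype="odd", padlen=spec.padlen)


def estimate_velocity(position: np.ndarray, sample_rate: float = 1000.0) -> np.ndarray:
    """Finite-difference velocity: central differences, one-sided endpoints."""
    x = np.asarray(position, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("position must be a 1-D series with at least 2 samples")
    return np.gradient(x, 1.0 / sample_rate)


@dataclass(frozen=True)
class Segment:
    """Contiguous run of one label; ``stop`` is exclusive."""

    start: int
    stop: int
    state: int  # 0 = down/cw, 1 = stationary, 2 = up/ccw

    @property
    def n_samples(self) -> int:
        return self.stop - self.start


@dataclass
class SegmentSequence:
    """Per-sample three-state labels plus the derived contiguous segments."""

    states: np.ndarray
    dt: float
    kind: Literal["hand", "board"] = "hand"
    min_duration: float = 0.05
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if not self.segments:
            self.segments = _runs(self.states)

    @property
    def labels(self) -> tuple[str, str, str]:
        return HAND_LABELS if self.kind == "hand" else BOARD_LABELS

    @property
    def label_names(self) -> np.ndarray:
        return np.asarray(self.labels)[self.states]

    def moving_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.state != 1]

    def onsets(self) -> np.ndarray:
        """First sample index of every non-stationary segment."""
        return np.asarray([s.start for s in self.moving_segments()], dtype=int)

    def validate(self) -> None:
        if self.segments[0].start != 0 or self.segments[-1].stop != self.states.size:
            raise AssertionError("segments do not cover the series")
        for a, b in zip(self.segments, self.segments[1:]):
            if a.stop != b.start:
                raise AssertionError("segments overlap or leave gaps")
            if a.state == b.state:
                raise AssertionError("consecutive segments share a label")


def _runs(states: np.ndarray) -> list[Segment]:
    if states.size == 0:
        return []
    bounds = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], bounds])
    stops = np.concatenate([bounds, [states.size]])
    return [Segment(int(a), int(b), int(states[a])) for a, b in zip(starts, stops)]


@dataclass
class SegmenterModel:
    """Fitted 3-state Gaussian HMM, states ordered by ascending emission mean.

    State 0 therefore always reads "moving down" (or clockwise), state 1
    "stationary", state 2 "moving up" (counterclockwise), whatever the
    internal ordering EM happened to converge to.
    """

    means: np.ndarray  # shape (3,), ascending
    variances: np.ndarray  # shape (3,)
    transmat: np.ndarray  # shape (3, 3), rows sum to 1
    startprob: np.ndarray  # shape (3,)
    kind: Literal["hand", "board"] = "hand"
    seed: int | None = None
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float).reshape(3)
        self.variances = np.asarray(self.variances, dtype=float).reshape(3)
        self.transmat = np.asarray(self.transmat, dtype=float).reshape(3, 3)
        self.startprob = np.asarray(self.startprob, dtype=float).reshape(3)
        if np.any(np.diff(self.means) <= 0):
            raise ValueError("emission means must be strictly ascending")
        if not np.allclose(self.transmat.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")

    def to_hmm(self) -> GaussianHMM:
        hmm = GaussianHMM(n_components=3, covariance_type="diag", min_covar=_MIN_COVAR)
        hmm.n_features = 1
        hmm.means_ = self.means.reshape(3, 1)
        hmm.covars_ = self.variances.reshape(3, 1)
        hmm.transmat_ = self.transmat.copy()
        hmm.startprob_ = self.startprob.copy()
        return hmm

    def as_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "transmat": self.transmat.tolist(),
            "startprob": self.startprob.tolist(),
            "kind": self.kind,
            "seed": self.seed,
            "log_likelihood": self.log_likelihood,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmenterModel":
        return cls(
            means=np.asarray(d["means"]),
            variances=np.asarray(d["variances"]),
            transmat=np.asarray(d["transmat"]),
            startprob=np.asarray(d["startprob"]),
            kind=d.get("kind", "hand"),
            seed=d.get("seed"),
            log_likelihood=d.get("log_likelihood", float("nan")),
        )


# variance floor for EM; small enough not to blur the ~0.05 m/s scale of
# hand movement velocities, large enough to survive noiseless input
_MIN_COVAR = 1e-7


def fit_segmenter(
    velocities: Sequence[np.ndarray] | np.ndarray,
    seed: int = 0,
    *,
    kind: Literal["hand", "board"] = "hand",
    n_restarts: int = 5,
    n_iter: int = 50,
    max_fit_samples: int = 50_000,
) -> SegmenterModel:
    """EM-fit a 3-state Gaussian HMM to pooled velocity profiles.

    ``velocities`` is one array or a collection of per-trial arrays (pooled
    with their lengths passed to EM so no transition spans a trial boundary).
    The best of ``n_restarts`` differently-initialised fits is kept and its
    states are relabelled by ascending emission mean.  When the pool exceeds
    ``max_fit_samples``, whole leading trials up to the cap are used for the
    fit (decoding always runs on full trials; the emission and transition
    parameters stabilise long before that many samples).
    """
    if isinstance(velocities, np.ndarray) and velocities.ndim == 1:
        velocities = [velocities]
    arrays = [np.asarray(v, dtype=float).ravel() for v in velocities]
    if not arrays or any(a.size == 0 for a in arrays):
        raise ValueError("empty velocity collection")
    if sum(a.size for a in arrays) > max_fit_samples:
        kept, total = [], 0
        for a in arrays:
            kept.append(a)
            total += a.size
            if total >= max_fit_samples:
                break
        arrays = kept
    pooled = np.concatenate(arrays)
    if not np.isfinite(pooled).all():
        raise ValueError("velocities contain non-finite values")
    spread = np.std(pooled)
    if spread < 1e-6:
        raise DegenerateSignalError(
            f"velocity spread {spread:.2e} is too small to separate three states"
        )
    X = pooled.reshape(-1, 1)
    lengths = [a.size for a in arrays]

    # the EM monitor logs a warning whenever the last step moved the bound
    # by less than its tolerance; that is expected at convergence
    logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

    best: GaussianHMM | None = None
    best_score = -np.inf
    for i in range(n_restarts):
        hmm = GaussianHMM(
            n_components=3,
            covariance_type="diag",
            min_covar=_MIN_COVAR,
            n_iter=n_iter,
            random_state=seed + i,
        )
        try:
            hmm.fit(X, lengths)
            score = hmm.score(X, lengths)
        except (ValueError, np.linalg.LinAlgError):  # degenerate restart
            continue
        if np.isfinite(score) and score > best_score:
            best, best_score = hmm, score
    if best is None:
        raise DegenerateSignalError("every EM restart failed to produce a usable fit")

    order = np.argsort(best.means_.ravel())
    return SegmenterModel(
        means=best.means_.ravel()[order],
        variances=best.covars_.reshape(3, -1)[order, 0],
        transmat=best.transmat_[np.ix_(order, order)],
        startprob=best.startprob_[order],
        kind=kind,
        seed=seed,
        log_likelihood=float(best_score),
    )


def decode_segments(
    velocity: np.ndarray,
    model: SegmenterModel,
    min_duration: float = 0.05,
    dt: float = 0.001,
) -> SegmentSequence:
    """Viterbi-decode a velocity profile into a label sequence.

    Segments shorter than ``min_duration`` are merged into whichever
    neighbouring state carries the higher mean posterior probability over the
    segment's samples, shortest segment first, until every segment satisfies
    the minimum duration.
    """
    v = np.asarray(velocity, dtype=float).reshape(-1, 1)
    hmm = model.to_hmm()
    states = hmm.predict(v)
    posteriors = hmm.predict_proba(v)
    min_samples = max(1, int(round(min_duration / dt)))
    states = _merge_short_segments(states, posteriors, min_samples)
    seq = SegmentSequence(states=states, dt=dt, kind=model.kind, min_duration=min_duration)
    seq.validate()
    return seq


def _merge_short_segments(
    states: np.ndarray, posteriors: np.ndarray, min_samples: int
) -> np.ndarray:
    states = np.asarray(states, dtype=int).copy()
    while True:
        segs = _runs(states)
        if len(segs) <= 1:
            return states
        short = [s for s in segs if s.n_samples < min_samples]
        if not short:
            return states
        seg = min(short, key=lambda s: (s.n_samples, s.start))
        idx = segs.index(seg)
        candidates = []
        if idx > 0:
            candidates.append(segs[idx - 1].state)
        if idx < len(segs) - 1:
            candidates.append(segs[idx + 1].state)
        mass = posteriors[seg.start : seg.stop].mean(axis=0)
        new_state = max(candidates, key=lambda s: mass[s])
        states[seg.start : seg.stop] = new_state


def threshold_segments(
    velocity: np.ndarray,
    threshold: float,
    dt: float = 0.001,
    kind: Literal["hand", "board"] = "hand",
) -> SegmentSequence:
    """Plain +/- threshold segmentation (the brute-force reference rule)."""
    v = np.asarray(velocity, dtype=float)
    states = np.where(v > threshold, 2, np.where(v < -threshold, 0, 1))
    return SegmentSequence(states=states, dt=dt, kind=kind)
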
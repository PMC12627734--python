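"""Study orchestration: simulate, segment, measure, compare, summarise.

:func:`run_study` executes the whole synthetic pipeline for a configured
study — dyad generation, per-participant HMM segmentation, per-trial and
per-block metric tables, and the condition-level repeated-measures
comparison — writing every product as delimited text plus a JSON manifest.
Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from . import metrics as met
from .agents import DyadGroundTruth, DyadSpec, generate_dyad_dataset
from .io import write_recording
from .signals import (
    FilterSpec,
    SegmenterModel,
    SegmentSequence,
    decode_segments,
    estimate_velocity,
    fit_segmenter,
    zero_phase_filter,
)
from .simulator import CONDITION_LABELS, ModelParams, TrialConfig, TrialRecording

logger = logging.getLogger("dyadboard")

__all__ = [
    "StudyConfig",
    "StudyResult",
    "ConditionComparison",
    "TrialSegmentation",
    "segment_trial",
    "fit_dyad_segmenters",
    "trial_metrics_row",
    "pooled_leadership",
    "compare_conditions",
    "run_study",
]


@dataclass
class StudyConfig:
    """Layout and parameters of one synthetic study.

    The default layout mirrors the five-condition dyadic session: blocks come
    in sets of five, each set covering all five haptic conditions in
    seed-randomised order.  ``trials_per_block`` counts successful trials;
    failed trials are repeated and excluded from analysis.
    """

    dyads: Sequence[DyadSpec] = field(default_factory=lambda: [DyadSpec()])
    n_blocks: int = 5
    trials_per_block: int = 4
    conditions: Sequence[str] = CONDITION_LABELS
    params: ModelParams = field(default_factory=ModelParams)
    trial_config: TrialConfig = field(default_factory=lambda: TrialConfig(max_duration=30.0))
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    min_segment_duration: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks <= 0 or self.trials_per_block <= 0:
            raise ValueError("n_blocks and trials_per_block must be > 0")
        if not self.dyads:
            raise ValueError("at least one dyad spec is required")
        if not self.conditions:
            raise ValueError("empty condition schedule")
        for label in self.conditions:
            if label not in CONDITION_LABELS:
                raise ValueError(f"unknown condition {label!r}")


@dataclass
class TrialSegmentation:
    """Label sequences plus the low-pass-filtered kinematics of one trial.

    All downstream metrics run on the filtered channels, mirroring the
    preprocessing applied to the recorded data before any analysis.
    """

    left: SegmentSequence
    right: SegmentSequence
    board: SegmentSequence
    z_left: np.ndarray = field(default_factory=lambda: np.empty(0))
    z_right: np.ndarray = field(default_factory=lambda: np.empty(0))
    theta: np.ndarray = field(default_factory=lambda: np.empty(0))


def _filtered_velocity(series: np.ndarray, spec: FilterSpec) -> np.ndarray:
    return estimate_velocity(zero_phase_filter(series, spec), spec.sample_rate)


def fit_dyad_segmenters(
    recordings: Sequence[TrialRecording],
    seed: int,
    filter_spec: FilterSpec = FilterSpec(),
) -> dict[str, SegmenterModel]:
    """Fit the two hand models and the board model on pooled trial velocities."""
    vel_l = [_filtered_velocity(r.z_L, filter_spec) for r in recordings]
    vel_r = [_filtered_velocity(r.z_R, filter_spec) for r in recordings]
    vel_b = [_filtered_velocity(r.theta, filter_spec) for r in recordings]
    return {
        "left": fit_segmenter(vel_l, seed=seed, kind="hand"),
        "right": fit_segmenter(vel_r, seed=seed + 1, kind="hand"),
        "board": fit_segmenter(vel_b, seed=seed + 2, kind="board"),
    }


def segment_trial(
    recording: TrialRecording,
    models: Mapping[str, SegmenterModel],
    min_duration: float = 0.05,
    filter_spec: FilterSpec = FilterSpec(),
) -> TrialSegmentation:
    """Filter, differentiate and Viterbi-decode one trial's three channels."""
    dt = recording.dt
    z_l = zero_phase_filter(recording.z_L, filter_spec)
    z_r = zero_phase_filter(recording.z_R, filter_spec)
    theta = zero_phase_filter(recording.theta, filter_spec)
    rate = filter_spec.sample_rate
    return TrialSegmentation(
        left=decode_segments(estimate_velocity(z_l, rate), models["left"], min_duration, dt),
        right=decode_segments(estimate_velocity(z_r, rate), models["right"], min_duration, dt),
        board=decode_segments(estimate_velocity(theta, rate), models["board"], min_duration, dt),
        z_left=z_l,
        z_right=z_r,
        theta=theta,
    )


def trial_metrics_row(recording: TrialRecording, seg: TrialSegmentation) -> dict:
    """One tidy row of per-trial coordination and leadership measures."""
    timeline = met.classify_interaction(seg.left, seg.right, dt=recording.dt)
    ratios = met.coordination_ratios(timeline, recording.completion_time)
    obs, skipped = met.aligned_delays(seg.board, seg.left, seg.right)
    delays = np.asarray([o.delay for o in obs])
    corrective = met.corrective_ratio(seg.z_left, seg.z_right)
    unilateral = met.unilateral_ratio(timeline, seg.left, seg.right, seg.z_left, seg.z_right)
    return {
        "dyad": recording.dyad_id,
        "pairing": recording.pairing,
        "block": recording.block,
        "trial": recording.trial,
        "condition": recording.condition,
        "completion_time": recording.completion_time,
        "ratio_aligned": ratios["aligned"],
        "ratio_opposed": ratios["opposed"],
        "ratio_single": ratios["single"],
        "ratio_stationary": ratios["stationary"],
        "n_delays": int(delays.size),
        "n_delays_skipped": int(skipped),
        "mean_delay": float(delays.mean()) if delays.size else float("nan"),
        "mean_abs_delay": float(np.abs(delays).mean()) if delays.size else float("nan"),
        "C_L": corrective.c_left,
        "C_R": corrective.c_right,
        "CR_L": corrective.cr_left,
        "CR_R": corrective.cr_right,
        "unilateral_L": unilateral.ratio_left,
        "unilateral_R": unilateral.ratio_right,
    }


@dataclass
class ConditionComparison:
    """One-way repeated-measures comparison across haptic conditions."""

    metric: str
    f_value: float
    df1: float
    df2: float
    p_uncorrected: float
    p_gg: float
    eps: float
    pairwise: pd.DataFrame  # columns: A, B, t, df, p_unc, p_holm

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "F": self.f_value,
            "df1": self.df1,
            "df2": self.df2,
            "p_uncorrected": self.p_uncorrected,
            "p_GG": self.p_gg,
            "eps": self.eps,
            "pairwise": self.pairwise.to_dict(orient="records"),
        }


def compare_conditions(
    means: pd.DataFrame,
    metric: str = "value",
    *,
    subject: str = "subject",
    condition: str = "condition",
    value: str = "value",
) -> ConditionComparison:
    """rmANOVA over conditions plus Holm-corrected pairwise paired t-tests.

    ``means`` is a tidy frame of per-subject condition means; the design must
    be complete (every subject observed in every condition, no imputation).
    The uncorrected F is reported alongside the Greenhouse-Geisser corrected
    p-value.
    """
    df = means[[subject, condition, value]].copy()
    if df[value].isna().any():
        raise ValueError("missing values in the design; incomplete cells are not imputed")
    counts = df.groupby([subject, condition], observed=True).size()
    if (counts != 1).any():
        raise ValueError("design must have exactly one mean per subject x condition")
    subjects = df[subject].unique()
    conditions = list(df[condition].unique())
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    pivot = df.pivot(index=subject, columns=condition, values=value)
    if pivot.isna().any().any():
        raise ValueError("incomplete design: every subject must appear in every condition")

    data = pivot.to_numpy()
    n_subj, n_cond = data.shape
    df1 = float(n_cond - 1)
    df2 = float((n_cond - 1) * (n_subj - 1))
    scale = float(np.var(data)) * data.size
    grand = data.mean()
    ss_cond = n_subj * float(((data.mean(axis=0) - grand) ** 2).sum())

    if ss_cond <= 1e-14 * max(scale, 1e-30):
        # no condition effect whatsoever (including the all-identical design
        # whose error variance is also zero): the null F
        f_value, p_unc, p_gg, eps = 0.0, 1.0, 1.0, 1.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            aov = pg.rm_anova(
                data=df, dv=value, within=condition, subject=subject,
                correction=True, detailed=True,
            )
        row = aov.loc[aov["Source"] == condition].iloc[0]
        f_value = float(row["F"])
        p_unc = float(row["p_unc"])
        p_gg = (
            float(row["p_GG_corr"])
            if "p_GG_corr" in aov.columns and pd.notna(row.get("p_GG_corr"))
            else p_unc
        )
        eps = float(row["eps"]) if "eps" in aov.columns and pd.notna(row.get("eps")) else 1.0

    pairs = []
    for i in range(len(conditions)):
        for j in range(i + 1, len(conditions)):
            a, b = conditions[i], conditions[j]
            t_stat, p = _paired_t(pivot[a].to_numpy(), pivot[b].to_numpy())
            pairs.append({"A": a, "B": b, "t": t_stat, "df": float(len(subjects) - 1), "p_unc": p})
    pairwise = pd.DataFrame(pairs)
    pairwise["p_holm"] = multipletests(pairwise["p_unc"], method="holm")[1]

    return ConditionComparison(
        metric=metric,
        f_value=f_value,
        df1=df1,
        df2=df2,
        p_uncorrected=p_unc,
        p_gg=p_gg,
        eps=eps,
        pairwise=pairwise,
    )


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Paired t-test that degrades gracefully for zero-variance differences."""
    d = a - b
    if float(np.std(d, ddof=1)) == 0.0:
        if float(d.mean()) == 0.0:
            return 0.0, 1.0
        return float(np.copysign(np.inf, d.mean())), 0.0
    res = sp_stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class StudyResult:
    """Everything :func:`run_study` produced, with the output paths."""

    out_dir: Path
    trial_metrics: pd.DataFrame
    leadership: pd.DataFrame
    comparisons: dict[str, ConditionComparison]
    ground_truths: list[DyadGroundTruth]
    manifest: dict


def pooled_leadership(
    recordings: Sequence[TrialRecording],
    segmentations: Sequence[TrialSegmentation],
) -> met.LeadershipSummary:
    """Leadership metrics with observations pooled over a set of trials.

    Board-segment endpoints enter one joint movement-ratio fit, delay
    observations are concatenated, and the corrective and unilateral
    quantities are accumulated before forming their ratios.
    """
    theta_pts, zl_pts, zr_pts = [], [], []
    delays: list[float] = []
    c_l = c_r = 0.0
    path_l = path_r = 0.0
    any_single = False
    for rec, seg in zip(recordings, segmentations):
        ends = met.segment_endpoints(seg.board)
        theta_pts.append(seg.theta[ends])
        zl_pts.append(seg.z_left[ends])
        zr_pts.append(seg.z_right[ends])
        obs, _ = met.aligned_delays(seg.board, seg.left, seg.right)
        delays.extend(o.delay for o in obs)
        corr = met.corrective_ratio(seg.z_left, seg.z_right)
        c_l += corr.c_left
        c_r += corr.c_right
        timeline = met.classify_interaction(seg.left, seg.right, dt=rec.dt)
        uni = met.unilateral_ratio(timeline, seg.left, seg.right, seg.z_left, seg.z_right)
        if uni.defined:
            any_single = True
            path_l += uni.path_left
            path_r += uni.path_right
    fit = met.movement_ratio_from_points(
        np.concatenate(theta_pts), np.concatenate(zl_pts), np.concatenate(zr_pts)
    )
    darr = np.asarray(delays)
    return met.LeadershipSummary(
        fit=fit,
        mean_delay=float(darr.mean()) if darr.size else float("nan"),
        mean_abs_delay=float(np.abs(darr).mean()) if darr.size else float("nan"),
        n_delays=darr.size,
        corrective=met.CorrectiveResult(c_left=c_l, c_right=c_r, flagged=(c_l + c_r) == 0),
        unilateral=met.UnilateralResult(path_l, path_r, defined=any_single),
    )


def _block_leadership_rows(
    dyad_id: str,
    recordings: Sequence[TrialRecording],
    segmentations: Sequence[TrialSegmentation],
) -> list[dict]:
    """Per-block leadership: endpoints pooled over the block's trials."""
    by_block: dict[int, list[int]] = {}
    for i, rec in enumerate(recordings):
        by_block.setdefault(rec.block, []).append(i)
    rows = []
    for block in sorted(by_block):
        idxs = by_block[block]
        summary = pooled_leadership(
            [recordings[i] for i in idxs], [segmentations[i] for i in idxs]
        )
        fit = summary.fit
        corrective = summary.corrective
        unilateral = summary.unilateral
        rows.append(
            {
                "dyad": dyad_id,
                "block": block,
                "condition": recordings[idxs[0]].condition,
                "n_trials": len(idxs),
                "n_endpoints": fit.n_points,
                "k_L": fit.k_left,
                "k_R": fit.k_right,
                "b_L": fit.b_left,
                "b_R": fit.b_right,
                "r2_L": fit.r2_left,
                "r2_R": fit.r2_right,
                "p_L": fit.p_left,
                "p_R": fit.p_right,
                "mean_delay": summary.mean_delay,
                "mean_abs_delay": summary.mean_abs_delay,
                "n_delays": summary.n_delays,
                "CR_L": corrective.cr_left,
                "CR_R": corrective.cr_right,
                "unilateral_L": unilateral.ratio_left,
                "unilateral_R": unilateral.ratio_right,
                "leader": summary.leader,
            }
        )
    return rows


def run_study(config: StudyConfig, out_dir: str | Path) -> StudyResult:
    """Simulate, segment and analyse a full synthetic study.

    Writes per-trial recordings (CSV + JSON sidecars), segmentation label
    tables and model parameters, the tidy per-trial metrics table, the
    per-block leadership table, condition comparisons and a run manifest.
    Failed trials are recorded but excluded from all metric tables.
    """
    out_dir = Path(out_dir)
    rec_dir = out_dir / "recordings"
    seg_dir = out_dir / "segments"
    met_dir = out_dir / "metrics"
    for d in (rec_dir, seg_dir, met_dir):
        d.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(config.seed)
    trial_rows: list[dict] = []
    leadership_rows: list[dict] = []
    truths: list[DyadGroundTruth] = []
    counts = {"generated": 0, "failed": 0, "delay_skipped": 0}

    for dyad_index, spec in enumerate(config.dyads):
        dyad_seed = int(rng.integers(2**31))
        logger.info("dyad %s: generating %d blocks x %d trials (seed %d)",
                    spec.dyad_id, config.n_blocks, config.trials_per_block, dyad_seed)
        recordings, truth = generate_dyad_dataset(
            spec,
            config.n_blocks,
            config.trials_per_block,
            dyad_seed,
            params=config.params,
            config=config.trial_config,
        )
        truths.append(truth)
        counts["generated"] += len(recordings)

        for rec in recordings:
            write_recording(rec, rec_dir / f"{spec.dyad_id}_b{rec.block:02d}_t{rec.trial:03d}.csv")

        analysed = [r for r in recordings if r.outcome == "success"]
        counts["failed"] += len(recordings) - len(analysed)

        seg_seed = int(rng.integers(2**31))
        models = fit_dyad_segmenters(analysed, seg_seed, config.filter_spec)
        with open(seg_dir / f"{spec.dyad_id}_models.json", "w") as fh:
            json.dump({k: m.as_dict() for k, m in models.items()}, fh, indent=1, sort_keys=True)

        segmentations = []
        for rec in analysed:
            seg = segment_trial(rec, models, config.min_segment_duration, config.filter_spec)
            segmentations.append(seg)
            table = pd.DataFrame(
                {
                    "t": rec.t,
                    "label_zL": seg.left.label_names,
                    "label_zR": seg.right.label_names,
                    "label_theta": seg.board.label_names,
                }
            )
            table.to_csv(seg_dir / f"{spec.dyad_id}_b{rec.block:02d}_t{rec.trial:03d}.csv",
                         index=False, float_format="%.17g")
            row = trial_metrics_row(rec, seg)
            counts["delay_skipped"] += row["n_delays_skipped"]
            trial_rows.append(row)

        leadership_rows.extend(_block_leadership_rows(spec.dyad_id, analysed, segmentations))

    trial_metrics = pd.DataFrame(trial_rows)
    leadership = pd.DataFrame(leadership_rows)
    trial_metrics.to_csv(met_dir / "trial_metrics.csv", index=False, float_format="%.17g")
    leadership.to_csv(met_dir / "leadership.csv", index=False, float_format="%.17g")

    comparisons: dict[str, ConditionComparison] = {}
    scheduled = set()
    for truth in truths:
        scheduled.update(truth.condition_schedule)
    if len(config.dyads) >= 2 and len(scheduled) >= 2:
        for metric_name in ("completion_time", "ratio_aligned"):
            means = (
                trial_metrics.groupby(["dyad", "condition"], observed=True)[metric_name]
                .mean()
                .reset_index()
                .rename(columns={"dyad": "subject", metric_name: "value"})
            )
            try:
                comparisons[metric_name] = compare_conditions(means, metric_name)
            except ValueError as exc:
                logger.warning("condition comparison for %s skipped: %s", metric_name, exc)
        with open(met_dir / "condition_comparisons.json", "w") as fh:
            json.dump({k: c.as_dict() for k, c in comparisons.items()}, fh, indent=1, sort_keys=True)

    manifest = {
        "seed": config.seed,
        "n_dyads": len(config.dyads),
        "n_blocks": config.n_blocks,
        "trials_per_block": config.trials_per_block,
        "conditions": sorted(scheduled),
        "params": config.params.as_dict(),
        "counts": counts,
        "ground_truth": [t.as_dict() for t in truths],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("study complete: %d recordings, %d failures repeated",
                counts["generated"], counts["failed"])

    return StudyResult(
        out_dir=out_dir,
        trial_metrics=trial_metrics,
        leadership=leadership,
        comparisons=comparisons,
        ground_truths=truths,
        manifest=manifest,
    )
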
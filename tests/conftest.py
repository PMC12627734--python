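"""Shared fixtures: synthetic dyad sessions analysed once per test run.

The expensive artefacts (trial generation, HMM fits, full studies) are
session-scoped so that unit, property and acceptance tests all share them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from dyadboard import metrics as met
from dyadboard.agents import AgentParams, DyadSpec, generate_dyad_dataset
from dyadboard.pipeline import (
    StudyConfig,
    fit_dyad_segmenters,
    pooled_leadership,
    run_study,
    segment_trial,
)
from dyadboard.simulator import ModelParams, TrialConfig, TrialRecording


@dataclass
class RecoveryCase:
    """One dyad session, segmented and summarised for recovery checks."""

    spec: DyadSpec
    recordings: list[TrialRecording]
    successes: list[TrialRecording]
    segmentations: list
    summary: met.LeadershipSummary

    @property
    def success_rate(self) -> float:
        return len(self.successes) / len(self.recordings)


def _analyse(spec: DyadSpec, seed: int, n_blocks: int = 5, trials_per_block: int = 4) -> RecoveryCase:
    recordings, _ = generate_dyad_dataset(
        spec,
        n_blocks,
        trials_per_block,
        seed,
        config=TrialConfig(max_duration=30.0),
    )
    successes = [r for r in recordings if r.outcome == "success"]
    models = fit_dyad_segmenters(successes, seed=1)
    segmentations = [segment_trial(r, models) for r in successes]
    return RecoveryCase(
        spec=spec,
        recordings=recordings,
        successes=successes,
        segmentations=segmentations,
        summary=pooled_leadership(successes, segmentations),
    )


@pytest.fixture(scope="session")
def asym_case() -> RecoveryCase:
    """20-trial session of a 0.7/0.3 dyad with a 120 ms follower lag."""
    spec = DyadSpec(
        left=AgentParams(gain_share=0.7),
        right=AgentParams(gain_share=0.3, reaction_delay=0.12),
    )
    return _analyse(spec, seed=42)


@pytest.fixture(scope="session")
def balanced_case() -> RecoveryCase:
    """20-trial session of a symmetric 0.5/0.5 dyad with no imposed lag."""
    spec = DyadSpec(left=AgentParams(gain_share=0.5), right=AgentParams(gain_share=0.5))
    return _analyse(spec, seed=42)


@pytest.fixture(scope="session")
def study_pair(tmp_path_factory):
    """The same reduced five-condition study executed twice with one seed."""
    results = []
    for name in ("run_a", "run_b"):
        config = StudyConfig(
            dyads=[
                DyadSpec(
                    left=AgentParams(gain_share=0.65),
                    right=AgentParams(gain_share=0.35, reaction_delay=0.12),
                    dyad_id="dyadA",
                ),
                DyadSpec(
                    left=AgentParams(gain_share=0.45),
                    right=AgentParams(gain_share=0.55),
                    dyad_id="dyadB",
                ),
            ],
            n_blocks=5,
            trials_per_block=2,
            seed=11,
            trial_config=TrialConfig(max_duration=30.0),
        )
        out = tmp_path_factory.mktemp("study") / name
        results.append(run_study(config, out))
    return results
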
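"""Reading and writing trial recordings and their metadata sidecars.

A recording is stored as a delimited table (CSV, one column per channel,
``%.17g`` formatting so every float round-trips exactly) plus a JSON sidecar
``<stem>.meta.json`` carrying trial metadata, the model-parameter snapshot
and the seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulator import CHANNEL_NAMES, CONDITION_LABELS, TrialRecording

__all__ = ["write_recording", "read_recording", "meta_path"]

_REQUIRED_META = (
    "dyad_id",
    "pairing",
    "condition",
    "block",
    "trial",
    "start_side",
    "outcome",
    "completion_time",
)


def meta_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".meta.json")


def write_recording(recording: TrialRecording, path: str | Path) -> Path:
    """Write channels as CSV and metadata as a JSON sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame({name: getattr(recording, name) for name in CHANNEL_NAMES})
    frame.to_csv(path, index=False, float_format="%.17g")
    with open(meta_path(path), "w") as fh:
        json.dump(recording.metadata(), fh, indent=1, sort_keys=True, allow_nan=True)
    return path


def read_recording(path: str | Path) -> TrialRecording:
    """Read a recording written by :func:`write_recording`, validating schema."""
    path = Path(path)
    # round_trip parsing: the writer prints %.17g precisely so that every
    # float survives the text round trip bit-for-bit
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CHANNEL_NAMES if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    side = meta_path(path)
    if not side.exists():
        raise ValueError(f"{path}: metadata sidecar {side.name} not found")
    with open(side) as fh:
        meta = json.load(fh)
    absent = [k for k in _REQUIRED_META if k not in meta]
    if absent:
        raise ValueError(f"{side}: missing metadata key(s) {', '.join(absent)}")
    if meta["condition"] not in CONDITION_LABELS:
        raise ValueError(
            f"{side}: condition {meta['condition']!r} is not one of {CONDITION_LABELS}"
        )
    t = frame["t"].to_numpy()
    steps = np.diff(t)
    if t.size < 2 or not np.all(steps > 0) or not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
        raise ValueError(f"{path}: time channel is not a uniform increasing grid")
    completion = meta["completion_time"]
    return TrialRecording(
        **{name: frame[name].to_numpy() for name in CHANNEL_NAMES},
        dyad_id=meta["dyad_id"],
        pairing=meta["pairing"],
        condition=meta["condition"],
        block=int(meta["block"]),
        trial=int(meta["trial"]),
        start_side=meta["start_side"],
        outcome=meta["outcome"],
        failure_reason=meta.get("failure_reason"),
        completion_time=float("nan") if completion is None else float(completion),
        seed=meta.get("seed"),
        params=meta.get("params", {}),
    )
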
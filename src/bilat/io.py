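"""Session file format: ``spikes.csv`` + ``trials.csv`` (+ ``ground_truth.json``).

The same dialect is used for simulated sessions and for real exported data:

* ``spikes.csv`` — columns ``unit_id`` (string), ``time_s`` (float, seconds
  from session start), sorted by time within each unit.
* ``trials.csv`` — columns ``trial_id, block_id, block_type, prepare_onset_s,
  go_onset_s, rest_onset_s, end_s, ipsi_dir_deg, contra_dir_deg``; direction
  fields are empty for the unused arm of a unimanual block.
* ``ground_truth.json`` — optional list of per-unit generative parameters
  (only present for simulated sessions).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import TASKS, NeuronGroundTruth

__all__ = [
    "SessionFormatError",
    "write_session",
    "read_session",
    "read_ground_truth",
]

SPIKE_COLUMNS = ("unit_id", "time_s")
TRIAL_COLUMNS = (
    "trial_id",
    "block_id",
    "block_type",
    "prepare_onset_s",
    "go_onset_s",
    "rest_onset_s",
    "end_s",
    "ipsi_dir_deg",
    "contra_dir_deg",
)


class SessionFormatError(ValueError):
    """Raised when a session file is malformed; the message names the offending row."""


def write_session(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    path: str | Path,
    ground_truth: Sequence[NeuronGroundTruth] | None = None,
) -> Path:
    """Write a session directory; returns its path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spikes.to_csv(path / "spikes.csv", index=False)
    trials.to_csv(path / "trials.csv", index=False)
    if ground_truth is not None:
        with open(path / "ground_truth.json", "w") as fh:
            json.dump([g.to_dict() for g in ground_truth], fh, indent=1)
    return path


def _require_columns(df: pd.DataFrame, required: Sequence[str], fname: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{fname}: missing column(s) {missing}")


def validate_trials(trials: pd.DataFrame, fname: str = "trials.csv") -> None:
    _require_columns(trials, TRIAL_COLUMNS, fname)
    for row in trials.itertuples():
        onsets = (row.prepare_onset_s, row.go_onset_s, row.rest_onset_s, row.end_s)
        if any(pd.isna(v) for v in onsets):
            raise SessionFormatError(f"{fname}: trial row {row.Index} has a missing phase onset")
        if not (onsets[0] < onsets[1] < onsets[2] < onsets[3]):
            raise SessionFormatError(
                f"{fname}: trial row {row.Index} has non-increasing phase onsets {onsets}"
            )
        if row.block_type not in TASKS:
            raise SessionFormatError(
                f"{fname}: trial row {row.Index} has unknown block_type {row.block_type!r}"
            )
        if row.block_type == "ipsi" and not pd.isna(row.contra_dir_deg):
            raise SessionFormatError(f"{fname}: trial row {row.Index} (ipsi) sets contra_dir_deg")
        if row.block_type == "contra" and not pd.isna(row.ipsi_dir_deg):
            raise SessionFormatError(f"{fname}: trial row {row.Index} (contra) sets ipsi_dir_deg")


def validate_spikes(spikes: pd.DataFrame, fname: str = "spikes.csv") -> None:
    _require_columns(spikes, SPIKE_COLUMNS, fname)
    if len(spikes) == 0:
        return
    if spikes["time_s"].isna().any():
        bad = int(spikes["time_s"].isna().idxmax())
        raise SessionFormatError(f"{fname}: spike row {bad} has missing time_s")
    # sorted by time within unit
    for unit, grp in spikes.groupby("unit_id", sort=False):
        t = grp["time_s"].to_numpy()
        if np.any(np.diff(t) < 0):
            bad = int(grp.index[np.argmax(np.diff(t) < 0) + 1])
            raise SessionFormatError(
                f"{fname}: spike row {bad} (unit {unit}) breaks within-unit time order"
            )


def read_session(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a session directory; returns ``(spikes, trials)``."""
    path = Path(path)
    spikes = pd.read_csv(path / "spikes.csv", dtype={"unit_id": str})
    trials = pd.read_csv(path / "trials.csv")
    validate_spikes(spikes)
    validate_trials(trials)
    return spikes, trials


def read_ground_truth(path: str | Path) -> list[NeuronGroundTruth]:
    with open(Path(path) / "ground_truth.json") as fh:
        return [NeuronGroundTruth.from_dict(d) for d in json.load(fh)]
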
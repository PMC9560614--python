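"""Trial-table CSV I/O and run configuration.

The single interchange format is a tidy CSV with one row per trial, sorted
by (subject, block, trial).  Confidence is stored both raw (0-10) and
normalized (0-1); the normalized column is authoritative for computation.
Rewards are written as empty fields on trials where the learner did not
observe them (the no-feedback phase).
"""

from __future__ import annotations

import hashlib
import json
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .task import TrialRecord

__all__ = [
    "TRIAL_COLUMNS",
    "trials_to_frame",
    "read_trial_table",
    "write_trial_table",
    "load_config",
    "config_hash",
]

TRIAL_COLUMNS = [
    "subject", "block", "trial", "phase", "left_cs", "right_cs",
    "left_value", "right_value", "chosen_side", "chosen_cs",
    "reward", "confidence_raw", "confidence", "correct",
]

_REQUIRED = ["subject", "block", "trial", "phase", "left_cs", "right_cs",
             "chosen_side", "chosen_cs", "reward"]


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Convert trial records to the canonical tidy table."""
    rows = []
    for t in trials:
        rows.append({
            "subject": t.subject_id,
            "block": t.block_index,
            "trial": t.trial_index,
            "phase": t.phase,
            "left_cs": t.left_cs,
            "right_cs": t.right_cs,
            "left_value": t.left_value,
            "right_value": t.right_value,
            "chosen_side": t.chosen_side,
            "chosen_cs": t.chosen_cs,
            "reward": t.reward if t.reward_observed else np.nan,
            "confidence_raw": t.confidence_raw,
            "confidence": t.confidence,
            "correct": (np.nan if t.correct is None else float(t.correct)),
        })
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return df.sort_values(["subject", "block", "trial"]).reset_index(drop=True)


def _fail(row: int, message: str) -> None:
    raise ValueError(f"trial table row {row}: {message}")


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Derives the normalized confidence from the raw rating when only the raw
    column is present; checks phases, confidence bounds, feedback-phase
    rewards and within-block trial contiguity, naming the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    if "confidence" not in df.columns:
        if "confidence_raw" not in df.columns:
            raise ValueError("trial table needs a confidence or confidence_raw column")
        df["confidence"] = df["confidence_raw"] / 10.0
    if "confidence_raw" not in df.columns:
        df["confidence_raw"] = df["confidence"] * 10.0
    if "correct" not in df.columns:
        df["correct"] = np.nan
    for col in ("left_value", "right_value"):
        if col not in df.columns:
            df[col] = np.nan

    for i, row in enumerate(df.itertuples(index=False)):
        if row.phase not in (1, 2, 3):
            _fail(i, f"phase {row.phase} not in {{1, 2, 3}}")
        if not 0.0 <= row.confidence_raw <= 10.0:
            _fail(i, f"confidence_raw {row.confidence_raw} outside [0, 10]")
        if row.chosen_side not in ("left", "right"):
            _fail(i, f"chosen_side {row.chosen_side!r} must be 'left' or 'right'")
        if row.left_cs == row.right_cs:
            _fail(i, "a CS is paired with itself")
        if row.phase != 2 and pd.isna(row.reward):
            _fail(i, "missing reward in a feedback phase")

    df = df.sort_values(["subject", "block", "trial"]).reset_index(drop=True)
    for (subject, block), bdf in df.groupby(["subject", "block"]):
        tr = bdf["trial"].to_numpy()
        if not np.array_equal(tr, np.arange(tr[0], tr[0] + len(tr))):
            first = int(bdf.index[0])
            _fail(first, f"non-contiguous trial indices in subject {subject} "
                         f"block {block}")
    return df[TRIAL_COLUMNS + [c for c in df.columns if c not in TRIAL_COLUMNS]]


def write_trial_table(df: pd.DataFrame, path) -> None:
    """Write a trial table with fixed column order and float precision."""
    out = df.copy()
    for col in TRIAL_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[TRIAL_COLUMNS]
    out.to_csv(path, index=False, float_format="%.6g")


def load_config(path) -> dict:
    """Load a YAML (or JSON) run-configuration file."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for run logs."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
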
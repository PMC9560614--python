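"""Shared fixtures and independent oracle helpers.

``naive_nll`` re-derives the learner state from scratch for every trial by
replaying the block prefix through the pure transition functions — an
O(n^2) reference path that shares no state-propagation code with the
compiled likelihood kernel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cpelearn.models import (
    ACTIVE_PARAMS,
    LearnerState,
    ParameterSet,
    TrialContext,
    TrialObservation,
    choice_probability,
    step_trial,
)
from cpelearn.task import DesignConfig, generate_experiment_design


@pytest.fixture(scope="session")
def default_design():
    return generate_experiment_design(DesignConfig(), seed=1)


@pytest.fixture(scope="session")
def small_design():
    """A 3-block design for fast end-to-end tests."""
    cfg = DesignConfig(n_blocks=3, n_control_blocks=1)
    return generate_experiment_design(cfg, seed=7)


def random_trial_table(
    rng: np.random.Generator,
    n_blocks: int = 3,
    n_trials: int = 18,
    n_cs: int = 5,
    n1: int = 6,
    n2: int = 6,
    subject: str = "s000",
) -> pd.DataFrame:
    """A random (non-simulated) trial table for likelihood property tests."""
    rows = []
    means = np.array([18.5, 21.5, 24.5, 27.5, 21.5])
    for b in range(n_blocks):
        for t in range(n_trials):
            left, right = rng.choice(n_cs, size=2, replace=False)
            phase = 1 if t < n1 else (2 if t < n1 + n2 else 3)
            side = "right" if rng.random() < 0.5 else "left"
            chosen = right if side == "right" else left
            conf = float(np.round(rng.random(), 3))
            rows.append({
                "subject": subject, "block": b, "trial": t, "phase": phase,
                "left_cs": left, "right_cs": right,
                "left_value": means[left], "right_value": means[right],
                "chosen_side": side, "chosen_cs": chosen,
                "reward": float(rng.integers(0, 51)) if phase != 2 else np.nan,
                "confidence_raw": conf * 10, "confidence": conf,
                "correct": np.nan,
            })
    return pd.DataFrame(rows)


def random_params(model_kind: str, rng: np.random.Generator) -> ParameterSet:
    """Random parameters within bounds (caps gamma/lambda at moderate values)."""
    draw = {
        "alpha_r": rng.uniform(0.05, 0.95),
        "beta": rng.uniform(0.05, 1.5),
        "alpha_c": rng.uniform(0.0, 1.0),
        "alpha_d": rng.uniform(0.0, 1.0),
        "gamma": rng.uniform(0.0, 20.0),
        "lambda_": rng.uniform(0.0, 5.0),
        "eta": rng.uniform(-3.0, 3.0),
    }
    return ParameterSet(model_kind=model_kind,
                        **{k: draw[k] for k in ACTIVE_PARAMS[model_kind]})


def _replay_prefix(model_kind, params, block_df, upto, n_cs=5):
    state = LearnerState.initial(n_cs)
    for row in block_df.iloc[:upto].itertuples(index=False):
        ctx = TrialContext(phase=int(row.phase), left_cs=int(row.left_cs),
                           right_cs=int(row.right_cs), mode="fitting")
        observed = row.phase != 2
        obs = TrialObservation(
            chosen_cs=int(row.chosen_cs),
            reward=float(row.reward) if observed else None,
            reward_observed=observed,
            confidence=float(row.confidence),
        )
        state, _ = step_trial(model_kind, params, state, ctx, obs)
    return state


def naive_nll(model_kind: str, params: ParameterSet, df: pd.DataFrame) -> float:
    """From-scratch likelihood oracle: replays every block prefix per trial."""
    total = 0.0
    for _, bdf in df.groupby("block", sort=False):
        bdf = bdf.reset_index(drop=True)
        for t in range(len(bdf)):
            state = _replay_prefix(model_kind, params, bdf, t)
            row = bdf.iloc[t]
            ctx = TrialContext(phase=int(row.phase), left_cs=int(row.left_cs),
                               right_cs=int(row.right_cs), mode="fitting")
            p_right = choice_probability(model_kind, params, state, ctx)
            p = p_right if row.chosen_side == "right" else 1.0 - p_right
            total -= np.log(max(p, 1e-12))
    return total
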
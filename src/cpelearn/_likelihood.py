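"""Compiled likelihood kernel.

The negative log-likelihood of a subject's choice sequence is a strictly
sequential recursion (the learner state at trial t depends on all earlier
trials), so it cannot be vectorised.  The production path packs the trial
table into flat arrays once and runs a numba-compiled loop; grid search and
the two local optimizers then cost microseconds per likelihood evaluation.
The kernel is held to exact agreement with the pure transition functions in
:mod:`cpelearn.models` by the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

try:  # pragma: no cover - numba is a hard dependency, fallback for safety
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

MODEL_ID = {
    "Static": 0,
    "Deval": 1,
    "Choice": 2,
    "ConfSpec": 3,
    "ConfUnspec": 4,
    "Perseveration": 5,
}

#: slot layout of the dense parameter vector handed to the kernel
_SLOT = {"alpha_r": 0, "beta": 1, "alpha_c": 2, "alpha_d": 3,
         "gamma": 4, "lambda_": 5, "eta": 6}

P_FLOOR = 1e-12  # per-trial likelihood floor before the log


@dataclass(frozen=True)
class TrialArrays:
    """One subject's trials as flat arrays, ordered by (block, trial)."""

    new_block: np.ndarray   # bool: True at the first trial of each block
    phase: np.ndarray       # int8 in {1,2,3}
    left: np.ndarray        # int8 CS index within block
    right: np.ndarray
    chosen_right: np.ndarray  # int8 0/1
    reward: np.ndarray        # float64, NaN where unobserved
    confidence: np.ndarray    # float64 normalized rating
    n_cs: int

    @property
    def n_trials(self) -> int:
        return len(self.phase)


def pack_trials(df: pd.DataFrame, n_cs: int = 5) -> TrialArrays:
    """Pack a (single-subject) trial table into kernel arrays.

    The frame must be sorted by (block, trial); rows of several subjects
    would silently share learner state, so multiple subject ids are rejected.
    """
    if "subject" in df.columns and df["subject"].nunique() > 1:
        raise ValueError("pack_trials expects the trials of a single subject")
    block = df["block"].to_numpy()
    new_block = np.empty(len(df), dtype=np.bool_)
    new_block[0] = True
    new_block[1:] = block[1:] != block[:-1]
    chosen_right = (df["chosen_side"].to_numpy() == "right").astype(np.int8)
    reward = df["reward"].to_numpy(dtype=np.float64, na_value=np.nan)
    return TrialArrays(
        new_block=new_block,
        phase=df["phase"].to_numpy(dtype=np.int8),
        left=df["left_cs"].to_numpy(dtype=np.int8),
        right=df["right_cs"].to_numpy(dtype=np.int8),
        chosen_right=chosen_right,
        reward=reward,
        confidence=df["confidence"].to_numpy(dtype=np.float64),
        n_cs=n_cs,
    )


def dense_params(model_kind: str, vec: np.ndarray) -> np.ndarray:
    """Spread a model's active-parameter vector into the 7-slot dense vector."""
    from .models import ACTIVE_PARAMS

    out = np.zeros(7)
    for name, val in zip(ACTIVE_PARAMS[model_kind], vec):
        out[_SLOT[name]] = val
    return out


@njit(cache=True)
def _nll_core(model_id, theta, new_block, phase, left, right,
              chosen_right, reward, confidence, n_cs):  # pragma: no cover
    alpha_r = theta[0]
    beta = theta[1]
    alpha_c = theta[2]
    alpha_d = theta[3]
    gamma = theta[4]
    lam = theta[5]
    eta = theta[6]

    v = np.zeros(n_cs)
    c_global = 0.0
    c_cs = np.zeros(n_cs)
    prev = np.full((n_cs, n_cs), -1, dtype=np.int8)

    nll = 0.0
    for t in range(phase.shape[0]):
        if new_block[t]:
            v[:] = 0.0
            c_global = 0.0
            c_cs[:] = 0.0
            prev[:, :] = -1

        l = left[t]
        r = right[t]
        ph = phase[t]
        drive = v[r] - v[l]
        if model_id == 5 and ph == 2:
            lo = l if l < r else r
            hi = r if l < r else l
            pc = prev[lo, hi]
            if pc == r:
                drive += eta
            elif pc == l:
                drive -= eta
        x = beta * drive
        if x > 700.0:
            x = 700.0
        elif x < -700.0:
            x = -700.0
        p_right = 1.0 / (1.0 + math.exp(-x))

        chosen = r if chosen_right[t] == 1 else l
        p_obs = p_right if chosen_right[t] == 1 else 1.0 - p_right
        if p_obs < P_FLOOR:
            p_obs = P_FLOOR
        nll -= math.log(p_obs)

        dc = 0.0
        if model_id == 3:  # ConfSpec: per-CS expected confidence
            dc = confidence[t] - c_cs[chosen]
            c_cs[chosen] += alpha_c * dc
        elif model_id == 4:  # ConfUnspec: global expected confidence
            dc = confidence[t] - c_global
            c_global += alpha_c * dc

        if ph != 2:
            v[chosen] += alpha_r * (reward[t] - v[chosen])
        else:
            if model_id == 3 or model_id == 4:
                # the confidence-value transfer targets the model's own
                # predicted choice: updating the actually chosen CS would
                # hand the model the very information it has to predict
                target = r if p_right >= 0.5 else l
                v[target] += gamma * dc
            elif model_id == 2:
                v[chosen] += lam
            elif model_id == 1:
                v[chosen] *= 1.0 - alpha_d

        if model_id == 5:
            lo = l if l < r else r
            hi = r if l < r else l
            prev[lo, hi] = chosen

    return nll


def nll_arrays(model_kind: str, vec: np.ndarray, arrays: TrialArrays) -> float:
    """Negative log-likelihood from pre-packed arrays (the hot path)."""
    theta = dense_params(model_kind, np.asarray(vec, dtype=np.float64))
    return float(
        _nll_core(
            MODEL_ID[model_kind], theta, arrays.new_block, arrays.phase,
            arrays.left, arrays.right, arrays.chosen_right, arrays.reward,
            arrays.confidence, arrays.n_cs,
        )
    )
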
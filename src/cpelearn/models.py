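"""Trial-wise learning models as pure, side-effect-free transition functions.

Six models describe what happens to a learner's expected CS values when
trial-wise reward feedback is withheld (phase 2):

========================  =====================================================
``Static``                values are unchanged
``Deval``                 the chosen CS is devalued as if rewarded with zero
``Choice``                the mere act of choosing adds a fixed bonus (lambda)
``ConfSpec``              values move with *stimulus-specific* confidence
                          prediction errors, scaled by the transfer gamma
``ConfUnspec``            as ConfSpec, but the expected-confidence reference is
                          a single stimulus-unspecific running average
``Perseveration``         values are static, but the choice rule carries an
                          additive bias (eta) toward repeating the previous
                          choice for a CS pair
========================  =====================================================

In feedback phases all models share a Rescorla-Wagner reward update
``v <- v + alpha_r * (r - v)`` and a softmax choice rule with inverse decision
noise beta.  The confidence models additionally track expected confidence on
every trial via ``c_bar <- c_bar + alpha_c * (c - c_bar)``; the confidence
prediction error ``dc = c - c_bar`` is the internal teaching signal that
replaces the reward prediction error when no feedback is given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

__all__ = [
    "MODEL_KINDS",
    "ACTIVE_PARAMS",
    "PARAM_BOUNDS",
    "ParameterSet",
    "LearnerState",
    "StepInfo",
    "TrialContext",
    "TrialObservation",
    "softmax_choice_prob",
    "perseveration_choice_prob",
    "update_value_reward",
    "update_expected_confidence",
    "transfer_confidence_to_value",
    "update_value_choice",
    "update_value_deval",
    "step_trial",
]

MODEL_KINDS = ("Static", "Deval", "Choice", "ConfSpec", "ConfUnspec", "Perseveration")

#: free parameters of each model, in canonical fitting order
ACTIVE_PARAMS: dict[str, tuple[str, ...]] = {
    "Static": ("alpha_r", "beta"),
    "Deval": ("alpha_r", "beta", "alpha_d"),
    "Choice": ("alpha_r", "beta", "lambda_"),
    "ConfSpec": ("alpha_r", "beta", "alpha_c", "gamma"),
    "ConfUnspec": ("alpha_r", "beta", "alpha_c", "gamma"),
    "Perseveration": ("alpha_r", "beta", "eta"),
}

#: hard parameter bounds (gamma and lambda have no natural upper bound;
#: fitting imposes a configurable practical cap)
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha_r": (0.0, 1.0),
    "beta": (0.0, 2.0),
    "alpha_c": (0.0, 1.0),
    "alpha_d": (0.0, 1.0),
    "gamma": (0.0, math.inf),
    "lambda_": (0.0, math.inf),
    "eta": (-5.0, 5.0),
}


@dataclass(frozen=True)
class ParameterSet:
    """The free parameters of one model.

    Parameters not used by ``model_kind`` are dropped (set to None); active
    parameters must lie within their bounds.
    """

    model_kind: str
    alpha_r: float
    beta: float
    alpha_c: Optional[float] = None
    alpha_d: Optional[float] = None
    gamma: Optional[float] = None
    lambda_: Optional[float] = None
    eta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        active = ACTIVE_PARAMS[self.model_kind]
        for name in ("alpha_r", "beta", "alpha_c", "alpha_d", "gamma", "lambda_", "eta"):
            val = getattr(self, name)
            if name in active:
                if val is None:
                    raise ValueError(f"{self.model_kind} requires parameter {name}")
                lo, hi = PARAM_BOUNDS[name]
                if not (lo <= val <= hi):
                    raise ValueError(f"{name}={val} outside bounds [{lo}, {hi}]")
            elif val is not None:
                object.__setattr__(self, name, None)

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(ACTIVE_PARAMS[self.model_kind])

    def to_vector(self) -> np.ndarray:
        """Active parameter values in canonical order."""
        return np.array([getattr(self, n) for n in ACTIVE_PARAMS[self.model_kind]], float)

    @classmethod
    def from_vector(cls, model_kind: str, vec) -> "ParameterSet":
        names = ACTIVE_PARAMS[model_kind]
        if len(vec) != len(names):
            raise ValueError(f"{model_kind} expects {len(names)} parameters, got {len(vec)}")
        return cls(model_kind=model_kind, **dict(zip(names, map(float, vec))))

    def to_dict(self) -> dict:
        d = {"model_kind": self.model_kind}
        for n in ACTIVE_PARAMS[self.model_kind]:
            d[n] = getattr(self, n)
        return d


@dataclass
class LearnerState:
    """Latent state of a learner within one block.

    ``v``: expected value per CS (euros); ``c_global`` / ``c_cs``: expected
    confidence, a single scalar for stimulus-unspecific tracking and one entry
    per CS for stimulus-specific tracking; ``prev_choice``: the CS chosen at
    the most recent encounter of each unordered CS pair.  All are reset to
    zero / empty at every block start (new CS per block).
    """

    v: np.ndarray
    c_global: float
    c_cs: np.ndarray
    prev_choice: dict[frozenset, int]

    @classmethod
    def initial(cls, n_cs: int = 5) -> "LearnerState":
        return cls(
            v=np.zeros(n_cs),
            c_global=0.0,
            c_cs=np.zeros(n_cs),
            prev_choice={},
        )

    def copy(self) -> "LearnerState":
        return LearnerState(
            v=self.v.copy(),
            c_global=self.c_global,
            c_cs=self.c_cs.copy(),
            prev_choice=dict(self.prev_choice),
        )

    def _check_cs(self, cs: int) -> None:
        if not 0 <= cs < len(self.v):
            raise ValueError(f"unknown CS {cs} for a state over {len(self.v)} CS")


# ---------------------------------------------------------------------------
# Choice rules
# ---------------------------------------------------------------------------

def softmax_choice_prob(beta: float, v_right: float, v_left: float) -> float:
    """Probability of choosing the right CS under the softmax rule.

    ``p_right = 1 / (1 + exp(-beta * (v_right - v_left)))``; beta = 0 yields
    random choice.  Stable for arbitrarily large |beta * dv|.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if not (np.isfinite(v_right) and np.isfinite(v_left)):
        raise ValueError("CS values must be finite")
    return float(expit(beta * (v_right - v_left)))


def perseveration_choice_prob(
    beta: float,
    eta: float,
    v_right: float,
    v_left: float,
    c_prev_right: int,
    c_prev_left: int,
) -> float:
    """Softmax choice probability with an additive perseveration bias.

    The previous-choice indicators mark which side's CS was chosen at the last
    encounter of this pair ((0, 0) if the pair is new); a positive eta biases
    toward repetition, a negative one toward alternation.
    """
    if c_prev_right == 1 and c_prev_left == 1:
        raise ValueError("at most one previous-choice indicator can be set")
    if (c_prev_right, c_prev_left) not in ((0, 0), (1, 0), (0, 1)):
        raise ValueError("previous-choice indicators must be 0/1")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if not (np.isfinite(v_right) and np.isfinite(v_left)):
        raise ValueError("CS values must be finite")
    drive = (v_right - v_left) + eta * (c_prev_right - c_prev_left)
    return float(expit(beta * drive))


# ---------------------------------------------------------------------------
# Update rules
# ---------------------------------------------------------------------------

def update_value_reward(
    state: LearnerState, chosen_cs: int, reward: float, alpha_r: float
) -> LearnerState:
    """Rescorla-Wagner reward update of the chosen CS (feedback phases)."""
    state._check_cs(chosen_cs)
    new = state.copy()
    dv = reward - new.v[chosen_cs]
    new.v[chosen_cs] += alpha_r * dv
    return new


def update_expected_confidence(
    state: LearnerState,
    reference_cs: int,
    confidence: float,
    alpha_c: float,
    specificity: str = "global",
) -> tuple[LearnerState, float]:
    """Running-average update of expected confidence; returns (state, dc).

    ``dc`` is the confidence prediction error computed *before* the update.
    In "global" mode the single scalar estimate is updated and
    ``reference_cs`` is ignored; in "per-cs" mode the estimate of the
    reference CS is updated.  Applied on every trial of every phase.
    """
    if not 0.0 <= confidence <= 1.0:
        raise ValueError(f"confidence {confidence} outside [0, 1]")
    if specificity not in ("global", "per-cs"):
        raise ValueError(f"unknown specificity {specificity!r}")
    new = state.copy()
    if specificity == "global":
        dc = confidence - new.c_global
        new.c_global += alpha_c * dc
    else:
        state._check_cs(reference_cs)
        dc = confidence - new.c_cs[reference_cs]
        new.c_cs[reference_cs] += alpha_c * dc
    return new, float(dc)


def _require_no_feedback(no_feedback: bool, rule: str) -> None:
    if not no_feedback:
        raise ValueError(f"{rule} applies only on trials without external feedback")


def transfer_confidence_to_value(
    state: LearnerState,
    target_cs: int,
    delta_c: float,
    gamma: float,
    no_feedback: bool = True,
) -> LearnerState:
    """Confidence-value transfer: v[target] += gamma * dc (no-feedback only)."""
    _require_no_feedback(no_feedback, "confidence-value transfer")
    state._check_cs(target_cs)
    new = state.copy()
    new.v[target_cs] += gamma * delta_c
    return new


def update_value_choice(
    state: LearnerState, target_cs: int, lambda_: float, no_feedback: bool = True
) -> LearnerState:
    """Choice-reinforcement update: v[target] += lambda (no-feedback only)."""
    _require_no_feedback(no_feedback, "choice reinforcement")
    state._check_cs(target_cs)
    new = state.copy()
    new.v[target_cs] += lambda_
    return new


def update_value_deval(
    state: LearnerState, target_cs: int, alpha_d: float, no_feedback: bool = True
) -> LearnerState:
    """Devaluation update: v[target] *= (1 - alpha_d), i.e. an effective
    reward of zero (no-feedback only)."""
    _require_no_feedback(no_feedback, "devaluation")
    state._check_cs(target_cs)
    new = state.copy()
    new.v[target_cs] *= 1.0 - alpha_d
    return new


# ---------------------------------------------------------------------------
# One-trial dispatcher
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialContext:
    """Phase, stimulus pair and mode of one trial.

    ``mode`` is "generative" (phase-2 updates target the sampled choice) or
    "fitting" (phase-2 updates target the model-predicted choice: the right
    CS if p_right >= 0.5, else the left).
    """

    phase: int
    left_cs: int
    right_cs: int
    mode: str = "fitting"

    def __post_init__(self) -> None:
        if self.phase not in (1, 2, 3):
            raise ValueError(f"phase must be 1, 2 or 3, got {self.phase}")
        if self.mode not in ("fitting", "generative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.left_cs == self.right_cs:
            raise ValueError("a CS cannot be paired with itself")


@dataclass(frozen=True)
class TrialObservation:
    """The applied choice, reward and confidence of one trial."""

    chosen_cs: int
    reward: Optional[float] = None
    reward_observed: bool = False
    confidence: Optional[float] = None


@dataclass(frozen=True)
class StepInfo:
    """Transient quantities of one trial step (logged, never stored state)."""

    p_right: float
    p_chosen: float
    delta_c: Optional[float]
    phase2_target: Optional[int]


def _prev_indicators(state: LearnerState, left: int, right: int) -> tuple[int, int]:
    prev = state.prev_choice.get(frozenset((left, right)))
    if prev is None:
        return 0, 0
    return (1, 0) if prev == right else (0, 1)


def choice_probability(
    model_kind: str, params: ParameterSet, state: LearnerState, ctx: TrialContext
) -> float:
    """p_right for the current trial under the model's choice rule.

    The perseveration bias enters only in the no-feedback phase; all other
    cases use the plain softmax on expected values.
    """
    vr, vl = state.v[ctx.right_cs], state.v[ctx.left_cs]
    if model_kind == "Perseveration" and ctx.phase == 2:
        cr, cl = _prev_indicators(state, ctx.left_cs, ctx.right_cs)
        return perseveration_choice_prob(params.beta, params.eta, vr, vl, cr, cl)
    return softmax_choice_prob(params.beta, vr, vl)


def step_trial(
    model_kind: str,
    params: ParameterSet,
    state: LearnerState,
    ctx: TrialContext,
    obs: TrialObservation,
) -> tuple[LearnerState, StepInfo]:
    """Advance the learner by one trial; returns the new state and step info.

    Feedback phases apply the reward update to the applied choice; phase 2
    applies the model-specific no-feedback update to the target CS (sampled
    choice in generative mode, model-predicted choice in fitting mode).
    Confidence models track expected confidence on every trial; the
    Perseveration model records the previous choice of every pair on every
    trial but uses it in the choice rule only in phase 2.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    if params.model_kind != model_kind:
        raise ValueError("parameter set does not match model kind")
    if ctx.phase == 2 and obs.reward_observed:
        raise ValueError("phase-2 observations cannot carry an observed reward")
    if obs.chosen_cs not in (ctx.left_cs, ctx.right_cs):
        raise ValueError("chosen CS is not part of the presented pair")

    p_right = choice_probability(model_kind, params, state, ctx)
    p_chosen = p_right if obs.chosen_cs == ctx.right_cs else 1.0 - p_right

    new = state
    delta_c: Optional[float] = None
    if model_kind in ("ConfSpec", "ConfUnspec"):
        if obs.confidence is None:
            raise ValueError("confidence models require a confidence observation")
        spec = "per-cs" if model_kind == "ConfSpec" else "global"
        new, delta_c = update_expected_confidence(
            new, obs.chosen_cs, obs.confidence, params.alpha_c, spec
        )

    target: Optional[int] = None
    if ctx.phase != 2:
        if not obs.reward_observed or obs.reward is None:
            raise ValueError("feedback phases require an observed reward")
        new = update_value_reward(new, obs.chosen_cs, obs.reward, params.alpha_r)
    else:
        if model_kind in ("ConfSpec", "ConfUnspec"):
            # during fitting the confidence-value transfer targets the
            # model-predicted choice (right CS iff p_right >= 0.5): the
            # actually chosen CS is the observation the likelihood has to
            # predict, so using it would leak information
            if ctx.mode == "fitting":
                target = ctx.right_cs if p_right >= 0.5 else ctx.left_cs
            else:
                target = obs.chosen_cs
            new = transfer_confidence_to_value(new, target, delta_c, params.gamma)
        elif model_kind == "Choice":
            target = obs.chosen_cs
            new = update_value_choice(new, target, params.lambda_)
        elif model_kind == "Deval":
            target = obs.chosen_cs
            new = update_value_deval(new, target, params.alpha_d)
        # Static and Perseveration: values unchanged

    if model_kind == "Perseveration":
        if new is state:
            new = state.copy()
        new.prev_choice[frozenset((ctx.left_cs, ctx.right_cs))] = obs.chosen_cs

    if new is state:
        new = state.copy()
    return new, StepInfo(p_right=p_right, p_chosen=p_chosen,
                         delta_c=delta_c, phase2_target=target)
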
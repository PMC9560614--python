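"""Behavioral/generative effect statistics, parameter sweeps and power.

Four statistics summarize behavior in the no-feedback phase of a trial
table (simulated or empirical):

* **Performance effect** - least-squares slope of the proportion of correct
  choices on the within-phase-2 trial index (per block, averaged up).
* **Confidence effect** - the same slope for normalized confidence.
* **Confidence x value effect** - per CS, the phase-2 confidence slope on
  trials where that CS was chosen, regressed on the CS mean value; the
  regression coefficient (confidence-slope units per euro).
* **Consistency effect** - for CS pairs seen at least three times in
  phase 2, the proportion of pairs chosen identically at the 2nd and 3rd
  occurrence minus the proportion chosen identically at the 1st and 2nd.

Self-reinforcing learning predicts positive confidence and consistency
effects with an essentially flat performance curve; a static learner
predicts all four near zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitConfig, fit_subject
from .models import ACTIVE_PARAMS, ParameterSet
from .simulate import simulate_cohort
from .task import DesignConfig

__all__ = [
    "EffectResult",
    "EffectEstimates",
    "performance_effect",
    "confidence_effect",
    "confidence_value_effect",
    "consistency_effect",
    "all_effects",
    "sweep_grid",
    "run_generative_sweep",
    "power_analysis",
    "PowerResult",
]


@dataclass
class EffectResult:
    """One effect: the across-dataset mean, its SEM and the per-dataset values."""

    name: str
    value: float
    sem: float
    per_subject: np.ndarray

    @property
    def n(self) -> int:
        return len(self.per_subject)


@dataclass
class EffectEstimates:
    """All four effects of one trial table / simulated cohort."""

    performance: EffectResult
    confidence: EffectResult
    confidence_value: EffectResult
    consistency: EffectResult

    def to_dict(self) -> dict:
        out = {}
        for eff in (self.performance, self.confidence,
                    self.confidence_value, self.consistency):
            out[eff.name] = eff.value
            out[f"{eff.name}_sem"] = eff.sem
        return out


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    """OLS slope of y on x; NaN when x has no variance or fewer than 2 points."""
    if len(x) < 2 or np.ptp(x) == 0:
        return np.nan
    return float(np.polyfit(x, y, 1)[0])


def _phase2(trials: pd.DataFrame) -> pd.DataFrame:
    p2 = trials[trials["phase"] == 2]
    if p2.empty:
        raise ValueError("trial table contains no phase-2 trials")
    p2 = p2.copy()
    # within-phase-2 trial index: phase-2 trials are contiguous within a block
    p2["t2"] = p2["trial"] - p2.groupby(["subject", "block"])["trial"].transform("min")
    return p2


def _summarize(name: str, per_subject: list[float]) -> EffectResult:
    arr = np.asarray([v for v in per_subject if np.isfinite(v)], float)
    if arr.size == 0:
        raise ValueError(f"no dataset yields a finite {name}")
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else np.nan
    return EffectResult(name=name, value=float(arr.mean()), sem=sem, per_subject=arr)


def performance_effect(trials: pd.DataFrame) -> EffectResult:
    """Mean phase-2 slope of proportion correct (equal-value pairs excluded)."""
    p2 = _phase2(trials)
    p2 = p2[p2["correct"].notna()]
    if p2.empty:
        raise ValueError("no phase-2 trials with defined correctness")
    per_subject = []
    for _, sdf in p2.groupby("subject", sort=False):
        slopes = [
            _slope(bdf["t2"].to_numpy(float), bdf["correct"].to_numpy(float))
            for _, bdf in sdf.groupby("block", sort=False)
        ]
        per_subject.append(np.nanmean(slopes) if slopes else np.nan)
    return _summarize("performance_effect", per_subject)


def confidence_effect(trials: pd.DataFrame) -> EffectResult:
    """Mean phase-2 slope of normalized confidence."""
    p2 = _phase2(trials)
    per_subject = []
    for _, sdf in p2.groupby("subject", sort=False):
        slopes = [
            _slope(bdf["t2"].to_numpy(float), bdf["confidence"].to_numpy(float))
            for _, bdf in sdf.groupby("block", sort=False)
        ]
        per_subject.append(np.nanmean(slopes) if slopes else np.nan)
    return _summarize("confidence_effect", per_subject)


def confidence_value_effect(trials: pd.DataFrame) -> EffectResult:
    """Interaction of CS-specific confidence slopes with CS value.

    Per block, the phase-2 confidence slope is computed for every CS chosen
    at least twice; those slopes are regressed on the CS mean values and the
    regression coefficient is averaged across blocks, then subjects.
    """
    p2 = _phase2(trials)
    p2["chosen_value"] = np.where(p2["chosen_side"] == "right",
                                  p2["right_value"], p2["left_value"])
    per_subject = []
    any_valid = False
    for _, sdf in p2.groupby("subject", sort=False):
        coefs = []
        for _, bdf in sdf.groupby("block", sort=False):
            slopes, values = [], []
            for (cs, value), cdf in bdf.groupby(["chosen_cs", "chosen_value"]):
                if len(cdf) < 2:
                    continue
                s = _slope(cdf["t2"].to_numpy(float), cdf["confidence"].to_numpy(float))
                if np.isfinite(s):
                    slopes.append(s)
                    values.append(value)
            if len(slopes) >= 2 and np.ptp(values) > 0:
                coefs.append(_slope(np.asarray(values), np.asarray(slopes)))
        if coefs:
            any_valid = True
        per_subject.append(np.nanmean(coefs) if coefs else np.nan)
    if not any_valid:
        raise ValueError("no CS was chosen at least twice in phase 2 of any block")
    return _summarize("confidence_value_effect", per_subject)


def consistency_effect(trials: pd.DataFrame) -> EffectResult:
    """Change of choice consistency between pair repetitions in phase 2.

    Effect = p(choice at 3rd occurrence equals 2nd) - p(2nd equals 1st),
    pooled over unordered CS pairs with >= 3 phase-2 occurrences.
    """
    p2 = _phase2(trials)
    per_subject = []
    any_valid = False
    for _, sdf in p2.groupby("subject", sort=False):
        c12, c23 = [], []
        for _, bdf in sdf.groupby("block", sort=False):
            lo = np.minimum(bdf["left_cs"], bdf["right_cs"])
            hi = np.maximum(bdf["left_cs"], bdf["right_cs"])
            pair = lo.astype(str) + "-" + hi.astype(str)
            for _, pdf in bdf.groupby(pair.to_numpy()):
                if len(pdf) < 3:
                    continue
                chosen = pdf.sort_values("t2")["chosen_cs"].to_numpy()
                c12.append(chosen[0] == chosen[1])
                c23.append(chosen[1] == chosen[2])
        if c12:
            any_valid = True
            per_subject.append(float(np.mean(c23)) - float(np.mean(c12)))
        else:
            per_subject.append(np.nan)
    if not any_valid:
        raise ValueError("no CS pair has three phase-2 occurrences")
    return _summarize("consistency_effect", per_subject)


def all_effects(trials: pd.DataFrame) -> EffectEstimates:
    """All four effect statistics of one trial table."""
    return EffectEstimates(
        performance=performance_effect(trials),
        confidence=confidence_effect(trials),
        confidence_value=confidence_value_effect(trials),
        consistency=consistency_effect(trials),
    )


# ---------------------------------------------------------------------------
# Generative parameter sweeps
# ---------------------------------------------------------------------------

#: parameters fixed during sweeps (they shape feedback-phase behavior only)
SWEEP_FIXED = {"alpha_r": 0.2, "beta": 0.2}


def sweep_grid(model_kind: str) -> list[dict]:
    """The generative-performance sweep nodes for one model.

    ConfUnspec/ConfSpec vary alpha_c over {0, 0.5, 1} and gamma over
    exp(0..4) in 8 equidistant log steps; Choice varies lambda over 0.5-10
    in 7 exponential steps; Perseveration varies eta over -1.5..1.5 in steps
    of 0.5.  alpha_r and beta are fixed at 0.2 throughout.
    """
    if model_kind in ("ConfUnspec", "ConfSpec"):
        return [
            {"alpha_c": ac, "gamma": float(np.exp(lg))}
            for ac in (0.0, 0.5, 1.0)
            for lg in np.linspace(0.0, 4.0, 8)
        ]
    if model_kind == "Choice":
        return [{"lambda_": float(l)} for l in np.geomspace(0.5, 10.0, 7)]
    if model_kind == "Perseveration":
        return [{"eta": float(e)} for e in np.arange(-1.5, 1.51, 0.5)]
    raise ValueError(f"no generative sweep defined for model {model_kind!r}")


def run_generative_sweep(
    model_kind: str,
    n_datasets: int = 250,
    seed=0,
    nodes: Optional[Sequence[dict]] = None,
    design_config: Optional[DesignConfig] = None,
) -> pd.DataFrame:
    """Simulate cohorts over the sweep grid and tabulate the four effects.

    Returns one row per sweep node with the varied parameters, each effect's
    mean and its SEM across the simulated datasets.
    """
    nodes = list(nodes) if nodes is not None else sweep_grid(model_kind)
    rows = []
    master = np.random.SeedSequence(seed)
    for node, child in zip(nodes, master.spawn(len(nodes))):
        params = ParameterSet(model_kind=model_kind, **SWEEP_FIXED, **node)
        subjects = simulate_cohort(model_kind, params, n_datasets,
                                   design_config, seed=child)
        table = pd.concat([s.to_frame() for s in subjects], ignore_index=True)
        est = all_effects(table)
        rows.append({**node, **est.to_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Forward power simulation
# ---------------------------------------------------------------------------

#: educated-guess generative parameters of the sample-size simulation
POWER_GUESS = {"alpha_r": 0.1, "alpha_c": 0.1, "alpha_d": 0.1,
               "beta": 1.0 / 3.0, "gamma": 1.0}


@dataclass
class PowerResult:
    """Outcome of the forward power simulation."""

    power: float
    p_values: np.ndarray
    mean_aic_diff: float  # generative-model AIC minus Static AIC, mean over reps


def power_analysis(
    n_subjects: int = 64,
    model_kind: str = "ConfUnspec",
    params: Optional[ParameterSet] = None,
    n_replications: int = 10,
    alpha: float = 0.05,
    seed=0,
    fit_config: Optional[FitConfig] = None,
    design_config: Optional[DesignConfig] = None,
) -> PowerResult:
    """Probability of dissociating a generative model from Static by AIC.

    Per replication a cohort is simulated from the generative model, every
    subject is fitted with both that model and Static, and a two-tailed
    paired t-test compares the per-subject AIC values; the returned power is
    the fraction of replications with p < alpha.
    """
    if model_kind == "Static":
        raise ValueError("the generative model must be non-Static")
    if n_replications < 1:
        raise ValueError("n_replications must be >= 1")
    if params is None:
        missing = [k for k in ACTIVE_PARAMS[model_kind] if k not in POWER_GUESS]
        if missing:
            raise ValueError(
                f"no educated-guess default for {missing}; pass params explicitly"
            )
        params = ParameterSet(model_kind=model_kind, **{
            k: POWER_GUESS[k] for k in ACTIVE_PARAMS[model_kind]
        })
    fit_config = fit_config or FitConfig()
    master = np.random.SeedSequence(seed)
    p_values, aic_diffs = [], []
    for child in master.spawn(n_replications):
        subjects = simulate_cohort(model_kind, params, n_subjects,
                                   design_config, seed=child)
        diffs = []
        for subj in subjects:
            table = subj.to_frame()
            fit_gen = fit_subject(model_kind, table, config=fit_config)
            fit_static = fit_subject("Static", table, config=fit_config)
            diffs.append(fit_gen.aic - fit_static.aic)
        diffs = np.asarray(diffs)
        if np.allclose(diffs, diffs[0]):
            p_values.append(1.0)
        else:
            _, p = stats.ttest_rel(diffs, np.zeros_like(diffs))
            p_values.append(float(p))
        aic_diffs.append(diffs.mean())
    p_values = np.asarray(p_values)
    return PowerResult(
        power=float(np.mean(p_values < alpha)),
        p_values=p_values,
        mean_aic_diff=float(np.mean(aic_diffs)),
    )
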
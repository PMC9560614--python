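"""Model-recovery confusion matrices and parameter-recovery correlations.

Model recovery asks: if data are generated by model X, does the fitting
pipeline (lowest AIC among all candidates) pick X back out?  Two
row-stochastic matrices summarize the answer - p(fit = Y | gen = X) and,
under equalized generation base rates, p(gen = X | fit = Y).

Parameter recovery asks: varying one generative parameter while holding the
others at an anchor point, does the fitted value of that parameter track the
generative one?  Reported as product-moment correlations between each varied
generative parameter and every fitted parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import FitConfig, fit_subject
from .models import ACTIVE_PARAMS, MODEL_KINDS, ParameterSet
from .simulate import simulate_cohort, simulate_subject
from .task import DesignConfig, generate_experiment_design

__all__ = [
    "RecoveryGrid",
    "ConfusionMatrices",
    "mid_grid_params",
    "run_model_recovery",
    "run_parameter_recovery",
]


@dataclass(frozen=True)
class RecoveryGrid:
    """Per-parameter generative grids of the recovery study.

    Learning rates run over 5 equidistant values in [0.1, 1]; beta over 5
    doubling steps in [0.1, 1.6]; gamma over 5 exponential steps in
    [1, 100]; lambda over 5 exponential steps in [0.5, 5]; eta over 6
    equidistant values in [-1.5, 1.5].  A model with N parameters therefore
    has k^N grid configurations.
    """

    alpha_r: tuple[float, ...] = tuple(np.linspace(0.1, 1.0, 5))
    alpha_c: tuple[float, ...] = tuple(np.linspace(0.1, 1.0, 5))
    alpha_d: tuple[float, ...] = tuple(np.linspace(0.1, 1.0, 5))
    beta: tuple[float, ...] = (0.1, 0.2, 0.4, 0.8, 1.6)
    gamma: tuple[float, ...] = tuple(np.geomspace(1.0, 100.0, 5))
    lambda_: tuple[float, ...] = tuple(np.geomspace(0.5, 5.0, 5))
    eta: tuple[float, ...] = tuple(np.linspace(-1.5, 1.5, 6))

    def axis(self, name: str) -> tuple[float, ...]:
        return getattr(self, name)

    def n_configurations(self, model_kind: str) -> int:
        n = 1
        for name in ACTIVE_PARAMS[model_kind]:
            n *= len(self.axis(name))
        return n


def mid_grid_params(model_kind: str, grid: Optional[RecoveryGrid] = None) -> ParameterSet:
    """The mid-point of each parameter's recovery grid, as a ParameterSet."""
    grid = grid or RecoveryGrid()
    vals = {}
    for name in ACTIVE_PARAMS[model_kind]:
        axis = grid.axis(name)
        vals[name] = axis[len(axis) // 2]
    return ParameterSet(model_kind=model_kind, **vals)


@dataclass
class ConfusionMatrices:
    """Model-recovery result: both confusion matrices plus the raw counts."""

    p_fit_given_gen: pd.DataFrame
    p_gen_given_fit: pd.DataFrame
    counts: pd.DataFrame
    n_per_gen: dict[str, int] = field(default_factory=dict)


def run_model_recovery(
    model_kinds: Sequence[str] = MODEL_KINDS,
    params_per_model: Optional[dict[str, Sequence[ParameterSet]]] = None,
    n_datasets: int = 20,
    seed=0,
    criterion: str = "aic",
    fit_config: Optional[FitConfig] = None,
    design_config: Optional[DesignConfig] = None,
) -> ConfusionMatrices:
    """Simulate datasets per generative model, fit all candidates, tally wins.

    ``params_per_model`` maps each generative model to the parameter
    configurations to simulate from (default: the single mid-grid point of
    the recovery grid - the scaled preset; the full study iterates all k^N
    configurations).  ``n_datasets`` subjects are simulated per model and
    configuration, each on a freshly generated design.  For
    p(gen | fit) the generation base rates are equalized by seeded
    subsampling to the smallest per-model dataset count.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    model_kinds = list(model_kinds)
    if params_per_model is None:
        params_per_model = {m: [mid_grid_params(m)] for m in model_kinds}
    fit_config = fit_config or FitConfig()
    master = np.random.SeedSequence(seed)
    gen_labels, fit_labels = [], []
    for gen_model, child in zip(model_kinds, master.spawn(len(model_kinds))):
        configs = params_per_model[gen_model]
        for params, cc in zip(configs, child.spawn(len(configs))):
            subjects = simulate_cohort(gen_model, params, n_datasets,
                                       design_config, seed=cc)
            for subj in subjects:
                table = subj.to_frame()
                best_model, best_crit = None, np.inf
                for cand in model_kinds:
                    fit = fit_subject(cand, table, config=fit_config)
                    val = fit.aic if criterion == "aic" else fit.bic
                    if val < best_crit:
                        best_crit, best_model = val, cand
                gen_labels.append(gen_model)
                fit_labels.append(best_model)

    gen_arr = np.asarray(gen_labels)
    fit_arr = np.asarray(fit_labels)
    counts = pd.DataFrame(0, index=model_kinds, columns=model_kinds, dtype=int)
    for g, f in zip(gen_arr, fit_arr):
        counts.loc[g, f] += 1

    p_fit_given_gen = counts.div(counts.sum(axis=1), axis=0)

    # equalize generation base rates by subsampling without replacement
    rng = np.random.default_rng(master.spawn(1)[0])
    per_gen = {m: int((gen_arr == m).sum()) for m in model_kinds}
    n_min = min(per_gen.values())
    keep = np.zeros(len(gen_arr), dtype=bool)
    for m in model_kinds:
        idx = np.flatnonzero(gen_arr == m)
        keep[rng.choice(idx, size=n_min, replace=False)] = True
    eq_counts = pd.DataFrame(0, index=model_kinds, columns=model_kinds, dtype=int)
    for g, f in zip(gen_arr[keep], fit_arr[keep]):
        eq_counts.loc[f, g] += 1  # rows: best-fitting model; columns: generative
    row_sums = eq_counts.sum(axis=1).replace(0, np.nan)
    p_gen_given_fit = eq_counts.div(row_sums, axis=0)

    return ConfusionMatrices(
        p_fit_given_gen=p_fit_given_gen,
        p_gen_given_fit=p_gen_given_fit,
        counts=counts,
        n_per_gen=per_gen,
    )


#: default ranges over which each parameter is varied in parameter recovery
PARAM_RECOVERY_RANGES = {
    "alpha_r": (0.01, 1.0),
    "beta": (0.02, 2.0),
    "alpha_c": (0.0, 1.0),
    "gamma": (0.0, 10.0),
}


def run_parameter_recovery(
    model_kind: str = "ConfUnspec",
    varied: str = "alpha_r",
    n_values: int = 250,
    value_range: Optional[tuple[float, float]] = None,
    anchor: Optional[dict[str, float]] = None,
    seed=0,
    fit_config: Optional[FitConfig] = None,
    design_config: Optional[DesignConfig] = None,
) -> pd.Series:
    """Vary one generative parameter; correlate it with every fitted parameter.

    One subject is simulated per varied value (equidistant over
    ``value_range``) with the remaining parameters held at ``anchor``; the
    model is fitted to each subject and the returned series holds the
    product-moment correlation of the varied generative parameter with each
    fitted parameter (NaN where undefined, e.g. a degenerate range).
    """
    if n_values < 3:
        raise ValueError("n_values must be >= 3")
    if varied not in ACTIVE_PARAMS[model_kind]:
        raise ValueError(f"{varied!r} is not a parameter of {model_kind}")
    value_range = value_range or PARAM_RECOVERY_RANGES.get(varied)
    if value_range is None:
        raise ValueError(f"no default range for {varied!r}; pass value_range")
    anchor = dict(anchor or {})
    for name in ACTIVE_PARAMS[model_kind]:
        if name == varied:
            continue
        anchor.setdefault(name, float(mid_grid_params(model_kind).to_dict()[name]))

    fit_config = fit_config or FitConfig()
    design_config = design_config or DesignConfig()
    values = np.linspace(value_range[0], value_range[1], n_values)
    master = np.random.SeedSequence(seed)
    fitted = {name: [] for name in ACTIVE_PARAMS[model_kind]}
    for val, child in zip(values, master.spawn(n_values)):
        words = child.generate_state(2)
        design = generate_experiment_design(design_config,
                                            seed=int(words[0] % 2**31))
        params = ParameterSet(model_kind=model_kind,
                              **{**anchor, varied: float(val)})
        subj = simulate_subject(model_kind, params, design,
                                seed=int(words[1] % 2**31))
        fit = fit_subject(model_kind, subj.to_frame(), config=fit_config)
        for name in fitted:
            fitted[name].append(getattr(fit.params, name))

    out = {}
    for name, est in fitted.items():
        est = np.asarray(est, float)
        if np.ptp(values) == 0 or np.ptp(est) == 0:
            out[name] = np.nan
        else:
            out[name] = float(np.corrcoef(values, est)[0, 1])
    return pd.Series(out, name=f"gen_{varied}")
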
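"""Per-subject maximum-likelihood fitting and cohort model comparison.

Each model is fitted to one subject's full trial sequence (all blocks) by
minimizing the negative log-likelihood of the observed choices.  Learner
state is re-initialized at every block start.  Following common practice for
these likelihood surfaces, a coarse exhaustive grid search provides the
starting point for two local optimizers run in parallel - the bounded
quasi-Newton L-BFGS-B routine and the derivative-free Powell direction-set
routine - and the better of the two is kept (never worse than the grid
optimum).  Model evidence is summarized per subject by AIC and BIC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._likelihood import TrialArrays, nll_arrays, pack_trials
from .models import ACTIVE_PARAMS, MODEL_KINDS, PARAM_BOUNDS, ParameterSet

__all__ = [
    "FitConfig",
    "FitResult",
    "ComparisonResult",
    "negative_log_likelihood",
    "grid_search_init",
    "fit_subject",
    "fit_cohort",
    "compare_models",
]


def _default_grids(cap: float) -> dict[str, np.ndarray]:
    return {
        "alpha_r": np.linspace(0.1, 0.9, 5),
        "alpha_c": np.linspace(0.1, 0.9, 5),
        "alpha_d": np.linspace(0.0, 1.0, 5),
        "beta": np.geomspace(0.05, 1.6, 5),
        "gamma": np.geomspace(0.5, cap, 5),
        "lambda_": np.geomspace(0.1, 10.0, 5),
        "eta": np.linspace(-3.0, 3.0, 7),
    }


@dataclass
class FitConfig:
    """Fitting settings: bounds, initialization grid, optimizer tolerances.

    ``unbounded_cap`` is the practical upper bound imposed on the two
    parameters without a natural one (gamma, lambda).
    """

    unbounded_cap: float = 100.0
    grids: dict[str, np.ndarray] = field(default_factory=dict)
    methods: tuple[str, ...] = ("L-BFGS-B", "Powell")
    tol: float = 1e-6

    def __post_init__(self) -> None:
        defaults = _default_grids(self.unbounded_cap)
        for name, grid in defaults.items():
            self.grids.setdefault(name, grid)
        for name, grid in self.grids.items():
            if len(grid) == 0:
                raise ValueError(f"empty grid for parameter {name}")

    def bounds_for(self, model_kind: str) -> list[tuple[float, float]]:
        out = []
        for name in ACTIVE_PARAMS[model_kind]:
            lo, hi = PARAM_BOUNDS[name]
            if not np.isfinite(hi):
                hi = self.unbounded_cap
            out.append((lo, hi))
        return out


@dataclass
class FitResult:
    """A single (subject, model) maximum-likelihood fit."""

    model_kind: str
    params: ParameterSet
    nll: float
    aic: float
    bic: float
    n_trials: int
    grid_init_nll: float
    optimizer_label: str

    @property
    def k(self) -> int:
        return self.params.k

    def to_dict(self) -> dict:
        d = {"model_kind": self.model_kind, "nll": self.nll, "aic": self.aic,
             "bic": self.bic, "n_trials": self.n_trials,
             "grid_init_nll": self.grid_init_nll,
             "optimizer": self.optimizer_label}
        for name in ACTIVE_PARAMS[self.model_kind]:
            d[name] = getattr(self.params, name)
        return d


def _as_arrays(trials) -> TrialArrays:
    if isinstance(trials, TrialArrays):
        return trials
    return pack_trials(trials)


def negative_log_likelihood(model_kind: str, params, trials) -> float:
    """Summed -log p(observed choice) over all trials of all blocks.

    ``params`` may be a :class:`ParameterSet` or an active-parameter vector;
    ``trials`` a trial table or pre-packed :class:`TrialArrays`.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    arrays = _as_arrays(trials)
    if np.any(np.isnan(arrays.confidence)):
        raise ValueError("confidence must be present on every trial")
    feedback = arrays.phase != 2
    if np.any(np.isnan(arrays.reward[feedback])):
        raise ValueError("rewards must be present on every feedback-phase trial")
    vec = params.to_vector() if isinstance(params, ParameterSet) else np.asarray(params, float)
    return nll_arrays(model_kind, vec, arrays)


def grid_search_init(
    model_kind: str,
    trials,
    grids: Optional[Mapping[str, Sequence[float]]] = None,
    config: Optional[FitConfig] = None,
) -> tuple[np.ndarray, float]:
    """Exhaustive Cartesian grid search; returns (best point, its nll)."""
    config = config or FitConfig()
    arrays = _as_arrays(trials)
    grids = grids or config.grids
    axes = []
    for name in ACTIVE_PARAMS[model_kind]:
        if name not in grids or len(grids[name]) == 0:
            raise ValueError(f"grid missing for parameter {name}")
        axes.append(np.asarray(grids[name], float))
    best_vec, best_nll = None, np.inf
    for point in itertools.product(*axes):
        nll = nll_arrays(model_kind, np.array(point), arrays)
        if nll < best_nll:
            best_nll, best_vec = nll, np.array(point)
    return best_vec, float(best_nll)


def fit_subject(
    model_kind: str,
    trials,
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Maximum-likelihood fit of one model to one subject's trials.

    Runs L-BFGS-B and Powell from the grid-search optimum and keeps the
    better solution; the returned nll is never worse than the grid optimum.
    """
    config = config or FitConfig()
    arrays = _as_arrays(trials)
    x0, grid_nll = grid_search_init(model_kind, arrays, config=config)
    bounds = config.bounds_for(model_kind)

    def objective(x):
        return nll_arrays(model_kind, x, arrays)

    best_x, best_nll, label = x0, grid_nll, "grid"
    n_failed = 0
    for method in config.methods:
        try:
            res = optimize.minimize(objective, x0, method=method,
                                    bounds=bounds, tol=config.tol)
        except Exception:
            n_failed += 1
            continue
        if np.isfinite(res.fun) and res.fun < best_nll:
            x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
            best_x, best_nll, label = x, float(objective(x)), method
    if n_failed == len(config.methods):
        raise RuntimeError(
            f"both optimizers failed for {model_kind}; grid fallback: "
            f"params={x0}, nll={grid_nll}"
        )

    n = arrays.n_trials
    params = ParameterSet.from_vector(model_kind, best_x)
    k = params.k
    return FitResult(
        model_kind=model_kind,
        params=params,
        nll=best_nll,
        aic=2.0 * k + 2.0 * best_nll,
        bic=k * np.log(n) + 2.0 * best_nll,
        n_trials=n,
        grid_init_nll=grid_nll,
        optimizer_label=label,
    )


def fit_cohort(
    model_kinds: Iterable[str],
    subject_tables: Mapping[str, pd.DataFrame],
    config: Optional[FitConfig] = None,
) -> pd.DataFrame:
    """Fit every model to every subject; returns one row per (subject, model)."""
    rows = []
    for subject, df in subject_tables.items():
        arrays = pack_trials(df)
        for kind in model_kinds:
            fit = fit_subject(kind, arrays, config=config)
            row = {"subject": subject, **fit.to_dict()}
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ComparisonResult:
    """Cohort-level model comparison on an information criterion."""

    criterion: str
    table: pd.DataFrame          # subjects x models criterion matrix
    mean: pd.Series
    sem: pd.Series
    winner: str
    ttests: dict[tuple[str, str], tuple[float, float, int]]

    def summary(self) -> str:
        lines = [f"Model comparison ({self.criterion}); winner: {self.winner}"]
        for model in self.mean.index:
            lines.append(f"  {model:<14s} {self.mean[model]:9.2f} "
                         f"+/- {self.sem[model]:.2f}")
        for (a, b), (t, p, df) in self.ttests.items():
            lines.append(f"  {a} vs {b}: t({df}) = {t:.2f}, p = {p:.3g}")
        return "\n".join(lines)


def compare_models(
    fits: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = (),
    criterion: str = "aic",
) -> ComparisonResult:
    """Compare models across subjects by mean AIC (or BIC).

    ``fits`` is the long table from :func:`fit_cohort`.  The winner is the
    model with the minimal mean criterion; requested model pairs are tested
    with a two-tailed paired t-test on the per-subject criterion values.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    wide = fits.pivot(index="subject", columns="model_kind", values=criterion)
    if wide.isna().any().any():
        raise ValueError("every subject must be fitted under every model")
    mean = wide.mean(axis=0)
    sem = wide.sem(axis=0)
    winner = str(mean.idxmin())
    ttests = {}
    for a, b in pairs:
        diff = wide[a] - wide[b]
        df = len(diff) - 1
        if np.allclose(diff, 0.0):
            ttests[(a, b)] = (0.0, 1.0, df)
        else:
            t, p = stats.ttest_rel(wide[a], wide[b])
            ttests[(a, b)] = (float(t), float(p), df)
    return ComparisonResult(
        criterion=criterion.upper(),
        table=wide,
        mean=mean,
        sem=sem,
        winner=winner,
        ttests=ttests,
    )
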
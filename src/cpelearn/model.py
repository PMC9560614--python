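"""Model/Results front end, in the style of statsmodels estimators.

``ValueLearningModel`` binds one subject's trial table to a model kind;
``fit()`` returns a ``ValueLearningResults`` carrying the estimates,
information criteria, optimizer provenance, a ``summary()`` table, the
replayed latent time courses, and posterior-predictive simulation.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from ._likelihood import pack_trials
from .fitting import FitConfig, FitResult, fit_subject, negative_log_likelihood
from .models import ACTIVE_PARAMS, MODEL_KINDS, ParameterSet
from .simulate import SimulatedSubject, replay_latents, simulate_subject
from .task import ExperimentDesign

__all__ = ["ValueLearningModel", "ValueLearningResults"]


class ValueLearningModel:
    """A trial-wise value-learning model bound to one subject's data.

    Parameters
    ----------
    trials : pandas.DataFrame
        Single-subject trial table (see :mod:`cpelearn.io` for the layout),
        sorted by block and trial.
    kind : str
        One of ``Static``, ``Deval``, ``Choice``, ``ConfSpec``,
        ``ConfUnspec``, ``Perseveration``.
    fit_config : FitConfig, optional
        Grid, bounds and optimizer settings.
    """

    def __init__(self, trials: pd.DataFrame, kind: str = "ConfUnspec",
                 fit_config: Optional[FitConfig] = None):
        if kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {kind!r}")
        self.kind = kind
        self.trials = trials.reset_index(drop=True)
        self.fit_config = fit_config or FitConfig()
        self._arrays = pack_trials(self.trials)

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame, kind: str = "ConfUnspec",
                       **kwargs) -> "ValueLearningModel":
        return cls(trials, kind=kind, **kwargs)

    @classmethod
    def from_csv(cls, path, kind: str = "ConfUnspec", **kwargs) -> "ValueLearningModel":
        from .io import read_trial_table

        return cls(read_trial_table(path), kind=kind, **kwargs)

    @property
    def param_names(self) -> tuple[str, ...]:
        return ACTIVE_PARAMS[self.kind]

    def loglike(self, params) -> float:
        """Log-likelihood of the observed choices at ``params``."""
        return -negative_log_likelihood(self.kind, params, self._arrays)

    def fit(self) -> "ValueLearningResults":
        """Maximum-likelihood fit (grid init + L-BFGS-B / Powell)."""
        res = fit_subject(self.kind, self._arrays, config=self.fit_config)
        return ValueLearningResults(self, res)


class ValueLearningResults:
    """Results of a :class:`ValueLearningModel` fit."""

    def __init__(self, model: ValueLearningModel, fit: FitResult):
        self.model = model
        self._fit = fit

    @property
    def params(self) -> ParameterSet:
        return self._fit.params

    @property
    def nll(self) -> float:
        return self._fit.nll

    @property
    def llf(self) -> float:
        return -self._fit.nll

    @property
    def aic(self) -> float:
        return self._fit.aic

    @property
    def bic(self) -> float:
        return self._fit.bic

    @property
    def n_trials(self) -> int:
        return self._fit.n_trials

    @property
    def optimizer(self) -> str:
        return self._fit.optimizer_label

    def latents(self) -> pd.DataFrame:
        """Replayed latent time courses on the observed trials."""
        return replay_latents(self.model.kind, self.params, self.model.trials)

    def simulate(self, design: ExperimentDesign, seed,
                 subject_id: str = "pp000") -> SimulatedSubject:
        """Posterior-predictive simulation at the fitted parameters."""
        return simulate_subject(self.model.kind, self.params, design, seed,
                                subject_id=subject_id)

    def summary(self) -> str:
        f = self._fit
        lines = [
            f"{self.model.kind} value-learning model (maximum likelihood)",
            f"  n trials: {f.n_trials}    optimizer: {f.optimizer_label}",
            f"  -log L: {f.nll:.3f}   AIC: {f.aic:.2f}   BIC: {f.bic:.2f}",
            f"  grid-init -log L: {f.grid_init_nll:.3f}",
            "  parameters:",
        ]
        for name in ACTIVE_PARAMS[self.model.kind]:
            lines.append(f"    {name:<8s} {getattr(self.params, name):10.4f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<ValueLearningResults {self.model.kind} "
                f"nll={self.nll:.2f} aic={self.aic:.2f}>")
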
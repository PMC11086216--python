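"""scikit-learn style estimator wrapping the full EMG-to-torque model.

``HillTorqueModel.fit`` runs the genetic-algorithm calibration on a list of
trials; ``predict`` runs the deterministic forward model.  The estimator
composes with sklearn tooling (``get_params`` / ``set_params`` / ``clone``);
samples are :class:`~emg2torque.synthetic.Trial` objects rather than feature
rows, so it is meant for direct use, not for sklearn pipelines that slice X.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from . import defaults
from .calibration import GAConfig, ParameterBounds, run_ga
from .hill import MuscleParams
from .pipeline import ModelConfig, default_model_config, predict_trial, rmse

__all__ = ["HillTorqueModel"]


class HillTorqueModel(BaseEstimator):
    """EMG-driven Hill-type ankle torque model with GA calibration.

    Parameters
    ----------
    initial_params : mapping, optional
        Muscle label -> :class:`MuscleParams` initial values (defaults to the
        anatomical set); also the centre of the calibration bounds.
    config : ModelConfig, optional
        Activation parameters, curve constants and geometry.
    population, generations, crossover_prob, mutation_prob, bits_per_param,
    mutation_mode :
        Genetic-algorithm settings (see :class:`GAConfig`).
    random_state : int
        Seed for the GA.

    Attributes
    ----------
    muscles_ : dict
        Calibrated muscle parameters after :meth:`fit`.
    result_ : CalibrationResult
        Full calibration outcome (objective trace, per-trial RMSE, seed).
    """

    def __init__(
        self,
        initial_params: Mapping[str, MuscleParams] | None = None,
        config: ModelConfig | None = None,
        population: int = 100,
        generations: int = 150,
        crossover_prob: float = 0.6,
        mutation_prob: float = 0.1,
        bits_per_param: int = 12,
        mutation_mode: str = "per_param",
        random_state: int = 0,
    ):
        self.initial_params = initial_params
        self.config = config
        self.population = population
        self.generations = generations
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.bits_per_param = bits_per_param
        self.mutation_mode = mutation_mode
        self.random_state = random_state

    def _resolved(self):
        base = self.initial_params or defaults.default_muscle_params()
        config = self.config or default_model_config()
        return base, config

    def fit(self, X: Sequence, y=None) -> "HillTorqueModel":
        """Calibrate the 16 muscle parameters on a list of trials.

        ``X`` is a sequence of trials carrying their own measured torque;
        ``y`` is ignored (present for sklearn API compatibility).
        """
        base, config = self._resolved()
        bounds = ParameterBounds.from_initial(base)
        ga = GAConfig(
            population=self.population,
            generations=self.generations,
            crossover_prob=self.crossover_prob,
            mutation_prob=self.mutation_prob,
            bits_per_param=self.bits_per_param,
            mutation_mode=self.mutation_mode,
            seed=self.random_state,
        )
        self.result_ = run_ga(X, bounds=bounds, ga=ga, config=config, base=base)
        self.muscles_ = self.result_.muscles
        self.objective_trace_ = self.result_.objective_trace
        return self

    def _check_fitted(self):
        if not hasattr(self, "muscles_"):
            raise NotFittedError(
                "This HillTorqueModel instance is not fitted yet; call fit first."
            )

    def predict(self, X) -> list[np.ndarray] | np.ndarray:
        """Predicted torque series for each trial (a single trial returns one array)."""
        self._check_fitted()
        _, config = self._resolved()
        single = not isinstance(X, (list, tuple))
        trials = [X] if single else list(X)
        preds = [predict_trial(t, self.muscles_, config) for t in trials]
        return preds[0] if single else preds

    def score(self, X, y=None) -> float:
        """Negative mean torque RMSE over trials (greater is better)."""
        self._check_fitted()
        preds = self.predict(list(X))
        errs = [rmse(p, t.torque) for p, t in zip(preds, X)]
        return -float(np.mean(errs))
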
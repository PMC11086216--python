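"""Forward pipeline: EMG + joint angle -> predicted joint torque, and evaluation.

``predict_trial`` composes the three model stages deterministically:

1. activation dynamics per muscle (delay, recursion, nonlinear shaping),
2. Hill-type fiber integration per muscle, driven by the musculotendon
   length from the geometry polynomials,
3. torque summation over muscles with angle-dependent moment arms.

``evaluate`` reports per-trial torque RMSE, per-muscle mean activation and
per-muscle torque contributions, plus the clamp counts that signal numerical
stress in the fiber solver.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import defaults
from .activation import ActivationParams, activation_from_emg
from .exceptions import InvalidInputError
from .geometry import GeometryPoly, moment_arm, mtu_length
from .hill import FiberStateSeries, ModelConstants, MuscleParams, integrate_fiber_length

__all__ = [
    "ModelConfig",
    "default_model_config",
    "rmse",
    "predict_trial",
    "muscle_contributions",
    "evaluate",
    "EvaluationReport",
]


@dataclass(frozen=True)
class ModelConfig:
    """Everything the forward model needs besides the calibrated muscle set."""

    activation: ActivationParams = field(default_factory=ActivationParams)
    constants: ModelConstants = field(default_factory=ModelConstants)
    geometry: Mapping[str, Mapping[str, GeometryPoly]] = field(
        default_factory=defaults.default_geometry
    )
    a_min: float = 0.01
    use_effective_l0m: bool = True
    engine: str = "numba"

    def activation_at(self, sample_rate: float) -> ActivationParams:
        """Activation parameters with the sample rate matched to a trial."""
        if self.activation.sample_rate == sample_rate:
            return self.activation
        return dataclasses.replace(self.activation, sample_rate=sample_rate)


def default_model_config() -> ModelConfig:
    return ModelConfig()


def rmse(predicted: np.ndarray, measured: np.ndarray) -> float:
    """Root-mean-square error between two torque series, N*m."""
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape:
        raise InvalidInputError(f"series length mismatch: {p.shape} vs {m.shape}")
    return float(np.sqrt(np.mean((p - m) ** 2)))


def predict_trial(
    trial,
    muscles: Mapping[str, MuscleParams],
    config: ModelConfig | None = None,
    return_details: bool = False,
):
    """Predict the joint torque series of one trial.

    Parameters
    ----------
    trial : Trial
        Carries ``t``, ``theta`` (rad), per-muscle ``emg`` in [0, 1] and
        ``dof``; the measured torque is not used.
    muscles : mapping
        Muscle label -> :class:`MuscleParams`.
    return_details : bool
        If true, also return a dict with per-muscle activation series,
        :class:`FiberStateSeries` and torque contributions.

    Returns
    -------
    torque : ndarray
        Predicted torque, N*m; with ``return_details`` a ``(torque, details)``
        tuple.
    """
    if config is None:
        config = default_model_config()
    act_p = config.activation_at(trial.sample_rate)
    geoms = config.geometry[trial.dof]
    dt = 1.0 / trial.sample_rate

    torque = np.zeros_like(trial.theta)
    activations: dict[str, np.ndarray] = {}
    states: dict[str, FiberStateSeries] = {}
    contributions: dict[str, np.ndarray] = {}
    for name, mp in muscles.items():
        try:
            a = activation_from_emg(trial.emg[name], act_p)
            lmt = mtu_length(trial.theta, geoms[name], warn=False)
            state = integrate_fiber_length(
                a,
                lmt,
                dt,
                mp,
                config.constants,
                a_min=config.a_min,
                use_effective_l0m=config.use_effective_l0m,
                engine=config.engine,
            )
        except Exception as err:
            raise type(err)(
                f"forward model failed for muscle {name!r} "
                f"on trial {getattr(trial, 'movement', '?')!r}: {err}"
            ) from err
        r = moment_arm(trial.theta, geoms[name])
        contrib = r * state.Ft
        torque = torque + contrib
        activations[name] = a
        states[name] = state
        contributions[name] = contrib

    if return_details:
        return torque, {
            "activations": activations,
            "states": states,
            "contributions": contributions,
            "clamp_counts": {n: s.clamp_count for n, s in states.items()},
        }
    return torque


def muscle_contributions(
    trial, muscles: Mapping[str, MuscleParams], config: ModelConfig | None = None
) -> pd.DataFrame:
    """Per-muscle torque-contribution series plus activation summary.

    Returns a DataFrame with one column per muscle (``torque_<m>``, N*m),
    the total (exactly the joint torque), and attrs carrying the mean
    activation per muscle.
    """
    torque, details = predict_trial(trial, muscles, config, return_details=True)
    df = pd.DataFrame({"t": trial.t})
    for name, contrib in details["contributions"].items():
        df[f"torque_{name}"] = contrib
    df["torque_total"] = torque
    df.attrs["mean_activation"] = {
        n: float(np.mean(a)) for n, a in details["activations"].items()
    }
    return df


@dataclass
class EvaluationReport:
    """Evaluation of a parameter set over a collection of trials."""

    per_trial: pd.DataFrame
    mean_rmse: float
    sd_rmse: float
    clamp_total: int

    def summary(self) -> str:
        lines = [
            f"trials evaluated : {len(self.per_trial)}",
            f"torque RMSE      : {self.mean_rmse:.3f} +/- {self.sd_rmse:.3f} N*m (mean +/- SD)",
            f"fv clamp events  : {self.clamp_total}",
            "",
            self.per_trial.to_string(index=False),
        ]
        return "\n".join(lines)


def evaluate(
    trials: Sequence,
    muscles: Mapping[str, MuscleParams],
    config: ModelConfig | None = None,
) -> EvaluationReport:
    """Compute torque RMSE and contribution statistics for each trial."""
    rows = []
    clamp_total = 0
    for trial in trials:
        pred, details = predict_trial(trial, muscles, config, return_details=True)
        err = rmse(pred, trial.torque)
        contribs = details["contributions"]
        dominant = max(contribs, key=lambda n: float(np.mean(np.abs(contribs[n]))))
        row = {
            "movement": getattr(trial, "movement", "?"),
            "role": trial.meta.get("role", "") if hasattr(trial, "meta") else "",
            "rmse_Nm": err,
            "peak_measured_Nm": float(np.max(np.abs(trial.torque))),
            "peak_predicted_Nm": float(np.max(np.abs(pred))),
            "dominant_muscle": dominant,
        }
        for name, a in details["activations"].items():
            row[f"mean_act_{name}"] = float(np.mean(a))
        for name, contrib in contribs.items():
            row[f"mean_abs_torque_{name}"] = float(np.mean(np.abs(contrib)))
        row["clamp_events"] = sum(details["clamp_counts"].values())
        clamp_total += row["clamp_events"]
        rows.append(row)
    df = pd.DataFrame(rows)
    return EvaluationReport(
        per_trial=df,
        mean_rmse=float(df["rmse_Nm"].mean()),
        sd_rmse=float(df["rmse_Nm"].std(ddof=1)) if len(df) > 1 else 0.0,
        clamp_total=clamp_total,
    )
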
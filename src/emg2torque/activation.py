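"""Muscle activation dynamics: normalized sEMG envelope -> muscle activation.

The chain is

    e(t)  --[delay + second-order recursion]-->  u(t)  --[nonlinear shaping]-->  a(t)

where ``e`` is the MVC-normalized EMG envelope, ``u`` the neural activation and
``a`` the muscle activation, all dimensionless in [0, 1].  The recursion

    u(t) = alpha * e(t - d) - beta1 * u(t-1) - beta2 * u(t-2)

is a linear IIR filter preceded by an integer-sample electromechanical delay
``d = round(de * fs / 1000)``.  With the default coefficients the filter has
real characteristic roots of magnitude < 0.06 and DC gain
alpha / (1 + beta1 + beta2) ~= 0.99997, i.e. it is essentially a delayed
unit-gain pass-through with a short memory — the common discrete form of
activation dynamics used in EMG-driven modelling.

The nonlinear shaping

    a(t) = (exp(A * u(t)) - 1) / (exp(A) - 1),    A in (-3, 0)

maps [0, 1] onto [0, 1] monotonically and models the curvature of the
EMG-to-force relationship at low effort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import ConfigurationError, InvalidInputError, InvalidParameterError

log = logging.getLogger(__name__)

__all__ = [
    "ActivationParams",
    "normalize_emg",
    "neural_activation",
    "muscle_activation",
    "activation_from_emg",
    "preprocess_raw_emg",
]


@dataclass(frozen=True)
class ActivationParams:
    """Parameters of the activation dynamics, shared across muscles.

    Parameters
    ----------
    de : float
        Electromechanical delay in milliseconds (force lags EMG onset;
        physiological range roughly 10–100 ms).
    alpha : float
        Gain of the recursion.
    beta1, beta2 : float
        Recursion coefficients.  The characteristic polynomial
        ``z**2 + beta1*z + beta2`` must have roots of magnitude < 1.
    A : float
        Nonlinear shape factor, strictly inside (-3, 0).
    sample_rate : float
        Sampling rate of the envelope series in Hz.
    """

    de: float = 40.0
    alpha: float = 0.9486
    beta1: float = -0.052
    beta2: float = 0.000627
    A: float = -1.5
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        if not -3.0 < self.A < 0.0:
            raise ConfigurationError(
                f"shape factor A must lie strictly in (-3, 0); got {self.A}"
            )
        if self.de < 0:
            raise InvalidParameterError(f"electromechanical delay must be >= 0 ms; got {self.de}")
        if self.sample_rate <= 0:
            raise InvalidParameterError(f"sample_rate must be positive; got {self.sample_rate}")
        r = np.abs(self.characteristic_roots)
        if r.max() >= 1.0:
            raise ConfigurationError(
                "unstable activation recursion: characteristic root magnitudes "
                f"{r} must all be < 1"
            )

    @property
    def characteristic_roots(self) -> np.ndarray:
        """Roots of z**2 + beta1*z + beta2 (stability requires |z| < 1)."""
        return np.roots([1.0, self.beta1, self.beta2])

    @property
    def delay_samples(self) -> int:
        """Delay in whole samples, round-half-up."""
        return int(np.floor(self.de * self.sample_rate / 1000.0 + 0.5))

    @property
    def dc_gain(self) -> float:
        """Steady-state gain alpha / (1 + beta1 + beta2) of the recursion."""
        return self.alpha / (1.0 + self.beta1 + self.beta2)


def normalize_emg(raw_envelope: np.ndarray, mvc_max: float) -> np.ndarray:
    """Normalize a rectified EMG envelope by its MVC reference and clip to [0, 1].

    Parameters
    ----------
    raw_envelope : array_like
        Nonnegative envelope samples (arbitrary units).
    mvc_max : float
        Peak envelope recorded during maximum voluntary contraction, same units.
    """
    if not np.isscalar(mvc_max) or mvc_max <= 0:
        raise InvalidParameterError(f"mvc_max must be a positive scalar; got {mvc_max!r}")
    raw = np.asarray(raw_envelope, dtype=float)
    if (raw < 0).any():
        raise InvalidInputError("raw envelope values must be nonnegative")
    return np.clip(raw / mvc_max, 0.0, 1.0)


def neural_activation(
    e: np.ndarray, params: ActivationParams, clip: bool = True
) -> np.ndarray:
    """Delayed second-order recursion mapping e(t) to neural activation u(t).

    Samples before the delay are treated as zero drive; the recursion starts
    with u = 0.  With ``clip=False`` the raw (linear) filter output is
    returned, which is useful for verifying linearity.
    """
    e = np.asarray(e, dtype=float)
    if e.ndim != 1:
        raise InvalidInputError("e must be one-dimensional")
    if (e < 0).any() or (e > 1).any():
        raise InvalidInputError("normalized EMG must lie in [0, 1]")
    d = params.delay_samples
    if d >= e.size:
        raise InvalidInputError(
            f"delay of {d} samples is not shorter than the series ({e.size} samples)"
        )
    delayed = np.concatenate([np.zeros(d), e[: e.size - d]])
    u = signal.lfilter([params.alpha], [1.0, params.beta1, params.beta2], delayed)
    if clip:
        n_out = int(((u < 0.0) | (u > 1.0)).sum())
        if n_out:
            log.warning("neural_activation clipped %d samples to [0, 1]", n_out)
        u = np.clip(u, 0.0, 1.0)
    return u


def muscle_activation(u: np.ndarray, A: float = -1.5) -> np.ndarray:
    """Nonlinear shaping a = (exp(A*u) - 1) / (exp(A) - 1), elementwise.

    Strictly increasing on [0, 1] for any A in (-3, 0); a(0) = 0, a(1) = 1.
    A = 0 is a singular point of the formula and is rejected.
    """
    if not -3.0 < A < 0.0:
        raise ConfigurationError(f"shape factor A must lie strictly in (-3, 0); got {A}")
    u = np.asarray(u, dtype=float)
    if (u < 0).any() or (u > 1).any():
        raise InvalidInputError("neural activation must lie in [0, 1]")
    return np.expm1(A * u) / np.expm1(A)


def activation_from_emg(e: np.ndarray, params: ActivationParams) -> np.ndarray:
    """Full activation dynamics: normalized envelope -> muscle activation."""
    return muscle_activation(neural_activation(e, params), params.A)


def preprocess_raw_emg(
    raw: np.ndarray,
    sample_rate: float,
    band: tuple[float, float] = (20.0, 450.0),
    envelope_cutoff: float = 6.0,
) -> np.ndarray:
    """Optional helper: raw EMG -> rectified low-pass envelope.

    Band-pass (4th-order Butterworth), full-wave rectify, then low-pass the
    rectified signal to obtain a linear envelope.  This is a convenience
    extension for users starting from raw recordings; the core pipeline
    accepts already-computed envelopes.
    """
    raw = np.asarray(raw, dtype=float)
    nyq = sample_rate / 2.0
    lo, hi = band
    hi = min(hi, 0.99 * nyq)
    if not 0 < lo < hi:
        raise InvalidParameterError(f"invalid band {band} for sample rate {sample_rate}")
    sos = signal.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    rectified = np.abs(signal.sosfiltfilt(sos, raw))
    sos_env = signal.butter(2, envelope_cutoff / nyq, btype="lowpass", output="sos")
    return np.maximum(signal.sosfiltfilt(sos_env, rectified), 0.0)
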
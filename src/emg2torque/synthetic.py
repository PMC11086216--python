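"""Synthetic trial generation.

No public recordings accompany the ankle-bench protocol this package models,
so every downstream stage is exercised on synthetic trials produced from
known ground-truth parameters:

* the joint angle sweeps from neutral to the movement's range of motion and
  back as a half-sine (slow, smooth, as on a motor-driven bench);
* per-muscle EMG envelopes are smooth bells with movement-specific agonist
  weighting (tibialis anterior for dorsiflexion, triceps surae for
  plantarflexion, ...), a small resting baseline, plus band-limited noise,
  clipped to [0, 1];
* the torque is the forward model run at the ground-truth parameters on the
  *stored* (noisy) envelopes, plus white measurement noise whose SD is a
  fraction of the trial's peak torque.

Because the stored torque is generated from the stored inputs, a noiseless
trial is exactly reproduced by the forward model at the true parameters, and
the torque-noise SD is the irreducible error floor of any calibration.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import defaults
from .exceptions import InvalidInputError, InvalidParameterError, TrialFormatError
from .hill import MuscleParams
from .pipeline import ModelConfig, default_model_config, predict_trial

__all__ = [
    "TrialSpec",
    "Trial",
    "generate_trial",
    "draw_subject_params",
    "generate_scenario",
    "write_trial",
    "read_trial",
]

_FORMAT_TAG = "emg2torque-trial v1"


@dataclass(frozen=True)
class TrialSpec:
    """Specification of one synthetic movement trial.

    ``rom_deg`` is signed (negative for plantarflexion / external rotation);
    ``torque_noise`` is the white torque-noise SD as a fraction of the
    trial's peak torque, ``emg_noise`` the absolute SD of the band-limited
    envelope noise.
    """

    movement: str
    rom_deg: float | None = None
    duration: float = 5.0
    sample_rate: float = 1000.0
    torque_noise: float = 0.05
    emg_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.movement not in defaults.MOVEMENTS:
            raise InvalidParameterError(
                f"unknown movement {self.movement!r}; known: {sorted(defaults.MOVEMENTS)}"
            )
        if self.rom_deg is None:
            object.__setattr__(self, "rom_deg", defaults.MOVEMENTS[self.movement][1])
        if self.rom_deg == 0:
            raise InvalidParameterError("rom_deg must be nonzero")
        if self.duration <= 0 or self.sample_rate <= 0:
            raise InvalidParameterError("duration and sample_rate must be positive")
        if self.torque_noise < 0 or self.emg_noise < 0:
            raise InvalidParameterError("noise SDs must be nonnegative")

    @property
    def dof(self) -> str:
        return defaults.MOVEMENTS[self.movement][0]


@dataclass
class Trial:
    """Aligned time series of one movement: angle, EMG envelopes, torque."""

    movement: str
    dof: str
    t: np.ndarray
    theta: np.ndarray  # rad
    emg: dict[str, np.ndarray]  # muscle -> envelope in [0, 1]
    torque: np.ndarray  # N*m
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.t.size
        if self.theta.size != n or self.torque.size != n:
            raise InvalidInputError("all trial series must share one time base")
        if n < 2:
            raise InvalidInputError("a trial needs at least two samples")
        dt = np.diff(self.t)
        if dt.min() <= 0 or np.abs(dt - dt[0]).max() > 1e-9 * max(dt[0], 1e-12):
            raise InvalidInputError("trial time base must be uniform and increasing")
        for name, e in self.emg.items():
            if e.size != n:
                raise InvalidInputError(f"EMG channel {name!r} length mismatch")
            if (e < 0).any() or (e > 1).any():
                raise InvalidInputError(f"EMG channel {name!r} outside [0, 1]")

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def _envelope_bells(spec: TrialSpec, t: np.ndarray) -> dict[str, np.ndarray]:
    profile = defaults.envelope_profile(spec.movement)
    sigma = 0.15 * spec.duration
    out = {}
    for m in defaults.MUSCLES:
        amp, centre = profile[m]
        bell = amp * np.exp(-((t - centre * spec.duration) ** 2) / (2.0 * sigma**2))
        out[m] = defaults.ENVELOPE_BASELINE + bell
    return out


def _bandlimited_noise(rng: np.random.Generator, n: int, sample_rate: float, sd: float):
    """Gaussian noise smoothed to ~50 ms correlation time, rescaled to `sd`."""
    raw = rng.standard_normal(n)
    smooth = gaussian_filter1d(raw, sigma=max(0.05 * sample_rate, 1.0))
    s = smooth.std()
    if s > 0:
        smooth = smooth / s
    return sd * smooth


def generate_trial(
    spec: TrialSpec,
    muscles: dict[str, MuscleParams] | None = None,
    config: ModelConfig | None = None,
) -> Trial:
    """Generate one synthetic trial; deterministic given ``spec.seed``.

    ``muscles`` are the ground-truth parameters (defaults to the anatomical
    initial set); ``config`` carries activation parameters, curve constants
    and geometry shared between generation and later calibration.
    """
    if muscles is None:
        muscles = defaults.default_muscle_params()
    if config is None:
        config = default_model_config()
    rng = np.random.default_rng(spec.seed)

    n = int(round(spec.duration * spec.sample_rate)) + 1
    t = np.arange(n) / spec.sample_rate
    theta = np.radians(spec.rom_deg) * np.sin(np.pi * t / spec.duration)

    emg = {}
    for m, clean in _envelope_bells(spec, t).items():
        noisy = clean + _bandlimited_noise(rng, n, spec.sample_rate, spec.emg_noise)
        emg[m] = np.clip(noisy, 0.0, 1.0)

    trial = Trial(
        movement=spec.movement,
        dof=spec.dof,
        t=t,
        theta=theta,
        emg=emg,
        torque=np.zeros(n),
        meta={"spec": asdict(spec), "synthetic": True},
    )
    clean_torque = predict_trial(trial, muscles, config)
    noise_sd = spec.torque_noise * float(np.max(np.abs(clean_torque)))
    trial.torque = clean_torque + (
        rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0
    )
    trial.meta["torque_noise_sd_Nm"] = noise_sd
    trial.meta["true_params"] = {
        m: {"F0m": p.F0m, "l0m": p.l0m, "lst": p.lst, "phi0_deg": p.phi0_deg, "v0m": p.v0m}
        for m, p in muscles.items()
    }
    return trial


#: Per-parameter draw of the synthetic subject's ground truth, as
#: multiplicative factors of the anatomical initial values.  ``two_sided``
#: draws the factor as 1 +/- U(lo, hi) with a random sign, so every subject
#: differs appreciably from the anatomical initial set (a near-nominal
#: subject would leave calibration nothing to recover); ``uniform`` draws the
#: factor from U(lo, hi).  Length factors are kept narrow so the
#: anatomical-initial forward run always remains feasible.
SUBJECT_DRAW_RANGES = {
    "F0m": ("two_sided", 0.20, 0.45),
    "l0m": ("uniform", 0.88, 1.12),
    "lst": ("uniform", 0.98, 1.02),
    "phi0_deg": ("two_sided", 0.10, 0.25),
}


def _draw_factor(rng: np.random.Generator, kind: str, lo: float, hi: float) -> float:
    if kind == "two_sided":
        return 1.0 + rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi)
    return rng.uniform(lo, hi)


def draw_subject_params(
    rng: np.random.Generator, base: dict[str, MuscleParams] | None = None
) -> dict[str, MuscleParams]:
    """Draw a synthetic 'subject': ground-truth parameters around the
    anatomical initial set, inside the calibration bounds.

    v0m is kept at the base value (it is not calibrated).
    """
    if base is None:
        base = defaults.default_muscle_params()
    out = {}
    for name, p in base.items():
        factors = {
            k: _draw_factor(rng, kind, lo, hi)
            for k, (kind, lo, hi) in SUBJECT_DRAW_RANGES.items()
        }
        out[name] = MuscleParams(
            name=name,
            F0m=p.F0m * factors["F0m"],
            l0m=p.l0m * factors["l0m"],
            lst=p.lst * factors["lst"],
            phi0_deg=p.phi0_deg * factors["phi0_deg"],
            v0m=p.v0m,
        )
    return out


def generate_scenario(
    seed: int,
    movements: tuple[str, ...] | None = None,
    reps: int = 3,
    duration: float = 5.0,
    sample_rate: float = 1000.0,
    torque_noise: float = 0.05,
    emg_noise: float = 0.02,
    muscles: dict[str, MuscleParams] | None = None,
    config: ModelConfig | None = None,
):
    """Generate a full study scenario: ``reps`` trials per movement.

    The ground truth is one subject drawn with :func:`draw_subject_params`
    (unless ``muscles`` is given).  The last repetition of every movement is
    marked ``role="test"``, the others ``role="train"``.

    Returns
    -------
    (trials, truth) : (list[Trial], dict[str, MuscleParams])
    """
    if movements is None:
        movements = tuple(defaults.MOVEMENTS)
    if reps < 1:
        raise InvalidParameterError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    if muscles is None:
        muscles = draw_subject_params(rng)
    trials = []
    for movement in movements:
        for rep in range(reps):
            spec = TrialSpec(
                movement=movement,
                duration=duration,
                sample_rate=sample_rate,
                torque_noise=torque_noise,
                emg_noise=emg_noise,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            trial = generate_trial(spec, muscles, config)
            trial.meta["rep"] = rep
            trial.meta["role"] = "test" if rep == reps - 1 else "train"
            trials.append(trial)
    return trials, muscles


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_trial(trial: Trial, path) -> None:
    """Write a trial as CSV with a commented header carrying its metadata."""
    path = Path(path)
    df = pd.DataFrame({"t": trial.t, "theta_deg": np.degrees(trial.theta)})
    for m in defaults.MUSCLES:
        df[f"emg_{m}"] = trial.emg[m]
    df["torque_Nm"] = trial.torque
    buf = _io.StringIO()
    df.to_csv(buf, index=False, lineterminator="\n")
    header = [
        f"# {_FORMAT_TAG}",
        f"# movement: {trial.movement}",
        f"# dof: {trial.dof}",
        f"# samples: {len(df)}",
        f"# meta: {json.dumps(trial.meta, sort_keys=True)}",
    ]
    path.write_text("\n".join(header) + "\n" + buf.getvalue())


def read_trial(path) -> Trial:
    """Read a trial CSV written by :func:`write_trial`.

    Validates the declared sample count (a truncated file is an error, never
    a silently shorter trial) and the uniformity of the time base.
    """
    path = Path(path)
    header: dict[str, str] = {}
    with path.open() as fh:
        first = fh.readline().strip()
        if first != f"# {_FORMAT_TAG}":
            raise TrialFormatError(f"{path}: not an emg2torque trial file")
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                header[key.strip()] = val.strip()
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as err:
        raise TrialFormatError(f"{path}: cannot parse CSV: {err}") from err
    required = ["t", "theta_deg"] + [f"emg_{m}" for m in defaults.MUSCLES] + ["torque_Nm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{path}: missing columns {missing}")
    if df[required].isna().any().any():
        raise TrialFormatError(f"{path}: file contains missing values (truncated row?)")
    declared = header.get("samples")
    if declared is not None and int(declared) != len(df):
        raise TrialFormatError(
            f"{path}: declared {declared} samples but found {len(df)} (truncated file?)"
        )
    meta = json.loads(header["meta"]) if "meta" in header else {}
    t = df["t"].to_numpy()
    dt = np.diff(t)
    if dt.size == 0 or dt.min() <= 0 or np.abs(dt - dt[0]).max() > 1e-9 * dt[0]:
        raise TrialFormatError(f"{path}: non-uniform time column")
    return Trial(
        movement=header.get("movement", meta.get("spec", {}).get("movement", "?")),
        dof=header.get("dof", "?"),
        t=t,
        theta=np.radians(df["theta_deg"].to_numpy()),
        emg={m: df[f"emg_{m}"].to_numpy() for m in defaults.MUSCLES},
        torque=df["torque_Nm"].to_numpy(),
        meta=meta,
    )
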
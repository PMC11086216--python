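"""Package default parameter sets.

The muscle constants below are the anatomical initial estimates for the four
recorded lower-leg muscles (tibialis anterior ``ta``, soleus ``sol``, medial
and lateral gastrocnemius ``gm``/``gl``): maximum isometric force F0m,
optimal fiber length l0m, tendon slack length lst and pennation angle phi0.
They are the starting point (and the centre of the search bounds) for
calibration.

The geometry polynomials are PACKAGE DEFAULTS, not measured values: moment
arms at neutral were chosen to be anatomically plausible in sign and
magnitude while keeping fiber excursions over the full range of motion
within the active force-length support, given the short optimal fiber
lengths above.  They can be overridden via configuration.
"""

from __future__ import annotations

import math

from .activation import ActivationParams
from .geometry import GeometryPoly
from .hill import ModelConstants, MuscleParams

__all__ = [
    "MUSCLES",
    "MUSCLE_NAMES",
    "DOFS",
    "MOVEMENTS",
    "BOUND_FRACTIONS",
    "default_muscle_params",
    "default_geometry",
    "default_activation",
    "default_constants",
    "envelope_profile",
]

#: Canonical muscle order used throughout (CSV columns, parameter vectors).
MUSCLES = ("ta", "sol", "gm", "gl")

MUSCLE_NAMES = {
    "ta": "tibialis anterior",
    "sol": "soleus",
    "gm": "gastrocnemius medialis",
    "gl": "gastrocnemius lateralis",
}

#: Ankle degrees of freedom with the positive-angle convention.
DOFS = {
    "sagittal": "dorsiflexion(+) / plantarflexion(-)",
    "frontal": "inversion(+) / eversion(-)",
    "transverse": "internal(+) / external(-) rotation",
}

#: Movement protocol: movement -> (dof, signed range of motion in degrees).
MOVEMENTS = {
    "dorsiflexion": ("sagittal", 30.0),
    "plantarflexion": ("sagittal", -45.0),
    "inversion": ("frontal", 15.0),
    "internal_rotation": ("transverse", 35.0),
    "external_rotation": ("transverse", -25.0),
}

#: Calibration bound half-widths relative to the initial value, per parameter.
BOUND_FRACTIONS = {"F0m": 0.50, "l0m": 0.50, "lst": 0.15, "phi0_deg": 0.50}

# (F0m [N], l0m [m], lst [m], phi0 [deg])
_ANATOMICAL = {
    "ta": (1270.0, 0.031, 0.310, 12.0),
    "sol": (2830.0, 0.030, 0.268, 25.0),
    "gm": (1115.0, 0.045, 0.408, 17.0),
    "gl": (490.0, 0.064, 0.385, 8.0),
}

# (mu1 [m/rad], mu2 [m/rad^2], mu3 [m/rad^3]) per (dof, muscle); mu0 is
# lst + l0m*cos(phi0) so the tendon is exactly slack with the fiber at l0m
# in the neutral posture.
_ARMS = {
    ("sagittal", "ta"): (0.020, 0.0015, 0.0),
    ("sagittal", "sol"): (-0.018, 0.0010, 0.0),
    ("sagittal", "gm"): (-0.015, 0.0010, 0.0),
    ("sagittal", "gl"): (-0.014, 0.0008, 0.0),
    ("frontal", "ta"): (0.013, 0.0005, 0.0),
    ("frontal", "sol"): (0.011, 0.0, 0.0),
    ("frontal", "gm"): (0.009, 0.0, 0.0),
    ("frontal", "gl"): (-0.007, 0.0, 0.0),
    ("transverse", "ta"): (0.010, 0.0, 0.0),
    ("transverse", "sol"): (-0.004, 0.0, 0.0),
    ("transverse", "gm"): (0.004, 0.0, 0.0),
    ("transverse", "gl"): (-0.009, 0.0, 0.0),
}

_ROM_DEG = {
    "sagittal": (-50.0, 35.0),
    "frontal": (-20.0, 20.0),
    "transverse": (-40.0, 40.0),
}

# Synthetic envelope profile per movement: muscle -> (peak amplitude above the
# 0.02 resting baseline, bell-centre as fraction of trial duration).  Agonist
# weighting mirrors the observed muscle contributions: tibialis anterior
# drives dorsiflexion; the triceps surae (strong plantarflexors, hence low
# normalized effort) drive plantarflexion; during inversion the triceps act
# early and tibialis anterior late; soleus is nearly silent in internal
# rotation and the medial gastrocnemius in external rotation.
_ENVELOPES = {
    "dorsiflexion": {
        "ta": (0.45, 0.5),
        "sol": (0.02, 0.5),
        "gm": (0.03, 0.5),
        "gl": (0.03, 0.5),
    },
    "plantarflexion": {
        "ta": (0.03, 0.5),
        "sol": (0.10, 0.5),
        "gm": (0.10, 0.5),
        "gl": (0.10, 0.5),
    },
    "inversion": {
        "ta": (0.12, 0.68),
        "sol": (0.16, 0.42),
        "gm": (0.16, 0.42),
        "gl": (0.04, 0.5),
    },
    "internal_rotation": {
        "ta": (0.30, 0.5),
        "sol": (0.03, 0.5),
        "gm": (0.25, 0.5),
        "gl": (0.04, 0.5),
    },
    "external_rotation": {
        "ta": (0.03, 0.5),
        "sol": (0.25, 0.5),
        "gm": (0.03, 0.5),
        "gl": (0.30, 0.5),
    },
}

#: Resting envelope baseline added to every channel.
ENVELOPE_BASELINE = 0.02


def default_muscle_params() -> dict[str, MuscleParams]:
    """Anatomical initial muscle parameters (v0m = 10 * l0m per second)."""
    return {
        name: MuscleParams(name, F0m, l0m, lst, phi0)
        for name, (F0m, l0m, lst, phi0) in _ANATOMICAL.items()
    }


def default_geometry() -> dict[str, dict[str, GeometryPoly]]:
    """Default geometry polynomials: dof -> muscle -> GeometryPoly."""
    out: dict[str, dict[str, GeometryPoly]] = {}
    for dof in DOFS:
        out[dof] = {}
        for m in MUSCLES:
            F0m, l0m, lst, phi0 = _ANATOMICAL[m]
            mu0 = lst + l0m * math.cos(math.radians(phi0))
            mu1, mu2, mu3 = _ARMS[(dof, m)]
            out[dof][m] = GeometryPoly(
                muscle=m, dof=dof, mu0=mu0, mu1=mu1, mu2=mu2, mu3=mu3,
                rom_deg=_ROM_DEG[dof],
            )
    return out


def default_activation() -> ActivationParams:
    return ActivationParams()


def default_constants() -> ModelConstants:
    return ModelConstants()


def envelope_profile(movement: str) -> dict[str, tuple[float, float]]:
    """Per-muscle (amplitude, centre-fraction) of the synthetic envelope bells."""
    if movement not in _ENVELOPES:
        raise KeyError(f"unknown movement {movement!r}; known: {sorted(_ENVELOPES)}")
    return dict(_ENVELOPES[movement])
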
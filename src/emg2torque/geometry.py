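"""Joint geometry: musculotendon length polynomials, moment arms, torque.

The musculotendon length of each muscle is approximated, per degree of
freedom, by a cubic polynomial of the joint angle,

    lmt(theta) = mu0 + mu1*theta + mu2*theta**2 + mu3*theta**3,

and the moment arm is its exact derivative

    r(theta) = mu1 + 2*mu2*theta + 3*mu3*theta**2.

Torque-direction signs are absorbed into the coefficients: with theta = 0 at
the neutral anatomical position and positive theta meaning dorsiflexion /
inversion / internal rotation, a muscle whose moment arm is positive
produces positive torque.  Joint torque is the sum over muscles of moment
arm times tendon force.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .exceptions import ConfigurationError, InvalidParameterError

log = logging.getLogger(__name__)

__all__ = [
    "GeometryPoly",
    "LoadCellConfig",
    "mtu_length",
    "moment_arm",
    "joint_torque",
    "loadcell_torque",
]


@dataclass(frozen=True)
class GeometryPoly:
    """Cubic musculotendon-length polynomial for one (muscle, DOF) pair.

    Coefficients are in m, m/rad, m/rad^2 and m/rad^3.  ``rom_deg`` declares
    the range of motion over which the polynomial is trusted; construction
    verifies lmt > 0 and |moment arm| <= 0.15 m over that range.
    """

    muscle: str
    dof: str
    mu0: float
    mu1: float
    mu2: float = 0.0
    mu3: float = 0.0
    rom_deg: tuple[float, float] = (-45.0, 45.0)

    def __post_init__(self) -> None:
        lo, hi = self.rom_deg
        if not lo < hi:
            raise InvalidParameterError(f"rom_deg must be an increasing pair; got {self.rom_deg}")
        theta = np.radians(np.linspace(lo, hi, 101))
        lmt = mtu_length(theta, self, warn=False)
        if (lmt <= 0).any():
            raise ConfigurationError(
                f"lmt polynomial for ({self.muscle}, {self.dof}) is non-positive inside the ROM"
            )
        r = moment_arm(theta, self)
        if (np.abs(r) > 0.15).any():
            raise ConfigurationError(
                f"moment arm for ({self.muscle}, {self.dof}) exceeds 0.15 m inside the ROM"
            )

    @property
    def rom_rad(self) -> tuple[float, float]:
        return (math.radians(self.rom_deg[0]), math.radians(self.rom_deg[1]))


def mtu_length(theta, g: GeometryPoly, warn: bool = True):
    """Musculotendon length at joint angle theta (rad).

    Angles outside the declared ROM are still evaluated but trigger a warning.
    """
    th = np.asarray(theta, dtype=float)
    if warn:
        lo, hi = g.rom_rad
        n_out = int(((th < lo) | (th > hi)).sum())
        if n_out:
            log.warning(
                "mtu_length: %d angles outside the declared ROM of (%s, %s)",
                n_out,
                g.muscle,
                g.dof,
            )
    out = g.mu0 + th * (g.mu1 + th * (g.mu2 + th * g.mu3))
    return out if out.ndim else float(out)


def moment_arm(theta, g: GeometryPoly):
    """Moment arm r(theta) = d lmt / d theta (m); sign encodes torque direction."""
    th = np.asarray(theta, dtype=float)
    out = g.mu1 + th * (2.0 * g.mu2 + 3.0 * g.mu3 * th)
    return out if out.ndim else float(out)


def joint_torque(
    fiber_forces: Mapping[str, np.ndarray],
    geoms: Mapping[str, GeometryPoly],
    theta: np.ndarray,
) -> np.ndarray:
    """Joint torque M(theta, t) = sum_i r_i(theta) * F_i(t), N*m.

    ``fiber_forces`` maps muscle label to its tendon-force series; every
    supplied muscle must have a geometry entry.
    """
    theta = np.asarray(theta, dtype=float)
    torque = np.zeros_like(theta)
    for name, force in fiber_forces.items():
        if name not in geoms:
            raise ConfigurationError(f"no geometry supplied for muscle {name!r}")
        force = np.asarray(force, dtype=float)
        if force.shape != theta.shape:
            raise ConfigurationError(
                f"force series for {name!r} has shape {force.shape}, expected {theta.shape}"
            )
        torque = torque + moment_arm(theta, geoms[name]) * force
    return torque


@dataclass(frozen=True)
class LoadCellConfig:
    """Lever arms (m) converting the bench's three load-cell forces to torques."""

    l1: float = 0.050
    l2: float = 0.200
    l3: float = 0.040

    def __post_init__(self) -> None:
        if min(self.l1, self.l2, self.l3) <= 0:
            raise InvalidParameterError("all load-cell lever arms must be positive")

    @property
    def arms(self) -> tuple[float, float, float]:
        return (self.l1, self.l2, self.l3)


def loadcell_torque(forces, cfg: LoadCellConfig = LoadCellConfig()):
    """Per-channel torque T_i = F_i * l_i for the three load-cell channels.

    ``forces`` is a sequence of three force series (N); returns a list of
    three torque series (N*m).
    """
    if len(forces) != 3:
        raise InvalidParameterError("expected exactly three force channels")
    out = []
    for f, arm in zip(forces, cfg.arms):
        f = np.asarray(f, dtype=float)
        if not np.isfinite(f).all():
            raise InvalidParameterError("load-cell forces must be finite")
        out.append(f * arm)
    return out
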
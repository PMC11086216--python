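"""Hill-type muscle-tendon unit mechanics.

A muscle-tendon unit (MTU) of total length ``lmt`` is modelled as a fiber of
length ``lm`` (contractile element + parallel elastic element) in series with
a tendon of length ``lt``, at pennation angle ``phi``:

    lt = lmt - lm * cos(phi)
    Ft = (FAm + FPm) * cos(phi)                 (series force balance)
    FAm = fA(l) * fv(v) * a * F0m               (active fiber force)
    FPm = fP(l) * F0m                           (passive fiber force)

with normalized fiber length ``l`` (relative to the activation-dependent
optimal length) and normalized velocity ``v = vm / v0m``.  The normalized
curves are:

* active force-length: quadratic ``q0 + q1*l + q2*l**2`` on [0.5, 1.5], 0
  outside;
* passive force-length: ``exp(10*l - 15)``;
* force-velocity: Hill hyperbola, ``0.3*(v+1)/(0.3-v)`` for shortening
  (v < 0) and ``(2.34*v + 0.039)/(1.3*v + 0.039)`` for lengthening, continuous
  with value 1 at v = 0 and bounded by the eccentric asymptote 2.34/1.3 = 1.8;
* tendon force-strain: zero for slack, quadratic toe region
  ``1480.3 * eps**2`` for 0 < eps < 0.0127, linear ``37.5*eps - 0.24`` beyond.

At every time step the tendon force (from ``lt``) and the fiber curves (from
``lm`` and the activation) determine the required force-velocity value; its
closed-form inverse yields the fiber velocity, which is integrated forward
with classic 4th-order Runge-Kutta to advance ``lm``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    GeometryError,
    IntegrationError,
    InvalidInputError,
    InvalidParameterError,
)

log = logging.getLogger(__name__)

__all__ = [
    "MuscleParams",
    "ModelConstants",
    "FiberStateSeries",
    "FV_ECCENTRIC_ASYMPTOTE",
    "FV_CAP",
    "active_force_length",
    "passive_force_length",
    "force_velocity",
    "invert_force_velocity",
    "tendon_strain",
    "tendon_force",
    "pennation_angle",
    "tendon_length",
    "effective_optimal_length",
    "fiber_velocity",
    "integrate_fiber_length",
]

#: Supremum of the force-velocity curve (lengthening limit).
FV_ECCENTRIC_ASYMPTOTE = 2.34 / 1.3

#: Force-velocity value at v_norm = +1; fiber velocities are confined to
#: [-v0m, +v0m] by clamping fv into [0, FV_CAP] before inversion.
FV_CAP = (2.34 + 0.039) / (1.3 + 0.039)

#: Relative fiber-length bounds outside which integration aborts.
LM_REL_BOUNDS = (0.25, 2.5)


@dataclass(frozen=True)
class MuscleParams:
    """Physiological constants of one muscle.

    Parameters
    ----------
    name : str
        Muscle label (e.g. ``"ta"`` for tibialis anterior).
    F0m : float
        Maximum isometric fiber force, N.
    l0m : float
        Optimal fiber length, m.
    lst : float
        Tendon slack (relaxation) length, m.
    phi0_deg : float
        Pennation angle at optimal fiber length, degrees (0-45).
    v0m : float, optional
        Maximum contraction velocity, m/s.  Defaults to ``10 * l0m`` per
        second, the standard musculoskeletal convention.
    """

    name: str
    F0m: float
    l0m: float
    lst: float
    phi0_deg: float
    v0m: float | None = None

    def __post_init__(self) -> None:
        if self.v0m is None:
            object.__setattr__(self, "v0m", 10.0 * self.l0m)
        for attr in ("F0m", "l0m", "lst", "v0m"):
            if getattr(self, attr) <= 0:
                raise InvalidParameterError(
                    f"{self.name}: {attr} must be strictly positive; got {getattr(self, attr)}"
                )
        if not 0.0 <= self.phi0_deg <= 45.0:
            raise InvalidParameterError(
                f"{self.name}: phi0_deg must lie in [0, 45]; got {self.phi0_deg}"
            )

    @property
    def phi0(self) -> float:
        """Pennation angle at optimal fiber length, radians."""
        return math.radians(self.phi0_deg)


@dataclass(frozen=True)
class ModelConstants:
    """Shared curve constants of the Hill model.

    lambda_pct is the fractional widening of the optimal fiber length at zero
    activation; (q0, q1, q2) the active force-length quadratic; eps_knee the
    tendon-strain breakpoint between the quadratic toe region and the linear
    region with slope k_lin and intercept -c_lin.
    """

    lambda_pct: float = 0.15
    q0: float = -2.06
    q1: float = 6.16
    q2: float = -3.13
    eps_knee: float = 0.0127
    k_quad: float = 1480.3
    k_lin: float = 37.5
    c_lin: float = 0.24

    def __post_init__(self) -> None:
        # the quadratic must be nonnegative over its support [0.5, 1.5]
        pts = [0.5, 1.5]
        if self.q2 != 0:
            vertex = -self.q1 / (2.0 * self.q2)
            if 0.5 < vertex < 1.5:
                pts.append(vertex)
        vals = [self.q0 + self.q1 * l + self.q2 * l * l for l in pts]
        if min(vals) < 0:
            raise ConfigurationError(
                "active force-length quadratic is negative on [0.5, 1.5]: "
                f"min {min(vals):.4f}"
            )
        if not 0 < self.eps_knee < 1:
            raise ConfigurationError(f"eps_knee must be in (0, 1); got {self.eps_knee}")


# ---------------------------------------------------------------------------
# normalized curves
# ---------------------------------------------------------------------------

def active_force_length(l_norm, c: ModelConstants = ModelConstants()):
    """Normalized active force-length curve: quadratic on [0.5, 1.5], 0 outside."""
    l = np.asarray(l_norm, dtype=float)
    quad = c.q0 + c.q1 * l + c.q2 * l * l
    out = np.where((l >= 0.5) & (l <= 1.5), quad, 0.0)
    return out if out.ndim else float(out)


def passive_force_length(l_norm):
    """Normalized passive force-length curve exp(10*l - 15); positive, increasing."""
    l = np.asarray(l_norm, dtype=float)
    out = np.exp(10.0 * l - 15.0)
    return out if out.ndim else float(out)


def force_velocity(v_norm):
    """Normalized force-velocity curve.

    Shortening branch (v < 0): 0.3*(v+1)/(0.3-v), zero at v = -1.
    Lengthening branch (v >= 0): (2.34*v + 0.039)/(1.3*v + 0.039), asymptote 1.8.
    Inputs below -1 are clamped to -1 with a warning.
    """
    v = np.asarray(v_norm, dtype=float)
    n_below = int((v < -1.0).sum())
    if n_below:
        log.warning("force_velocity clamped %d values below v_norm = -1", n_below)
        v = np.maximum(v, -1.0)
    conc = 0.3 * (v + 1.0) / (0.3 - v)
    ecc = (2.34 * v + 0.039) / (1.3 * v + 0.039)
    out = np.where(v < 0.0, conc, ecc)
    return out if out.ndim else float(out)


def invert_force_velocity(fv):
    """Closed-form inverse of :func:`force_velocity`.

    Each branch is a Moebius function; solving for v gives

        v = 0.3*(fv - 1) / (fv + 0.3)          for fv in [0, 1)   (shortening)
        v = 0.039*(fv - 1) / (2.34 - 1.3*fv)   for fv in [1, 1.8) (lengthening)

    Inputs are clamped into [0, 1.8 - 1e-6]; clamping is logged.
    """
    f = np.asarray(fv, dtype=float)
    lo, hi = 0.0, FV_ECCENTRIC_ASYMPTOTE - 1e-6
    n_out = int(((f < lo) | (f > hi)).sum())
    if n_out:
        log.warning("invert_force_velocity clamped %d values into [0, 1.8)", n_out)
    f = np.clip(f, lo, hi)
    conc = 0.3 * (f - 1.0) / (f + 0.3)
    ecc = 0.039 * (f - 1.0) / (2.34 - 1.3 * f)
    out = np.where(f < 1.0, conc, ecc)
    return out if out.ndim else float(out)


def tendon_strain(lt, mp: MuscleParams):
    """Tendon strain eps = (lt - lst) / lst (sign kept for diagnostics)."""
    lt = np.asarray(lt, dtype=float)
    out = (lt - mp.lst) / mp.lst
    return out if out.ndim else float(out)


def tendon_force(lt, mp: MuscleParams, c: ModelConstants = ModelConstants()):
    """Tendon force in N: slack below lst, quadratic toe, then linear region."""
    eps = np.asarray(tendon_strain(lt, mp), dtype=float)
    quad = c.k_quad * eps * eps
    lin = c.k_lin * eps - c.c_lin
    f_norm = np.where(eps <= 0.0, 0.0, np.where(eps < c.eps_knee, quad, lin))
    out = mp.F0m * f_norm
    return out if out.ndim else float(out)


def pennation_angle(lm, mp: MuscleParams):
    """Pennation angle phi = asin(l0m * sin(phi0) / lm), radians.

    The constant-thickness assumption keeps ``lm * sin(phi)`` fixed.  If the
    fiber is shorter than that fixed height the argument exceeds 1 and phi is
    clamped to pi/2 with a warning.
    """
    lm = np.asarray(lm, dtype=float)
    if (lm <= 0).any():
        raise InvalidParameterError("fiber length must be strictly positive")
    arg = mp.l0m * math.sin(mp.phi0) / lm
    n_over = int((arg > 1.0).sum())
    if n_over:
        log.warning(
            "pennation_angle: %d fiber lengths below the fixed-height limit "
            "for %s; clamping to pi/2",
            n_over,
            mp.name,
        )
    out = np.arcsin(np.clip(arg, 0.0, 1.0))
    return out if out.ndim else float(out)


def tendon_length(lmt, lm, phi):
    """Series decomposition lt = lmt - lm * cos(phi).

    Raises :class:`GeometryError` if the result is negative (fiber projection
    longer than the whole unit).
    """
    lmt = np.asarray(lmt, dtype=float)
    lt = lmt - np.asarray(lm, dtype=float) * np.cos(phi)
    if (np.asarray(lt) < 0).any():
        raise GeometryError("negative tendon length: lm * cos(phi) exceeds lmt")
    return lt if lt.ndim else float(lt)


def effective_optimal_length(a, mp: MuscleParams, c: ModelConstants = ModelConstants()):
    """Activation-dependent optimal fiber length l0m * (lambda*(1-a) + 1).

    Sub-maximally activated muscle develops peak force at a longer fiber
    length; at a = 1 this reduces to l0m, at a = 0 to (1 + lambda) * l0m.
    """
    a = np.asarray(a, dtype=float)
    out = mp.l0m * (c.lambda_pct * (1.0 - a) + 1.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# fiber-state solution
# ---------------------------------------------------------------------------

def fiber_velocity(
    lm: float,
    a: float,
    lmt: float,
    mp: MuscleParams,
    c: ModelConstants = ModelConstants(),
    a_min: float = 0.01,
    eps_den: float = 1e-6,
    use_effective_l0m: bool = True,
    full_output: bool = False,
):
    """Solve the force balance for the instantaneous fiber velocity vm (m/s).

    The tendon force implied by the current geometry must equal the fiber
    force projected through the pennation angle; dividing out the known
    length-dependent terms leaves the required force-velocity value

        fv = (Ft - fP(l) * F0m * cos(phi)) / (fA(l) * a * F0m * cos(phi))

    which is mapped to vm through the closed-form inverse.  fv is clamped
    into the invertible window [0, FV_CAP] (|vm| <= v0m); the activation is
    floored at ``a_min`` and the denominator at ``eps_den * F0m * cos(phi)``
    so that near-zero activation produces bounded, damped shortening instead
    of a division blow-up.
    """
    a_eff = max(float(a), a_min)
    l0_eff = effective_optimal_length(a_eff, mp, c) if use_effective_l0m else mp.l0m
    l = lm / l0_eff
    sin_phi = min(mp.l0m * math.sin(mp.phi0) / lm, 1.0)
    cos_phi = max(math.sqrt(max(1.0 - sin_phi * sin_phi, 0.0)), 1e-6)
    lt = lmt - lm * cos_phi
    ft_norm = tendon_force(lt, mp, c) / mp.F0m  # normalized tendon force
    fa = active_force_length(l, c)
    fp = passive_force_length(l)
    num = ft_norm / cos_phi - fp
    den = fa * a_eff
    clamped = False
    if den < eps_den:
        den = eps_den
        clamped = True
    fv = num / den
    if fv < 0.0:
        fv, clamped = 0.0, True
    elif fv > FV_CAP:
        fv, clamped = FV_CAP, True
    vm = mp.v0m * invert_force_velocity(fv)
    if full_output:
        return vm, {
            "fv": fv,
            "clamped": clamped,
            "l_norm": l,
            "phi": math.asin(sin_phi),
            "lt": lt,
            "Ft": ft_norm * mp.F0m,
            "FAm": fa * fv * a_eff * mp.F0m,
            "FPm": fp * mp.F0m,
        }
    return vm


@dataclass
class FiberStateSeries:
    """Time series of the fiber state produced by the integrator.

    Velocities are negative during shortening.  ``Ft`` is the tendon force,
    which equals the whole-unit force; ``clamp_count`` counts time steps at
    which the force-velocity value had to be clamped (numerical-health
    indicator).
    """

    t: np.ndarray
    lm: np.ndarray
    vm: np.ndarray
    phi: np.ndarray
    FAm: np.ndarray
    FPm: np.ndarray
    Ft: np.ndarray
    muscle: str = ""
    clamp_count: int = 0
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "lm": self.lm,
                "vm": self.vm,
                "phi_deg": np.degrees(self.phi),
                "FAm": self.FAm,
                "FPm": self.FPm,
                "Ft": self.Ft,
            }
        )


def _integrate_python(a, lmt, dt, mp, c, lm0, a_min, use_effective_l0m):
    """Reference RK4 loop in plain Python (slow; used for cross-checking)."""
    n = a.size
    lm = np.empty(n)
    lm[0] = lm0
    lo, hi = LM_REL_BOUNDS[0] * mp.l0m, LM_REL_BOUNDS[1] * mp.l0m

    def rhs(lm_i, a_i, lmt_i):
        return fiber_velocity(
            lm_i, a_i, lmt_i, mp, c, a_min=a_min, use_effective_l0m=use_effective_l0m
        )

    for i in range(n - 1):
        if not lo < lm[i] < hi:
            return lm, i
        a_h = 0.5 * (a[i] + a[i + 1])
        lmt_h = 0.5 * (lmt[i] + lmt[i + 1])
        k1 = rhs(lm[i], a[i], lmt[i])
        k2 = rhs(lm[i] + 0.5 * dt * k1, a_h, lmt_h)
        k3 = rhs(lm[i] + 0.5 * dt * k2, a_h, lmt_h)
        k4 = rhs(lm[i] + dt * k3, a[i + 1], lmt[i + 1])
        lm[i + 1] = lm[i] + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if not lo < lm[n - 1] < hi:
        return lm, n - 1
    return lm, -1


def integrate_fiber_length(
    a: np.ndarray,
    lmt: np.ndarray,
    dt: float,
    mp: MuscleParams,
    c: ModelConstants = ModelConstants(),
    lm0: float | None = None,
    a_min: float = 0.01,
    use_effective_l0m: bool = True,
    engine: str = "numba",
) -> FiberStateSeries:
    """Integrate dlm/dt = vm with classic 4th-order Runge-Kutta.

    Parameters
    ----------
    a, lmt : ndarray
        Activation and MTU length on one uniform time base (values at the
        half-steps are obtained by linear interpolation).
    dt : float
        Sampling interval, s (also the integration step).
    lm0 : float, optional
        Initial fiber length; defaults to the optimal fiber length l0m.
    engine : {"numba", "python"}
        Compiled kernel (default) or the pure-Python reference loop.

    Raises
    ------
    IntegrationError
        If the fiber length leaves (0.25, 2.5) * l0m; the message names the
        muscle and the first offending step.
    """
    a = np.ascontiguousarray(a, dtype=float)
    lmt = np.ascontiguousarray(lmt, dtype=float)
    if a.shape != lmt.shape or a.ndim != 1:
        raise InvalidInputError("a and lmt must be 1-D arrays of equal length")
    if a.size < 2:
        raise InvalidInputError("need at least two samples to integrate")
    if dt <= 0:
        raise InvalidParameterError(f"dt must be positive; got {dt}")
    if lm0 is None:
        lm0 = mp.l0m

    if engine == "numba":
        from ._kernel import simulate_muscle

        lm, vm, phi, fam, fpm, ft, n_clamp, bad = simulate_muscle(
            a,
            lmt,
            float(dt),
            mp.F0m,
            mp.l0m,
            mp.lst,
            math.sin(mp.phi0),
            mp.v0m,
            c.lambda_pct,
            c.q0,
            c.q1,
            c.q2,
            c.eps_knee,
            c.k_quad,
            c.k_lin,
            c.c_lin,
            float(lm0),
            a_min,
            1 if use_effective_l0m else 0,
        )
        if bad >= 0:
            raise IntegrationError(
                f"fiber length of muscle {mp.name!r} left "
                f"({LM_REL_BOUNDS[0]}, {LM_REL_BOUNDS[1]}) * l0m at step {bad} "
                f"(lm = {lm[bad]:.4g} m)",
                muscle=mp.name,
                step=int(bad),
            )
        t = np.arange(a.size) * dt
        return FiberStateSeries(
            t, lm, vm, phi, fam, fpm, ft, muscle=mp.name, clamp_count=int(n_clamp)
        )

    if engine != "python":
        raise InvalidParameterError(f"unknown engine {engine!r}")

    lm, bad = _integrate_python(a, lmt, dt, mp, c, lm0, a_min, use_effective_l0m)
    if bad >= 0:
        raise IntegrationError(
            f"fiber length of muscle {mp.name!r} left "
            f"({LM_REL_BOUNDS[0]}, {LM_REL_BOUNDS[1]}) * l0m at step {bad} "
            f"(lm = {lm[bad]:.4g} m)",
            muscle=mp.name,
            step=int(bad),
        )
    n = a.size
    vm = np.empty(n)
    phi = np.empty(n)
    fam = np.empty(n)
    fpm = np.empty(n)
    ft = np.empty(n)
    n_clamp = 0
    for i in range(n):
        v, info = fiber_velocity(
            lm[i],
            a[i],
            lmt[i],
            mp,
            c,
            a_min=a_min,
            use_effective_l0m=use_effective_l0m,
            full_output=True,
        )
        vm[i] = v
        phi[i] = info["phi"]
        fam[i] = info["FAm"]
        fpm[i] = info["FPm"]
        ft[i] = info["Ft"]
        n_clamp += info["clamped"]
    t = np.arange(n) * dt
    return FiberStateSeries(
        t, lm, vm, phi, fam, fpm, ft, muscle=mp.name, clamp_count=n_clamp
    )
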
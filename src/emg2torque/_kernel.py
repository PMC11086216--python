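"""Compiled inner loop of the fiber-length integration.

Scalar re-implementation of the muscle-tendon curves plus the classic RK4
driver, jitted with numba.  The public, vectorized versions of the same
formulas live in :mod:`emg2torque.hill`; the test suite asserts that both
code paths agree, and the ``engine="python"`` reference integrator provides
an independent route through the same model.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_FV_CAP = (2.34 + 0.039) / (1.3 + 0.039)
_EPS_DEN = 1e-6


@njit(cache=True)
def _fiber_velocity_scalar(
    lm,
    a,
    lmt,
    F0m,
    l0m,
    lst,
    sin_phi0,
    v0m,
    lam,
    q0,
    q1,
    q2,
    eps_knee,
    k_quad,
    k_lin,
    c_lin,
    a_min,
    use_eff,
):
    """Return (vm, fv_used, sin_phi, ft_norm, fa, fp, clamped)."""
    a_eff = a if a > a_min else a_min
    if use_eff == 1:
        l0_eff = l0m * (lam * (1.0 - a_eff) + 1.0)
    else:
        l0_eff = l0m
    l = lm / l0_eff

    sin_phi = sin_phi0 * l0m / lm
    if sin_phi > 1.0:
        sin_phi = 1.0
    cos_phi = math.sqrt(max(1.0 - sin_phi * sin_phi, 0.0))
    if cos_phi < 1e-6:
        cos_phi = 1e-6

    lt = lmt - lm * cos_phi
    eps = (lt - lst) / lst
    if eps <= 0.0:
        ft_norm = 0.0
    elif eps < eps_knee:
        ft_norm = k_quad * eps * eps
    else:
        ft_norm = k_lin * eps - c_lin

    if 0.5 <= l <= 1.5:
        fa = q0 + q1 * l + q2 * l * l
    else:
        fa = 0.0
    fp = math.exp(10.0 * l - 15.0)

    num = ft_norm / cos_phi - fp
    den = fa * a_eff
    clamped = 0
    if den < _EPS_DEN:
        den = _EPS_DEN
        clamped = 1
    fv = num / den
    if fv < 0.0:
        fv = 0.0
        clamped = 1
    elif fv > _FV_CAP:
        fv = _FV_CAP
        clamped = 1

    if fv < 1.0:
        v_norm = 0.3 * (fv - 1.0) / (fv + 0.3)
    else:
        v_norm = 0.039 * (fv - 1.0) / (2.34 - 1.3 * fv)
    return v0m * v_norm, fv, sin_phi, ft_norm, fa, fp, clamped


@njit(cache=True)
def simulate_muscle(
    a,
    lmt,
    dt,
    F0m,
    l0m,
    lst,
    sin_phi0,
    v0m,
    lam,
    q0,
    q1,
    q2,
    eps_knee,
    k_quad,
    k_lin,
    c_lin,
    lm0,
    a_min,
    use_eff,
):
    """RK4 integration of dlm/dt = vm over one trial for one muscle.

    Returns (lm, vm, phi, FAm, FPm, Ft, n_clamp, bad_index); bad_index is -1
    on success, else the first step at which lm left (0.25, 2.5) * l0m.
    """
    n = a.size
    lm = np.empty(n)
    vm = np.empty(n)
    phi = np.empty(n)
    fam = np.empty(n)
    fpm = np.empty(n)
    ft = np.empty(n)
    lm[0] = lm0
    lo = 0.25 * l0m
    hi = 2.5 * l0m
    n_clamp = 0
    bad = -1

    for i in range(n):
        if not (lo < lm[i] < hi):
            bad = i
            break
        v, fv, sphi, ftn, fa, fp, cl = _fiber_velocity_scalar(
            lm[i], a[i], lmt[i], F0m, l0m, lst, sin_phi0, v0m,
            lam, q0, q1, q2, eps_knee, k_quad, k_lin, c_lin, a_min, use_eff,
        )
        a_eff = a[i] if a[i] > a_min else a_min
        vm[i] = v
        phi[i] = math.asin(sphi)
        ft[i] = ftn * F0m
        fam[i] = fa * fv * a_eff * F0m
        fpm[i] = fp * F0m
        n_clamp += cl

        if i == n - 1:
            break
        a_h = 0.5 * (a[i] + a[i + 1])
        lmt_h = 0.5 * (lmt[i] + lmt[i + 1])
        k1 = v
        k2, _, _, _, _, _, _ = _fiber_velocity_scalar(
            lm[i] + 0.5 * dt * k1, a_h, lmt_h, F0m, l0m, lst, sin_phi0, v0m,
            lam, q0, q1, q2, eps_knee, k_quad, k_lin, c_lin, a_min, use_eff,
        )
        k3, _, _, _, _, _, _ = _fiber_velocity_scalar(
            lm[i] + 0.5 * dt * k2, a_h, lmt_h, F0m, l0m, lst, sin_phi0, v0m,
            lam, q0, q1, q2, eps_knee, k_quad, k_lin, c_lin, a_min, use_eff,
        )
        k4, _, _, _, _, _, _ = _fiber_velocity_scalar(
            lm[i] + dt * k3, a[i + 1], lmt[i + 1], F0m, l0m, lst, sin_phi0, v0m,
            lam, q0, q1, q2, eps_knee, k_quad, k_lin, c_lin, a_min, use_eff,
        )
        lm[i + 1] = lm[i] + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)

    return lm, vm, phi, fam, fpm, ft, n_clamp, bad
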
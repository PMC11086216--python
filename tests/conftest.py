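import numpy as np
import pytest
from hypothesis import settings

from emg2torque import defaults

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from emg2torque.activation import ActivationParams
from emg2torque.hill import ModelConstants, MuscleParams


@pytest.fixture
def act_params():
    return ActivationParams()


@pytest.fixture
def constants():
    return ModelConstants()


@pytest.fixture
def muscles():
    return defaults.default_muscle_params()


@pytest.fixture
def ta(muscles):
    return muscles["ta"]


@pytest.fixture
def geometry():
    return defaults.default_geometry()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def isometric_setup(mp: MuscleParams, c: ModelConstants, a: float = 0.5, l_norm: float = 1.05):
    """Construct (lm, lmt) at an exact isometric equilibrium (fv = 1).

    Chooses the fiber length at ``l_norm`` times the activation-scaled
    optimal length and solves the tendon curve for the total length at which
    the tendon force equals the isometric fiber capacity.
    """
    l0_eff = mp.l0m * (c.lambda_pct * (1.0 - a) + 1.0)
    lm = l_norm * l0_eff
    sin_phi = mp.l0m * np.sin(mp.phi0) / lm
    cos_phi = np.sqrt(1.0 - sin_phi**2)
    fa = c.q0 + c.q1 * l_norm + c.q2 * l_norm**2
    fp = np.exp(10.0 * l_norm - 15.0)
    ft_norm = (fa * a + fp) * cos_phi  # required normalized tendon force
    # invert the tendon curve for the strain
    if ft_norm < c.k_quad * c.eps_knee**2:
        eps = np.sqrt(ft_norm / c.k_quad)
    else:
        eps = (ft_norm + c.c_lin) / c.k_lin
    lt = mp.lst * (1.0 + eps)
    lmt = lt + lm * cos_phi
    return lm, lmt
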
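"""Genetic-algorithm calibration of the 16 physiological parameters.

Four parameters per muscle (F0m, l0m, lst, phi0) times four muscles are
optimized to minimize the summed squared mismatch between measured and
model-predicted joint torque over the calibration trials:

    min  sum_trials sum_t ( M_measured(t) - sum_i r_i(theta) * F_i(t) )**2

Each parameter is binary-coded over its bounds (linear quantization); the GA
uses roulette-wheel selection on rank-derived weights (scale-free selection
pressure over a minimization objective), single-point crossover, low-rate
per-parameter mutation, and elitist carry-over of the best individual, so
the best-so-far objective trace is nonincreasing.  Bounds are half-widths
relative to the initial anatomical values: +/-50% for F0m, l0m and phi0,
+/-15% for the tendon slack length.

Forward-model quantities that do not depend on the calibrated parameters
(activations, musculotendon lengths, moment arms) are precomputed once per
trial, so each objective evaluation only reruns the fiber integration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import defaults
from ._kernel import simulate_muscle
from .activation import activation_from_emg
from .exceptions import ConfigurationError, InvalidParameterError
from .geometry import moment_arm, mtu_length
from .hill import MuscleParams
from .pipeline import ModelConfig, default_model_config, rmse

log = logging.getLogger(__name__)

__all__ = [
    "PARAM_FIELDS",
    "ParameterBounds",
    "GAConfig",
    "CalibrationResult",
    "params_to_vector",
    "encode",
    "decode",
    "objective",
    "run_ga",
]


def params_to_vector(
    muscles: Mapping[str, "MuscleParams"],
    order: tuple[str, ...] = defaults.MUSCLES,
) -> np.ndarray:
    """Flatten a muscle parameter set into the 16-vector (muscle-major)."""
    return np.array(
        [getattr(muscles[m], f) for m in order for f in PARAM_FIELDS], dtype=float
    )

#: Calibrated fields per muscle, in vector order.
PARAM_FIELDS = ("F0m", "l0m", "lst", "phi0_deg")

#: Penalty objective assigned when the forward model aborts for a candidate.
PENALTY = 1e12


@dataclass(frozen=True)
class ParameterBounds:
    """Initial value and [lower, upper] bounds of each of the 16 parameters.

    Vector order is muscle-major: for each muscle in ``muscle_order`` the
    four fields of :data:`PARAM_FIELDS`.
    """

    muscle_order: tuple[str, ...]
    initial: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        if not (self.lower < self.initial).all() or not (self.initial < self.upper).all():
            raise ConfigurationError("bounds must satisfy lower < initial < upper")

    @classmethod
    def from_initial(
        cls,
        muscles: Mapping[str, MuscleParams] | None = None,
        fractions: Mapping[str, float] | None = None,
    ) -> "ParameterBounds":
        if muscles is None:
            muscles = defaults.default_muscle_params()
        if fractions is None:
            fractions = defaults.BOUND_FRACTIONS
        order = tuple(muscles)
        init, lo, hi = [], [], []
        for m in order:
            p = muscles[m]
            for f in PARAM_FIELDS:
                v = getattr(p, f)
                frac = fractions[f]
                init.append(v)
                lo.append(v * (1.0 - frac))
                hi.append(v * (1.0 + frac))
        return cls(order, np.array(init), np.array(lo), np.array(hi))

    @property
    def n_params(self) -> int:
        return self.initial.size

    def names(self) -> list[tuple[str, str]]:
        return [(m, f) for m in self.muscle_order for f in PARAM_FIELDS]

    def clip(self, vec: np.ndarray) -> np.ndarray:
        clipped = np.clip(vec, self.lower, self.upper)
        if not np.array_equal(clipped, vec):
            log.warning("parameter vector clipped into bounds before encoding")
        return clipped

    def contains(self, vec: np.ndarray) -> bool:
        return bool((vec >= self.lower).all() and (vec <= self.upper).all())

    def to_muscles(
        self, vec: np.ndarray, base: Mapping[str, MuscleParams] | None = None
    ) -> dict[str, MuscleParams]:
        """Expand a 16-vector into MuscleParams (v0m taken from ``base``)."""
        if base is None:
            base = defaults.default_muscle_params()
        out = {}
        for i, m in enumerate(self.muscle_order):
            F0m, l0m, lst, phi0 = vec[4 * i : 4 * i + 4]
            out[m] = MuscleParams(
                name=m, F0m=F0m, l0m=l0m, lst=lst, phi0_deg=phi0, v0m=base[m].v0m
            )
        return out


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    The study-scale defaults are population 100 / 150 generations; the
    reduced scale used throughout the tests is population 40 / 60
    generations.  Mutation fires with probability ``mutation_prob`` and
    flips one random bit; the default ``"per_param"`` mode draws that event
    independently for every parameter block (keeping exploration alive as
    the population converges), ``"individual"`` draws it once per
    individual, and ``"bitwise"`` flips every bit independently with
    ``mutation_prob``.
    """

    population: int = 100
    generations: int = 150
    crossover_prob: float = 0.6
    mutation_prob: float = 0.1
    bits_per_param: int = 12
    mutation_mode: str = "per_param"
    seed: int = 0
    max_infeasible_generations: int = 5

    def __post_init__(self) -> None:
        if self.population < 2:
            raise InvalidParameterError("population must be >= 2")
        if self.generations < 1:
            raise InvalidParameterError("generations must be >= 1")
        if self.bits_per_param < 8:
            raise InvalidParameterError("bits_per_param must be >= 8")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError("probabilities must lie in [0, 1]")
        if self.mutation_mode not in ("per_param", "individual", "bitwise"):
            raise InvalidParameterError(
                "mutation_mode must be 'per_param', 'individual' or 'bitwise'"
            )


# ---------------------------------------------------------------------------
# binary coding
# ---------------------------------------------------------------------------

def encode(vec: np.ndarray, bounds: ParameterBounds, bits_per_param: int = 16) -> np.ndarray:
    """Linear quantization of each parameter into ``bits_per_param`` bits.

    The lower bound maps to the all-zero codeword, the upper bound to
    all-ones.  Out-of-bounds values are clipped (logged).  Returns a flat
    uint8 0/1 array of length ``16 * bits_per_param``, most significant bit
    first within each parameter block.
    """
    vec = bounds.clip(np.asarray(vec, dtype=float))
    levels = (1 << bits_per_param) - 1
    frac = (vec - bounds.lower) / (bounds.upper - bounds.lower)
    codes = np.rint(frac * levels).astype(np.int64)
    shifts = np.arange(bits_per_param - 1, -1, -1)
    bits = (codes[:, None] >> shifts[None, :]) & 1
    return bits.astype(np.uint8).ravel()


def decode(bits: np.ndarray, bounds: ParameterBounds, bits_per_param: int = 16) -> np.ndarray:
    """Inverse of :func:`encode`; decoded values always lie inside bounds."""
    bits = np.asarray(bits, dtype=np.int64).reshape(bounds.n_params, bits_per_param)
    shifts = np.arange(bits_per_param - 1, -1, -1)
    codes = (bits << shifts[None, :]).sum(axis=1)
    levels = (1 << bits_per_param) - 1
    return bounds.lower + codes / levels * (bounds.upper - bounds.lower)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

@dataclass
class TrialFeatures:
    """Parameter-independent per-trial quantities for fast objective evaluation."""

    movement: str
    a: np.ndarray  # (n_muscles, T) activations
    lmt: np.ndarray  # (n_muscles, T) musculotendon lengths
    r: np.ndarray  # (n_muscles, T) moment arms
    torque: np.ndarray  # (T,) measured torque
    dt: float


def precompute_features(
    trials: Sequence,
    config: ModelConfig,
    muscle_order: tuple[str, ...] = defaults.MUSCLES,
) -> list[TrialFeatures]:
    feats = []
    for trial in trials:
        act_p = config.activation_at(trial.sample_rate)
        geoms = config.geometry[trial.dof]
        a = np.stack([activation_from_emg(trial.emg[m], act_p) for m in muscle_order])
        lmt = np.stack([mtu_length(trial.theta, geoms[m], warn=False) for m in muscle_order])
        r = np.stack([moment_arm(trial.theta, geoms[m]) for m in muscle_order])
        feats.append(
            TrialFeatures(
                movement=getattr(trial, "movement", "?"),
                a=np.ascontiguousarray(a),
                lmt=np.ascontiguousarray(lmt),
                r=r,
                torque=np.asarray(trial.torque, dtype=float),
                dt=trial.dt,
            )
        )
    return feats


def _predict_features(
    vec: np.ndarray,
    feats: TrialFeatures,
    bounds: ParameterBounds,
    config: ModelConfig,
    v0m: np.ndarray,
) -> np.ndarray | None:
    """Forward torque for one trial at a candidate vector; None on abort."""
    c = config.constants
    use_eff = 1 if config.use_effective_l0m else 0
    pred = np.zeros_like(feats.torque)
    for i in range(len(bounds.muscle_order)):
        F0m, l0m, lst, phi0 = vec[4 * i : 4 * i + 4]
        lm, vm, phi, fam, fpm, ft, n_clamp, bad = simulate_muscle(
            feats.a[i],
            feats.lmt[i],
            feats.dt,
            F0m,
            l0m,
            lst,
            math.sin(math.radians(phi0)),
            v0m[i],
            c.lambda_pct,
            c.q0,
            c.q1,
            c.q2,
            c.eps_knee,
            c.k_quad,
            c.k_lin,
            c.c_lin,
            l0m,
            config.a_min,
            use_eff,
        )
        if bad >= 0:
            return None
        pred += feats.r[i] * ft
    return pred


def objective(
    vec: np.ndarray,
    trials: Sequence,
    config: ModelConfig | None = None,
    bounds: ParameterBounds | None = None,
    base: Mapping[str, MuscleParams] | None = None,
    _features: list[TrialFeatures] | None = None,
) -> float:
    """Summed squared torque mismatch over trials for a 16-parameter vector.

    A forward-model abort (fiber length out of range for the candidate)
    yields the large finite :data:`PENALTY` so the GA can continue.
    """
    if config is None:
        config = default_model_config()
    if bounds is None:
        bounds = ParameterBounds.from_initial(base)
    if base is None:
        base = defaults.default_muscle_params()
    feats = _features if _features is not None else precompute_features(trials, config, bounds.muscle_order)
    v0m = np.array([base[m].v0m for m in bounds.muscle_order])
    vec = np.asarray(vec, dtype=float)
    total = 0.0
    for f in feats:
        pred = _predict_features(vec, f, bounds, config, v0m)
        if pred is None:
            log.warning("objective: forward model aborted on trial %s; penalized", f.movement)
            return PENALTY
        d = f.torque - pred
        total += float(d @ d)
    return total


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Outcome of one GA calibration run."""

    best_vector: np.ndarray
    muscles: dict[str, MuscleParams]
    objective_trace: np.ndarray  # best-so-far objective per generation
    initial_objective: float  # best of the initial population
    rmse_per_trial: list[float]  # on the calibration trials, at the optimum
    seed: int
    n_evaluations: int
    bounds: ParameterBounds = field(repr=False, default=None)

    @property
    def best_objective(self) -> float:
        return float(self.objective_trace[-1])


def run_ga(
    trials: Sequence,
    bounds: ParameterBounds | None = None,
    ga: GAConfig | None = None,
    config: ModelConfig | None = None,
    base: Mapping[str, MuscleParams] | None = None,
) -> CalibrationResult:
    """Calibrate the 16 parameters on ``trials`` with the genetic algorithm.

    The initial population contains one individual encoding the initial
    (anatomical) parameter values — the benchmark the search starts from —
    and otherwise random codewords.  Raises ``RuntimeError`` if every
    individual is penalized for ``max_infeasible_generations`` consecutive
    generations.
    """
    if len(trials) == 0:
        raise InvalidParameterError("at least one calibration trial is required")
    if bounds is None:
        bounds = ParameterBounds.from_initial(base)
    if ga is None:
        ga = GAConfig()
    if config is None:
        config = default_model_config()
    if base is None:
        base = defaults.default_muscle_params()

    feats = precompute_features(trials, config, bounds.muscle_order)

    def f_obj(vec):
        return objective(vec, trials, config, bounds, base, _features=feats)

    rng = np.random.default_rng(ga.seed)
    n_bits = bounds.n_params * ga.bits_per_param
    pop = rng.integers(0, 2, size=(ga.population, n_bits), dtype=np.uint8)
    pop[0] = encode(bounds.initial, bounds, ga.bits_per_param)

    def evaluate_pop(p):
        return np.array(
            [f_obj(decode(ind, bounds, ga.bits_per_param)) for ind in p]
        )

    obj = evaluate_pop(pop)
    n_eval = ga.population
    best_idx = int(np.argmin(obj))
    best_bits = pop[best_idx].copy()
    best_obj = float(obj[best_idx])
    initial_best = best_obj
    trace = []
    infeasible_streak = 0

    # roulette weights from population rank: scale-free selection pressure
    # (weight ratio between adjacent ranks is constant), unlike raw
    # 1/(1+objective) whose pressure vanishes when the objective is large
    rank_base = 0.85

    for gen in range(ga.generations):
        order = np.argsort(np.argsort(obj))  # 0 = best
        fitness = rank_base**order
        probs = fitness / fitness.sum()
        parents = pop[rng.choice(ga.population, size=ga.population, p=probs)].copy()

        # single-point crossover on consecutive pairs
        for i in range(0, ga.population - 1, 2):
            if rng.random() < ga.crossover_prob:
                cut = int(rng.integers(1, n_bits))
                tail = parents[i, cut:].copy()
                parents[i, cut:] = parents[i + 1, cut:]
                parents[i + 1, cut:] = tail

        if ga.mutation_mode == "per_param":
            for i in range(ga.population):
                for k in range(bounds.n_params):
                    if rng.random() < ga.mutation_prob:
                        b = k * ga.bits_per_param + int(rng.integers(0, ga.bits_per_param))
                        parents[i, b] ^= 1
        elif ga.mutation_mode == "individual":
            for i in range(ga.population):
                if rng.random() < ga.mutation_prob:
                    b = int(rng.integers(0, n_bits))
                    parents[i, b] ^= 1
        else:
            mask = rng.random(size=parents.shape) < ga.mutation_prob
            parents[mask] ^= 1

        obj = evaluate_pop(parents)
        n_eval += ga.population

        if (obj >= PENALTY).all():
            infeasible_streak += 1
            if infeasible_streak >= ga.max_infeasible_generations:
                raise RuntimeError(
                    f"GA aborted: every individual penalized for "
                    f"{infeasible_streak} consecutive generations"
                )
        else:
            infeasible_streak = 0

        # elitism: the best-ever individual replaces the current worst
        gen_best = int(np.argmin(obj))
        if obj[gen_best] < best_obj:
            best_obj = float(obj[gen_best])
            best_bits = parents[gen_best].copy()
        else:
            worst = int(np.argmax(obj))
            parents[worst] = best_bits
            obj[worst] = best_obj
        pop = parents
        trace.append(best_obj)

    best_vec = decode(best_bits, bounds, ga.bits_per_param)
    muscles = bounds.to_muscles(best_vec, base)
    v0m = np.array([base[m].v0m for m in bounds.muscle_order])
    rmses = []
    for f in feats:
        pred = _predict_features(best_vec, f, bounds, config, v0m)
        rmses.append(rmse(pred, f.torque) if pred is not None else float("nan"))

    return CalibrationResult(
        best_vector=best_vec,
        muscles=muscles,
        objective_trace=np.array(trace),
        initial_objective=initial_best,
        rmse_per_trial=rmses,
        seed=ga.seed,
        n_evaluations=n_eval,
        bounds=bounds,
    )
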
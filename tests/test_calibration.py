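"""Binary coding, the torque-mismatch objective, and the genetic algorithm."""

import dataclasses

import numpy as np
import pytest

from emg2torque import defaults
from emg2torque.calibration import (
    GAConfig,
    PENALTY,
    ParameterBounds,
    decode,
    encode,
    objective,
    run_ga,
)
from emg2torque.geometry import GeometryPoly
from emg2torque.pipeline import ModelConfig
from emg2torque.synthetic import TrialSpec, draw_subject_params, generate_trial


def params_vector(muscles, order=defaults.MUSCLES):
    out = []
    for m in order:
        p = muscles[m]
        out += [p.F0m, p.l0m, p.lst, p.phi0_deg]
    return np.array(out)


@pytest.fixture(scope="module")
def bounds():
    return ParameterBounds.from_initial()


@pytest.fixture(scope="module")
def short_trials():
    """Two short noiseless trials at a drawn ground truth (500 Hz, 1.5 s)."""
    rng = np.random.default_rng(7)
    truth = draw_subject_params(rng)
    trials = []
    for i, movement in enumerate(("dorsiflexion", "plantarflexion")):
        spec = TrialSpec(
            movement=movement,
            duration=1.5,
            sample_rate=500.0,
            torque_noise=0.0,
            emg_noise=0.0,
            seed=100 + i,
        )
        trials.append(generate_trial(spec, truth))
    return trials, truth


class TestBinaryCoding:
    def test_bound_endpoints_map_to_extreme_codewords(self, bounds):
        bits_lo = encode(bounds.lower, bounds)
        bits_hi = encode(bounds.upper, bounds)
        assert not bits_lo.any()
        assert bits_hi.all()
        assert np.allclose(decode(bits_lo, bounds), bounds.lower)
        assert np.allclose(decode(bits_hi, bounds), bounds.upper)

    @pytest.mark.parametrize("bits_per_param", [8, 12, 16])
    def test_round_trip_within_one_quantization_step(self, bounds, rng, bits_per_param):
        step = (bounds.upper - bounds.lower) / (2**bits_per_param - 1)
        for _ in range(20):
            vec = rng.uniform(bounds.lower, bounds.upper)
            back = decode(encode(vec, bounds, bits_per_param), bounds, bits_per_param)
            assert np.all(np.abs(back - vec) <= step + 1e-12)

    def test_midpoint_decodes_from_half_range_codeword(self, bounds):
        mid = 0.5 * (bounds.lower + bounds.upper)
        step = (bounds.upper - bounds.lower) / (2**16 - 1)
        back = decode(encode(mid, bounds), bounds)
        assert np.all(np.abs(back - mid) <= step)

    def test_out_of_bounds_clipped_before_encoding(self, bounds):
        vec = bounds.upper * 1.5
        back = decode(encode(vec, bounds), bounds)
        assert np.allclose(back, bounds.upper)

    def test_decoded_vectors_always_in_bounds(self, bounds, rng):
        for _ in range(20):
            bits = rng.integers(0, 2, bounds.n_params * 16).astype(np.uint8)
            vec = decode(bits, bounds)
            assert bounds.contains(vec)

    def test_bounds_derived_from_initial_fractions(self, bounds):
        names = bounds.names()
        i = names.index(("ta", "F0m"))
        assert bounds.lower[i] == pytest.approx(635.0)
        assert bounds.upper[i] == pytest.approx(1905.0)
        j = names.index(("sol", "lst"))
        assert bounds.lower[j] == pytest.approx(0.268 * 0.85)
        assert bounds.upper[j] == pytest.approx(0.268 * 1.15)


class TestObjective:
    def test_zero_at_generating_parameters(self, short_trials, bounds):
        trials, truth = short_trials
        obj = objective(params_vector(truth), trials, bounds=bounds)
        scale = sum(float(t.torque @ t.torque) for t in trials)
        assert obj <= 1e-10 * scale

    def test_perturbing_any_parameter_increases_it(self, short_trials, bounds):
        trials, truth = short_trials
        vec = params_vector(truth)
        base = objective(vec, trials, bounds=bounds)
        for i in (0, 1, 3, 4):  # ta F0m, ta l0m, ta phi0, sol F0m
            for sign in (-1, 1):
                pert = vec.copy()
                pert[i] *= 1.0 + sign * 0.05
                assert objective(pert, trials, bounds=bounds) > base

    def test_invariant_to_trial_ordering(self, short_trials, bounds):
        trials, truth = short_trials
        vec = params_vector(truth) * 1.02
        assert objective(vec, trials, bounds=bounds) == pytest.approx(
            objective(vec, trials[::-1], bounds=bounds), rel=1e-12
        )


class TestGA:
    def test_trace_monotone_and_converges_from_two_seeds(self, short_trials):
        trials, _ = short_trials
        finals = []
        for seed in (11, 12):
            res = run_ga(trials, ga=GAConfig(population=40, generations=60, seed=seed))
            assert np.all(np.diff(res.objective_trace) <= 0)
            assert res.best_objective <= res.initial_objective
            assert res.bounds.contains(res.best_vector)
            # convergence sanity on an easy synthetic problem
            assert res.best_objective <= 0.10 * res.initial_objective
            finals.append(res.best_objective)
        assert finals[0] != finals[1]

    def test_single_free_parameter_recovered_within_two_steps(self, short_trials):
        """Degenerate problem: only ta F0m free; brute-force grid is the oracle."""
        trials, truth = short_trials
        vec = params_vector(truth)
        tiny = 1e-8
        lower = vec * (1.0 - tiny)
        upper = vec * (1.0 + tiny)
        i = 0  # ta F0m
        lower[i] = vec[i] * 0.5
        upper[i] = vec[i] * 1.5
        bounds = ParameterBounds.from_initial()
        bounds = dataclasses.replace(
            bounds, initial=vec * (1 + tiny / 2), lower=lower, upper=upper
        )
        bits = 10
        step = (upper[i] - lower[i]) / (2**bits - 1)

        # oracle: brute-force sweep of the free parameter over all code levels
        grid = lower[i] + np.arange(0, 2**bits, 8) / (2**bits - 1) * (upper[i] - lower[i])
        objs = []
        for val in grid:
            v = vec.copy()
            v[i] = val
            objs.append(objective(v, trials, bounds=bounds))
        grid_best = grid[int(np.argmin(objs))]
        assert abs(grid_best - vec[i]) <= 8 * step  # the oracle pins the optimum

        res = run_ga(
            trials,
            bounds=bounds,
            ga=GAConfig(population=20, generations=40, bits_per_param=bits, seed=3),
        )
        assert abs(res.best_vector[i] - vec[i]) <= 2 * step

    def test_all_infeasible_population_aborts(self, short_trials):
        trials, _ = short_trials
        # geometry so short that every candidate's fiber collapses -> penalty
        bad_geo = {
            dof: {
                m: GeometryPoly(muscle=m, dof=dof, mu0=0.05, mu1=0.001, rom_deg=(-60, 60))
                for m in defaults.MUSCLES
            }
            for dof in defaults.DOFS
        }
        cfg = ModelConfig(geometry=bad_geo)
        vec = params_vector(defaults.default_muscle_params())
        assert objective(vec, trials, config=cfg) == PENALTY
        with pytest.raises(RuntimeError, match="penalized"):
            run_ga(
                trials,
                ga=GAConfig(population=8, generations=10, seed=1),
                config=cfg,
            )
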
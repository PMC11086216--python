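# emg2torque

EMG-driven modelling of ankle joint torque for rehabilitation research.

Measuring ankle torque directly lags the movement; surface electromyography
(sEMG) leads it. `emg2torque` computes the torque the ankle produces during
dorsiflexion/plantarflexion, inversion and internal/external rotation from
four sEMG envelopes (tibialis anterior, soleus, medial and lateral
gastrocnemius) plus the joint angle — the signal chain a myoelectrically
controlled ankle-rehabilitation device needs. It is written for
biomechanics and rehabilitation-robotics researchers who want a tested,
fully synthetic-data-backed reference implementation of this pipeline.

## Model

Three stages, composed per muscle *i* and summed:

1. **Activation dynamics** — normalized envelope `e(t)` → neural activation
   `u(t) = α·e(t−d) − β1·u(t−1) − β2·u(t−2)` (electromechanical delay
   d ≙ 40 ms) → muscle activation `a(t) = (e^{A·u}−1)/(e^A−1)`, A ∈ (−3,0).
2. **Hill-type muscle–tendon unit** — active force–length (quadratic on
   [0.5, 1.5]·l0m), passive force–length `e^{10l−15}`, Hill force–velocity
   with closed-form inverse, quadratic-toe/linear tendon curve,
   constant-height pennation `φ = asin(l0m sin φ0 / lm)`; fiber length
   integrated by classic RK4 from the force-balance velocity.
3. **Joint geometry** — musculotendon length as a cubic in the joint angle
   `lmt(θ) = μ0+μ1θ+μ2θ²+μ3θ³`, moment arm `r(θ) = ∂lmt/∂θ`, torque
   `M(θ,t) = Σᵢ rᵢ(θ)·Fᵢ(θ,t)`.

The 16 physiological parameters (maximum isometric force F0m, optimal
fiber length l0m, tendon slack length lst, pennation φ0 — for each of four
muscles) are calibrated with a binary-coded genetic algorithm (roulette
selection, single-point crossover 0.6, mutation 0.1, elitism) minimizing
`min Σ (M_measured − Σᵢ Fᵢ·rᵢ)²` within physiological bounds (±50%, lst
±15%). Because no public recordings exist for this protocol, the package
includes a synthetic-trial generator with known ground truth (see
`docs/methods.md`).

## Worked example

```python
import numpy as np
from emg2torque import GAConfig, evaluate, generate_scenario, run_ga
from emg2torque.defaults import default_muscle_params

# five movements x three repetitions at a drawn ground-truth subject;
# last repetition of each movement is held out
trials, truth = generate_scenario(seed=1)
train = [t for t in trials if t.meta["role"] == "train"]
test = [t for t in trials if t.meta["role"] == "test"]

result = run_ga(train, ga=GAConfig(population=40, generations=60, seed=2))
print("objective", f"{result.initial_objective:.0f} -> {result.best_objective:.0f}")
print("held-out RMSE, anatomical initial params:",
      f"{evaluate(test, default_muscle_params()).mean_rmse:.3f} N*m")
print("held-out RMSE, calibrated params:       ",
      f"{evaluate(test, result.muscles).mean_rmse:.3f} N*m")
```

prints

```
objective 112236 -> 28215
held-out RMSE, anatomical initial params: 2.668 N*m
held-out RMSE, calibrated params:        0.598 N*m
```

i.e. the genetic algorithm cuts the held-out torque error of the
uncalibrated anatomical parameter set by ~78%, down to the trials' noise
floor (the torque-noise SD, here ≈ 0.59 N·m). The same pipeline is
available from the shell:

```bash
emg2torque simulate  --out sim --seed 1
emg2torque calibrate --manifest sim/manifest.yaml --out cal --seed 2 \
                     --population 40 --generations 60
emg2torque evaluate  --manifest sim/manifest.yaml \
                     --params cal/calibrated_params.yaml --out report
```

The sklearn-style estimator `emg2torque.HillTorqueModel` wraps
fit (= GA calibration) / predict (= forward torque) / score (= −RMSE) for
use with scikit-learn tooling.

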
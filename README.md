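# nmcif — robust neural decoding with a maximum correntropy information filter

`nmcif` estimates a low-dimensional behavioral state from noisy,
high-dimensional neural population activity, the core signal-processing
problem of motor brain–machine interfaces (BMI).  It is written for
neural-engineering and state-space-filtering practitioners who need a decoder
that (a) handles hundreds of correlated spiking channels, (b) tolerates
heavy-tailed, outlier-prone measurement noise, and (c) does not require a
well-known initial state.

## The model

The decoder combines three pieces:

1. **Linear state dynamics.**  The 2-D behavioral state `x_k` (lever-position
   code of a rodent two-lever task: rest `[0,0]`, high lever `[1,1]`, low
   lever `[1,−1]`) follows `x_k = F x_{k−1} + q_k` with process-noise
   information matrix `W = Q⁻¹`, fitted by least squares on labeled training
   trajectories binned at 100 ms.

2. **A nonlinear pseudo-observation.**  A one-hidden-layer perceptron `g(·)`
   maps the current and recent firing rates (32 channels × 5 bins = 160
   inputs by default) to a state-dimensional pseudo-observation
   `g(y_k) = x_k + r_k`, with residue information `V = R⁻¹` estimated from
   training residuals.  This absorbs the nonlinearity and inter-channel
   correlation of the population code, and makes the observation matrix the
   identity.

3. **A correntropy (Welsch) M-estimate update.**  Prior and pseudo-observation
   are stacked and whitened into `D = M x + e` with unit noise covariance, and
   the posterior maximizes the correntropy cost

   `J(x) = (1/2n) Σ_i exp(−(d_i − m_i x)² / 2σ²)`,

   solved per time bin by an iteratively reweighted least-squares (IRLS) fixed
   point.  The Gaussian kernel's influence function `φ(e) = e·exp(−e²/2σ²)` is
   bounded and redescending, so gross outliers are ignored rather than
   followed.  As the kernel bandwidth `σ → ∞` every weight becomes 1 and the
   filter reduces exactly to a nonlinear information filter (NIF), the
   information-form Kalman update — which also makes a near-total-uncertainty
   initialization (`χ̂₀ = 10⁻⁶ I`) well defined.

The posterior information matrix is propagated either from the final IRLS
weights (`nmcif_b`, the default) or via the asymptotic influence-function
constant `c(σ,θ) = σ³(σ²+2θ²)^{3/2} / (θ²(σ²+θ²)³)` (`nmcif_a`).  Baselines
included: a covariance-form Kalman filter on the raw channels (`kf`) and the
raw network output (`nn`).

Because no public recordings exist for this task, the package ships a
first-class synthetic generator that emulates the two-lever sessions
(sigmoid-smoothed trial trajectories, linear-Gaussian or
linear–nonlinear–Poisson spike counts, shot-noise contamination, deviated
initializations) so every claim is testable end to end.

## Worked example

Fit the dynamics on a clean training session, then decode a test session whose
pseudo-observations carry 3.3 % heavy-tailed contamination (variance ×100):

```python
import numpy as np
from nmcif import (
    TaskScenario, generate_states, generate_pseudo_observations,
    ContaminationSpec, contaminate, fit_transition, estimate_residue_information,
    StateSpaceModel, DecoderSpec, KernelSpec, run_filter, mse_2d,
)

train = generate_states(TaskScenario(n_trials=100, seed=0))
F, q_mean, Q, W = fit_transition(train.states)
model = StateSpaceModel(F=F, q_mean=q_mean, Q=Q, W=W)
g_train = generate_pseudo_observations(train.states, 0.2, np.random.default_rng(1))
r_mean, R, V = estimate_residue_information(g_train - train.states)

test = generate_states(TaskScenario(n_trials=12, seed=100))
g = generate_pseudo_observations(test.states, 0.2, np.random.default_rng(2))
g, outliers = contaminate(g, ContaminationSpec(fraction=0.033, magnitude=100.0, seed=3),
                          baseline_var=np.diag(R))

for kind, sigma in [("nif", 2.0), ("nmcif_b", 2.0)]:
    spec = DecoderSpec(kind=kind, kernel=KernelSpec(sigma))
    result = run_filter(test, model, spec, pseudo_obs=g, V=V, r_mean=r_mean)
    print(f"{spec.label:18s} 2D-MSE = {mse_2d(result.estimates, test.states):.4f}  "
          f"mean iterations = {result.iterations.mean():.2f}")
```

which prints

```
nif                2D-MSE = 0.2009  mean iterations = 1.00
nmcif_b(sigma=2)   2D-MSE = 0.0815  mean iterations = 11.43
```

The 2D-MSE is the time-averaged squared Euclidean distance between the decoded
and true 2-D states; the six contaminated bins inflate the non-robust NIF's
error by a factor of ~2.5 while the correntropy filter's redescending weights
suppress them, at the cost of a few IRLS iterations per bin.

A command-line interface exposes the same pipeline
(`nmcif simulate | fit | decode | evaluate | experiment`, each seeded and
config-driven); see `nmcif --help`.

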
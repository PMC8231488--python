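# Methods

This note records the model, the numerical choices, and the design decisions
behind `nmcif`, in enough detail that a maintainer can reproduce or revise
them.

## State-observation model

The state `x_k ∈ R^n` (n = 2 throughout: the two-lever task's position code)
evolves as `x_k = F x_{k−1} + q_{k−1}` with `q ~ (q_mean, Q)` and process-noise
information `W = Q⁻¹`.  `F` is fitted by ordinary least squares on labeled
training trajectories.  With `assume_zero_mean=True` (default) no intercept is
fitted, `q_mean = 0`, and `Q` is the second moment of the residues about zero,
consistent with the zero-mean noise assumption of the filter; setting the flag
false fits an intercept and folds it into `q_mean`.  Covariances are inverted
only after symmetric jitter regularization: when the smallest eigenvalue falls
below `1e−12` of the largest, `λI` with `λ = 1e−9·trace/n` is added; an
exactly-zero covariance raises, except in `fit_transition`, where a `1e−12·I`
absolute floor (with a warning) keeps the noise-free interpolation case
well defined.

Two observation layers exist.  The Kalman baseline uses per-channel linear
tuning `y = Hx + ζ` fitted independently per channel (intercepts folded into
the residual mean; zero-variance channels floored at a configurable epsilon).
The information filters use a learned pseudo-observation `g(y_k) = x_k + r_k`
whose residue statistics `(r_mean, R, V = R⁻¹)` come from training residuals;
a residue mean above 10 % of the state scale triggers a warning because the
update assumes zero-mean residues.

## The correntropy update

Per time bin, the prior `(x̄, χ̄)` is obtained in information form,
`χ̄ = W − WF(χ̂ + FᵀWF)⁻¹FᵀW`, which never inverts `χ̂` and therefore accepts a
near-zero initial information matrix (`1e−6·I` by default — "the initial state
is unknown").  Prior and pseudo-observation are stacked as a regression with
noise covariance `blockdiag(χ̄⁻¹, V⁻¹)` and whitened by a factor `S` of the
information matrix.

**Whitening factor.**  We use the symmetric positive definite matrix square
root, `S² = blockdiag(χ̄, V)`.  A symmetric factor satisfies both
`S·Sᵀ = info` and `Sᵀ·S = info` simultaneously, so (i) the whitened noise has
exactly identity covariance, (ii) at `σ → ∞` the normal equations reduce
exactly to the information-filter update `χ̂ = χ̄ + V` in both mean and
information, and (iii) the two possible sandwich orders of the weighted
information matrix (`SCSᵀ` vs `SᵀCS`) coincide, removing an ordering ambiguity
that exists for triangular factors.  An upper-triangular Cholesky option
(`factor="cholesky"`, `SᵀS = info`) is retained; it preserves (i) and (ii) but
yields different per-row weights at finite bandwidth, which is why the factor
convention is fixed for reproducibility.

**Fixed point.**  The update maximizes `J(x) = (1/2n) Σ G_σ(d_i − m_i x)` by
IRLS with lagged weights: each pass solves `(MᵀC M) x = MᵀC D` with
`C = diag(G_σ(e_i))` evaluated at the previous iterate.  This is a
half-quadratic majorize-minimize step for the Welsch loss, so the cost is
nondecreasing along the iteration.  Stopping: relative change
`‖x⁽ᵗ⁾−x⁽ᵗ⁻¹⁾‖₂/(‖x⁽ᵗ⁻¹⁾‖₂+1e−12) ≤ ω` (default `ω = 1e−6`, cap 50
iterations, both configurable), or weight stationarity
(`max|ΔC| ≤ 1e−12`): when no weight moves at that level, the next solve would
return the same iterate, which is what makes the one-step convergence of the
Gaussian limit visible at large finite bandwidths.  A divergence guard aborts
with an instructive error when the iterate norm exceeds `1e6×` the observation
scale or all weights underflow (bandwidth too small); bandwidths below
`min_sigma_guard = 0.1` (whitened units) draw a warning up front.

**Two-start IRLS and basin selection.**  The correntropy cost is bimodal
whenever the innovation spans several whitened bandwidths: one fixed point
sits near the prior, one near the least-squares solution.  A single IRLS run
started at the prior cannot leave the prior basin, which is catastrophic
exactly in the deviated-initialization setting (a vacuous prior plus a large
but *correct* innovation).  The solver therefore runs IRLS from the prior mean
and, at finite bandwidth, also from the least-squares solution, and switches
to the least-squares basin only when its cost is higher by at least half a
whitened row, `0.5/(2n)`.  The margin separates the two regimes: with a
vacuous prior the observation mode explains all `2n` rows (cost gap ≈ 0.5) and
wins; a gross outlier mode merely ties the prior mode (`n` rows each) and is
rejected.  Ties keep the prior start, which also keeps iteration counts
stable.  With this rule the solver matches a brute-force grid maximizer on
scalar instances in the convergent-bandwidth regime (`σ` not small relative to
the whitened innovation); at very small bandwidths the iteration is local by
design, matching the known fragility of the estimator there.

**Posterior information.**  Variant B (default) re-weights the whitened rows
with the final IRLS weights, `χ̂ = MᵀCM = S_χᵀC_χS_χ + S_VᵀC_VS_V`: rows hit by
outliers contribute less information, which is the behavior wanted at low
state dimension.  Variant A uses the asymptotic influence-function constant,
`χ̂ = c(σ,θ)·MᵀM` with `c = σ³(σ²+2θ²)^{3/2}/(θ²(σ²+θ²)³)`, the closed form of
`(E[φ′])²/E[φ²]` under a reference whitened-residual distribution `N(0, θ²)`
(`θ` is the standard deviation; the constant is verified against Gauss–Hermite
quadrature in the tests, and `c → 1/θ²` as `σ → ∞`).  `θ` defaults to 1, the
scale of correctly whitened residuals.

## The observer

A one-hidden-layer perceptron (10 tanh hidden units by default) regresses the
state on the current firing bin plus 4 past bins (400 ms of history; 32
channels → 160 standardized inputs).  Training is full-batch constant-rate
gradient descent (learning rate 0.05, up to 2000 epochs, training-loss plateau
early stopping) via scikit-learn's `MLPRegressor` with momentum 0; the fitted
weights are extracted into a plain numpy forward pass so prediction and
serialization are deterministic and self-contained.  Twenty seeded restarts
are trained and the one with the lowest held-out MSE is kept; the 60/40 split
is contiguous in time to avoid temporal leakage (a flag switches to random
rows).  Residue statistics come from training-split residuals, with an
eigenvalue floor (`1e−8`) guarding near-perfect fits.  The hidden
nonlinearity (tanh) and the repeat-first-bin padding of the lag window are
implementation choices where the procedure is otherwise underdetermined.

## Synthetic task generator

The generator emulates the rodent two-lever discrimination sessions: per
trial, 500 ms rest at `[0,0]`, a logistic ramp (steepness 1.5 per bin, chosen
to give a smooth sub-second transition; no canonical value exists) over 500 ms
to the instructed target (`[1,1]` high, `[1,−1]` low), ≥500 ms hold, and a
200 ms sigmoid return.  Plateau bins equal the targets exactly; ramp bins are
strictly between, monotone.  Session composition is deterministic:
`round(p_high·n_trials)` high-lever trials (default `p_high = 0.4`, echoing
the recorded sessions' high/low imbalance) in seeded shuffled order — fixed
realized counts, as in a real session log, which also guarantees the state
design has full rank for model fitting.

Firing models: `lnp_poisson` (default) draws counts `Poisson(exp(aᵀx + b))`
with gains scaled for 0–5 counts per 100-ms bin; `linear_gaussian` is an
idealized rate code (weak gains, unit noise — single-bin SNR below 1, as for
cortical units) used for exactness tests and the KF's model.  A rate overflow
guard rejects log-rates above 30.  `generate_pseudo_observations` emulates a
trained observer directly (`g(y) = x + r`, `r ~ N(0, 0.2² I)`, the residual
scale the perceptron reaches on this task), so filter-level studies do not
retrain a network per replicate.  Contamination adds zero-mean shots with
variance `magnitude × baseline residue variance` (defaults: 3.3 % of bins,
×100) to a seeded bin subset and returns the ground-truth outlier indices;
clean bins are preserved bitwise.

What the generator does **not** emulate: spike waveforms, inter-neuron
connectivity beyond shared state tuning, region (M1 vs mPFC) differences,
nonstationary tuning drift, or behavioral variability in trial timing.
Passing tests therefore demonstrate the filters' claimed properties under the
stated state-space assumptions, not decoding performance on real recordings.

## Benchmark protocol and problem sizes

Experiments use a training session of 100 trials (~1700 bins, the scale of
the recorded sessions) and 10 test segments of 3 trials each, scored by
2D-MSE (sum over the two state dimensions, mean over time — chosen so that
reported error scales match a `[−1,1]²` state box; a mean-over-dims variant is
selectable and the convention is echoed in every output).  Segment statistics
are mean ± sample sd (ddof = 1) over the 10 segments, and improvements are
quoted as `100·(a−b)/a` on the means.  The paired robustness and
deviated-initialization studies use 20 replicate seeds of fitted-model +
10-segment (robustness) or single-session (initialization) runs; unit tests
use smaller sizes (8–30 trials) chosen to keep the suite fast while leaving
the measured effects far from their decision thresholds.  Decoder
initialization follows the task protocol: mean at the first labeled state,
information `1e−6·I` for information filters, covariance `1·I` for the KF.

## Known limitations

- Bandwidth selection is left to the user (the sweep condition makes the
  trade-off measurable); too-small bandwidths degrade or diverge, and an
  outlier in the very first bin of a vacuous-prior run is indistinguishable
  from a valid observation — no filter can resolve that ambiguity.
- At aggressive bandwidths the robustness/efficiency trade-off can cost
  accuracy on clean data relative to the NIF; the efficiency regime
  (`σ ≳ 5` whitened units) recovers it.
- The linear transition fitted on smoothed trial trajectories is a
  convenience model; its residues are small but not white, so `W` should be
  read as a fitted smoothing weight rather than a literal noise inverse.
- The KF baseline uses current-bin raw rates with fitted linear tuning; no
  lagged-history KF variant is provided.
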
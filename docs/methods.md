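# Methods

## The estimator family

All estimators act on a recording `X` of shape (n_nodes, n_time) with uniform
sampling interval `dt`; traces are z-scored per node (population convention,
divisor n) before estimation unless `standardize=False` is passed. The
returned matrix follows the row-is-target convention: entry (i, j) encodes
the influence of node j on node i.

| name | definition |
|---|---|
| Cov | ⟨x, x⟩ (equals the correlation matrix on z-scored data) |
| P | Cov⁻¹ |
| L1reg | graphical-lasso penalized inverse covariance, penalty weight λ |
| L2reg | (Cov + λI)⁻¹, rescaled to unit diagonal for λ > 0 |
| Δc | ⟨dx/dt, x⟩ |
| Δp | Δc_ij − Cov_jK Cov_KK⁻¹ Δc_iKᵀ, K = all nodes but i, j |
| ΔL | ⟨dx/dt, x⟩ ⟨x, x⟩⁻¹ |
| ΔR / ΔReLU | ⟨dx/dt, x⟩ ⟨R(x), x⟩⁻¹ |
| ΔD | (τ⟨dx/dt, x⟩ + ⟨x, x⟩) ⟨R(x), x⟩⁻¹ |
| Cspk | causal-window average of the centered spike cross-correlogram |

⟨a, b⟩ is the time-averaged outer product (1/T) Σ_t a_t b_tᵀ. ΔL is exactly
the least-squares solution of (dx/dt)_t = W x_t, i.e. a row-wise ordinary
regression of each derivative trace on all state traces; the nonlinear
variants replace the regressors by R(x).

### Derivative and sample pairing

The derivative is the symmetric difference quotient (x[t+1] − x[t−1])/(2 dt);
endpoints are dropped, never padded. Which state sample accompanies the
derivative matters more than it looks:

* **Δc and Δp** pair the derivative at t with the state at the same t (the
  stencil center). This is the classical differential-covariance definition,
  and its finite-dt bias on stochastic data is part of what these estimators
  are.
* **The DDC estimators** pair the derivative at t with the state one step
  earlier (t − dt, the trailing stencil edge). For a stochastically driven
  system the state at t already contains the noise increment over
  (t − dt, t), which also appears inside the difference stencil; same-time
  pairing therefore correlates regressor and noise and biases the
  least-squares solution by Q P⁻¹/2 — an O(1) distortion that no amount of
  data removes (on the three-node confounder it moves the diagonal of ΔL from
  −1 to ≈ 0). The trailing state predates every increment in the stencil, so
  the cross term has zero mean and shrinks as 1/√T, restoring the
  unbiasedness that holds for the exact equations. On smooth
  (deterministic) data the one-step shift costs only O(dt): ΔL ≈ W + dt·W².

### Response functions and centering

The built-in responses are the identity, the rectifier R(x; θ) = max(x, θ)
and the centered logistic 1/(1+e^{−αx}) − 1/2, applied elementwise to the
z-scored state. R(x) is mean-centered over time before the outer product, so
additive constants in the response are irrelevant; with θ below the data
minimum, ΔReLU then reproduces ΔL exactly, and a low threshold approximates
a linear model. The θ grid for `relu_threshold_scan` spans the 5th–95th
percentiles of the pooled z-scored samples (19 evenly spaced percentile
steps by default); ties break toward the smaller θ, i.e. toward the linear
model.

### Inversion policy

Matrix inverses use a direct solve and refuse matrices with condition number
above 1e12; the Moore–Penrose pseudoinverse is available only behind an
explicit `pseudoinverse=True`, because the inverse of a rank-deficient matrix
is not unique and silently picking one would hide a modeling problem.
Rank-deficiency arises in practice: deterministic tonic-firing neurons can
phase-lock into nearly collinear voltage pairs (condition numbers ~1e13
observed on 50-neuron integrate-and-fire runs), which is why the spiking
analyses set the flag explicitly.

### Regularized precision

L1 solves the graphical-lasso objective (penalized Gaussian maximum
likelihood with an L1 penalty on off-diagonal precision entries) via
scikit-learn; L2 inverts the ridge-shrunk covariance and rescales it to unit
diagonal. At λ = 0 both return the plain precision matrix; the L2 rescaling
applies only for λ > 0 so that the λ → 0 contract with `precision_estimator`
holds exactly.

### Spike cross-correlogram

Spike trains are binned at dt = 0.5 ms and mean-centered; the Pearson-scaled
cross-correlogram is averaged over the causal window t ∈ [−τ, 0] with
τ = 0.1 s, so Cspk(i, j) integrates the correlation of i's present with j's
recent past. Neuron pairs in which either unit fires below 0.1 Hz are zeroed
— their correlograms are too sparse to be meaningful.

## Simulators

All integrators are fixed-step Euler (Euler–Maruyama for the stochastic
models), jit-compiled with numba when available. Every simulator is
deterministic given (config, seed); noise is drawn from
`numpy.random.default_rng(seed)` up front and fed to the loop.

* **Linear SDE** dx/dt = Wx + Du: state update x += dt·Wx + D·σ√dt·z, i.e.
  the drive is white noise with spectral density σ² (default σ = 1,
  dt = 0.01 s, duration 1,000 s, x₀ = 0). Under this convention the
  stationary covariance solves W P + P Wᵀ + σ² D Dᵀ = 0, which
  `lyapunov_steady_cov` computes (SciPy's Bartels–Stewart solver; the
  Kronecker-vectorized form is the independent oracle in the tests).
  Observational noise of sd σ_obs is added after integration.
  `return_drive=True` exposes the per-step dβ/dt paired with the pre-update
  state — the pairing under which the cross term has zero mean, used to
  measure the size of the stochastic residual.
* **Sigmoid network** dx/dt = W R(x) + u with the odd response
  R(x) = 1/(1+e^{−αx}) − 1/2 (α = 1), integrated at dt = 0.1 ms and decimated
  to 100 Hz *before* estimation (the decimation stage is a config switch;
  pre-estimation decimation is the default because it is the variant that
  changes results).
* **Rössler** with a = b = 0.2, c = 5.7 at dt = 0.01 s; the first 100 s of
  transient are discarded. Fixed-step Euler keeps the attractor bounded at
  these settings (max |x| ≈ 27 over 1,000 s).
* **Two-state system**: constant W; the noise-mixing matrix switches from the
  identity to D2 = [[1,0,1],[1,1,0],[0,1,1]] at 500 s of a 1,000 s run — a
  nonstationary process with time-invariant connectivity.
* **LIF network**: τ_m dV/dt = −V + Wr + I_bias with double-exponential
  synapses (dr/dt = −r/τ_d + h, dh/dt = −h/τ_r + (τ_d τ_r)⁻¹ Σ δ(t−t_k));
  threshold 1, reset 0, dt = 0.05 ms, voltage decimated to 2,000 Hz, reset
  applied before recording so the reported subthreshold trace never exceeds
  threshold. The kinetic constants (τ_m = 20 ms, τ_d = 10 ms, τ_r = 1 ms) are
  repository defaults for a sparse few-Hz regime, not literature-fixed
  values; the bias current must be tuned jointly with the coupling — the
  inhibition-balanced operating point sits near
  I_bias ≈ 1 + rate·|w|·in-degree. Runs whose mean rate exceeds 200 Hz abort
  with an error. `split_active_quiet` partitions samples by proximity
  (±window) to any spike and keeps the contiguous runs so that derivative
  cross-products never span a gap; `ddc_linear_segmented` pools the
  cross-products across segments with shared standardization statistics.
* **Reduced Wong–Wang**: dS/dt = −S/τ + (1−S)γH(x) + σν with
  H(x) = (ax−b)/(1−e^{−d(ax−b)}) (removable singularity at ax = b filled
  with its limit 1/d), x_i = cJS_i + GJ Σ_j W_ij S_j + I0, sampled at
  1,000 Hz. Transfer and kinetic constants default to the standard
  reduced-model values (a = 270, b = 108, d = 0.154, γ = 0.641, τ = 0.1 s,
  J = 0.2609); `wong_wang_dmri_preset` carries the brain-surface preset
  c = 0.01, I0 = −0.1. All constants are config data, fully overridable.

Ground-truth graphs: 3-node chain (1→2→3) and confounder (1→2, 1→3) motifs
with diagonal −1 and uniform inhibitory strength −0.5; directed Erdős–Rényi
graphs where each ordered off-diagonal pair independently carries an edge
with probability equal to the sparsity; and degree-preserving
double-edge-swap randomization (networkx) as a control that keeps every in-
and out-degree.

## Evaluation conventions

Estimate and truth are each divided by their largest absolute compared entry
(scaling both into [−1, 1]); the diagonal is always excluded, and comparisons
can optionally be restricted to the strictly lower triangle. Across trials
the error decomposes orthogonally — Error (RMS over trials), Bias (distance
of the trial-mean estimate from truth), Variance (RMS spread about the trial
mean) — with Error² = Bias² + Variance² holding exactly by construction, and
θ_b = arctan(Bias/Variance). Degenerate conventions: variance 0 gives
θ_b = π/2 (all bias); bias = variance = 0 gives θ_b = 0.

ROC curves sweep binarization thresholds over off-diagonal |estimate| values
(absolute values, since only the presence of a connection is classified);
AUC is the trapezoidal area. c-sensitivity is the fraction of true-edge
magnitudes above the 95th percentile of the non-edge magnitudes; it warns
when fewer than 20 non-edges make that percentile degenerate.

The AR bootstrap fits each node its own autoregressive model — conditional
least squares, order chosen by a forward BIC search that accepts a higher
order only when BIC falls by more than 2 — and simulates surrogate datasets
with resampled Gaussian innovations, independently across nodes. That is
precisely the null hypothesis (no cross-dependence) with every node's power
spectrum preserved; one shared surrogate set serves all edges since the null
model is per-node. A Gaussian fitted per edge to the surrogate estimates
yields two-sided tail probabilities (estimates are signed, so two-sided is
the conservative choice). No multiple-testing correction is applied by
default — binarization uses raw significance levels.

Subject identification vectorizes each matrix without its diagonal, ranks
database entries by Pearson correlation with the target, and scores a success
when the true label falls in the top-m pool; accuracy is nondecreasing in m.

## Validation design and problem sizes

The acceptance suite runs every claim at sizes a single CPU handles in
seconds to minutes: the stochastic-residual ratio and Lyapunov bridge on the
3-node confounder at 1,000 s; bias ordering over 50 trials at 100 s and
1,000 s; motif recovery on chain and confounder under both linear and
sigmoid dynamics at 1,000 s; spiking recovery on 50-neuron ER(0.04) networks
over 10 seeds of 20 s compared against an independent same-sparsity control
graph (Wilcoxon signed-rank); bootstrap calibration on 20 independent AR(1)
nodes with 5,000 samples and 200 surrogates.

Two statistics needed care:

* **Two-state comparison.** For the confounder motif with the D2 above, the
  two states' analytic off-diagonal covariances are affinely related — their
  entrywise Pearson correlation is exactly 1 — so a correlation between
  window-wise estimates cannot register the state switch. The nonstationarity
  claim is therefore tested with a scale-sensitive statistic: the normalized
  distance between mean state-1 and mean state-2 window estimates, which is
  large for Cov (≈1.5; the off-diagonal covariances flip sign between states)
  and small for ΔL (≈0.2, pure sampling noise). Single 400-s windows carry
  ~10% covariance sampling error (slowest relaxation rate ≈ 1/s), so
  window-versus-analytic checks average over five realizations.
* **Leaky closed form.** (W − I)/τ for the 3-node motifs is a defective
  matrix (a single repeated eigenvalue), so a deterministic decay trajectory
  spans the state space too anisotropically to invert; the closed form
  ΔL = (W − I)/τ is instead verified on stochastically driven data with a
  full-matrix relative Frobenius tolerance.

## What the synthetic data does and does not show

The generators produce exactly the model classes the estimator family is
derived from (plus deliberate mismatches: sigmoid dynamics estimated with a
rectifier response, spiking networks estimated with the linear model).
Passing tests demonstrate recovery when a dynamical model of roughly the
right family generated the data, under white or correlated drive noise,
nonstationary noise switching, chaotic dynamics and spike-reset
discontinuities. They do not emulate measurement physics (hemodynamic
convolution, slow calcium kinetics), filtering or artifact structure of real
recordings, non-uniform sampling (rejected rather than resampled), or
graded/weighted anatomical truth — real-data performance additionally
depends on all of these.

## Known limitations

* ΔReLU threshold selection is a validation-time procedure: it requires a
  ground-truth graph, so on real data θ must be set a priori (the
  brain-surface analyses simply use θ = 0).
* The derivative quotient makes all differential estimators sensitive to
  observational noise at small dt (variance grows as 1/dt²); ΔL's
  unbiasedness survives, but variance grows.
* Δp's diagonal is undefined by its elementwise formula; it is copied from
  Δc and excluded from every metric.
* The AR bootstrap's Gaussian edge null is an approximation; with heavy
  tails in the estimator distribution its calibration at extreme α is not
  guaranteed (calibration is verified at α = 0.05).
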
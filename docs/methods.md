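# Methods

## The samplers

All five samplers are Euler–Maruyama discretizations of SDEs that share
one invariant density, the (unnormalized) posterior π(θ):

    dθ = b(θ) dt + σ(θ) dW,        σ(θ) σ(θ)ᵀ = 2β B(θ),

with temperature β (we follow the convention β = 1/2 throughout the
shipped studies, so the invariant law is the posterior itself) and a
symmetric positive-definite state-dependent matrix B(θ) — the inverse of
a Riemannian metric, here always built from expected Fisher information.

| kind  | drift b(θ)                                    | diffusion factor |
|-------|-----------------------------------------------|------------------|
| LD    | β ∇log π                                      | √(2β) I          |
| RM    | β B ∇log π + β ∇·B                            | √(2β B)          |
| Irr   | (β I + J) ∇log π                              | √(2β) I          |
| RMIrr | (β B + J) ∇log π + β ∇·B                      | √(2β B)          |
| GiIrr | (β B + C) ∇log π + ∇·(β B + C)                | √(2β B)          |

J is a constant skew-symmetric matrix; adding J ∇log π breaks detailed
balance without changing the invariant law.  The geometry-informed
irreversible perturbation (GiIrr) instead uses the state-dependent skew
field

    C(θ) = ½ (J B(θ) + B(θ) J),

which inherits the metric's anisotropy.  Because C varies with θ, the
divergence correction ∇·C must be added for π to remain invariant; we
assemble it exactly from the metric derivative tensor
T[i,j,k] = ∂B_ij/∂θ_k as

    (∇·C)_i = ½ [ J ∇·B ]_i + ½ Σ_{j,k} T[i,k,j] J_kj.

Correctness of each assembled drift/diffusion pair is verified in two
independent ways: (i) the stationary Fokker–Planck residual
−∇·(bπ) + Σ_ij ∂²(βB_ij π) is checked to vanish (relative to the scale
of its constituent terms) at random states using nested finite
differences of the unnormalized density; (ii) in the linear-Gaussian
setting every kind's chain is compared against the *exact* stationary
law of the discrete recurrence, obtained from the discrete Lyapunov
equation Σ = (I − hA) Σ (I − hA)ᵀ + h·2βB.

Skew-matrix construction (`build_skew`): a dense all-ones upper-triangle
pattern scaled by δ; a seeded random ±1 lower-triangle minus its
transpose; or the Kronecker pattern (I⊗C₀)+(C₀⊗I) used for matrix-valued
states.  Where the construction prescribes "norm one" we normalize the
spectral norm (it bounds the stiffness J adds to the drift); the
Frobenius norm is available as an option.

## Stochastic gradients

For factorized posteriors π ∝ π₀ Π_i π(X_i|θ) the score is estimated by

    ∇̂ log π = ∇log π₀ + (N/n) Σ_{i∈τ} ∇log π(X_{τ_i}|θ),

with a fresh size-n index set τ each step, drawn without replacement by
default (the N/n scaling is unbiased either way; a with-replacement flag
exists).  Minibatch indices and Gaussian noise come from separate named
substreams of each chain's generator, so toggling subsampling never
perturbs the noise sequence.  The step size is fixed (no decay
schedule), matching the fixed-step SGLD variant used in the studies.

## Targets

* **Linear Gaussian** — conjugate posterior of a normal mean;
  constant metric B = Γ_p⁻¹ (so the reversibly-perturbed drift matrix is
  the identity), all divergence terms vanish.
* **Normal parameters (μ, σ)** — flat (improper) prior;
  B = (σ²/N)·diag(1, ½) is the inverse expected Fisher information, with
  √B = (σ/√N)·diag(1, 1/√2) and ∇·B = (0, σ/N) in closed form.  States
  with σ ≤ 0 are a domain error: the sampler flags the chain and the
  step index rather than silently reflecting, because silent clipping
  would bias the estimators (an excursion is improbable at the study's
  step size but not impossible).
* **Bayesian logistic regression** — N(0, α⁻¹I) prior on the weights;
  metric B = I + G⁻¹ with G = α⁻¹I + XΛXᵀ, Λ_ii = φ_i(1−φ_i), which is
  positive definite with B − I ≻ 0 everywhere.  ∂B/∂w_k =
  −G⁻¹(X ∂_kΛ Xᵀ)G⁻¹ with (∂_kΛ)_ii = φ_i(1−φ_i)(1−2φ_i)x_ik is
  analytic; a finite-difference implementation exists only as a test
  oracle.  The prior precision α is not fixed by the study description;
  the default is α = 1.
* **Bayesian ICA** — state vec(W), *column-major*, so the natural-
  gradient identity vec(f WᵀW) = (WᵀW ⊗ I) vec(f) holds literally;
  metric B(W) = (I + WᵀW) ⊗ I_m, whose divergence reduces to the closed
  form (m+1)·vec(W) (cross-checked against finite differences).  Source
  density ¼ sech²(y/2) is the standard logistic law; the prior precision
  λ defaults to 1 (not fixed by the study description).

All gradients, metric square roots (symmetric PSD roots via
eigendecomposition), divergences and derivative tensors are analytic and
vectorized over a leading chain axis; every one is validated against
central finite differences at random states (rel. tol. 1e-5 for scores,
1e-4 for metric derivatives).

## Integrator and ensembles

Ensembles advance in lock-step as a single (M, d) state array.  When a
study compares several sampler kinds, all kinds are stacked into one
heterogeneous ensemble whose per-chain drifts equal the per-kind
assembly exactly (asserted in tests); per-(kind, chain) noise streams
depend only on (base_seed, kind, chain index), so joint, per-kind and
single-chain runs are bit-for-bit interchangeable and smaller ensembles
are prefixes of larger ones.  A chain that leaves the admissible domain
(non-finite state, σ ≤ 0) is frozen at its last valid state, flagged
with its failure step, and excluded from estimates; a run fails only if
more than 10% of chains fail.

Observables are recorded at every step (θ₀ … θ_{K−1}, matching the
estimator (1/K)Σ_{k<K} φ(θ_k)); states may be thinned or streamed.
Long-run metrics are accumulated streaming (batch sums, prefix means at
log-spaced checkpoints) so a 5-kind × 50-chain × 10⁶-step study needs
megabytes, not gigabytes.

## Diagnostics

* **Bias/variance/MSE** across an ensemble of running averages, against
  a supplied reference expectation (analytic for the Gaussian target; a
  long reference run otherwise).  Variance uses the population (1/M)
  form; MSE = bias² + variance holds identically.
* **Batch means** — after the burn-in, the observable series is split
  into 20 equal contiguous batches (tail remainder dropped) and the
  asymptotic variance estimated as L·h·Var(batch means) with the
  unbiased sample variance; this is the finite-K version of
  K·h·Var(φ̄_K).  A single 20-batch estimate carries ~√(2/19) ≈ 32%
  relative spread, so studies report across-chain means and stds.
  Validated against the closed form 2β/a² for an exactly simulated
  Ornstein–Uhlenbeck process.
* **Kernelized Stein discrepancy** — inverse multiquadric base kernel
  r(x,y) = (c² + ‖x−y‖²)^p with c = 1, p = −1/2 by default; the Stein
  kernel r₀ʲ combines r, its first/second cross-derivatives (analytic)
  and the score.  We report the *normalized* form w_j = (1/K)·√(Σ_{k,k'}
  r₀ʲ), S = ‖w‖₂, which decays as K^{−1/2} for exact i.i.d. samples (the
  raw pairwise sum is available behind a flag).  Pairwise sums are
  evaluated blockwise (default 1024 columns) with cumulative prefix
  bookkeeping, so a whole log-spaced curve costs one O(K²) pass and
  bounded memory.

## Study presets and the synthetic data

The four presets carry the reference protocol parameters as defaults
(dimension, dataset size, minibatch size, step size, chain length,
burn-in, δ, initial state, skew pattern).  Synthetic data emulate the
stated generating processes: Gaussian observations with known noise
precision; 30 scalar draws from N(0, 10²); Gaussian-feature logistic
data with Bernoulli labels (a seeded stand-in for the external tabular
dataset, whose file layout the reader also accepts); and mixed signals
from one Laplace plus (m−1) logistic sources through a seeded
well-conditioned (cond ≤ 10) mixing matrix.  What these generators do
*not* emulate: real-data feature correlations and class imbalance
(logistic), non-stationary or noisy mixing (ICA).  Passing tests
therefore demonstrate correctness of the samplers and estimators under
the stated models, not robustness to real-data misspecification.

Two protocol choices deserve emphasis:

* **Dataset-realization sensitivity (normal-parameters study).**  The
  efficiency tables for the (μ, σ) posterior are conditional on a single
  N = 30 dataset.  The asymptotic variances scale roughly like σ̂⁴ in the
  realized sample standard deviation σ̂ for the non-metric samplers (the
  relaxation time and the stationary spread both grow with σ̂) and more
  slowly (≈σ̂²) for the metric-preconditioned ones.  Since σ̂ has ~13%
  relative spread at N = 30, redrawing the dataset moves the headline
  numbers by tens of percent.  The reproduction protocol therefore
  rescales the generated sample to its population moments (sample mean
  0, sample std 10) — `gen_normal_data(..., match_moments=True)` — so
  that reported numbers measure sampler efficiency, not dataset luck.
  The generator's default remains a faithful draw.
* **Burn-in transients.**  With the protocol burn-in time T_b = 10 from
  the initial state (5, 20), the slow samplers (LD in particular) retain
  a residual transient that inflates their batch-means estimates by
  ~20%+ (measured by extending the burn-in).  The protocol value is kept;
  this is part of why the unperturbed sampler's numbers sit above the
  reference ones while the geometry-informed sampler — which
  equilibrates within the burn-in — reproduces closely.

Problem sizes: the normal-parameters study runs at its reference size
(K = 10⁶, h = 10⁻³) with M = 50 chains rather than 1000; the Gaussian
study at K = 10⁵ with M = 100; KSD curves evaluate up to K = 10⁴ (the
pairwise cost is quadratic and the decay rate is already unambiguous
there).  The ICA preset defaults to a desk-scale run (T = 20 at
h = 10⁻⁴, burn-in time 2, 10 chains per kind) — at this scale only the
efficiency *ordering* is meaningful, and that is all the tests assert;
the full-scale protocol (T = 2000 at h = 2×10⁻⁵, 100 chains) is available
via `get_preset("ica", paper_scale=True)`.

## Numerical choices

* Symmetric PSD matrix square roots via eigendecomposition (unique),
  with eigenvalues clipped at 0; Cholesky would be an equally valid
  Euler–Maruyama noise factor but the symmetric root matches the √B
  notation and is basis-stable.
* Fixed chunk size (4096 steps) between bulk random draws, independent
  of ensemble size and chain length, so chunking never changes a chain's
  random stream.
* Without-replacement minibatch draws via per-step uniform keys and an
  argpartition (vectorized over steps); with n = N the full index set is
  returned verbatim.
* `em_stationary_law` refuses step sizes for which the linear recurrence
  is unstable (spectral radius of I − hA ≥ 1) and advises reducing h.
  Near-unit spectral radius — e.g. strongly rotating Irr/RMIrr drifts at
  large h — is exactly the stiffness regime where discretized
  irreversibility can hurt; the Lyapunov oracle quantifies it.
* δ for the Gaussian study is not fixed by the protocol; the preset uses
  δ = 1 and treats the resulting values as ordering-sensitive only.
  Likewise the random eigenvectors of the prior precision are
  regenerated (seeded), so only orderings are comparable there.
* The Gaussian preset's per-datum noise precision defaults to 0.025 I,
  i.e. a total data precision N·Γ_X = 0.25 I.  The study's design
  requires the metric B = Γ_p⁻¹ to have eigenvalues greater than one
  (B − I ≻ 0): that is what makes the reversible perturbation
  accelerate — with B = cI, c < 1, the reversibly-perturbed drift rate β
  falls below every plain-Langevin rate βλ_i and RM *slows down* — and
  what makes the geometry-informed skew field C = ½(JB + BJ) larger in
  norm than J, the stated mechanism behind its advantage.  A per-datum
  precision of 0.25 I with N = 10 observations would give Γ_p ≈ 2.5 I
  and violate both.  The trade-off: the corrected target mixes ~10×
  slower, so KSD curves over K ≤ 10⁴ are still pre-asymptotic on it; the
  KSD decay-rate check therefore runs on the faster 0.25-per-datum
  variant (the rate property is scale-free; only reaching the asymptote
  within the evaluation window is not).

## Known limitations

* No Metropolis adjustment: all estimators inherit the discretization
  bias of the unadjusted algorithm.
* Only the C = ½(JB + BJ) geometry-informed skew field is implemented;
  infinitely many valid C(θ) exist.
* No search for an optimal J, no step-size adaptation, no higher-order
  or multiscale integrators.
* The batch-means estimator needs the chain to decorrelate well within a
  batch; at severely scaled-down horizons (the default ICA preset) its
  absolute values are not comparable to long-run values — only
  cross-sampler orderings are.
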
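# Methods

## Model

Data are n_t i.i.d. samples per time point t = 1, …, T, assumed Gaussian
N(0, Σ_t) in p variables. Each data matrix is standardized column-wise
(zero mean, unit variance), so the sufficient statistic per time point is
the sample correlation matrix S_t = X′ᵀX′/n_t together with n_t.
Standardization puts all variables on one scale so that a single sparsity
penalty acts evenly; without it, a variable measured on a larger scale
would be penalized effectively less.

The estimate Θ̂ = (Θ̂_1, …, Θ̂_T) maximizes the penalized log-likelihood

    Φ(Θ) = Σ_t (n_t/2)[log det Θ_t − Tr(S_t Θ_t)]
           − (λ/2) Σ_t ‖Θ_t‖₁ − (ρ/2) Σ_{t≥2} ‖Θ_t − Θ_{t−1}‖₁

over positive-definite Θ_t, where ‖·‖₁ sums absolute values over the full
matrix. The problem is convex and the optimum unique. Both penalties can
be read as Laplace priors (MAP estimation): a sparsity prior on entries
and a smoothness prior on consecutive differences. Because both are L1,
entries and entry *changes* are driven to exact zeros, giving sparse
graphs whose topology changes only when the data insist.

### Diagonal convention

The formula above includes the diagonal in the λ term; the implementation
follows it by default and exposes `penalize_diagonal=False` for the
convention used by several graphical-lasso implementations (the positive-
definiteness constraint prevents diagonal entries from reaching zero
either way, so the choice affects magnitudes, not topology). Penalty
exemption masks (see the two-stage refit) apply to off-diagonal entries
only, so a refit with an empty edge selection reproduces the plain fit
exactly.

## Solver

A two-block ADMM on the splitting Θ = Z:

- **Likelihood block** (separable over t): minimize
  (n_t/2)[Tr(S_tΘ) − log det Θ] + (β/2)‖Θ − A‖². With the
  eigendecomposition A − (n_t/2β)S_t = QDQᵀ, the solution has the same
  eigenvectors and eigenvalues (d_i + √(d_i² + 2n_t/β))/2 — positive by
  construction, so iterates never leave the PD cone.
- **Penalty block** (separable over unique matrix entries): for each
  upper-triangle entry, a length-T fused-lasso chain
  min_z (β/2)‖z − a‖² + Σ_t μ_t|z_t| + (ρ/2)Σ|z_t − z_{t−1}|, with
  μ_t ∈ {0, λ/2} encoding diagonal handling and mask exemptions (the
  factor-2 duplication of off-diagonal entries in the full-matrix norms
  cancels against the duplicated quadratic term, so one weight serves
  both diagonal and off-diagonal chains). The chain prox is solved by a
  small warm-started inner ADMM (a T×T tridiagonal solve plus two
  soft-thresholds per iteration), vectorized across all p(p+1)/2 entries
  and run to a tolerance that tightens as the outer iteration converges
  (1e−4 down to 1e−11 max-norm). With ρ = 0 the prox is plain
  soft-thresholding in closed form. The returned estimate is the
  soft-thresholded consensus copy, so sparsity means bitwise zeros, not
  post-hoc rounding.

Convergence is declared when primal and dual residuals fall below
relative tolerances (default 1e−6, max 2000 iterations); the ADMM penalty
β (default 1.0) is adapted by residual balancing with over-relaxation
α = 1.6. λ = ρ = 0 short-circuits to the closed-form ML estimate S_t⁻¹
and is refused when some S_t is near-singular (smallest eigenvalue below
1e−10), where the ML estimate does not exist; any λ > 0 regularizes that
case. Failure to converge raises an error carrying the last iterate and
residuals.

Correctness is checked three independent ways in the test suite: a
smoothed-L1 continuation solver (L-BFGS-B) must agree with the optimum
to 1e−4 relative on small random programs; scikit-learn's graphical
lasso must agree entrywise at ρ = 0; and the chain prox must attain the
minimum of its one-dimensional problems against a generic smooth
optimizer.

## Critical penalties and model selection

- λ* = max_{t, i≠j} n_t |S_t(i,j)|: for λ ≥ λ* (ρ = 0) the diagonal
  estimate satisfies the stationarity conditions, so every graph is
  empty.
- ρ* = max_{t≥2} [max(n_t, n_{t−1}) · max_{i≠j} |S_t(i,j) − S_{t−1}(i,j)|],
  the inner maxima taken jointly per consecutive pair: for ρ ≥ ρ* a
  single pooled estimate is optimal at every time point. Absolute values
  are used in both formulas — a signed maximum could be negative and
  cannot bound a nonnegative penalty — and the disconnection/constancy
  guarantees are verified as property tests rather than assumed.

Model selection minimizes

    BIC(λ, ρ) = Σ_t −(n_t/2)[log det Θ̂_t − Tr(S_t Θ̂_t)]
                + Σ_t (k_t/2) log(n_t/2π)
                + (λ/2)Σ‖Θ̂_t‖₁ + (ρ/2)Σ‖Θ̂_t − Θ̂_{t−1}‖₁
                − c(λ, ρ, T, p),

with k_t the number of unique nonzero entries of Θ̂_t, counted on the
upper triangle including the diagonal — matching the p(p+1)/2 free
parameters of a symmetric matrix. The prior constant uses an entrywise
independence approximation: each Laplace factor exp(−(λ/2)|x|) has
normalizer 4/λ, giving c = T·m·log(λ/4) + (T−1)·m·log(ρ/4) with
m = p(p+1)/2. This closed form is isolated in `prior_constant` so an
alternative construction can be swapped in; it is data-independent and
removes the gross scale bias of the un-normalized prior. At λ = 0 or
ρ = 0 the corresponding part is dropped (flat-prior limit);
`prior_constant` itself refuses zero penalties, and the search
accordingly runs over strictly positive grids.

The search evaluates a log-spaced grid on (10⁻³λ*, λ*] × (10⁻³ρ*, ρ*]
(defaults 8×8), warm-starting each solve from its predecessor, then
refines the ±1-cell window around the minimum at double resolution, up to
three rounds or until the minimum is interior. The procedure is
deterministic given the data. Cross-validation is deliberately not
offered: it optimizes prediction rather than sparsity, costs a fold
multiplier, and is unreliable for model selection in this setting.

## Two-stage refit

L1 shrinkage biases retained edges toward zero. Stage 1 fits at (λ, ρ)
and selects entries with |partial correlation| above a threshold
(default 1e−3 — separating solver-exact zeros from retained edges; a
raw-precision-entry mode is available since the magnitude criterion could
also be read on Θ̂ directly, but partial correlation is scale-invariant).
Stage 2 re-solves with the selected (i, j, t) triples exempt from the λ
penalty — per time point, so an edge selected only at time t is exempt
only at time t — while ρ is kept unchanged to preserve smoothness. The
refit never shrinks exempted entries below their stage-1 magnitudes;
this is verified empirically as a regression test, not asserted as a
theorem.

## Synthetic-data generator

The generator emulates the benchmark's study conditions:

- **Network**: directed Erdős–Rényi edge placement (no self-loops), edge
  count tuned by a rejection loop (≤ 100 draws, multiplicative density
  updates) so that P₁ = (I − W)ᵀ(I − W) has an off-diagonal zero-fraction
  inside the target range, aiming at the sparser part of the band to
  leave headroom for later support growth. Weights are uniform on
  (−1, −δ] ∪ [δ, 1), δ = 0.2, so no structural edge is numerically weak.
- **Drift**: P_t = P_{t−1} + D_t with D_t symmetric PSD (Gershgorin
  diagonally dominant plus ridge εI, ε = perturb_scale/10), supported on
  a random half of the existing support plus a few new pairs (default
  ⌈0.02p²⌉ per step, capped by a per-step budget derived from the
  remaining sparsity headroom and halved on repeated rejection), scaled
  to max |D_t| = perturb_scale (default 0.05). A rejection loop keeps
  every P_t inside the sparsity range. How the original benchmark kept
  sparsity while adding PSD perturbations is unspecified; this
  sparse-support-plus-budget construction is a documented choice.
- **Sampling**: n_t draws from N(0, P_t⁻¹) via Cholesky, plus i.i.d.
  N(0, noise_sd²) observation noise on every entry (default 0.1 on the
  standardized scale — the benchmark's noise variance is not stated in
  the sources available to this package, so a mild value was fixed once
  and exposed in the config).

Defaults: p = 30, T = 6, n_t = 1000, sparsity range 75–80%, δ = 0.2. One
integer seed drives a single generator stream in the fixed order network
→ drift → samples. The generator produces exactly the Gaussian data the
estimator assumes; it does not emulate mass-cytometry marginals
(zero-inflation, arcsinh-scale heavy tails), so passing benchmarks show
correct recovery under the model, not robustness to real cytometry
artifacts.

## Evaluation

ROC curves sweep a threshold over |partial correlation|, pooling each
unordered pair once per time point across all T time points (per-time
curves can be derived from the exported matrices; pooling was chosen as
the primary readout since a single mean curve is wanted). AUROC is the
trapezoidal area, validated against the Mann–Whitney pairwise
formulation. Because a hard-sparse fit collapses the sweep to one point,
ROC fits use light regularization — λ at 5% of λ*, and ρ at 50% of ρ*
for the smoothed arm — while BIC-selected fits are evaluated separately
in the model-selection experiment. Structural variation counts, over
consecutive time points, unordered pairs whose edge status (|partial
correlation| > 1e−8) changes; it is non-increasing in ρ on average.

Benchmark problem sizes in the test suite are chosen to keep the full
suite fast while preserving each experiment's regime: the stable-truth
comparison runs at p = 15, T = 6, n_t = 500 over 10 seeds; the
high-dimensional comparison at n_t = 25, p = 30 (465 free parameters per
matrix); the BIC-tracking experiment at p = 10, T = 4, n_t = 1000 with a
6×6 grid.

## Numerical choices and edge cases

- Nonzero test for edges: |partial correlation| > 1e−8 on the consensus
  estimate (whose zeros are exact).
- Sample covariances are computed with population scaling (1/n_t); the
  scaling cancels in the correlation.
- Degenerate selection grids (λ* = 0 or ρ* = 0, e.g. identity
  correlation matrices) fall back to a single tiny penalty value — any
  positive penalty then yields the same trivial estimate.
- At exactly λ = λ* or ρ = ρ* the boundary subgradient conditions hold
  with equality; the solver still returns the disconnected/time-constant
  solution (verified over random instances).
- `PrecisionSequence` validates symmetry (1e−8) and positive
  definiteness on construction; `StandardizedCovarianceSequence`
  validates unit diagonals (1e−10) and off-diagonal range.
- Small-p generators: the sparsity band may contain no reachable
  discrete zero-fraction (steps of 2/(p(p−1))); the internal acceptance
  band widens to the full range in that case, and infeasible ranges
  raise a generation error reporting the achieved sparsity.

## Known limitations

- The fused penalty couples only consecutive time points; it does not
  model continuous-time smoothness, and no block/group (L2) smoothing
  variant is provided.
- The BIC prior constant is an independence approximation; its absolute
  level is not comparable across different (T, p).
- FCS files are not parsed; inputs are gated, debarcoded delimited
  tables. The preprocessing transform (raw vs. arcsinh) is configurable
  and defaults to none, with no claim about matching any particular
  upstream pipeline.
- ρ* guarantees time-constancy tightly for T ≤ 3; for longer sequences
  with strongly drifting correlations the constancy bound is
  approximate, which is why the search box treats ρ* as an upper limit
  rather than a sharp threshold.
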
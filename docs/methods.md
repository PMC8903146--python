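# Methods

## The model

The core estimator is generalized (Tikhonov-style) ridge regression with a
non-zero target vector:

```
ŵ(θ) = argmin_w ‖y − Xw‖₂² + θ‖w − w_prior‖₂²
     = (XᵀX + θI)⁻¹ (Xᵀy + θ w_prior),          θ ≥ 0.
```

The closed form follows from zeroing the gradient; `XᵀX + θI` is invertible
for every θ > 0, so under-determined designs (n < m) are handled without
special cases, and θ = 0 falls back to the minimum-norm OLS solution via the
pseudoinverse. The penalty applies one scalar θ to all m weights; a
direction-dependent penalty matrix is out of scope.

The logistic analogue maximizes the Bernoulli log-likelihood minus
(θ/2)‖w − w_prior‖₂², by damped Newton–Raphson:
`w ← w + t·(XᵀSX + θI)⁻¹ [Xᵀ(y − μ) − θ(w − w_prior)]` with `μ = σ(Xw)` and
`S = diag(μ(1 − μ))`. Iterations start at the prior (the natural warm start
on the shrinkage path), the step is halved while the penalized objective
decreases, and convergence is declared at gradient ∞-norm ≤ 1e−8 (default)
or 100 iterations, in which case the fit is flagged non-converged but
returned. The objective is concave, so accepted steps never decrease it.

No intercept is fit anywhere: paired-comparison rows are antisymmetric by
construction (swapping a pair's orientation negates x and y), and the
ternary codings are already centered and share a scale, so no further
standardization is applied.

### The θ = ∞ endpoint

Sign predictions are invariant to the scale of the weights, so at any finite
θ a shrunken-but-nonzero weight vector predicts exactly as its direction
does; the zero-prior model's often-cited collapse to chance under strong
penalties is a property of the *limit*, where the weights coincide with the
prior exactly. The default penalty grid ({0}, 30 log-spaced values in
[1e−2, 1e6], ∞) therefore includes θ = ∞ as an explicit grid point solved
exactly as ŵ := w_prior. For heuristic priors this endpoint *is* the
heuristic (see below); for the zero prior it yields all-zero scores, which
the prediction rule treats as no-evidence ties resolved by a fair coin.

## Priors

All heuristic priors are two-step: fit the constrained model on the training
rows, then use its point estimate as the target vector.

- **Cue validity.** `v̂_j = (R_j − W_j)/(R_j + W_j)` over rows where cue j
  discriminates (x_ij ≠ 0); rows with x_ij = 0 are ignored. A cue that never
  discriminates gets v̂_j := 0 — it then has direction 0, rank 0, and a zero
  prior entry, making it inert. Directions are `q̂ = sign(v̂)`; ranks
  `r̂_j = #{j′ : |v̂_j′| < |v̂_j|}` ascend from 0, with ties sharing a rank.
- **TAL prior.** The shared scalar `argmin_w ‖y − X(q̂w)‖²` has the closed
  form `(Xq̂)ᵀy / ‖Xq̂‖²`; `w_prior = q̂ · scale`. Because tallying's
  prediction is `sign(Σ_j q̂_j x_j) = sign(x·q̂)`, any positive shared scale
  reproduces the heuristic's choices exactly — which is why the TAL-prior
  model at θ = ∞ matches the tallying rule decision-for-decision (shared
  tie coins included; see sweeps below).
- **TTB prior.** The design is first transformed column-wise,
  `X_TTB = X·diag(φ^r̂)` with φ = 2 (φ is a parameter; φ = 1 recovers the TAL
  construction, which is tested). Geometric weights make the top
  discriminating cue dominate the score (Σ_{k<r} 2^k < 2^r), so the
  transformed prior reproduces take-the-best's lexicographic choices when
  validity ranks are distinct. The penalized model is fit, and must predict,
  in the transformed space; predicting from an untransformed design raises.
- **Logistic prior.** The 1-D ML scalar of the logistic model constrained to
  `w·q̂`, found by bounded scalar minimization of the negative log-likelihood
  on |w| ≤ 50 (under complete separation the likelihood has no interior
  maximum; the bound saturates and is flagged in diagnostics). The prior is
  `q̂·|ŵ|`, keeping it pointed along the cue directions.
- **Permuted-OLS control.** The OLS solution with entries randomly permuted
  (seeded) — a non-zero prior with no substantive content, used to show that
  robustness requires a *sensible* prior, not merely a non-zero one.
- **LSS prior (fMRI).** The per-voxel LSS estimates (below) as the target of
  a ridge on the LSA design.

## Data coding

Attributes are median-split: binary coding is 1 strictly above the column
median (applied uniformly; the ternary rule's tie-to-0 convention motivates
treating ties conservatively in both schemes), ternary coding is
sign(value − median). Constant columns code to all-zero with a warning. For
paired-comparison tasks, every unordered object pair with unequal criterion
values becomes one row of signed binary-attribute differences in {−1, 0, +1};
pairs tied on the criterion are undefined as comparisons and are dropped
(counted). Each pair's left/right orientation is randomized (seeded) so the
outcome classes are balanced in expectation. Classification tasks keep the
ternary-coded objects as rows with labels in {−1, +1} (inputs coded {0, 1}
are remapped). Rows with missing cells are deleted listwise before coding.

## Heuristics and ties

TAL votes: `sign(Σ_j sign(v̂_j x_j))`. TTB decides by the discriminating cue
of maximal |v̂|, applying its direction: `sign(q̂_{j*} x_{j*})`; |v̂| ties
break to the lowest column index (deterministic and documented — the
alternative conventions are indistinguishable on data without exact ties).
When no evidence exists (TAL sum 0, or no cue discriminates for TTB), the
choice is a fair coin from an injected seeded generator. Within a sweep
iteration one coin per test comparison is pre-drawn and shared by every
model and heuristic, so endpoint equivalences hold exactly rather than in
expectation, and accuracy records the realized outcome rather than 0.5
credit.

## Normalized entropy

Compensatoriness of a solution is measured by

```
H̃ = −Σ_j w̃_j log₂ w̃_j / log₂ m,    w̃_j = |ŵ_j| / (‖ŵ‖₁ · φ^r̂_j),
```

with 0·log₂0 := 0. φ = 1 for the zero- and TAL-prior families (H̃ ∈ [0, 1],
peaking at 1 for uniform predictive force); φ = 2 with the training ranks
for the TTB-prior family, whose weights live in the transformed space — its
equal-magnitude prior therefore scores H̃ < 1 by design. The rank-discounted
shares are implemented exactly as written, i.e. sub-normalized for φ > 1
(they sum to < 1); a variant that renormalizes the shares to a proper
distribution is exposed via `normalized_entropy(..., renormalize=True)` for
sensitivity checks. An all-zero weight vector has no defined entropy and
returns NaN with a warning (sweep averages skip it).

## Synthetic decision tasks

The generator emulates multi-attribute decision benchmarks: attributes are
i.i.d. standard normal, the criterion is `Σ_j β_j·attr_j + ε` with
ε ~ N(0, noise_sd²), and the validity profile sets the |β| spread —
`compensatory` equal magnitudes, `noncompensatory` a geometric ladder 2^j,
`mixed` random log-spaced; signs are random. Defaults used throughout the
scaled benchmark: m = 5 cues, N = 30 objects (435 pairs), noise_sd = 0.5 —
enough noise that heuristics and regression separate without drowning the
signal. What the generator does **not** emulate: correlated attributes,
mixed discrete/continuous cue types, and the idiosyncratic cue–criterion
structure of real datasets; passing tests therefore demonstrate the
estimators' comparative behavior under a known compensatory ground truth,
not performance claims about any particular real domain.

## Monte-Carlo sweeps

Each iteration draws a seeded train/test partition (50 training pairs by
default for paired comparisons, 100 items for classification), fits the
heuristic and every prior on the training rows only, fits each family at
every θ (the linear path is computed for the whole grid from one
eigendecomposition of XᵀX), and records test accuracy and H̃. Scaled study
sizes, chosen to keep a desk run in seconds while leaving Monte-Carlo error
well inside the tested margins: 5 tasks × 100 iterations × 15-point θ grid.
Full-scale sweeps (1000 iterations, larger grids) use the same entry points.

## fMRI simulation

One run presents 40 trials (20 each of 2 stimulus types; boxcars of
ED = 1.5 s separated by ISI ∈ {2, 3, 4} s) plus ⌈40/3⌉ null epochs of the
same slot length, randomly interleaved (seeded). Regressors are the boxcars
convolved with a canonical double-gamma HRF (peak 6 s, undershoot 16 s,
dispersions 1, ratio 1/6, peak-normalized — standard values, sampled at
TR = 1 s from a 20× oversampled grid). Scans per run:
n = ⌈(4/3)·ℓ·(ED+ISI) + t_end⌉ with t_end = 20 s of decay slack; the design
builder verifies all slots fit in the scan window.

Ground truth: per-stimulus mean vectors μ ~ N(0, σ²_Ψ) (σ²_Ψ ∈ {10, 15, 20})
over the 7³-voxel cluster; voxel covariance Σ ~ W(V, 7³)/7³ with V = 0.7 off
diagonal and 1 on it; per-trial weight rows ~ N(μ_cond, Σ), permuted along
the trial axis; the cluster is embedded at a uniformly drawn corner inside
the 21³ brain. μ and Σ are held fixed across the two runs of an iteration
and resampled across iterations; designs, trial draws, placement and noise
are independent per run.

Observation: `Y = X_LSA·Ω + E` with E i.i.d. N(0, σ²_scanner = 10000)
smoothed by a separable Gaussian along t, x, y, z (FWHM 4.5 s and 4 mm;
voxels 3 × 3 × 3.75 mm; reflect boundaries). The smoothing kernel is
truncated at a half-width of **one sample per axis** (a 3-tap kernel, the
compact kernel of the MATLAB volume-smoothing convention). This truncation
is deliberate and load-bearing: it induces the intended spatiotemporal
correlation while retaining noise power at trial frequency. A full (4σ)
Gaussian with these FWHMs removes ~95% of the noise amplitude at the
trial-spacing frequency, which eliminates the collinearity penalty on
per-trial estimation and *reverses* the LSA/LSS comparison the study is
about; `NoiseParams(kernel_radius=None)` exposes the full kernel for
sensitivity analysis. No variance rescaling is applied after smoothing.

Estimators, per cluster voxel: LSA (OLS on the full trial design), LSS (per
trial, the target coefficient of a two-column GLM [trial k, sum of all other
trials]), and the LSS-prior ridge on the LSA design across a θ grid
(default 10 log-spaced values in [1e−2, 1e5]). Scoring is per-voxel RMSE of
the ℓ trial weights against that run's Ψ, averaged over cluster voxels, runs
and iterations. Scaled study size: one design cell (ISI = 3, σ²_Ψ = 15),
25 iterations × 2 runs (≈10 s); the full 3 × 3 grid at 1000 iterations runs
through the same function.

## Numerical choices, summarized

- Linear solver: `np.linalg.solve` on the regularized normal equations;
  eigendecomposition reused across a θ grid; pseudoinverse at θ = 0.
- Logistic Newton: init at the prior, step-halving (≤ 50 halvings),
  tol 1e−8 on the gradient ∞-norm, max 100 iterations; near-singular
  Hessians (θ = 0, flat μ) get a 1e−10 diagonal bump.
- Logistic scale prior: bounded scalar minimization (|w| ≤ 50,
  xatol 1e−10); saturation flagged.
- Wishart draws: `scipy.stats.wishart`; a draw failing the positive-definite
  check (numerically impossible in practice at df = dim) is jittered by
  1e−8·I.
- Seeding: every stochastic component (splits, pair orientation, tie coins,
  permutations, simulation draws) derives from explicit integer seeds via
  `numpy.random.SeedSequence`, making all pipelines bit-reproducible.

## Known limitations

- The TTB-prior ↔ take-the-best equivalence at θ = ∞ is exact only when the
  discriminating cues' validity ranks are distinct; tied ranks make the
  transformed score a tally among the tied cues.
- The literal (sub-normalized) entropy for φ = 2 means TTB-prior entropies
  are not on the same [0, 1] scale as the φ = 1 families; comparisons across
  families are ordinal, which is how they are used.
- The fMRI simulation omits drift, motion, physiological regressors and
  autocorrelation-aware (GLS/prewhitened) estimation; conclusions concern
  the relative behavior of LSA/LSS/LSS-prior under the stated noise model.
- Logistic-ridge fits under complete separation at θ = 0 rely on the
  iteration cap rather than a diverging MLE; the fit is flagged.
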
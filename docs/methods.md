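# Methods

## Problem and approach

`entrofuse` addresses one-class (unsupervised) anomaly detection when no
single similarity measure is trusted a priori. Kernel detectors are sensitive
to the kernel and its hyperparameters, and cross-validation is unavailable
without labels. Instead of selecting one kernel, the package evaluates a bank
of Mercer kernels and fuses the information they carry into a single combined
kernel, letting the data decide how much each base kernel contributes.

The chain is:

1. **Kernel-induced metric.** Each base kernel `K_j` induces the feature-space
   distance `d_j^2(x, y) = K_j(x, x) + K_j(y, y) − 2 K_j(x, y)`.
2. **Local-entropy anomaly features.** The local entropy of a point is
   estimated from neighbour distances: `h_α(x) = d̄_k(x, S_n) / (1 − α)`,
   with `d̄_k` the mean distance to the `k` nearest sample neighbours and the
   Hartley order `α = 0` as default. For anomaly detection the package uses
   the fully global aggregation `φ_j(x) = mean_i d_j(x, x_i)` — the average
   feature-space distance from `x` to the training sample (the point itself
   excluded when it belongs to the sample). This is smooth, parameter-free,
   and consistent with the average-distance entropy estimator; a k-NN-mean
   variant (`use_knn_features`) reuses the entropy locality parameter `k`,
   whose default is `⌈√n⌉`.
3. **Anomaly kernels.** `K_j := φ_j φ_jᵀ` are rank-one PSD matrices whose
   diagonal carries each point's abnormality under kernel `j`.
4. **Fusion.** Three schemes produce the combined kernel:
   * *average*: `(1/m) Σ_j K_j`;
   * *entropy weighting*: `λ_j = E_j / Σ_l E_l`, where
     `E_j = Σ_{i,l} |K_j(x_i, x_l)|` is the K-entropy of the sample under
     `K_j`. These weights are the closed-form solution of the semidefinite
     program `max Σ λ_j E_j` subject to `Σ λ_j K_j ⪰ 0`, `Σ λ_j = 1`,
     `0 ≤ λ_j ≤ u_j` when the bounds equal the normalized entropies; kernels
     whose representation scatters the sample (large `E_j`, informative for
     outliers) are up-weighted;
   * *Karcher mean*: the Fréchet mean of the `K_j` on the SPD manifold under
     the affine-invariant metric `d_P(A,B) = ‖log(A^{−1/2} B A^{−1/2})‖_F`,
     i.e. the minimizer of `Σ_j d_P(X, K_j)²` and the unique SPD solution of
     `Σ_j log(K_j^{−1} X) = 0`.
5. **Detection.** The anomaly score is the combined kernel's diagonal (the
   squared feature-space norm); for linear schemes this is
   `Σ_j λ_j φ_j(x)²` and needs no n×n matrix. With contamination `ν` known a
   priori, the top `⌈νn⌉` training scores are flagged; the threshold (largest
   unflagged training score) transfers to test data via `score > threshold`.

### Detector choice

The score-threshold detector replaces an unspecified "modified one-class
SVM": the only tuning quantity the experiments use is the known contamination
`ν`, and flagging the top `ν` fraction makes the sensitivity/specificity
pair arithmetically consistent (`TN = N − (F − TP)` with `F = ⌈νn⌉`). A
standard one-class SVM on the precomputed combined kernel could be swapped
in, but would add a free parameter without changing the score ranking.

## Kernel bank

Default bank (11 kernels): Gaussians `exp(−σ‖x−y‖²)` with
`σ ∈ {10⁻³, 10⁻², 0.1, 1, 10, 50, 100, 500, 10³}`, the linear kernel, and
the degree-2 polynomial `(⟨x,y⟩ + 1)²`. Features are consumed as-is — no
internal standardization (a z-scoring flag can be added upstream by the
caller). Large-σ Gaussians saturate (`K → I`, all pairwise feature distances
→ √2), yielding uninformative constant features; this is expected and is
precisely what the entropy weighting down-weights.

Because `φ` scales with the kernel's feature-space diameter, kernels with
large output scale (the polynomial, for unstandardized data of scale ≳ 1)
dominate both the average and the entropy-weighted score. That reproduces
the benchmark behaviour where the combined detectors track the best single
kernel. The Karcher mean, being a geometric mean, is scale-balancing
instead of scale-dominated.

## SPD numerics

* **Ridging.** Anomaly kernels are rank one, hence singular; every manifold
  operation first adds `ε · (tr(K)/n) · I` with `ε = 10⁻⁶` (scale-aware,
  minimal perturbation making inverses and logs well-posed).
* **Karcher iteration.**
  `X ← X^{1/2} exp(θ · (1/m) Σ_j log(X^{−1/2} K_j X^{−1/2})) X^{1/2}`,
  initialized at the arithmetic mean. The plain step `θ = 1` oscillates on
  strongly ill-conditioned inputs (ridged rank-one kernels have condition
  numbers ~`1/ε`), so `θ` is halved — restarting from the best iterate —
  whenever the tangent-mean norm fails to decrease. Convergence is declared
  when that norm drops below `tol` (default `10⁻⁸`, relative to the first
  iterate's norm when it exceeds 1); `max_iter = 200` with a warning and the
  best iterate on failure. The report includes the residual
  `‖Σ_j log(K_j^{−1} X)‖_F`, computed exactly via the congruence identity
  `Σ_j log(K_j^{−1} X) = −X^{−1/2} (m T) X^{1/2}` with `T` the tangent mean.
* **Transductive Karcher evaluation.** The Karcher mean combines matrices,
  not kernel functions, so there is no out-of-sample extension operator. For
  train/test evaluation the anomaly kernels are built on train ∪ test points
  (features always computed relative to the training sample only), the mean
  is taken of the full matrices, and the threshold is calibrated on the
  training block. Cost is O(n³) per iteration in the combined sample size;
  beyond a few thousand points this is the method's practical cliff, and the
  benchmark driver exposes `include_karcher` to skip it.
* **Tie-breaks.** Score ties at the threshold are resolved by stable index
  order so the training flag count is exact and runs are deterministic.

## Functional data

Curves on a shared grid are smoothed by kernel ridge regression (representer
solution `(K + n γ I)^{−1} y` on the grid, `n` = grid size) and projected on
the leading eigenvectors of the smoother's grid Gram matrix — the empirical
(Nyström-style) surrogate for the eigenfunctions of the kernel integral
operator. Defaults: Gaussian smoother with `σ = 1/median²(pairwise grid
distance)`, `γ = 10⁻³`, 10 components. Eigenvector signs are fixed
deterministically. The detection pipeline consumes raw grid values by
default (the representation is opt-in via `PipelineConfig.representation`):
with equispaced grids the raw-value Euclidean geometry already reflects the
L² geometry of the curves, and the benchmark rates are computed on raw
values.

## Synthetic designs (what they emulate, and what not)

* **Functional mixture** (`simulate_functional`): inliers
  `X(t) = ξ₁ sin(πt) + ξ₂ sin(2πt) + ε(t)`, `ξ ~ N((1,2), I)`; outliers with
  coefficient mean `(4,5)`; contamination `ν = 0.1`; 30 equispaced grid
  points on [0,1]; `ε` a per-curve stationary AR(1) (marginal sd 0.3, lag-1
  correlation 0.5 — the mean shift dominates moderate noise choices, which
  are exposed as parameters). Exactly `⌊νn⌋` outliers; rows shuffled;
  bit-reproducible under a seed.
* **Conditionally normal bivariate** (`simulate_conditional_gaussian`):
  joint density ∝ `exp(−½(a x²y² + x² + y² − 2bxy))`, defaults `a = 1`,
  `b = 0.5`, Gibbs-sampled (burn-in 500, thinning 5) — the canonical
  conditionally-specified family with normal full conditionals; outliers
  from three unit-variance Gaussian clusters at distance ~5 from the mode.
  The published multivariate benchmark used an external model whose
  parameters are not recoverable, so numbers from this generator
  characterize *this* family, not that table.
* **Harmonic covariance study** (`simulate_harmonic`,
  `robustness_experiment`): noiseless `X(t) = ξ₁ sin t + ξ₂ cos t` on a
  50-point grid over [0,π], `ξ ~ N(0, [[0.75,−0.5],[−0.5,0.75]])`; 10
  replicates of 100 curves; per-replicate ML covariance of the projected
  coefficients (centered, divisor n). The stated anomalous covariance
  (7.5 diagonal, −10 off-diagonal) has eigenvalues 17.5 and −2.5 — not a
  covariance matrix as printed — and is projected to the nearest PD matrix
  (eigenvalue floor 10⁻³) with a logged warning before being appended.

None of the generators emulate heavy tails, missing grid points, irregular
sampling, or label noise; passing tests demonstrate correct mechanics and
behaviour under the stated Gaussian designs, not performance on real data.

## Problem sizes used by the shipped studies

The functional benchmark runs at its design size (4000 train / 2000 test
curves, 10 seeds); all linear-scheme quantities flow through the n×m feature
matrix, so this costs seconds per seed. The Karcher-vs-single-kernel
specificity study on the conditionally normal generator runs at n = 400 with
`tol = 10⁻⁶`: the property checked is a rank ordering of specificities, not
a scale-dependent value, and the transductive Karcher mean is cubic in n.
The covariance-robustness study runs at its design size (2×2 matrices; 20
seeds).

## Known limitations

* The mean-distance anomaly feature is a radial statistic: for kernels whose
  feature-space metric is (near-)Euclidean — the linear kernel and very
  narrow Gaussians — its ranking is bounded away from the optimum whenever
  the optimal decision boundary between the regular and outlier populations
  is not a sphere around the data centroid. On the shipped Gaussian-mixture
  benchmark this caps those single kernels several points below the
  quadratic (polynomial) kernel, whose feature space expresses the
  likelihood-ratio boundary much better; the fused detectors track the
  polynomial kernel.
* Entropy and average fusion inherit the feature scale of the base kernels;
  with unstandardized data a high-variance kernel can dominate. This matches
  the intended "track the best kernel" behaviour on the benchmarks but is a
  real sensitivity on arbitrary data.
* The Karcher scheme has no inductive out-of-sample rule (see above) and a
  cubic cost cliff around a few thousand points.
* `k_entropy` grows like n² for dense Gram matrices; weights on very large
  samples should use the rank-one shortcut
  (`entropy_weights_from_features`), which the pipeline does.
* The α-entropy is only ever computed through its k-NN estimator; no density
  estimation or partition-based entropy is attempted.
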
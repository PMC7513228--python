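# entrofuse

Entropy-weighted and Karcher-mean kernel fusion for one-class anomaly
detection on multivariate and functional data.

## The problem

Kernel-based outlier detectors stand or fall with the choice of kernel and
its hyperparameters, and in unsupervised settings there are no labels to
cross-validate against. `entrofuse` sidesteps model selection: it evaluates a
whole bank of Mercer kernels (a Gaussian width grid plus linear and
polynomial kernels by default) and fuses them into a single combined kernel
whose diagonal ranks points by abnormality. It targets practitioners —
biostatisticians and data analysts screening multivariate records or sampled
curves (e.g. emission profiles, density profiles, longitudinal measurements)
for atypical observations when a contamination fraction is known a priori.

## The method

For each base kernel `K_j` with induced feature-space metric
`d_j²(x,y) = K_j(x,x) + K_j(y,y) − 2K_j(x,y)`, the *anomaly feature*

    φ_j(x) = mean_i d_j(x, x_i)

is the average distance from `x` to the training sample in the kernel's
feature space — a local-entropy-style sparsity measure that is large off the
bulk of the data. The rank-one *anomaly kernels* `K_j = φ_j φ_jᵀ` are fused
by one of three schemes:

* **average** — `(1/m) Σ_j K_j`;
* **entropy** — `Σ_j λ_j K_j` with `λ_j = E_j / Σ_l E_l`, where
  `E_j = Σ_{i,l} |K_j(x_i, x_l)|` is the sample's *K-entropy* under `K_j`
  (the closed-form solution of the constrained weighting program that
  maximizes `Σ_j λ_j E_j`);
* **karcher** — the Karcher (Fréchet) mean of the `K_j` on the manifold of
  SPD matrices under the affine-invariant metric
  `d_P(A,B) = ‖log(A^{−1/2} B A^{−1/2})‖_F`, the geometric mean that
  respects the curvature of the SPD cone and is robust to anomalous
  members of the ensemble.

Scores are the combined kernel's diagonal; with contamination `ν` the top
`⌈νn⌉` training scores are flagged and the threshold transfers to new data.
Performance is reported as sensitivity (TPR), specificity (TNR) and ROC AUC.

## Worked example

```python
import numpy as np
from entrofuse import (FunctionalSimConfig, PipelineConfig,
                       run_detection, simulate_functional)

train = simulate_functional(FunctionalSimConfig(n=1000, nu=0.1, seed=7))
test = simulate_functional(FunctionalSimConfig(n=500, nu=0.1, seed=8))
res = run_detection(PipelineConfig(scheme="entropy", nu=0.1), train, test)

print(np.round(res.weights.lambdas, 4))
print(res.train.flags.sum())
mt, me = res.metrics_train, res.metrics_test
print(f"train: TPR {mt.tpr:.2f}  TNR {mt.tnr:.2f}  AUC {mt.auc:.2f}")
print(f"test : TPR {me.tpr:.2f}  TNR {me.tnr:.2f}  AUC {me.auc:.2f}")
```

prints

```
[0.     0.     0.     0.0001 0.0001 0.0001 0.0001 0.0001 0.0001 0.0022 0.9974]
100
train: TPR 95.00  TNR 99.44  AUC 99.93
test : TPR 90.00  TNR 99.56  AUC 99.80
```

The weight vector shows the K-entropy weighting at work: the last entry is
the degree-2 polynomial kernel, whose representation separates the shifted
outlier curves best and therefore absorbs almost all the weight; the very
narrow and very wide Gaussians contribute nothing. Exactly
`⌈0.1 · 1000⌉ = 100` training curves are flagged; about 95% of true outliers
are caught while 99.4% of regular curves are retained, and the ranking
quality (AUC ≈ 99.9%) carries over to the held-out split.

The same pipeline runs from the shell:

```sh
entrofuse simulate functional --n 1000 --seed 7 --out train.csv
entrofuse detect --train train.csv --functional --scheme entropy \
    --nu 0.1 --out-prefix run
entrofuse robustness --seeds 20 --out robustness.csv
```

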
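# fbnkit

Sparse low-rank functional brain networks, graph-based features, and
leave-one-out classification.

## The problem

Resting-state fMRI studies compare patients and controls through the
*functional brain network* (FBN): a graph whose nodes are atlas-parcellated
brain regions and whose edges are statistical dependencies between the
regions' time series. The most common edge estimate — pairwise Pearson
correlation — ignores the influence of all other regions, and classifiers
built on a single local measure of the network discard most of its
topology. `fbnkit` implements an alternative pipeline for two-group
classification from region×time matrices:

1. **Network construction.** For a subject's z-scored data matrix
   X ∈ ℝ^(t×m) (t time points, m regions), the connectivity matrix
   A ∈ ℝ^(m×m) solves

   ```
   min_A ‖X − XA‖²_F + λ₁‖A‖₁ + λ₂‖A‖*      s.t. diag(A) = 0,
   ```

   where ‖A‖* denotes the trace (nuclear) norm, the sum of singular
   values. Each region is represented by all the others: the ℓ1 penalty
   keeps only a few direct interactions per region (sparsity), and the
   trace norm pushes A toward low rank, i.e. a modular community
   organisation. The problem is solved by a two-split ADMM with
   soft-thresholding and singular-value-thresholding proximal steps.
   Pearson correlation and the pure-sparse model (λ₂ = 0) are included as
   baselines. A is then symmetrized, Ã = (A + Aᵀ)/2, its diagonal zeroed,
   and binarized (nonzero pattern for the regression models; strongest
   20% of correlations for Pearson).

2. **Graph features.** Eight measures per network: clustering coefficient,
   local efficiency, degree, betweenness centrality, participation
   coefficient, average neighbor degree (nodal, m values each) plus
   characteristic path length and global efficiency (global) — a feature
   vector of length 6m + 2 (698 for the 116-region AAL atlas).

3. **Selection and classification.** Features are ranked by the two-class
   Fisher score FS = [p₁(q₁−q)² + p₂(q₂−q)²] / (p₁σ₁² + p₂σ₂²); the number
   kept is chosen by inner leave-one-out accuracy on the training subjects;
   a linear SVM (C = 1) classifies the held-out subject. Accuracy,
   sensitivity and specificity are aggregated over leave-one-out folds.

Because clinical recordings of this kind are rarely shared, the package
ships a synthetic-cohort generator with planted block-modular covariance
and a controllable patient-vs-control difference, so every stage is
testable end to end.

## Worked example

```python
import fbnkit

spec = fbnkit.CohortSpec(
    n_patients=15, n_controls=15, m=16, t=134, n_modules=4,
    within_corr=0.6, between_corr=0.05, group_effect=0.5, seed=7,
)
subjects, labels = fbnkit.generate_cohort(spec)

res = fbnkit.SparseLowRankFBN(subjects[0], lam1=20, lam2=10).fit()
print(res.summary())

report = fbnkit.loocv_evaluate(
    subjects, labels, model="sparse_lowrank",
    params={"lam1": 20, "lam2": 10}, candidate_counts=[3, 5, 10],
)
print(report.summary())
```

prints

```
Connectivity results  [sparse_lowrank]
  subject:        patient_000
  regions:        16
  params:         {'lam1': 20.0, 'lam2': 10.0}
  symmetrized:    False
  nonzero off-diag: 105 / 240 (0.438)
  solver iters:   814 (converged=True)
  objective:      1340.74
  residuals:      primal=2.46e-05, dual=5.69e-06
LOOCV evaluation  [sparse_lowrank]
  folds:        30
  confusion:    TP=14 TN=12 FP=3 FN=1
  accuracy:     86.67%
  sensitivity:  93.33%
  specificity:  80.00%
  median selected features: 3
```

Each of the 30 subjects was held out once; with the strong planted module
reassignment the pipeline recovers the group labels well above the ~50%
chance level of a null cohort. The same pipeline is available from the
shell via the `fbnkit` command (`simulate`, `fbn`, `features`, `evaluate`,
`grid`, `report` subcommands).

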
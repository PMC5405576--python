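# Methods

## Network models

For one subject the data are a t×m matrix X (t time points, m regions);
every column is z-scored to mean 0 and unit *population* standard
deviation before model fitting, so penalty weights are comparable across
subjects (Pearson correlation is unaffected by this).

Three connectivity estimators are provided:

* **Pearson** — entry (i, j) is the correlation coefficient of regions i
  and j. Dense by construction; networks are formed by keeping the
  strongest fraction of entries by absolute value (default 20%, ties
  broken deterministically by ascending (row, column) index).
* **Sparse representation** — min ‖X − XA‖²_F + λ‖A‖₁, diag(A) = 0.
  Each region is regressed on all others with an ℓ1 penalty; the nonzero
  pattern of the symmetrized coefficient matrix is the network.
* **Sparse low-rank** — adds λ₂‖A‖\* (trace norm). The trace norm is the
  convex surrogate for rank; a low-rank coefficient matrix concentrates
  connectivity into a few latent components, i.e. a modular network.

The zero-diagonal constraint is exactly the "represent region i by all
*other* regions" convention: the per-column problem with column i removed
from the dictionary is identical to the full-matrix problem with a_ii
fixed at 0.

### Solver

The objective is convex with two nonsmooth terms, so it is solved with a
two-split consensus ADMM: auxiliary copies B (ℓ1 + zero diagonal; prox =
entrywise soft-threshold, then zero the diagonal) and C (trace norm; prox
= singular-value threshold), constraints A = B and A = C. The A-update is
a ridge least-squares solve by cached Cholesky factorisation. Stopping
uses combined absolute/relative primal and dual residual tolerances
(both 1e−6), with an iteration cap of 2000 and residual balancing: when
the primal and dual residuals differ by more than 10×, the penalty ρ
(initial 1.0) is doubled or halved and the scaled duals rescaled. This
keeps convergence fast across the λ range without changing the fixed
point. The sparse iterate B is returned as the estimate because its exact
zeros and zero diagonal are what the nonzero binarization consumes. A run
that hits the cap returns its best iterate, warns, and records
`converged=False` in the solver report; exit residuals in such cases are
typically ~1e−5 and the objective is optimal to well below test
tolerance.

A note on rank: with the zero-diagonal constraint, the optimum stays at
full numerical rank for small λ₂ — the diagonal zeros prevent the matrix
from collapsing onto few components — and rank deficiency appears only
once singular-value shrinkage actually binds (λ₂ of the order of the
leading singular values of the unpenalised solution). The test suite
demonstrates strict rank reduction in that regime and rank monotonicity
in λ₂ everywhere.

## Graph features

Networks are undirected, unweighted, zero-diagonal. Standard measures
(clustering, shortest paths, betweenness, greedy modularity communities,
Newman Q) are computed with networkx; participation coefficient, average
neighbor degree and the feature assembly are implemented here. All eight
are validated against brute-force enumeration oracles on small graphs.

Conventions for degenerate cases, chosen to keep every feature finite and
in its natural range:

* clustering and local efficiency are 0 for nodes of degree < 2;
* participation coefficient and average neighbor degree are 0 for
  isolated nodes;
* characteristic path length averages over *reachable* ordered pairs
  only; on an edgeless graph it is undefined (NaN, flagged) and encoded
  as 0.0 inside feature vectors so classifiers receive finite inputs;
* global efficiency uses 1/∞ = 0 and needs no special casing.

Betweenness uses the 1/((n−1)(n−2)) ordered-pair normalisation, under
which a star center scores exactly 1; this coincides with the standard
normalised undirected definition.

The module partition for the participation coefficient is computed *per
subject* by deterministic greedy (Clauset–Newman–Moore) modularity
agglomeration, with communities relabelled by smallest member for
reproducibility; edgeless graphs fall back to singleton modules. A single
cohort-level partition would be the alternative; per-subject partitions
require no group information and keep the feature a function of one
subject's network alone.

Feature-vector layout (length 6m + 2): nodal blocks in the fixed order
clustering | local efficiency | degree | betweenness | participation |
average neighbor degree, then [characteristic path length, global
efficiency]. The order is a package convention — only the total length is
canonical — and is what makes selected-feature indices interpretable.

## Selection and classification

The two-class Fisher score uses class counts and population variances;
features with zero pooled variance but separated means get an infinite
score and rank first, ties break by ascending index. The score is
invariant to affine rescaling of a feature, so no feature normalisation
is needed at the ranking stage.

The retained-feature count is chosen per outer fold by *inner*
leave-one-out accuracy over the training subjects, smallest count winning
ties; the default candidate grid is 1…150. The classifier is a linear SVM
with C = 1 behind a pluggable factory; features are standardised on
training-fold statistics inside a pipeline so no statistic of the
held-out subject leaks into training (a mutation test corrupts the
held-out row and asserts the fold's selection is unchanged).

Two grid-search protocols over (λ₁, λ₂) are exposed and documented as
distinct: the accuracy *surface* scored on the outer folds (the
figure-style protocol, optimistic because the pair is picked on the same
folds it is scored on) and a fully nested mode in which each outer fold
picks its own pair by inner cross-validation.

Reported metrics: accuracy, sensitivity (patient detection rate),
specificity (control detection rate), each ×100 rounded to 2 decimals; a
zero denominator reports the metric as undefined rather than 0.

## Synthetic cohorts

The generator emulates two groups of multivariate Gaussian time series
whose region-wise correlation matrix is block structured: `within_corr`
(default 0.6) inside modules, `between_corr` (default 0.1) across, unit
diagonal. This matrix is positive semidefinite by construction whenever
0 ≤ between < within < 1 (shared-factor plus idiosyncratic decomposition);
a 1e−8 diagonal ridge guards the Cholesky factorisation. Sampling is
`Z @ L.T` plus additive white measurement noise of standard deviation
`noise_sd` (default 0.1), which attenuates all correlations by
1/(1 + noise_sd²) ≈ 1% at the default — small enough that empirical block
correlations converge to their targets at large t.

The group difference defaults to *module reassignment*: a fraction
`group_effect` of regions (default 0.25; 0.5 in the strong-effect test
conditions, 0 in null calibrations) moves to the cyclically next module
in the patient group, as one fixed alternative architecture shared by all
patients. The scheme is deliberately deterministic rather than randomly
drawn: a random reassignment can land on a size-preserving permutation of
near-identical modules, and because most graph features are symmetric
under module relabelling, such a perturbation is nearly invisible to the
pipeline — the effective effect size would then be a lottery over seeds.
The cyclic move changes both memberships and module sizes by an amount
that grows steadily with `group_effect`, altering network *topology*
without inventing edge-level effect sizes — the original clinical data
give none. An alternative `corr_delta` mode raises the patients'
within-module correlation instead.
Default group sizes (31/29), m=116 and t=134 mirror the reference study
design.

What the generator does **not** emulate: hemodynamic autocorrelation,
scanner drift and motion artifacts, spatially heterogeneous noise,
inter-subject variability in module layout, and non-Gaussian tails.
Passing tests therefore show the pipeline recovers planted covariance
structure under idealised sampling — not that it would achieve any
particular accuracy on clinical recordings.

## Problem sizes used in tests and the acceptance script

Structural checks (feature length, fold structure) run at full scale
(m=116, t=134, 60 subjects) with the fast Pearson model. Solver-oracle
comparisons use 20 seeded instances at m ≤ 10, where the independent
Davis–Yin and coordinate-descent references are cheap and tight.
Modularity comparisons use m=24 cohorts of 4 subjects over 5 seeds, with
the pure-sparse baseline's λ bisected per subject to match the sparse
low-rank network's density. Classification calibration uses 40 subjects
at m=30 with penalties (λ₁=20, λ₂=10) chosen so the binarized networks
sit near 50% density, where the graph features are informative; the null
band is the central 99% binomial interval around 0.5. These sizes keep
the full suite to a few minutes while leaving every code path exercised
at atlas dimensionality somewhere in the suite.

## Known limitations

* Leave-one-out accuracy under null conditions is pessimistically biased
  (the held-out subject's class is always underrepresented in training).
  For null *cohorts* the bias stays well inside the 99% binomial band at
  the calibration scales used here, but under literal label *permutation*
  on strongly clustered features it can push accuracy below the band —
  binomial bands are approximations for LOOCV fold outcomes, which are
  not independent Bernoulli trials.
* The ADMM returns ε-accurate iterates; "nonzero" binarization therefore
  treats |entries| ≤ 1e−10 as zero, and numerical rank statements use a
  1e−6 relative singular-value tolerance.
* The full 50×50 (λ₁, λ₂) surface at atlas scale is computationally
  heavy (2500 leave-one-out runs); the CLI exposes it, but studies at
  desk scale should use reduced grids or the nested mode on reduced
  cohorts.
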
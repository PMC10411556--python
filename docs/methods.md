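# Methods

This note documents the models implemented in `qmtsvr`, the choices made
where the design was genuinely open, and what the synthetic data used by
the test suite can and cannot establish.

## Quasi multitask SVR

### Data expansion

The multitask extension does not solve a true multi-constraint
multitask dual (which would require a generalized SMO handling t
equality constraints at once). Instead, records of t traits are
standardized per trait and stacked into one response vector, and the
kernel is replaced by the block matrix Q. The bias b₀, the
regularization constant C and the tube width ε are shared across
traits, so a single equality constraint `Σ(α−α*) = 0` applies and the
standard SMO machinery carries over. A stacked formulation with one
constraint per trait would be inconsistent with a shared bias; the
single-constraint reading is implemented.

"Standardized to the same scale" is implemented as a per-trait z-score
using statistics of the *training rows only*. A min–max scaling would
also equalize scales, but the z-score keeps a shared ε and C meaningful
across traits (a residual of ε means the same number of SDs everywhere)
and is invariant to the affine scale of each trait. Using training-row
statistics (rather than all available records) avoids leaking test-set
information into CV1 predictions; the test suite verifies that
perturbing test phenotypes leaves CV1 output bit-identical.

Rows are stacked trait-major (all records of trait 1, then trait 2, …).
Individuals missing a record for a secondary trait simply contribute no
row for that trait; missing *target*-trait records in the training set
are an error, because the designs are defined by which target records
exist.

### The block kernel Q

Block (k,k′) of Q is `ρ_kk′ · exp(−θ_kk′ · d²_ij / s)`, where d² is the
squared Euclidean distance between marker dosage vectors and s is the
scale (p for the plain kernel, Σ_l w_l for a weighted one). Squared
distances are stored directly — no square-root round trip — and the raw
0/1/2 coding is used, since pairwise differences are invariant to any
per-column centering. Missing genotypes are mean-imputed per SNP before
distances are taken; this preserves expected distances under
missingness at random and is the standard low-cost choice. The distance
matrix is computed once over all genotyped individuals and subset
downstream, so train/test blocks are always mutually consistent.

Q with arbitrary (θ, ρ) need not be positive semidefinite. Before
fitting, the smallest eigenvalue is checked; if it falls below −1e−8,
`|λ_min| + 1e−8` is added to the whole diagonal. Diagonal jitter (rather
than eigenvalue clipping) preserves the off-diagonal distances the
method is built on, costs one eigendecomposition, and the applied
amount is recorded on the results object. θ must be symmetric positive
and ρ symmetric with unit diagonal and |ρ| ≤ 1; both are enforced at
construction.

### Hyperparameters

| parameter | meaning | default search interval |
|---|---|---|
| C | penalty on residuals beyond the ε-tube (response-SD units⁻¹) | [0.1, 4] |
| ε | half-width of the insensitivity tube (response SDs) | [1e−4, 0.1] |
| θ_kk | within-trait RBF bandwidth (per unit scaled distance) | [0.2, 7] |
| θ_kk′ | between-trait bandwidth | [0.2, 7] |
| ρ_kk′ | between-trait association constant | [0.1, 0.3] |

For t traits this is a 2 + t² dimensional space (6-D for a trait pair);
fixing ρ a priori (e.g. at a known genetic correlation) removes the
t(t−1)/2 association constants and leaves the t(t+1)/2 bandwidths plus
C and ε.

## The SMO solver

The dual is solved in net-multiplier form β = α − α* (valid because
α_i α*_i = 0 at any optimum), i.e. minimize
`½βᵀKβ − yᵀβ + ε‖β‖₁` subject to `Σβ = 0`, `|β_i| ≤ C`. Each iteration:

1. From the KKT conditions every row i admits an interval
   [b_lo_i, b_hi_i] for the shared bias. The working pair is the row
   forcing the largest lower bound against the row forcing the smallest
   upper bound (maximal violating pair); ties break at the lowest index,
   making the solver deterministic.
2. The two-variable subproblem along β_i + δ, β_j − δ is a piecewise
   quadratic (breakpoints where a multiplier crosses zero); it is
   minimized exactly by evaluating the per-sign-pattern stationary
   points, the breakpoints, and the box ends. The dual objective is
   therefore monotone.
3. Convergence is declared when max b_lo − min b_hi ≤ tol
   (default 1e−3, in standardized response units). b₀ is the mean
   implied bias over free support vectors, or the midpoint of the
   feasible bias interval if none are free.

ε = 0 is allowed (the L1 term vanishes). Degenerate pairs with zero
curvature fall back to endpoint evaluation; a stalled solver raises an
error carrying the best iterate and its violation. The solver is
validated against scikit-learn's precomputed-kernel SVR and against a
generic QP solution of the (α, α*) dual (SLSQP with analytic gradient);
objectives agree to ~1e−13 relative and multipliers to ~1e−6 on random
instances.

## SNP (co)variance weights

Per-SNP allele-substitution effects δ_lk are estimated one locus at a
time by OLS of all traits on [1, dosage_l, PC₁..PC₃₀], where the PCs are
eigenvectors of the genomic relationship matrix scaled by √eigenvalue
(sign-fixed deterministically). Since the design is shared across
traits, equation-by-equation OLS equals the multivariate-regression
point estimates; the implementation residualizes dosages and traits
against [1, PCs] once (Frisch–Waugh) so all p regressions reduce to
simple-regression slopes. The weight of locus l for pair (k,k′) is
`|2(1−q_l)q_l δ_lk δ_lk′|` max-normalized over loci, giving t(t+1)/2
weight vectors in [0, 1] with the top locus at exactly 1. Effects,
allele frequencies and PCs are computed on training individuals only,
and once per training set (not per GA fold) — refitting inside each GA
candidate would multiply cost ~750-fold for no change in ranking, since
every candidate sees the same weights. Degenerate (monomorphic) loci
get δ = 0 and hence weight 0 rather than being dropped, keeping locus
indexing aligned.

## Genetic-algorithm tuning

Chromosomes are fixed-point binary encodings, 8 bits per parameter
(resolution ≈ 0.4% of each interval; finer resolution would slow mixing
with no practical gain, and the encoding detail is exposed via
`ParamSpec.n_bits`). Defaults NG = 30, PS = 25, CR = 0.9, MR = 0.05,
tsize = 4. Per generation: evaluate all PS candidates (a by-bits cache
serves duplicates without altering the PS × NG accounting), create PS
children by two tournaments + two-point crossover + per-bit mutation,
then replace the v worst children with the v best of the previous
generation. The elite count v defaults to 1, the smallest value that
guarantees a monotone best-so-far trajectory. Fitness is the Pearson
correlation between observed and predicted target-trait values in
inner-validation generations carved out of the training data (the
analogue of tuning on the most recent generations before the test
ones); solver failures and degenerate correlations map to fitness −1.
The inner-validation generations are configuration, not hard-coded,
since the boundary between "train until" and "validate on" is a
modelling choice. Identical seed and configuration replay the identical
history; best-candidate ties break toward smaller C, then smaller
chromosome integer.

## Bayesian kernel mixed models

Single-trait: y = 1μ + u + e with u ~ N(0, K σ²_u), e ~ N(0, I σ²_e),
scaled-inverse-χ² priors on both variances (df = 5, scale set so the
prior mean of each variance is half the phenotypic variance — weakly
informative and symmetric between signal and noise). Multi-trait:
matrix-normal U with row covariance K and column covariance Σ_u,
inverse-Wishart priors (df = t + 3, diagonal scale matched the same
way). GBLUP and RKHS are one code path — only the kernel argument
differs (G vs RBF).

Sampling exploits the spectral decomposition K = VΛVᵀ, computed once:
rotating records by Vᵀ de-correlates the genetic effects so the U
update factors into independent t × t systems per eigen-component,
batched across components. Eigenvalues are floored at 1e−8 (singular
kernels are jittered and the amount logged). Missing data:

* rows with *no* observed trait never enter the likelihood; their
  genetic values are predicted afterwards as K_cross K⁻¹ E[U] —
  this is how CV1 test individuals are handled;
* rows with a *partially* observed trait vector (CV2 test individuals)
  have their missing entries drawn each iteration from the conditional
  Gaussian given the observed entries. Conditioning on observed entries
  only, without this augmentation, would destroy the inverse-Wishart
  conjugacy of the Σ_e update; the augmented sampler is the exact
  conjugate Gibbs scheme for the same posterior.

The reference chain length is 20,000 iterations with 5,000 burn-in and
thinning 5; the test suite runs scaled-down chains (1,500–4,000
iterations) chosen so posterior means are stable to well within the
tolerances being asserted.

ACCpar is computed by fitting the bi-trait model to (observations,
predictions) on the *test set only* with the GRM as kernel (the kernel
is configurable; G is the default because the quantity being estimated
is an additive-genetic correlation). Each retained draw yields
√h²(predictions) × r_g. λACC contrasts pair two independent chains by
draw index — the marginal distribution of the difference is unaffected
by the pairing, and no joint model of two fitted prediction vectors is
attempted.

## Synthetic populations

`simulate_population` emulates a closed nucleus line: generation-0
genotypes are binomial(2, q) with q ~ U(MAF range), and each later
generation is bred by random mating (optionally truncation selection on
trait 1) with per-SNP Mendelian gamete sampling, which induces drift
and family structure. A set of QTL (default min(100, p/2) — polygenic,
in line with the trait architectures the method targets) receives
per-trait effects from a multivariate normal whose correlation is the
target genetic correlation. Genetic values are rescaled so realized
h² matches the target exactly in-sample; residuals carry the requested
residual correlation; phenotypic variance is 1 per trait. Default
parameters describe a carcass-type target with a growth-type indicator:
h² = (0.56, 0.34), r_g = 0.23, r_e = 0.47. Reliabilities are drawn
uniform on (0.5, 0.95): their only roles here are as a QC threshold and
as the ACC denominator, so a PEV-based reliability model is not
reproduced.

What the generator does **not** emulate: overlapping generations,
linkage maps and realistic LD decay (SNPs are exchangeable), deregressed
proofs (responses are plain phenotypes, not de-regressed EBVs),
genotyping error, and non-random missingness (missing genotypes are
injected uniformly). Passing tests therefore demonstrate the internal
correctness and the qualitative behaviour of the methods (e.g. the CV2
advantage under strong genetic correlation), not field performance on
real breeding data.

## Numerical and testing choices

* Multipliers within 1e−12 of a box bound are snapped to it; RBF
  diagonals are set to exactly 1.
* Weight symmetry: the (k,k′) product is always taken in sorted trait
  order so weights for (k,k′) and (k′,k) are bit-identical.
* The ACCpar recovery check constructs predictions as TBV of a
  genetically correlated trait (r_g = 0.8) plus noise with
  h²_û = (0.7/0.8)², giving a true parametric accuracy of 0.7 strictly
  inside the parameter space. Building them from the target trait's own
  TBV would place the estimand at the r_g = 1 boundary, where the
  posterior mean of a correlation is necessarily biased downward and
  the check would measure boundary shrinkage rather than recovery.
* Problem sizes in the test suite: SMO oracle checks at n ≤ 50 (50
  instances); GA runs at N = 120, p = 300 (one full 750-candidate run);
  mixed-model recovery at N = 500, p = 600 over 5 seeds with
  2,000-iteration chains; the CV2-vs-ST comparison at N = 400, p = 500
  over 20 seeds. These sizes make the full suite complete in about a
  minute while keeping Monte-Carlo error small relative to every
  asserted tolerance.

## Known limitations

* The true multitask SVR with t simultaneous equality constraints is
  intentionally out of scope; QMTSVR shares C, ε and b₀ across traits.
* t > 2 is supported by the data structures and kernel assembly, but
  only trait pairs are exercised by the shipped tests.
* The GA is a heuristic; it does not certify global optimality, and the
  smooth-landscape convergence test documents typical, not guaranteed,
  accuracy.
* RMSE\* is defined as RMSE divided by the SD of the observed test
  values. A variance denominator would make the statistic
  dimension-dependent and inconsistent with its interpretation as a
  fraction of phenotypic spread.
* Spike-and-slab (BayesC-type) benchmarks and pedigree-based EBV
  machinery (AIREML, deregression) are not implemented; the simulator
  supplies response variables directly.
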
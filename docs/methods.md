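# Methods

## Model

Let `K` be the union of `m` genotype subsets `a_1, …, a_m` (n genotypes in
total) and let `G_a` be the relationship/covariance matrix observed on
subset `a` — a marker GRM, a pedigree A-matrix block, or a phenotypic
correlation matrix.  Each observed matrix is modeled as an independent
Wishart draw

    G_a ~ W(nu, Psi_a),    Sigma = nu * Psi,    E[G_a] = Sigma_a,

so the scale matrix `Psi` carries the combined relationship `Sigma` over
all of `K` and `nu` acts as the effective number of features behind each
kernel.  This parameterization is fixed by internal consistency: it is the
only one under which the EM fixed point for a fully observed sample is
`Sigma = G` and the estimate is invariant to `nu` (see below).

Assumptions worth stating explicitly:

* samples are independent given `Sigma` and share one `nu` (per-sample
  reliability is handled by the weighting scheme, not by per-sample
  degrees of freedom);
* entries are missing at the genotype-subset level (whole rows/columns),
  and the subset membership is unrelated to the values — a missing
  at-random assumption.  Panels chosen *because* of their relationships
  would bias the estimate;
* each `G_a` is positive (semi-)definite.  Indefinite inputs can be
  repaired with `kernels.ensure_psd`, which is offered but never applied
  silently.

## EM iteration

With `b = K \ a`, `B = Psi_ba Psi_a^{-1}` and
`Psi_{b|a} = Psi_b − Psi_ba Psi_a^{-1} Psi_ab`, each sample is completed
to a full `n × n` matrix by its conditional expectation under the current
model,

    [ G_a     G_a B' ]
    [ B G_a   nu * Psi_{b|a} + B G_a B' ]

aligned to `K` through integer index maps (mathematically the permutation
matrices of the estimator, without the `O(n^2)` products), and the update
averages the completions: `Psi^(t+1) = (1/(nu m)) Σ_a P_a [·] P_a'`.

Written in `Sigma = nu Psi` coordinates every appearance of `nu` cancels,
which is why the estimate does not depend on it; `nu` only scales the
curvature of the likelihood.  The package still exposes `nu` because the
log-likelihood (and any future standard-error work) needs it; the default
is the mean of the samples' recorded feature counts, else 1000.

* **Initialization** `Sigma^(0)`: identity by default (uninformative); any
  symmetric positive-definite matrix covering the union can encode prior
  knowledge.  Genotypes carried only by an explicit prior matrix remain in
  the union and are completed by conditioning — this is precisely the
  single-step H-matrix use-case, where `Sigma^(0) = A` (full pedigree) and
  a single nested genomic `G` is the only sample: one iteration then
  reproduces the closed form `H_22 = G`, `H_12 = A_12 A_22^{-1} G`,
  `H_11 = A_11 + A_12 A_22^{-1}(G − A_22)A_22^{-1}A_21` exactly
  (`combine.hmatrix_oracle`, asserted to 1e-10 in the tests).
* **Convergence**: relative Frobenius change of `Psi` below `tol`
  (default 1e-6), capped at `max_iter` (default 200) with an explicit
  non-convergence flag and warning.  With weak overlap the EM converges
  linearly (rate 1/2 for fully disjoint samples), so tight targets need
  smaller `tol`, not more faith.
* **Weighting**: a sample with weight `w` contributes
  `w G_a + (1−w) nu Psi_a^(t)` in place of `G_a` each iteration — full
  trust at `w=1`, pure model at `w=0`.  The likelihood trace is computed
  on the raw observations, so EM monotonicity is only guaranteed at unit
  weights.
* **Numerics**: block inversions go through Cholesky solves, never
  explicit inverses.  Factorizations are attempted *unregularized* first;
  a ridge of `jitter × mean diagonal` (default 1e-8, escalating ×100
  steps) is added only on failure.  This keeps exact algebraic identities
  (H-matrix equivalence, fixed points) at machine precision while
  remaining robust on rank-deficient blocks.  Observed GRMs centered at
  their own allele frequencies are exactly singular, so the constant
  `log|G_a|` term of the likelihood uses an escalating ridge too; being
  constant per sample it cannot affect the monotonicity of the trace.
  The trace is asserted non-decreasing with slack `1e-8 × (1 + |loglik|)`
  — a relative slack, since absolute 1e-8 is below float resolution for
  log-likelihoods of magnitude 1e3–1e4.
* **Correlation matrices**: combining trait-correlation matrices from
  phenotypic trials uses the same machinery; the result is a covariance-
  scale matrix and is *not* re-standardized by default — apply
  `kernels.cov2cor` to the output when a correlation matrix is wanted.

## Kernels

* `grm_vanraden`: `G = ZZ'/(2 Σ p_j(1−p_j))`, `Z = M − 2p`, allele
  frequencies observed per panel (panel-specific, not global, when
  multiple panels are processed — each panel is an independent
  experiment), per-marker mean imputation of missing dosages, monomorphic
  markers dropped.  Diploid only; tetraploid dosage files are accepted at
  the I/O layer but no autotetraploid kernel is implemented.
* `amatrix_tabular`: the standard recursive method on a topologically
  sorted pedigree; founders unrelated and non-inbred; unknown parents
  contribute zero.  Validated against gene-drop Monte-Carlo realized
  relationships (unbiased when centered at the true founder frequencies,
  which the simulator exposes) within 3 standard errors.

## Mixed-model prediction

The prediction model is `y = 1μ + g + e`, `g ~ N(0, σ_g² K)`,
`e ~ N(0, σ_e² I)`, fitted by REML:

* single kernel: profile the restricted likelihood over
  `λ = σ_g²/σ_e²` on the spectrum of `K` restricted to the orthogonal
  complement of the intercept (one eigendecomposition + bounded 1-D
  search on `log10 λ` over ±12 decades; residual variance profiled
  analytically).  A kernel proportional to the identity on the contrast
  space leaves `λ` unidentifiable and is rejected with an explicit error.
* several kernels: EM-REML updates
  `σ_k² ← σ_k² + (σ_k⁴/n)(y'P K_k P y − tr(P K_k))` (guaranteed uphill,
  robust far from the optimum) followed by an L-BFGS polish of the
  restricted likelihood in log-variance coordinates, because plain
  EM-REML's linear convergence cannot deliver the 1e-6 agreement with the
  spectral route that the test-suite demands.  Negative components are
  clamped at zero.
* GEBVs: `ĝ = λK(λK + I)^{-1}(y − μ̂)` on the training set;
  unphenotyped genotypes get the kernel conditional mean
  `K_21 K_11^{-1} ĝ` (per kernel, summed, for multi-kernel fits).
* accuracy: Pearson correlation of GEBVs with observed phenotypes, per
  random fold (pooled over folds as well) or per held-out dataset.  A
  constant prediction vector (e.g. a dataset with zero kernel connection
  to the training set) has undefined correlation; the harness reports 0
  with a warning, which matches its information content.
* `h2` is reported as `σ_g²/(σ_g² + σ_e²)`; kernels are used as given, so
  this equals the trait heritability only when the kernel's mean diagonal
  is ≈1 (true for VanRaden GRMs and for the phenotype simulator, which
  standardizes the kernel to mean diagonal 1).

## Synthetic data: what it emulates, what it does not

All generators are deterministic given a seed.

* `simulate_markers`: independent biallelic loci, dosages
  `Binomial(2, p_j)`, `p_j ~ U(maf_range)` — an unstructured panel.
* `simulate_structured_markers`: Balding–Nichols subpopulations
  (ancestral `p`, subpop frequencies `Beta(p(1−F)/F, (1−p)(1−F)/F)`)
  optionally with full-sib families inside each subpopulation (two
  Hardy–Weinberg parents per family, offspring by Mendelian sampling).
  Diversity panels of the kind the combiner targets carry both
  components: low-rank subpopulation blocks *and* high-rank cryptic
  relatedness.  The family component matters for evaluation: with an
  unstructured truth the unobserved relationships are ≈0 and any method
  (including doing nothing) scores well.  Defaults used in the
  experiments: 3 subpopulations, Fst 0.2, families of 5.
* `simulate_pedigree_genedrop`: random-mating pedigree, alleles dropped
  per locus; the true founder frequencies ride along on the marker matrix
  for unbiased oracle centering.
* `sample_wishart_partials`: exact `W(nu, Sigma_a/nu)` draws per design
  subset (Bartlett decomposition via scipy).  Drawing each block directly
  is identical in distribution to restricting a full draw, by the
  marginal-block property of the Wishart.
* Not emulated: linkage disequilibrium, genetic maps, selection,
  genotyping error, non-random missingness.  None of the asserted
  properties depend on them, but it means passing tests say nothing about
  LD-driven artifacts or informative missingness in real panels.

## Experiment harnesses and problem sizes

* **Anchoring** (`run_anchor_experiment`): one simulated pedigree
  (founders = group size, 3 generations, 2 offspring per cross) is split
  into two disconnected groups whose A-matrix blocks are two samples; a
  GRM on a genotyped subsample (half from each group) bridges them; the
  combined estimate is scored against the full-pedigree A on entries
  observed in no sample.  Default scale for validation: 100 genotypes per
  group, 10/20/40 genotyped per group, 2000 markers, 20 replicates —
  mean correlation rises monotonically with the number of anchors.
* **Combining vs. imputing** (`run_combine_vs_impute`): ground truth is
  the GRM of a structured panel (300 genotypes × 5000 markers); 20
  sub-panels of 100 genotypes × 500 markers are drawn at random; route
  one combines the sub-GRMs, route two soft-imputes the union
  genotype×marker matrix and builds a single GRM.  Scored against the
  truth over all upper-triangle entries (including the diagonal) and over
  never-observed entries.  The harness's own numerical defaults are EM
  `tol 1e-5`, `max_iter 150`: with many overlapping samples the EM's late
  iterations only add shrinkage toward the maximum-likelihood point
  without improving the truth error, so a moderate tolerance is the right
  operating point at this scale.  At this desk scale the union panel
  covers ~88% of the truth markers (versus ~10% in a full-size design),
  which makes the imputation route far more competitive than at full
  scale: combining wins on the full-matrix comparison (mean MSE ≈0.0014
  vs ≈0.0015, 17/20 replicates), while on the never-observed subset the
  low-rank fill is closer — a scale artifact worth remembering when
  extrapolating these numbers.
* **Recovery curve**: a known 50-genotype covariance (structured GRM +
  0.05·I ridge), 15-genotype random subsets drawn prefix-nested so the
  validation set (pairs co-observed in none of the 40 subsets) is fixed
  per seed; unobserved-entry MSE falls strictly through m = 3, 5, 10,
  20, 40 (mean over 20 seeds).
* `soft_impute`: iterative soft-thresholded SVD with observed entries
  restored each pass; rank capped at `min(50, dims)`, shrinkage `λ`
  chosen by a 5%-holdout grid {0, 5, 20} on the first replicate and
  reused (logged in the report parameters); dense LAPACK SVD below 600
  rows, ARPACK above.  Imputed dosages are clipped to `[0, ploidy]`.

## Known limitations

* No asymptotic standard errors for the combined estimate, and `nu` is
  never estimated from data.
* PSD of the combined estimate is an empirical observation (asserted to
  −1e-6 minimum eigenvalue on the test distribution), not a proved
  invariant of the iteration for arbitrary indefinite inputs.
* Fixed-effect structure in prediction is intercept-only; trials, years
  or environments must be pre-adjusted.
* The tabular A-matrix is diploid; autopolyploid pedigrees are out of
  scope.
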
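# Methods

## The model

For a cohort of n individuals with phenotype `y`, fixed effects `F`
(an intercept always, user covariates optionally), a confounder design `W`
(n x k_w standardized SNP dosages) and a tested set `V` (n x k_v standardized
SNP dosages), the phenotype covariance is modelled as

    Sigma(tau, delta) = sigma_g^2 [ (1 - tau) K_w + tau K_v + delta I ],
    K_w = W W' / k_w,   K_v = V V' / k_v,

the realized-relationship normalization for both kernels.  `tau in [0, 1]`
is the share of genetic variance attributed to the tested set and
`delta = sigma_e^2 / sigma_g^2` the residual-to-genetic variance ratio.  The
set test compares the restricted maximum likelihood at `tau = 0` (null) with
the maximum over `0 <= tau <= 1` (alternative); the statistic is twice the
difference, clipped at zero.  REML rather than ML is used throughout: the
fixed-effect design is identical under both hypotheses, so the restricted
likelihood is a valid likelihood for the ratio test, and variance components
are estimated without the fixed-effect bias of ML.

The convex-combination parameterization (rather than two free variances)
makes `tau` the single tested parameter with a box constraint, which is what
the boundary-null machinery below assumes, and puts both kernels on the same
trace scale so that `tau` is interpretable as a variance share.  Kernel
normalization by SNP count follows the realized-relationship convention;
constant (monomorphic after imputation) columns are dropped before
standardization, and a set whose columns are all constant is reported as
degenerate with statistic 0 and P = 1.

## Linear-time restricted likelihood

Writing `X(tau) = [sqrt((1-tau)/k_w) W, sqrt(tau/k_v) V]` (n x k,
k = k_w + k_v), the covariance is `sigma_g^2 (X X' + delta I)`.  All
quantities in the restricted likelihood - the log-determinant, the GLS
system for beta, the residual quadratic form, and log det(F' Sigma^-1 F) -
depend on the data only through the spectrum of `X X'` and the projections
of `y` and `F` onto its eigenvectors.  The implementation computes, once per
(set, permutation), the Gram blocks `W'W, W'V, V'V, X'y, X'F` in O(n k^2),
and then obtains the spectrum for any `tau` from the k x k matrix
`D(tau) C'C D(tau)` (C = [W, V], D diagonal) in O(k^3).  Eigenvalues below
`max(lambda_max * 1e-12, n * 1e-13)` are treated as null directions (their
contribution coincides with the residual subspace, so dropping them is
exact up to round-off).  sigma_g^2 and beta are profiled in closed form;
the restricted log-likelihood includes the `- log det(F'F)` constant so that
the k = 0 limit equals the ordinary least-squares REML value exactly.

Optimization is nested 1-D: for each `tau`, a bounded Brent search over
`log delta` on [-10, 10] (absolute tolerance 1e-6, endpoints also
evaluated); over `tau`, a bounded Brent search on [0, 1] (tolerance 1e-5)
with both endpoints evaluated explicitly, guarding against boundary optima
that an interior search can miss.  A `tau`-hat below 1e-5 is recorded as
exactly 0 - this is the event that feeds the point mass of the null mixture.
Permuting the rows of `V` only changes the Gram blocks involving `V`
(`V'V` is permutation-invariant), so each permutation statistic costs
O(n k_v k) plus the O(k^3) search, which is what makes ten permutations per
set affordable.

Consequences measured by the acceptance script: the low-rank restricted
likelihood agrees with a dense Cholesky evaluation to ~1e-13, wall time
grows sublinearly-in-practice between n = 2000 and n = 8000 at k = 100
(the spectral search does not depend on n at all), and peak allocation
during a fit at n = 8000 is a few MB where a dense covariance would need
512 MB.

## The null distribution

The textbook null for a variance component on the boundary - the 50-50
mixture of chi2_0 and chi2_1 - requires the outcome to decompose into many
i.i.d. subvectors; related individuals violate this, and the 50-50 weight
on chi2_0 is then too low, making the test conservative.  The null is
instead modelled as

    pi * chi2_0 + (1 - pi) * a * chi2_d

with real-valued degrees of freedom `d`.  Null statistics are generated by
permuting individuals within the tested set's genotypes only - the same
permutation for every SNP of the set (preserving within-set LD exactly) and
the same 10 permutations for every set - leaving phenotype, covariates and
confounder SNPs untouched, so the confounding structure itself survives
under the permutation null.

`pi` is estimated as the exact fraction of permutation fits with
`tau`-hat = 0.  `(a, d)` are fitted only to the largest 10% of statistics:
the j-th largest of the m_nz non-zero statistics is assigned the theoretical
tail probability `(1 - pi) j / (m_nz + 1)` (plotting positions on the
non-zero component), and (a, d) minimize the sum of squared differences of
log P-values, via BFGS in (log a, log d) from (1, 1) with a log-spaced grid
backstop.  Fitting the whole distribution by maximum likelihood instead
(the `fit_mixture_ml` comparator) matches the bulk at the expense of the
tail and yields P-values that are too small exactly where decisions are
made; the truncated tail regression avoids this.  P-values are
`(1 - pi) * S_chi2_d(t / a)` for `t > 0` and 1 at `t = 0`; the non-unity
P-values are therefore uniform on `(0, 1 - pi)` under the fitted null.
(The alternative reading - uniform on `(pi, 1)` - corresponds to the
substitution p -> 1 - p and would not control type I error at small alpha;
the implementation commits to the tail-probability definition.)

The two-sided risk of this machinery, quantified in the type-I harness: the
shared permutations couple all sets within a round, so empirical error
rates computed from few shared rounds have much higher variance than
binomial.  The harness therefore fits the mixture from shared-permutation
rounds (exactly what the pipeline does) but evaluates calibration on
held-out statistics drawn with independent permutations per set.

## Confounder selection and proximal exclusion

Confounder SNPs are ranked by univariate linear-regression P-value
(uncorrected, intercept only).  An explicit k may be given; with `k = auto`
the count is chosen from the grid {10, 20, 50, 100, ...} (capped at n/2) by
5-fold cross-validated out-of-sample predictive log-density of the
single-kernel LMM.  The ranking is recomputed inside each training fold:
ranking on the full data would leak the held-out phenotype into the choice
and systematically favour large k.  Among grid values within two
log-likelihood units of the best, the smallest is taken.  Per tested set,
any selected SNP belonging to the set or lying within 2 cM of a set SNP on
the same chromosome is removed from `W` before fitting - otherwise the
null model absorbs the very signal being tested.  Because the exclusion
changes `W` per set, the null (tau = 0) fit is recomputed per set.  When
the genetic-map column is absent, 1 cM is approximated by 1 Mb with a
prominent warning.

## Score-test comparator

The variance-component score statistic at the null REML fit is
`Q = y' P0 K_v P0 y` with `P0` the REML projection under
`Sigma0 = sigma_g^2 (K_w + delta I)`; its null is the weighted chi-square
mixture with weights the nonzero eigenvalues of `V' P0 V / k_v` (computed
in the k_v x k_v Gram form).  Tail probabilities come from numerical
inversion of the characteristic function: the Imhof integral is split at
`u0 = 1 / max(lambda)`, the head integrated directly and the slowly
decaying oscillatory tail with oscillatory-weight quadrature after writing
`sin(theta) = sin(phi) cos(qu/2) - cos(phi) sin(qu/2)`.  If the inversion
reports a large error estimate or an out-of-range probability, a
moment-matching (noncentral chi-square) approximation is substituted and
flagged `liu_fallback`.  Null variance parameters are plugged in at their
REML estimates, refitted per set after the per-set exclusion, for symmetry
with the LRT.

## The synthetic cohort generator

Real structured genotype panels cannot be redistributed, so validation runs
on a generator that reproduces the two confounders the model targets:

* **Population structure**: Balding-Nichols - ancestral MAF uniform on
  [0.05, 0.5], per-population frequencies Beta-distributed around it with
  parameter Fst (default 0.1, 4 populations).
* **Family relatedness**: individuals arrive in blocks (default 4): two
  founders drawn from the population frequencies, the rest Mendelian
  offspring of the founders.
* **Map**: SNPs evenly spaced in cM (default 0.25 cM; 1 cM = 1 Mb) across
  5 chromosomes, so windowing and the 2 cM exclusion are exercised.

Phenotypes are drawn from the generative LMM itself,
`y = u_conf + u_set + e`, each random effect sampled through its kernel
factor (never an n x n matrix).  Variance shares default to
confounding 0.3 / residual 0.7 under the null; with these defaults the
uncorrected univariate genomic-control lambda lands around 1.2-1.4 at
n = 2000, i.e. a strongly confounded cohort.  Causal SNPs are required to
lie more than 2 cM from every confounder-generator SNP, so that tested sets
are unambiguously true positives.  Set sizes are lognormal with mean 11 and
standard deviation 24 (minimum 2 by default), the shape of gene-set sizes
on dense panels; placement is non-overlapping within a chromosome.

What the generator does not emulate: local linkage disequilibrium beyond
family/population sharing (adjacent SNPs are conditionally independent
given ancestry), allele-frequency spectra of real arrays, genotyping error,
or case-control ascertainment.  Passing tests therefore demonstrate
correctness of the machinery and calibration under structure and
relatedness - not robustness to LD-driven proximal contamination, which is
precisely what the 2 cM exclusion is designed to absorb on real data.

## Experiment designs and problem sizes

All validation experiments are sized for a single CPU:

* **Oracle agreement**: 50 random instances, n <= 200, k_w <= 20, k_v <= 10,
  tau in {0, 0.3, 1}, delta in {0.1, 1, 10}; tolerance 1e-6 absolute on the
  restricted log-likelihood, 1e-8 relative on Q.
* **Scaling**: k = 100, n = 2000 vs 8000; the wall-time ratio is required
  below 4 (a cubic algorithm would give ~64) and peak traced allocation
  during the n = 8000 fit below 100 MB.
* **Type I error**: n = 500, 1500 SNPs, ~200 variable-size sets, confounded
  null phenotype; mixture fitted from 10 shared permutation rounds,
  evaluated on >= 2000 held-out per-set-permutation statistics at
  alpha = 0.05 and 0.01 against exact binomial 99% intervals.  The
  chi-bar-square comparator is expected conservative, the non-truncated ML
  comparator liberal-to-equal, at the same levels.
* **Null-fit recovery**: 10^4 draws from pi = 0.6, a = 1.5, d = 2.0;
  pi within 0.02, a and d within 15%.
* **Power**: five replicate cohorts (n = 800), 100 true sets each of 5 SNPs,
  variance shares 0.2 confounding / 0.4 set / 0.4 noise; paired LRT vs
  score detections at alpha = 0.05 with a one-sided sign test on discordant
  sets.
* **Confounding correction**: three replicate cohorts (n = 500, 1000 SNPs,
  1 cM spacing), lambda measured over non-generator polymorphic SNPs and
  averaged across replicates (lambda of one small scan is noisy because all
  tests share a single phenotype draw); set-size correlation pooled over
  ~180 variable-size sets.  Larger sets have more power to pick up
  unmodelled confounding, so the uncorrected pipeline shows a significant
  correlation between set size and log10 P (larger sets more significant)
  while the corrected pipeline shows none.
* **tau recovery**: 50 replicates at n = 2000, k_w = 50, k_v = 10,
  tau = 0.5, delta = 1; the mean of tau-hat within 0.1 of truth.

## Numerical choices and degenerate inputs

* Rank decisions use a relative 1e-12 spectral cut with an absolute floor;
  `F' Sigma^-1 F` is solved by Cholesky/`solve` with symmetrization.
* The inner Brent bracket on `log delta` is [-10, 10]; optima pinned at a
  bracket end are accepted (they correspond to pure-residual or
  pure-genetic limits).
* Negative LRT values (optimizer noise) are clipped to 0; clips above 1e-4
  are logged as optimizer failures.
* Monomorphic SNPs: dropped from kernels; scanned with P = 1.
* Collinear fixed effects raise an error naming the offending columns;
  conditional scans drop collinear conditioning columns at tolerance 1e-8.
* All randomness flows from explicit integer seeds; permutations are drawn
  once per run and reused, and results files are byte-identical across
  reruns of identical inputs.

## Known limitations

* **LRT versus score power on synthetic data.**  On real, LD-structured
  panels the restricted LRT has been observed to detect more sets than the
  variance-component score test.  Under this package's generator the two
  tests are empirically equivalent: when the null mixture is fitted from
  enough permutation rounds to make its own noise negligible, the LRT and
  the score test make identical per-set accept/reject decisions across all
  effect sizes examined (per-set noncentrality 5-15, n <= 2000).  The score
  test is the second-order approximation of the LRT at the null, and
  without local LD concentrating kernel eigenvalues the two do not separate
  at these scales.  The paired power experiment is still run and reported,
  but a significant LRT advantage should not be expected from this
  generator - detection differences at 10 permutations per set are mixture
  -calibration noise, which is why the experiment pools permutation
  statistics across replicates before fitting the null.

* Case-control phenotypes are analysed as 0/1 quantitative traits; with
  rare variants (MAF < 0.01) in a set this is known to inflate linear-model
  statistics, and the pipeline emits a runtime warning in that situation.
* The null-mixture fit assumes a common null across sets; strongly
  heterogeneous set sizes push against this assumption (it is the same
  assumption made by small-sample SKAT-style corrections).
* One genetic variance component per side only: no three-kernel models, no
  low-rank updates for per-set SNP exclusion (the exclusion recomputes the
  factor instead), no SKAT-O-style combination, no X-chromosome handling.
* P-values below roughly `(1 - pi) / (10 x number of sets)` rest on the
  parametric tail beyond the permutation support; with few sets they are
  extrapolations.
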
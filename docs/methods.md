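# Methods

This note documents the statistical models implemented in `qstfst`, the
choices made where conventions genuinely differ between tools, and what
the synthetic-data generators do and do not emulate.

## The nested half-sib model and Q_ST

The breeding design has two random grouping levels: populations, and
sires nested within populations.  Each sire is mated to several dams and
each dam contributes one brood record, so dam effects are confounded
with the residual by design — the model deliberately has no dam term.
For a trait y with an optional fixed covariate x (maternal total length,
or log10 rearing density for growth traits):

    y_ijk = mu + beta * x_ijk + u_i + v_ij + e_ijk
    u_i  ~ N(0, V_b)      population effects
    v_ij ~ N(0, V_male)   sire-within-population effects
    e_ijk ~ N(0, V_res)   residual (includes dam and measurement noise)

Components are estimated by REML through a profiled mixed-model fit
(statsmodels MixedLM: random population intercept plus a
sire-within-population variance component).  The optimizer is tried as
BFGS, then L-BFGS, then CG; a fit is accepted only if it converged with
finite components and a residual variance that has not collapsed to
numerical zero (below 1e-10 of the trait variance).  Otherwise the
method-of-moments nested ANOVA takes over, flagged via
`VarianceComponents.method == "mom"` and `converged == False`.  The MoM
estimator uses Henderson-style expected mean squares with the standard
unbalanced coefficients, and equals REML on balanced designs with
interior estimates (asserted in the tests at the 5% level).  Negative
solutions are truncated at zero and flagged as boundary estimates.

The divergence statistic is

    Q_ST = V_b / (2 * V_w + V_b),    V_w = V_male + V_res.

Covariate adjustment is done inside the mixed model as a fixed effect
(not by pre-residualizing), which keeps the variance partition coherent;
`mom_nested_anova` residualizes first and is documented as an
approximation.  Pairwise Q_ST refits the model on each population pair's
records (`mode="subset"`, the default); `mode="global"` instead shares
one whole-design V_w across pairs and re-estimates only each pair's V_b,
as a sensitivity alternative.  Pair fits on 2 x 4 x 4 = 32 records are
noisy and frequently sit at the V_b = 0 boundary; that is a property of
the design, not of the estimator, and degenerate pairs propagate as NaN
and are excluded listwise downstream.

With only 8 population effects observed, single-replicate Q_ST estimates
scatter widely.  The estimator also carries two small systematic
effects: truncation of negative V_b at zero pushes estimates up, while
Jensen's inequality on the ratio pushes the mean down; net, the mean
estimate over replicates at true Q_ST = 1/3 sits near 0.31.

## Weir-Cockerham theta

F_ST is estimated as Weir & Cockerham's (1984) theta — the estimator the
classical microsatellite tools report — with the multiallelic extension:
per locus and per allele, the among-population (a), among-individual-
within-population (b) and within-individual (c) components are computed
from sample sizes, allele frequencies and heterozygote frequencies,
summed over alleles, and the multilocus estimate is the ratio of sums

    theta = sum_l a_l / sum_l (a_l + b_l + c_l),

never the mean of per-locus ratios (the tests include a constructed case
where the two differ).  Missing genotypes are excluded per locus; a
genotype with one missing allele is treated as entirely missing (the
conservative reading; dialects differ).  The estimator is unbiased and
can go slightly negative; values are reported unclipped.  No
stepwise-mutation (R_ST-style) variant is provided.

## Exact Hardy-Weinberg tests

The conditional distribution of a genotype table given its allele counts
is exactly the distribution induced by pairing the 2n allele copies
uniformly at random.  The Markov chain therefore operates on pairings:
a step picks two individuals and one allele copy from each and swaps
them.  This switch proposal is symmetric and connected on the pairing
space, and the uniform stationary distribution on pairings induces the
Hardy-Weinberg conditional distribution on tables, so every move is
accepted (the Hastings ratio is identically 1 in this parameterisation).
The p-value is the fraction of post-dememorization states whose
conditional probability is at or below the observed table's (ties count
as extreme, compared in log space with 1e-9 tolerance).  Defaults follow
the published settings: 1,000,000 steps after 100,000 dememorization
steps; the Monte-Carlo standard error comes from 100 batch proportions.
A single-allele table returns p = 1 with a degenerate flag.

`hwe_exact_enumeration` computes the same p-value by enumerating every
table with the observed allele counts (practical for 2 alleles at any
modest n, and 3-4 alleles at small n).  It is the independent oracle for
the chain in the tests and is exact, not Monte Carlo.

## Linkage disequilibrium

The two-locus genotypic association within a population is measured by
the log-likelihood-ratio (G) statistic of the joint genotype
contingency table.  Its null distribution is generated by permuting one
locus's genotypes among individuals within the population, preserving
both single-locus margins; since the margins are fixed, G is monotone in
sum(O log O), which is what the compiled kernel tracks.  The run is
organised as batches x iterations (defaults 100 x 1,000 after 1,000
burn-in shuffles) so a batch-based standard error is available, and the
p-value uses +1 smoothing.  Populations monomorphic at either locus are
skipped with a note; the remaining k population p-values combine by
Fisher's method, chi-square with 2k degrees of freedom.

## Life-history GLMs

Trait models are ordinary least squares: response ~ covariate +
population (+ covariate x population when requested).  F-tests are
sequential (type I) in entry order — covariate first, then population,
then the interaction — matching the conventional ANCOVA table layout;
the increments are computed from explicit nested fits because patsy
reorders categorical terms in the design matrix.  Marginal (type III)
tests are available behind `tests="marginal"`.  Group sizes are
unbalanced (15-21 clutches per population), so post hoc comparisons use
the Tukey-Kramer form: adjusted means are evaluated at the grand
covariate mean, each pair's standard error comes from the model
coefficient covariance, and p-values come from the studentized range
distribution with the model's residual degrees of freedom.  Least-square
means are reported with t-based 95% CIs and an extrapolation flag when a
population's own covariate range excludes the grand mean.  All tests are
two-sided at alpha = 0.05 with no multiplicity correction beyond Tukey.

Trade-offs are measured on standardized residuals (residual of trait on
covariate divided by its ddof=0 SD, so mean 0 and SD 1 exactly).  Growth
comparisons are restricted to broods with 5-19 reared offspring
inclusive, and rearing densities are log10-transformed before use as
covariates.  Trait and environmental ordinations share one
correlation-matrix PCA engine (eigendecomposition of the correlation
matrix; the largest-magnitude loading on each axis is made positive;
loadings above 0.4 in magnitude are flagged as axis-defining).

The lake-vs-peripheral contrast is a two-group one-way ANOVA on the
population-level adjusted means, with data-determined denominator
degrees of freedom (6 for 8 populations); the corresponding published
table rows print 5, which is not derivable from an 8-population
two-group comparison — the discrepancy is documented rather than
imitated.

## Colwell predictability

A monthly series is binned into 10 states and cross-tabulated as
months-of-year x state.  With row, column and joint entropies H(X),
H(Y), H(XY):

    C = 1 - H(Y)/log s,   M = (H(X) + H(Y) - H(XY))/log s,   P = C + M.

"Bins of equal sizes" is read as equal-width intervals over the observed
range (the hydrostats convention), with the maximum value assigned to
the top, right-closed bin; equal-frequency quantile binning is available
via `binning="frequency"` for sensitivity.  Natural logarithms are used
internally; the normalisation by log(n_bins) makes the result
base-invariant, and the statistics are invariant to affine
transformations of the series because the bins follow the range.  A
constant series occupies a single state and returns (P, C, M) =
(1, 1, 0) with a degenerate flag.  P = C + M holds to 1e-12 by
construction and is asserted property-style in the tests.

## Q_ST-F_ST comparison

The association between the two pairwise matrices is Spearman's rho over
the lower-triangle cells (ties mid-ranked).  Distance-matrix cells are
not independent, so the null permutes one matrix's population labels
jointly over rows and columns (Mantel-style); the two-sided p-value is
(1 + #{|rho*| >= |rho|}) / (n_perm + 1), never exactly zero.  Default
n_perm = 9,999 with a mandatory seed.  An exhaustive mode enumerates all
k! label permutations for small panels, and a naive pair-level
permutation mode is provided for comparison but is anti-conservative.
Each pair is classified by sign(Q_ST - F_ST) with a tolerance band:
directional (Q_ST larger), stabilizing (F_ST larger), else
indistinguishable.

## Synthetic data: what it emulates, and what it does not

Genotypes follow the Balding-Nichols model: ancestral frequencies are
symmetric-Dirichlet, population frequencies are Dirichlet with
concentration p(1-F)/F, and genotypes are random unions of gametes, so
within-population Hardy-Weinberg holds by construction and F is the
expected theta.  Defaults (7 populations x 20 diploids, 7 loci x 10
alleles, F = 0.10, 1% missing) mirror the scale of the study's
microsatellite panel and its overall differentiation.

The experiment generator draws maternal total length log-normal
(median 85 mm, log-SD 0.08; lengths must be positive, and the slope acts
on centred TL so population means stay interpretable).  Each trait value
is population effect + sire effect + residual + tl_slope x (TL - mean).
Cross-trait correlations (the egg size/number trade-off, default
rho = -0.39 matching the observed size-corrected correlation; brood size
vs incubation -0.20 and vs release length -0.25) are applied through one
Cholesky factor at every level — population, sire and residual — so the
configured correlation also holds in pooled size-corrected data, not
only within populations.  Counts are rounded with a floor of 1 (a small
bias source), reared fry are capped at 32, and growth over each interval
carries a density slope (default -2 mm per log10 individuals) on the
log10 reared count.  Defaults give exactly 8 x 4 x 4 = 128 families at
~12.5 fry per brood, i.e. about 1,600 offspring.

Climate series are a 12-month baseline plus i.i.d. Gaussian noise over
15 years, with precipitation floored at zero.  The default profiles are
southern-hemisphere tropical seasonality (warm wet November-April).

Not emulated: real microsatellite mutation processes (no stepwise
mutation, so no R_ST analogue), linkage between loci, selection or
gene flow structure among populations, maternal age or transgenerational
effects, fry mortality between measurement days (densities are constant
within a brood), and spatial interpolation of climate.  Passing tests
therefore demonstrate that the estimators recover the generative
parameters under the study's design and sample sizes — not that the
biological conclusions of any particular dataset are correct.

## Numerical conventions and problem sizes

- All randomness flows from `numpy.random.default_rng` seeds derived
  deterministically from one global seed; compiled kernels are seeded
  per call.  Fixed seed implies byte-identical outputs, including the
  pipeline's `summary.json` (floats rounded to 10 decimals before
  serialisation).
- HWE/LD tie comparisons use a 1e-9 log-space tolerance so equal-
  probability tables count as extreme.
- REML convergence tolerance is the optimizer default with maxiter 500;
  boundary components below 1e-8 of the total variance report as 0.
- Calibration checks run at the study's design sizes: 200 replicates of
  the 128-family design for Q_ST recovery, 100 replicates of 2 x 100
  diploids at 7 loci for theta recovery, every 2-allele table with
  n <= 20 plus thirty 3-allele tables with n <= 12 against enumeration
  at 1e5 chain steps, and 500 replicates of 7-population matrices for
  permutation-p uniformity.  These sizes keep the full suite and the
  reproduction script within a few minutes on one CPU while leaving
  Monte-Carlo error well inside the asserted bounds.

## Known limitations

- Pairwise Q_ST from two-population refits is weakly identified; many
  pairs sit at the V_b = 0 boundary, giving Q_ST = 0 entries.  This
  matches the information actually available in a 32-record pair, but
  users should read pairwise matrices as noisy.
- The MoM fallback with a covariate residualizes against the covariate
  before the nested ANOVA, which slightly misallocates covariate-
  confounded variance when groups differ in covariate distribution.
- The exact-test p-value is conservative and discrete for very small
  samples (n = 3-5 per Table-2-sized cell), as for any conditional
  exact test.
- `hwe_exact_enumeration` scales combinatorially and is intended as an
  oracle and for small tables, not for highly polymorphic loci.
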
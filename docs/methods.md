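# Methods

## Setting

A stud supplies rams to a commercial flock. The commercial progeny are
group-mated (pedigree unknown), individually phenotyped for a categorical
trait — dag score, 1 (no breech soiling) to 5 (heavy soiling) — and then
*pooled by sex × score category* for genotyping, so that each DNA pool's
B-allele frequencies (BAFs) summarise the allele content of 30–40 animals of
one phenotype class. The sires are genotyped individually. The question is
how much each sire contributed, genetically, to each phenotype category, and
what his breeding value for the trait is.

## Hybrid genomic relationship matrix

The h-GRM stacks sire rows (BAF ∈ {0, 0.5, 1}, missing allowed) and pool
rows (BAF ∈ [0, 1]) over a shared locus panel and applies VanRaden's first
method in BAF coding:

* `M* = (Bfreq − 0.5)·2`, so sires sit at {−1, 0, 1} exactly as in the
  dosage formulation (the coding is an affine re-expression of 0/1/2
  dosages; the sire–sire block is bit-identical to a dosage VanRaden
  computation, which the tests assert at 1e−12).
* Centring is **per locus**: `pᵢ` is the unweighted mean BAF of column *i*
  across all stacked rows, with missing entries contributing 0.5, and
  `Z* = M* − P*` with `P*ᵢ = (pᵢ − 0.5)·2`. A pool of 40 animals counts the
  same as one sire in `pᵢ` by default; a member-count-weighted option and
  sires-only / pools-only reference-frequency options exist for sensitivity
  analysis, since the best choice of reference population is genuinely open.
* Missing sire calls are set to their column's `P*` value in `Z*` (they
  contribute zero relationship) — the least-informative imputation — while
  the 0.5 convention applies inside `p` itself.
* `G* = Z*Z*′ / (2Σ pᵢ(1−pᵢ))`. Fixed loci contribute zero to numerator and
  denominator and are **retained**: no MAF filter is applied anywhere,
  because rare alleles are exactly what ties a sire to the pools that
  contain his progeny. An all-fixed panel is a fatal error.
* `H_ij = G*_ij / √(G*_ii·G*_jj)`: unit diagonal by construction. The
  diagonal of a pool's G* shrinks roughly as 1/n with pool size; since the
  *effective* n is unknowable (unequal DNA concentrations), this scaling
  replaces any attempt to model it. H is the analysis-ready matrix; G* is
  kept for sensitivity flags.

G* is a Gram matrix over a positive denominator, hence positive
semidefinite; H inherits PSD-ness by congruence with a positive diagonal
matrix. Both are checked at tolerance 1e−8 relative to the trace.

## Sire slope regression and its calibration

For sire *i*, `Y_j` = H(sire *i*, pool *j*) is regressed on an intercept,
pool sex (0 = female, 1 = male) and pool dag score as a *numeric* 1–5
covariate — one slope per sire, matching the single fitted line the method
reports per sire; a 4-df categorical score would dilute the 20-pool design.
Slope p-values are two-sided t tests on n_pools − 3 degrees of freedom. A
relationship vector with no variation returns slope 0, p = 1.

With 20 pools, per-sire p-values are fragile, so calibration is global:

* **Permutation null.** Pool dag scores are shuffled *within sex* (sex
  labels fixed, preserving the stratification), all sire regressions are
  refit, and the pooled sire × permutation p-values give the permuted
  proportion at each level of the grid (0.05, 0.01, 0.005, 0.001, 0.0005).
  Proportions are cumulative (p ≤ level). 100 permutations by default.
* **Simulated chi-square.** Sires are binned into disjoint significance
  classes by observed p-value; expected class probabilities come from the
  permuted distribution; the Pearson statistic's p-value is computed by
  multinomial Monte-Carlo (2000 draws by default) rather than the
  asymptotic χ² law, which is unreliable at expected counts of order
  33 × 0.0005. Zero-expected classes are merged with a neighbour and
  logged.

The t test is the primary per-sire p-value; the permutation distribution is
retained on the summary object for anyone preferring empirical per-sire
p-values.

## gBLUP

`y = Xb + Zg + e` with `var(g) = H σg²`, `var(e) = I σe²`. Records are the
pool dag categories on the observed 1–5 scale treated as linear (a
threshold/probit link is out of scope); sires have missing records and all
take the male sex code in X, the only defensible coding for rams. REML is
self-contained:

* The phenotyped block `H_oo` is eigendecomposed once; after rotation the
  likelihood is a product of scalars and each evaluation is O(n).
* The restricted likelihood is profiled down to the single ratio
  λ = σe²/σg², searched by bounded Brent on log λ ∈ [log 1e−6, log 1e6]
  (tolerance 1e−10, 200 iterations). A non-finite search falls back to a
  121-point log-spaced grid — a simpler guard than an EM loop, and bounded
  by construction. Non-convergence returns `converged=False` with a
  warning; a ratio at the bounds is flagged `boundary=True` rather than
  hidden (with 20 exchangeable records a boundary σe² ≈ 0 solution is a
  real feature of the data, not a solver failure).
* If min eig(H) < 1e−8 the matrix is bent by εI with ε = 1e−6·trace/n and
  the event logged; unit-diagonal matrices from pooled data routinely sit
  at −1e−15.
* GEBVs for every sample follow from `ĝ = σg² H[:, obs] V⁻¹(y − Xb̂)`; the
  sires' values flow entirely through their H-covariances with the pools.
  `blup_solve` exposes the same solve at a fixed, user-chosen λ.
* An optional flag divides the residual variance of each pool record by its
  nominal member count; the default is homoscedastic, since the H scaling
  already absorbs pool-size effects.

GEBV and regression slope are near-equivalent summaries (their correlation
across sires exceeds 0.9 in simulation at h² = 0.35); the package reports
both plus their Pearson/Spearman concordance.

## Synthetic flock

The generator reproduces the design's statistical structure, with defaults
chosen to match the study conditions the analysis expects:

| parameter | default | why |
|---|---|---|
| sires / genotyped | 45 / 33 | sires present for sampling vs sires used |
| progeny | 2600 | one commercial drop |
| loci | 10 000 | stands in for a 50k SNP chip; enough that GRM noise (≈ loci⁻¹ᐟ²) sits well below the sire–pool signal |
| allele freq | U(0.05, 0.5) | common-SNP ascertainment of arrays |
| heritability | 0.35 | dag score's literature value |
| thresholds | N(0,1) quantiles at (−0.524, 0.176, 0.806, 1.555) | category occupancy ≈ 30/27/22/15/6 %, so the rarest cell holds ~78 of 1300 animals per sex — matching the 66–80-animal cells the pooling design caps |
| cap / replicates | 80 per sex × score cell, 2 pools | the race-sampling cap and replicate split |
| Dirichlet concentration | 10 | ≈ 30 % CV of per-animal DNA contribution, a plausible blood-sample spread; ∞ = equal contributions |

Mechanics: sires are Hardy–Weinberg draws at each locus; progeny get a
uniformly random sire (recorded only as truth), a paternal allele sampled
from his genotype and a maternal allele from the founder frequency (dams
are not modelled individually — exactly the information the method lacks);
per-locus additive effects are drawn Normal once per simulation and
rescaled so the genetic variance of liability equals h²; liability = genetic
value + N(0, 1−h²) (+ an optional sex effect, default 0, provided so the
sex covariate downstream is exercised); the dag score thresholds the
liability. Retention within a cell is first-come by default (mimicking a
sampling race) with a random-retention option. Every draw flows from one
seeded generator: a fixed seed reproduces the flock bit-for-bit.

**What it does not emulate:** linkage and LD (loci independent), dam
pedigree or maternal effects, multi-generation structure, genotyping error
beyond pooling noise, array-specific artifacts (clustering, GenCall-type
metrics), and non-additive architecture. Passing tests therefore show the
estimator is correct *under its own assumptions* — additive trait,
independent loci, known pool membership counts — not that it is robust to
violations of them.

## Problem sizes in the validation suite

The acceptance checks run the full study-scale design (45 sires, 2600
progeny, 10 000 loci, 20 pools): 20 independent flocks for the signal and
concordance averages, one flock × 100 within-sex permutations (3300 pooled
p-values) for the null calibration, and 50 replicates of n = 100 for REML
recovery of σg² = σe² = 1. Brute-force oracles (per-pair double loops,
dense V-inverse mixed-model solves) are kept tiny (3 × 4 matrices, 5-sample
systems) where exact agreement at 1e−12/1e−8 is asserted.

## Known limitations

* With 20 pool records the REML ratio often sits at a boundary; variance
  components from such fits are not interpretable even though the GEBV
  *ranking* remains stable (it is driven by the H-covariances).
* Per-sire p-values ignore the correlation between a sire's 20 relationship
  values; only the permutation-calibrated global statement is trustworthy.
* The pool phenotype is the category midpoint of its members by design;
  within-pool phenotype variance is discarded, as in any pooling design.
* `H_ij` comparisons across datasets are not meaningful: identity-by-state
  relationships depend on the reference population defining `p`, and small
  negative sire–pool relationships are expected, not errors.
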
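# Methods

This note documents the statistical models implemented in `pgxfreq`, the
choices made where several constructions were defensible, and what the
synthetic cohorts do and do not establish about real data.

## Data model

All computation reduces to per-locus genotype counts (n_ref-hom, n_het,
n_alt-hom) at biallelic SNVs annotated on the plus strand. Cohort-level
inputs are an individuals × loci matrix of alt-allele doses {0, 1, 2,
missing} plus categorical strata (e.g. self-identified skin-color category,
birth region). Missing calls are excluded per locus, so every locus has its
own effective n; this is the only defensible default when per-SNV call
rates are unreported. Published summary tables are carried as 2-decimal
genotype-frequency triples; a triple may sum to 1 ± 0.01 (rounding), and
larger discrepancies are rejected at read time. One bundled row transcribes
a printed confidence interval that cannot bracket its own point estimate
(rs2740574, interval likely reported for the complementary allele); the
reader preserves the printed values and emits a warning rather than
silently "fixing" data.

### Count reconstruction

`reconstruct_counts` inverts table rounding: it returns the integer triple
(a, b, c) with a+b+c = n minimizing Σ(kᵢ/n − fᵢ)², ties broken toward the
lexicographically smallest triple. This matches largest-remainder
apportionment on every bundled row checked by hand. Note the caveat proved
by the property tests: the constrained minimizer of the *rounded*
frequencies need not be the original triple (it can differ by a count or
two when a frequency sits near a rounding boundary), so quantities
recomputed from reconstructed counts — HWE p-values especially — are exact
functions of the published table, not of the unpublished raw data.
Borderline loci can therefore cross the p < 0.05 line in either direction;
only robustly deviating loci are asserted in tests.

## Allele frequencies and confidence intervals

p̂_alt = (n_het + 2 n_alt-hom)/(2n), treating the 2n allele copies as the
binomial sample. The default 95% interval is the Wilson score interval: it
always contains the point estimate and stays inside [0, 1], which the Wald
interval does not near the boundaries (both are exposed; the contrast is
tested). The construction behind the bundled table's printed CIs is
unstated, so printed intervals are treated as data to be carried, never as
golden values for either method.

## Hardy–Weinberg screening

The classical 1-df χ² against expected counts n·(q², 2pq, p²) with p
estimated from the same counts and no continuity correction — this choice
reproduces the bundled table's rs1799853 p = 0.83 on hand recomputation.
Monomorphic loci return a flagged degenerate result (χ² = 0, p = 1) so
whole-table scans never abort. Exact (Levene/Haldane) HWE tests are out of
scope. The type-I calibration test draws 2000 cohorts of n = 357 under true
equilibrium with p ∈ [0.1, 0.9] and confirms a 5% ± 1.5% rejection rate;
the asymptotic test is not trustworthy for very rare alleles at this n, a
known limitation.

## Pairwise variant-specific F_ST

F_ST(p₁, p₂) = (p₁ − p₂)² / [(p₁ + p₂)(2 − p₁ − p₂)]. This equals
(H_T − H_S)/H_T for two equally weighted populations (H_T from the pooled
mean frequency, H_S the mean within-population expected heterozygosity);
the equivalence is enforced to 10⁻¹² on a 101 × 101 grid as an independent
oracle. When both populations are fixed for the same allele the 0/0 form is
defined as 0 with a monomorphic flag, so panel-wide profiles never abort;
flagged loci stay in profile means (as zeros) with a logged count.
Divergence classes use half-open/closed-right intervals — low < 0.05 ≤
moderate < 0.15 ≤ large ≤ 0.25 < very large — so every value has exactly
one class; the conventional verbal thresholds overlap at their endpoints
and a single consistent convention had to be fixed. Profile means and SDs
are unweighted across loci with sample (n−1) SD, matching how per-marker
averages are conventionally reported. Multi-population estimators and
Weir–Cockerham variance components are out of scope.

## Exact stratification tests

Genotype-by-stratum r×c tables are tested under the fixed-margins
(multivariate hypergeometric) null with the Freeman–Halton two-sided
convention: p = Σ P(T) over margin-compatible tables with
P(T) ≤ P(observed)·(1 + 10⁻⁹), the relative slack absorbing float ties.
Mode selection is automatic: full enumeration when at most 10⁶ tables share
the margins (counted exactly, with the last row forced and the penultimate
row counted in closed form by inclusion–exclusion), otherwise Monte Carlo.
The MC estimator permutes stratum labels — an exact draw from the
conditional null — and reports (x + 1)/(N + 1), so an estimated p is never
0 and never exactly reaches the naive frequency; it requires an explicit
seed. Per-locus scans build 3×levels tables, drop zero rows/columns, report
raw p-values (no multiple-testing correction by default, since survey
counts of p < 0.05 loci are conventionally raw; Bonferroni/BH switches are
provided and logged), and derive per-locus MC sub-seeds from one scan seed.
Calibration: on cohorts whose strata share one ancestry distribution, the
scan rejects at 5% within ±1.5% over ~2000 locus-level replicates (Monte
Carlo mode, 2000 permutations per locus — the estimator targets the same
tail as enumeration and keeps the experiment fast).

## Supervised ancestry estimation

With fixed reference alt-allele frequencies p_jk (K populations × L loci,
clamped to [10⁻⁶, 1 − 10⁻⁶]), individual dose g_j ~ Binomial(2, Σ_k q_k
p_jk). EM maximizes the resulting log-likelihood from the uniform simplex:
each allele copy carries a responsibility over ancestral origins, and the
M-step averages responsibilities over the 2L observed copies. Stopping:
relative log-likelihood change < 10⁻⁸ or 2000 iterations; the
log-likelihood is non-decreasing at every step (asserted in tests). Missing
doses drop out of the likelihood per locus. This deterministic supervised
estimator is this package's desk-scale counterpart of Bayesian model-based
clustering with pre-assigned reference populations; MCMC, unsupervised
clustering and K-selection are deliberately out of scope. Two properties
matter for interpretation: estimates at L = 34 loci carry visible shrinkage
toward the uniform simplex (small components are overestimated — the
reported mean of a ~5% component lands around 7%), and recovery improves
with panel size (mean |q̂ − q| ≈ 0.07 at L = 34 vs ≈ 0.04 at L = 136 under
study conditions). Reported group means should be read with that bias in
mind.

Group contrasts use Kruskal–Wallis with tie correction, then Dunn's
post-hoc z-tests on mean ranks with the pooled tie-corrected variance.
Dunn p-values are two-sided and compared against a pre-stated pairwise
alpha (0.017 ≈ 0.05/3 for three groups) rather than adjusted — matching
the convention of fixing the corrected alpha in advance.

## Synthetic cohorts

The generator emulates a 3-way admixed population: per-stratum
q ~ Dirichlet(α) with α = concentration × target means (means renormalized;
zero components floored at 10⁻³ × concentration), genotypes
Binomial(2, q·p) at unlinked loci, panels drawn i.i.d. Beta(0.5, 0.5) per
population (U-shaped, hence AIM-like differentiation; mean pairwise panel
F_ST ≫ 0.05), and optional independent whole-gene-deletion indicators. The
study-condition default (`cuban_study_config`) uses the surveyed strata —
white n = 190 with mean ancestry (85.9, 9.3, 4.8)%, admixed n = 101 with
(57.7, 36.3, 6.0)%, black n = 66 with (31.2, 64.7, 4.1)% — L = 34 loci,
concentration 10 (chosen once: it yields individual-level spread comparable
to the wide surveyed ranges, e.g. European ancestry 41–98% within the white
stratum), and deletion probabilities (0.39, 0.18). One master seed expands
by `SeedSequence.spawn` into fixed per-stage child seeds (panel, ancestry,
genotypes, deletions), so identical configs are bit-identical and stages
can be re-run in isolation.

What the simulations do *not* model: linkage between markers (per-locus
statistics only), correlated allele frequencies between ancestral
populations (the uncorrelated mixture is a deliberate simplification of
correlated-frequency admixture priors), genotyping error, and per-SNV
missingness. Passing calibration and recovery tests therefore demonstrates
the estimators' correctness under the assumed mixture model, not robustness
to LD or panel misspecification in real cohorts.

A useful emergent check: pooling strata with distinct ancestry means
inflates the HWE rejection rate far above 5% (heterozygote deficit —
the Wahlund effect) while each stratum alone stays near nominal; under
study conditions with 400 loci the pooled rate is roughly 0.4 against
stratum rates ≤ ~0.1. That is the quantitative backbone of reading survey
HWE deviations as stratification.

## Pipeline and numerical conventions

`run_pipeline` executes cohort acquisition → frequencies → HWE → exact
stratification scan → ancestry (+ Kruskal–Wallis/Dunn) → pairwise
per-stratum F_ST, writing plain TSVs (6-decimal, round-trip stable), a text
summary, and a manifest with a config hash and SHA-256 of every output;
reruns of one config are byte-identical. VCF support is deliberately
minimal — biallelic, GT-only, phased and unphased treated identically, any
partially missing call treated as missing — and anything else errors loudly
rather than guessing. Problem sizes used by the test-suite calibration
experiments (2000-replicate calibrations, 52 × 39 locus scans, L = 34/136
recovery runs, 400-locus Wahlund cohorts) were chosen to give 3-SE
resolution on the quantities being checked while keeping each experiment a
matter of seconds to a couple of minutes.
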
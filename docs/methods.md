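# Methods

## Model and statistic

A gamete at two biallelic loci is one of AB, Ab, aB, ab; a diploid subject
carries two. Writing X = (X_A, X_B) for the pair of allele indicators of a
random gamete, X ~ multinomial(1, h) with h = (h_AB, h_Ab, h_aB, h_ab), so
each indicator is Bernoulli with

    mu_A = h_AB + h_Ab,   sigma2_A = mu_A (1 - mu_A),
    cov(X_A, X_B) = h_AB - mu_A mu_B = D   (gametic disequilibrium).

Cases and controls are treated as two subpopulations; the null hypothesis
is equality of their gamete-frequency vectors. This is a two-group MANOVA
hypothesis on E[X], and the two-locus fixation index is its Wilks' lambda
statistic

    Lambda = det(SSW) / det(SSW + SSB),

with SSW = n0 Sigma0 + n1 Sigma1 (per-group indicator covariance matrices
scaled by gamete counts n_i = 2 x subjects) and
SSB = sum_i n_i (mu_i - mu_t)(mu_i - mu_t)^T about the pooled mean. For
k = 2 variables and m = 2 groups, F = (1 - sqrt(Lambda))/sqrt(Lambda) *
(n - 3) is an exact monotone transform with null law F(2, 2(n - 3)),
n = n0 + n1 gametes; the test rejects in the upper tail.

Two conventions exist for the "total" scatter. The default uses
SSW + SSB, which satisfies the MANOVA decomposition identity exactly (the
identity is asserted to 1e-10 in the tests). The alternative
(`pooled_em=True`, CLI `--pooled-em`) sets the total to n * Sigma_t with
Sigma_t from an EM fit to the pooled genotype table; it differs only in
the off-diagonal (pooled D is not the mean-decomposed one). The default
was chosen because the distribution theory rests on the decomposition
identity; the worked example's severe-malaria result also discriminates
clearly in its favour (the pooled variant shifts that P-value by ~2.5x).

Gametes are not directly observed: unphased genotype data leave the double
heterozygote's phase ambiguous. Group-wise gamete frequencies are
maximum-likelihood estimates from an EM algorithm (below), run separately
within cases and controls because the statistic compares group-specific
pools.

## EM estimation of gamete frequencies

Every genotype-pair cell except (1, 1) determines its two gametes. The
E-step splits the double-heterozygote count between the phases AB/ab and
Ab/aB in proportion h_AB h_ab : h_Ab h_aB; the M-step re-counts gametes.

* Initialisation: linkage-equilibrium start, h0 = outer product of the
  observed allele frequencies — deterministic and phase-neutral. Random
  restarts (`n_restarts`) are available as a guard against multimodality,
  which we have not observed on real-scale tables.
* Convergence: max |delta h| < 1e-10, at most 1000 iterations. This is far
  tighter than needed for P-value stability; it costs tens of iterations.
* Boundaries: zero cells are allowed and no pseudocounts are added (they
  would bias small-table estimates); a monomorphic locus yields a valid
  boundary estimate with a `monomorphic` flag.
* The log-likelihood is non-decreasing across iterations (asserted
  per-iteration in tests) and the estimates match a brute-force
  zoom-enumeration grid search over the simplex to 1e-4 on random small
  tables.

## Comparison tests

* **Pearson chi-square** on the 9-genotype-class x status table (classes
  empty in both groups dropped; df = non-empty classes - 1). The 9-class
  table, rather than an allele or haplotype collapse, is what makes its
  behaviour track the MI test.
* **Mutual information**: plug-in MI in nats on the same 9 x 2 table;
  2n MI is algebraically identical to the likelihood-ratio G statistic
  (the identity is the test oracle) and is referred to chi-square(8). The
  df stays 8 even when classes are empty in-sample (`df_mode="observed"`
  is available for sparse-data sensitivity checks).
* **LD r-squared, case-only**: EM within the selected group (default:
  cases), r2 = D2 / (p_A p_a p_B p_b), statistic N r2 ~ chi-square(1) with
  N the number of *subjects* in the group. The subject count, not the
  gamete count 2N, is correct here: within a subject the second gamete is
  determined by the first given the genotype, so gametes do not contribute
  independent information pairwise. We verified this empirically: at 20,000
  null replicates, N r2 gives KS p = 0.77 against chi-square(1) and 5.2%
  type-I error, while 2N r2 gives KS p ~ 0 and 16.6%.

All statistics are invariant to allele relabelling at either locus, to
locus exchange, and (except the group-specific LD test) to case/control
swap; these invariances are property-tested.

## Synthetic-data generators

* **Null generator**: two independent SNPs with MAF ~ U(0.1, 0.4) drawn per
  replicate, genotypes in Hardy-Weinberg proportions, and a random half of
  the 1000 subjects labelled cases. These defaults are the calibration
  study's design conditions.
* **Disease-model generator**: an interaction-only penetrance model
  P(disease | g1, g2) = f0 exp(beta x1 x2) with coding x per locus —
  dominant: 1{dosage >= 1}; additive: dosage/2 (the double homozygote
  carries the full relative risk); recessive: 1{dosage = 2} — and baseline
  f0 solved in closed form so the HWE-weighted mean penetrance equals the
  prevalence (default 1%). Sampling is retrospective and exact: case
  genotype pairs from P(g | case) ∝ P_HWE(g) penetrance(g), controls from
  the complement, no rejection step. Optional extra null SNPs emulate a
  marker panel in which only two loci are functional. Defaults: 500 cases,
  500 controls, disease-allele frequency settings (0.2, 0.4) and
  (0.3, 0.8), ln RR grid 0 ... 1.3.
* What the generators do *not* emulate: linkage between panel SNPs,
  population structure, genotyping error, missingness, main effects at the
  functional loci. Passing power tests therefore demonstrate behaviour
  under clean interaction-only architectures, not robustness to those
  complications.

The Monte-Carlo drivers sample the 3x3x2 pair-count tensor directly
(multinomial on the conditional cell probabilities), which is
distributionally identical to simulating subjects and tabulating — the
dataset-level and count-level paths are cross-checked against each other in
the tests. Seeds derive from a master seed via `SeedSequence(master,
stream, replicate)`, so replicates are independent and order-insensitive.

## Calibration and power studies

The calibration study (default 10,000 replicates of 1000 subjects) collects
the F-transformed Fst statistic, 2n MI and the case-only N r2, tests each
against its asymptotic law by Kolmogorov-Smirnov, and reports empirical
type-I error at alpha = 0.05 for all four tests. Power is the proportion of
replicates whose statistic exceeds the theoretical critical value at alpha,
with binomial standard errors; the same theoretical-critical-value rule is
used for all four tests.

A known and deliberate finding: at 1000 subjects with MAF down to 0.1, the
rare double-homozygote genotype classes have expected counts near 0.1, and
the resulting finite-sample deviation of 2n MI from chi-square(8) —
invisible in a histogram and irrelevant at usual significance levels
(type-I error stays within the 99% binomial band) — is detectable by a
10,000-replicate KS test (KS D ~ 0.03). The deviation vanishes as samples
grow (KS p = 0.70 at 20,000 subjects, 0.95 at 100,000), confirming the
asymptotic law. The corresponding calibration assertion is left strict and
failing at the 1000-subject design point rather than loosened.

## Numerical and design notes

* Degenerate inputs (monomorphic locus in both groups, single genotype
  class, < 2 complete-case subjects in a group) produce flagged results
  with NaN P-values — or a `DegenerateInputError` at tabulation time —
  never silent numbers; the all-pairs scan reports flagged pairs and
  excludes them from the multiple-testing denominator.
* Missing genotypes are handled complete-case per SNP pair (unbiased under
  MCAR; no imputation).
* Allele orientation (which allele dosage counts) is cosmetic: every
  implemented statistic is relabel-invariant, so VCF alt-dosage input and
  the fixture's mutant-allele orientation are interchangeable.
* The scan's default adjustment is Bonferroni (conservative);
  Benjamini-Hochberg is available.
* Problem sizes in the automated studies: calibration at 10,000 replicates
  (~30 s), power on the full 10-point ln RR grid x 3 models at 200
  replicates/point (~20 s). The `--fast` CLI modes cut these to 2,000
  replicates and 200 replicates/point for interactive use.

## Limitations

* Two biallelic loci only; higher-order interactions and multiallelic loci
  are out of scope.
* P-values are asymptotic (no permutation option); with very few cases the
  F approximation, like the chi-square references, degrades.
* The Fst test is model-free: a significant pair says the gamete pools
  differ, not which interaction architecture produced the difference. Its
  power is lowest under recessive-by-recessive architectures, where only
  the AABB class carries signal.
* The case-only LD test assumes the loci are unlinked in the source
  population; background LD would inflate it.
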
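# Methods

This note documents the statistical models, the synthetic-data design,
the numerical choices, and the known limitations of `admixprs`.

## Clump-and-threshold PRS construction

Summary statistics are harmonized to the target panel before any PRS
step.  Matching is by (chromosome, position) plus allele
reconciliation — never by rsID, which drifts across builds and
releases.  If the effect allele equals the panel's alternate allele the
effect size is kept; if it equals the reference allele, alleles are
swapped and the effect negated; strand flips are resolved through
reverse complementation; A/T and C/G pairs are strand-ambiguous and
dropped (the conservative standard — frequency-based resolution is
deliberately not attempted).  Variants whose panel minor-allele
frequency is *strictly* below `maf_min` (default 0.01) are removed:
"below 1%" is a strict inequality, so a variant at exactly 1% survives.
A position carrying several panel allele pairs is used only on an exact
allele match, never guessed.  Every drop is counted by reason and
retained + dropped equals the input count; harmonization is idempotent.

Clumping is greedy: candidates are ordered by ascending p-value (ties
broken by chromosome then position, for determinism); the best
remaining variant becomes an index, and every other remaining variant
on the same chromosome within `window_kb` kilobases (symmetric distance
|posᵢ − posⱼ| ≤ window·1000) with r² *strictly greater* than `r2_max`
is removed from consideration.  LD is the squared Pearson correlation
of dosages over pairwise-complete samples.  The default grid is
R² ∈ {0.1, 0.2, 0.3} × windows {250, 500, 100} kb × 12 p-value
thresholds {5×10⁻⁸, 10⁻⁷, …, 10⁻², 0.1, …, 0.5}, i.e. 108 candidates
per GWAS.  The printed window set is used verbatim even though 100 kb
alongside 250/500 kb may look like a transposition of 1000 kb; the set
is configurable, so either convention is available.  Thresholding is
applied *after* clumping (p ≤ threshold, inclusive), so models within a
(R², window) cell are nested in the threshold; models with zero
variants are flagged degenerate and excluded from selection.

Scoring is additive in aligned effect-allele dosages.  Missing dosages
are imputed as 2·(effect-allele frequency) from the panel, which
preserves the score's expectation.  Model variants absent from the
panel are skipped with a logged count; if more than half are absent the
panel is considered mismatched and scoring fails hard.  An allele-label
flip (swap alleles, negate weight) shifts every raw score by a constant
2β and leaves standardized scores unchanged; the test suite asserts
this identity numerically.

## Selection by coefficient of variation

The cohort is reduced to a maximal unrelated set by iteratively
dropping the higher-degree member of each related pair (kinship above
0.0442, the 3rd-degree threshold), then dealt at random into k = 4
subsets whose sizes differ by at most one.  Subset assignment is not
stratified by center or background; nothing in the selection rule
requires it and unstratified assignment keeps the partition simple.
For each candidate model the MCI log-OR is estimated separately in each
subset (same covariate set as the primary analysis), and the candidate
minimizing CV = sample SD / |mean| of the k estimates is selected.

The absolute value in the denominator matters: subset log-ORs of a
useless score hover around zero and a signed mean could reward
candidates whose estimates flip sign.  A mean within 1e-8 of zero makes
the CV +∞ and the candidate degenerate; a candidate whose subset fit
fails to converge in any subset is likewise degenerate and never
selected.  Ties break toward fewer variants, then lower p-threshold,
smaller R², smaller window — preferring the sparser, stricter model.
Selection is invariant to relabeling the subsets, and the CV itself is
scale-invariant; both are asserted as tests.

Each selected model's standardization reference (mean and sample SD of
the raw score) is fitted on the full combined sample, not within
subsets, and stored on the model so an external cohort can be scored on
the training cohort's scale.  PRSsum is the unweighted sum of the
standardized component scores (a weighted sum would need an external
training dataset that this design assumes is unavailable) and is
re-standardized before association testing.  The APOE-excluded PRSsum
is built by removing *APOE*-region variants from each selected model
and re-scoring — never by post-hoc subtraction from the inclusive sum.
The *APOE* region is the 1 Mb window centered at chr19:44,908,822,
represented half-open [44,408,822, 45,408,822) for clean composition;
the boundary convention is configurable since a printed "1 Mb centered
at" a point does not pin down edge membership.

## Association models

Associations use fixed-effects maximum-likelihood logistic regression
(linear regression for cognitive-change outcomes) with Wald inference:
CI = estimate ± 1.96·SE.  This replaces logistic mixed models with
kinship/household/block random effects: binary GLMMs are heavy, their
variance components are not identifiable from anything this package can
see, and household clustering — the dominant sharing structure at desk
scale — is captured by cluster-robust (sandwich) SEs grouped on
household ID.  The substitution is recorded in every result's model
descriptor.  Wald tests are used uniformly (a Score test would differ
slightly in small samples); education enters as two indicator contrasts
against "no high-school diploma", center as indicators; genetic PCs
come from an SVD of the column-standardized dosage matrix with each
component's sign fixed by its largest-magnitude loading.  Collinear
designs and separation raise explicit errors rather than returning
unstable estimates.  No multiple-testing adjustment is applied; each
model's p-value is reported as is.

The primary analysis runs three blocks per score — APOE-inclusive PRS
unadjusted for ε counts, APOE-inclusive adjusted, APOE-excluded
adjusted — plus a sensitivity rerun dropping MCI+ (suspect severe
deficit) individuals.  Subgroup analyses reuse the full-sample
standardization (subgroup means of a standardized score are *not*
re-zeroed) and flag subgroups with fewer than 10 cases as unstable
while still reporting them.

Power for a standardized continuous predictor uses the Hsieh-type
closed form Φ(√(n·p(1−p))·|ln OR| − z₁₋α/₂); at OR = 1 it degrades to
α/2, the two-sided null rejection rate in one direction.  A vectorized
Monte-Carlo counterpart (per-replicate two-parameter Newton solver,
independent of the closed form) validates the formula to within 0.02
at 5000 replicates over a grid of (n, prevalence, OR).

The R² comparison of two PRSs computes each score's incremental
Nagelkerke R² over the covariate-only model and tests the difference by
a paired bootstrap over individuals (percentile CI, sign-based
two-sided p).  The analytic variance of an R² difference is replaced by
the bootstrap because it tests the same null without additional
distributional assumptions.

## Synthetic cohort generator

The generator produces the statistical structure the pipeline assumes,
not a realistic genome:

* **Genotypes.**  Variants live in equal-sized LD blocks laid out on
  autosomes (chr19 reserved for the APOE-like locus), 2 Mb apart, 10 kb
  between variants.  Each haplotype's alleles in a block come from an
  exchangeable latent Gaussian (shared factor + noise) thresholded at
  the allele-frequency quantile; the latent correlation is calibrated
  by bisection on the bivariate normal orthant probability so the
  *binary* allele r² hits the configured `block_r2` at the block's mean
  frequency.  Two haplotypes per individual are summed to dosages.
* **Admixture.**  Each individual belongs to one of six background
  groups (fractions and Dirichlet ancestry-proportion parameters chosen
  to mimic a heterogeneous Hispanic/Latino cohort: Mainland groups with
  high Amerindian/low African ancestry, Cuban with high European,
  Caribbean groups with high African ancestry).  Local ancestry is
  drawn per haplotype per block from the individual's proportions;
  ancestry-specific allele frequencies follow Balding–Nichols
  divergence (default Fst 0.05) drawn once per (ancestry, block) so
  that divergence behaves like haplotype background and the within-block
  LD target survives admixture.
* **APOE-like locus.**  Two SNPs at the rs429358/rs7412 positions.
  Haplotypes are drawn jointly from {ε2, ε3, ε4} with configured ε2/ε4
  frequencies (defaults 0.06/0.12), so the impossible both-minor
  haplotype never occurs; ε2/ε4 counts equal the two SNPs' dosages by
  construction.
* **Discovery GWAS.**  Per-variant estimates are true effect plus
  normal noise with SE = 1/√(2n·f(1−f)); p-values are two-sided Wald.
  The default suite has five GWAS with n from 5,000 to 80,000 —
  scaled-down stand-ins for the heterogeneous published AD GWAS (two
  large European studies, a biobank, a smaller African-ancestry study,
  a mid-size multi-ethnic study) at effect sizes the synthetic panel
  actually carries.
* **Phenotypes.**  MCI follows a logistic model whose linear predictor
  sums the polygenic liability (scaled so its variance is
  h²/(1−h²)·π²/3, h² default 0.15), APOE allele effects (defaults
  ε4 +0.4, ε2 −0.2 on the log-OR scale), covariate effects, and a
  shared-household normal intercept (default SD 0.3 — configurable, not
  calibrated, since no empirical household variance is available to
  target).  The intercept is calibrated by bisection so the expected
  case fraction equals the target prevalence (default 11%); an
  unattainable prevalence raises a calibration error.  Cognitive-change
  scores are linear in the standardized liability with Gaussian noise
  at the scale of published cohort summary tables.  About 13% of cases
  are flagged MCI+ for the sensitivity analysis.

What the generator does **not** emulate: recombination-map LD decay,
real haplotype sharing and cryptic relatedness beyond the explicit
kinship pairs, imputation error, survey sampling weights, and
genotype-covariate confounding beyond ancestry.  Passing tests
therefore demonstrate the correctness and calibration of the pipeline's
statistics under its stated model, not transferability of any specific
PRS to a real cohort.

## Problem sizes and numerical choices

Test and validation runs use deliberately modest sizes chosen to make
the Monte-Carlo bands tight enough to be meaningful: LD calibration at
n = 2,000; type-I error over 2,000 null replicates at n = 500 (accepted
band [0.035, 0.065]); CI coverage of a generating per-SD effect of
log(1.3) over 200 replicates at n = 5,000 (required ≥ 90%); the
APOE-pattern comparison over 100 replicates at n = 1,200; power-formula
validation at 5,000 replicates per grid point.  The clumping
implementation is validated against an independent brute-force oracle
on 500 random panels of up to 50 variants across the full 108-cell
grid.  All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); with a fixed seed every output is
bit-reproducible, and the pipeline manifest records seeds and SHA-256
hashes of all inputs and outputs.

## Known limitations

* Fixed-effects + sandwich SEs approximate, but do not reproduce, a
  mixed model's conditional estimates; marginal log-ORs are slightly
  attenuated relative to conditional ones when clustering is strong.
* The CV selection rule is implemented exactly as specified, but its
  behavior when all candidates are near-null is dominated by the
  degeneracy guard rather than by meaningful ranking.
* Genome-build liftover, INDEL normalization, multi-allelic splitting,
  Bayesian shrinkage PRS methods, and chromosome-X dosage conventions
  are out of scope; inputs must share one genome build.
* The Hsieh closed form is an asymptotic approximation; it is validated
  here to ±0.02 at moderate effect sizes (OR ≤ 1.5) and should not be
  trusted for extreme effects or tiny case counts.
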
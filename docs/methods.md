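# Methods

## The integration model

`eqtligate` treats a variant as disease-relevant only when three
statistically independent layers of evidence agree. Each layer is a
standard test; the contribution is the conjunction and the order in which
filters are applied.

**QC and candidate SNPs.** Genotypes are additive ALT-allele counts
(0 = wild-type, 1 = het, 2 = hom-ALT); a *variant sample* for a SNP carries
≥1 ALT allele. Per SNP we compute the folded minor-allele frequency
MAF = min(f, 1−f) with f = (n₁ + 2n₂)/2n, and a 1-df goodness-of-fit
chi-square of the genotype counts against Hardy-Weinberg proportions
(p², 2pq, q²). A SNP is a candidate when HWE p ≥ α_HWE and MAF ≥ 0.1.

*HWE scope.* When phenotypes are available the HWE statistic uses control
(normal) samples only, the convention of case/control QC tools such as
PLINK. The pooled cohort is a mixture of case and control allele
frequencies, and any truly associated SNP departs from pooled HWE purely
through that mixture (Wahlund effect: expected chi-square ≈ n·F² with F the
standardized frequency variance), so a pooled filter would preferentially
remove real signals. Without a phenotype table the pooled counts are used.

*Thresholds.* Two HWE levels are exposed because the source protocol uses
both: 0.05 at an upstream candidate-screening step and 0.001 at the
association (PLINK) stage. The pipeline default for the candidate filter is
0.05; the recovery and acceptance runs use the analysis-stage 0.001,
because the 0.05 screen belongs to upstream variant-calling QC that is out
of scope here, and because any α-level filter re-applied to final truth
removes each true SNP with probability α (a 0.05 filter on five true SNPs
fails exact recovery in ~23% of cohorts by construction). Both are plain
config fields (`hwe_candidate_alpha`, `hwe_assoc_alpha`).

SNPs with >10% missing genotype calls are dropped with a warning; all other
per-SNP statistics exclude missing calls pairwise.

**Association.** The allelic test builds the 2×2 ALT/REF × case/control
allele-count table and applies the Pearson chi-square (1 df, no continuity
correction — PLINK `--assoc`). Significance is a fixed genome-wide
threshold, default 5×10⁻⁸; no FDR at this stage. A genotypic 2-df variant
(3×2 genotype table) is available via `assoc_test: genotypic`. Zero-margin
tables (cohort-monomorphic) get p = 1 and a `degenerate` flag.

**Dual eQTL.** Each candidate SNP is tested only against its cis-mapped
gene. Expression enters every statistical model as log2(FPKM + 1) — FPKM
values are right-skewed and heteroscedastic, and the shifted log is the
standard variance-stabilising choice; the raw matrix is never modified.

*Algorithm 1 (ANOVA).* One-way ANOVA, F = (S_A/(s−1))/(S_E/(n−s)) with
S_A/S_E the between-/within-group sums of squares, under two
stratifications: (A) among variant carriers, groups = disease vs normal;
(B) among disease samples, groups = genotype codes present (s ≤ 3). Groups
with <2 members are dropped and s reduced; pairs with <2 usable groups are
excluded with a reason. BH-FDR is applied within each stratification and
the two pass sets are merged by union (q < 0.05 in either). The protocol's
description of stratification (A) admits a second reading — genotype-group
ANOVA over all samples — which is implemented behind
`anova_stratification_a: all_samples_genotype_groups`; the carrier reading
is the default.

*Algorithm 2 (additive model).* OLS of g on [1, k, x] with x the genotype
code and k the disease indicator; the γk term absorbs phenotype-driven
expression shifts so that β captures genotype effect only (omitting k
demonstrably inflates false positives on cohorts where genotype and
phenotype are correlated — this is covered by a test). Student t on β with
n−3 residual df; BH-FDR across all tested cis pairs, pass at q < 10⁻⁶.
Constant-genotype and rank-deficient designs are excluded with reasons; a
constant covariate is dropped (γ = 0); zero-residual fits are flagged
(`degenerate` when β ≈ 0, `perfect_fit` otherwise).

SNPs passing **both** algorithms are candidate risk SNPs; their mapped
genes are the candidate genes.

**Enrichment and final selection.** The query set is candidates ∪ known
causal genes; the universe is the expressed transcriptome (genes surviving
the FPKM > 0.5 in ≥ ceil(0.30·n_samples) samples filter — the background a
practitioner actually tested, since the protocol does not state its
universe). Categories with any query overlap get the hypergeometric
upper-tail p, P[X ≥ k], BH-adjusted over tested categories. A category is
*disease-related* iff q < 0.05 and it contains ≥1 candidate and ≥1 known
causal gene. A candidate gene becomes a susceptibility gene when it lies in
a disease-related category **and** one of its own candidate SNPs is
association-significant (the strict per-gene reading); that SNP is a risk
SNP. The report also gives per-phenotype variant-carrier counts per gene.

**Validation battery.** For every reported gene: (i) four
differential-expression contrasts (disease/normal; variant/nonvariant in
all, normal-only and disease-only samples) using a pooled-variance
two-sample t on log2(FPKM+1) — equivalent to an unmoderated two-group
linear-model fit; empirical-Bayes variance moderation is deliberately not
reproduced, a deviation that matters little at these group sizes. A missing
group (e.g. no variant carriers among normals) marks the contrast
untestable rather than erroring. (ii) Coexpression with a known causal gene
from the gene's disease-related category, by Pearson, Spearman and Kendall,
separately in variant and nonvariant samples — a cis variant that disrupts
co-regulation shows significance only in the nonvariant stratum.
(iii) Single-gene LOO AUC for three tasks (variant/nonvariant in all and in
disease samples; disease/normal). The classifier is the documented
class-mean **midpoint rule**: per LOO fold the held-out decision value is
the sample's offset from the midpoint of the training class means, oriented
along the feature axis; pooled held-out values are scored by Mann-Whitney
AUC. Any single-feature linear margin rule is monotone in the feature, so
the AUC is rule-invariant up to orientation; the fixed orientation makes
AUC(x) + AUC(−x) = 1 and leaves a negatively-oriented marker below 0.5.

## The synthetic cohort generator

The generator is first-class, tested code; its defaults define the study
conditions rather than being tuned per test.

* Sample shape: the `paper-shape` preset mirrors the reference cohort
  (98 disease / 91 normal); `power-shape` (300/300, 500 SNPs, 5 planted) is
  used for recovery, and `null` (300/300, 2000 SNPs, nothing planted) for
  calibration.
* Null SNPs: ALT frequency ~ U(0.1, 0.5), genotypes sampled genotype-wise
  from (p², 2pq, q²) identically in both phenotypes — genotype-wise
  sampling makes the HWE filter's behaviour exactly calibrated.
* Planted SNPs: HWE within each phenotype at ALT frequency 0.55 (cases) and
  0.25 (controls); the 0.3 gap gives allelic chi-square noncentrality ≈ 112
  at n = 600, comfortably past the 5×10⁻⁸ threshold.
* Optional HWE violators: genotypes drawn with inbreeding F = 0.8
  (heterozygote deficit), expected chi-square ≈ n·F², so they are flagged
  essentially always.
* Expression (FPKM-like): per-gene baseline ~ U(2, 8); a planted gene is
  baseline + 2.0·genotype + 2.0·1[disease] + N(0, 0.5), clipped at 0; null
  genes are baseline + noise. Known causal genes are deliberately
  expression-null so that the co-occurrence filter — not expression
  signal — is what links them to candidates.
* Categories (size 10, 20 of them): each planted gene shares a category
  with 4 known causal genes plus null fill; two known-only categories
  exercise the co-occurrence rule's negative branch; the rest are null.
* Determinism: a single `numpy` Generator seeded from the config; identical
  config + seed gives byte-identical bundles (fixed float formatting).

What the simulator does **not** emulate: linkage disequilibrium, population
stratification, read-level sampling noise, trans effects, multi-SNP genes,
and correlated expression beyond the planted effects. Passing tests
therefore demonstrate the pipeline's logic and calibration under the
stated generative model, not performance on real sequencing artifacts.

## Numerical and design notes

* BH-FDR is the step-up procedure (via statsmodels) wherever the protocol
  says "FDR"; the original procedure is unnamed.
* p-values come from scipy's survival functions (chi², F, t,
  hypergeometric); closed-form statistics are computed directly and
  cross-checked in tests against independent oracles (brute-force sums of
  squares, normal-equations OLS, tail enumeration, `f_oneway`,
  `chi2_contingency`, statsmodels OLS).
* Threshold conventions: "greater than 0.5" is strict; "at least 30%" uses
  ceil of the sample count; candidate filters use p ≥ α (removing SNPs
  significantly out of HWE).
* Multiallelic VCF records are rejected rather than split; the model is
  strictly biallelic.
* Problem sizes in tests and the acceptance script (600-sample recovery
  cohorts, 2000-SNP null cohorts, 10 recovery seeds) were chosen so the
  planted effects sit far from decision boundaries while a full run stays
  in the tens of seconds.

## Known limitations

* The exact HWE test (mid-p) is not implemented; the 1-df chi-square
  matches the rest of the chi-square register but is anticonservative at
  very low MAF.
* cis means "the SNP's mapped gene" only; no window-based or trans scan.
* The enrichment universe choice (expressed genes) and the ANOVA
  stratification-(A) reading are documented judgment calls; both have
  config escape hatches where alternatives exist.
* The validation battery's DE stage is unmoderated; with very small variant
  groups a moderated test would be more stable.
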
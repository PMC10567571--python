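# Methods

This note documents the statistical models implemented in `pqtlkit`, the
design of the synthetic cohort generator, and the numerical and design
choices that were genuinely open.

## Scope and setting

`pqtlkit` implements the analysis stack used to compare two affinity-based
plasma proteomics platforms through genetics: assay precision statistics,
inter-platform concordance of protein levels, protein quantitative trait
locus (pQTL) discovery with recursive stepwise conditional analysis,
cross-platform pQTL correspondence, single-causal fine-mapping and
colocalization, association power, protein–phenotype scans, and a
confidence-tier classification of targets. Individual-level biobank data
of the kind these analyses were designed for are access-controlled, so the
package ships a seeded generator that produces a two-platform cohort with
the statistical structure the analyses assume; every stage runs end to end
with no download.

Platform "A" throughout is an antibody-based platform (paired binders,
core + expansion panel sets, a substantial below-LOD fraction); platform
"B" is an aptamer-based platform (occasionally more than one assay per
target).

## Assay precision

Protein levels `x` are modelled as log-normal. With log-scale mean `mu`
and variance `sigma^2`, the mean level is `exp(mu + sigma^2/2)` and the
coefficient of variation (s.d./mean) is

    CV = sqrt(exp(sigma^2) - 1),

independent of `mu`. For duplicate measurements, the log-scale s.d. is
estimated robustly from the paired log differences `d_i = log x_i1 - log
x_i2`: `sigma_d = 1.4826 * MAD(d)` (the normal-consistency constant) and
`sigma = sigma_d / sqrt(2)` because a difference of two independent
equal-variance measurements has twice the variance of one. Neither
constant is forced by the definition of the MAD estimator; both are the
standard choices and are stated here because alternative conventions
exist. The random-pair CV replaces duplicates by seeded uniform pairs of
distinct donors, so biological variance enters; duplicate CV is below
random-pair CV in expectation whenever biological variance is positive,
and the package's tests check this ordering.

The batch-susceptibility statistic is the ratio of same-plate control CV
to across-plate control CV, clipped to [0, 1]: near 1 means plate effects
contribute little; near 0 means they dominate. Only the main-text form of
this statistic is implemented; vendor-specific refinements are out of
scope.

SMP normalization divides, within each dilution group, each sample's
levels by that sample's median ratio to a per-assay cohort-median
reference. The vendor's proprietary reference population is unavailable,
so the cohort median serves as the reference; the reference and the
per-sample factors are alternated to a fixed point (tolerance 1e-12, at
most 200 rounds), which makes the operation idempotent up to that
tolerance. One consequence of the median-based anchor: multiplying one
sample by a constant is removed exactly in relative terms, while the
cohort-wide scale may shift by a single global constant.

Assay LODs are carried in the panel; measurements below the LOD are
retained (flagged by per-assay below-LOD fractions), because strongly
censored assays can still carry genetic signal.

## Phenotype preparation and association testing

For each assay, levels (first measurement per donor) are transformed to
Blom rank-normal scores `Phi^-1((r - 3/8)/(n + 1/4))` (ties receive
average ranks), residualized by OLS on age, sex and sample age, and
transformed again, yielding a unit-variance phenotype. Association uses
ordinary least squares of the phenotype on alternate-allele dosage
(optionally with conditioning dosages); the p-value is the nested-model
likelihood-ratio statistic `n * log(RSS0 / RSS1)` referred to chi-squared
with 1 df. Effects are phenotype-s.d. units per alternate-allele copy; the
effect allele is always the alternate allele.

OLS on unrelated individuals replaces a linear mixed model: the synthetic
donors carry no relatedness or stratification, so the mixed-model
relatedness term and LD-score-regression intercept correction would be
inert. The genome-wide threshold is fixed at 1.8e-9 as a constant of the
analysis tradition the package follows; its derivation from variant-class
weighting is not re-derived here.

## Stepwise conditional analysis

Discovery per assay and chromosome restricts to candidates with marginal
P < 5e-6 and then greedily selects, at each round, the candidate with the
smallest conditional P given the already-selected set — provided that P is
below 1.8e-9 — recording each signal's conditional statistics at its
selection step. Ties in the minimum break by smaller position, then
lexicographic variant id, making discovery order deterministic. Candidates
that become collinear with the selected set are skipped; selection beyond
n/2 variants aborts with an error. A joint multiple-regression model of
all selected variants then provides per-variant joint effects and
drop-one likelihood-ratio p-values, flagging signals that lose genome-wide
significance jointly. The engine is verified against an independent
brute-force forward-selection oracle (statsmodels fits, explicit loops) on
random instances.

## Regions, cis/trans, clumping

Signals merge into regions by transitive single-linkage chaining at 2 Mb
(inclusive) per chromosome; any variant inside the configured MHC interval
(build-38 chr6:25.5–34.0 Mb) joins a single MHC region regardless of
chaining. The most significant variant by marginal P in each region is the
sentinel (rank 1; ties again by position then id); other signals keep
discovery-order ranks. A signal is *cis* iff it lies on the target gene's
chromosome within 1 Mb (inclusive) of its transcription start site, else
*trans*; windows use absolute base-pair distance with 1-based, inclusive
coordinates.

Across assays, signals are clumped into pQTLs greedily: the most
significant unclustered signal seeds a cluster and absorbs unclustered
signals whose variants have r² > 0.8 (strict) with the seed. Variants
associated with more than 10 distinct proteins are flagged non-specific;
more than 50, pleiotropic; proteins whose every pQTL is a non-specific
trans signal are flagged as potentially mis-targeted. Greedy seeding can
differ from the full transitive closure when LD chains through
intermediate variants; tests compare against a closure oracle and require
agreement whenever the two partitions have equal size.

## Cross-platform correspondence, replication, power, tiers

A sentinel on one platform corresponds to the other platform when any
signal (sentinel or secondary) of a same-target assay within 5 Mb is in
high LD (r² > 0.8, strict — r² = 0.8 exactly does not match) with it, with
LD computed in one designated reference genotype panel per comparison.
Correspondence is deliberately asymmetric between directions. Replication
of a single association requires P < 0.05 in the other cohort with the
same effect direction after allele alignment.

Power for the 1-df test at threshold `P`, sample size `N`, per-allele
effect `beta` and allele frequency `f` is

    1 - F(X^-1(1 - P), 2 N beta^2 f (1 - f)),

with `F` the noncentral chi-squared CDF (1 df) and `X^-1` the central
chi-squared quantile. At `beta = 0` the value is exactly `P` (special-
cased to avoid floating-point loss in the noncentral branch).

Targets are organized into confidence tiers: tier 1 — cis pQTL on both
platforms and strong inter-platform correlation; tier 2 — cis pQTL on at
least one platform but missing the other condition; tier 3 — cis pQTL on
neither. "Strong" defaults to Spearman r ≥ 0.5; no published value exists
for this cutoff, so it is configurable.

## Fine-mapping and colocalization

Per-variant evidence is the Wakefield approximate Bayes factor from
`z = beta/se` with shrinkage `r = W/(W + se^2)`:

    ABF = sqrt(1 - r) * exp(z^2 r / 2).

The prior effect variance defaults to W = 0.04 (prior s.d. 0.2 on the
standardized scale, for quantitative traits and on the log-odds scale for
binary ones); published descriptions of this analysis cite the
fine-mapping literature without a parameter value, so the default is this
package's choice. Under a flat single-causal prior, posteriors are
normalized ABFs and the 95% credible set is the minimal prefix in
decreasing-posterior order reaching 0.95 (ties by variant id). Credible
sets use marginal statistics for sentinels and conditional statistics for
secondary signals, over a ±1 Mb window around the signal (configurable;
no published window exists). A trait-associated variant is related to a
pQTL iff it is in high LD with the signal variant *and* a member of the
signal's credible set; both conditions are reported separately.

Colocalization over a shared variant list enumerates five hypotheses with
prior weights p1 = p2 = 1e-4, p12 = 1e-5 (the upstream defaults):
H0 = 1, H1 = p1·ΣBF_A, H2 = p2·ΣBF_B, H3 = p1·p2·(ΣBF_A·ΣBF_B − ΣBF_A·BF_B),
H4 = p12·ΣBF_A·BF_B, normalized to posteriors. All sums are accumulated in
log space (logsumexp); the H3 difference uses a guarded log1p and is set
to −inf when cancellation is complete (single-variant loci, or one variant
holding all mass), which is the correct limit. Posteriors sum to 1 to
1e-9 and are invariant to permuting the variant list; p12 → 0 forces
PP4 → 0. Only single-causal fine-mapping is provided; multi-causal
stochastic-search methods are out of scope.

## Protein–phenotype scans

Binary phenotypes with more than 50 cases are fitted by maximum-likelihood
logistic regression of disease on RINT-standardized protein level plus sex
and age (sample age optionally), reporting an odds ratio per s.d.;
quantitative traits are inverse-normal transformed and fitted by OLS.
Fits that separate (any fitted probability pinned to 0/1) or fail to
converge return flagged records rather than raising. Family-wise error is
Bonferroni-controlled over the number of assays on the platform
(threshold = FWER / n_assays). Because the protein enters after RINT, all
estimates are invariant to affine rescaling of raw levels. The scans
assume RINT-standardized protein levels for the per-s.d. scale; whether
raw or normalized levels are preferable is a reporting convention, not a
statistical necessity.

## The synthetic cohort generator

The generator's defaults define the study conditions for all end-to-end
tests; they are chosen once, as follows.

**Genotypes.** Variants live in LD blocks (default: 10 blocks of 25
variants over 1 Mb spans, blocks on the same chromosome spaced 10 spans
apart so inter-block LD and accidental region chaining are negligible).
Within a block, two latent Gaussian haplotype vectors per donor with
correlation `exp(-distance * ld_decay)` are thresholded at each variant's
minor-allele frequency; major/minor orientation is then applied by
recoding dosages `2 - d`, which preserves LD exactly. The default MAF
spectrum is log-uniform on [5e-4, 0.5], which produces rare (MAF < 1%)
variants; `ld_decay` defaults to 2e-6 per bp. A second population, when
enabled, shares variant positions but draws frequencies independently
(so some variants are effectively population-specific) and can use a
faster decay, reproducing the smaller high-LD classes of more diverse
populations. This copula construction is a deliberate simplification: it
gives controllable LD without recombination maps or a coalescent engine,
and it does not model haplotype phasing, mutation-age/frequency
correlation, or long-range LD.

**Proteome.** Each protein receives a baseline log abundance (uniform on
[2, 8], mapped to dilution groups by tertile — abundant proteins run at
high dilution), one cis causal variant within 1 Mb of its TSS with effect
drawn N(0, 0.5²) on the log scale, trans effects from a configurable
network (the default network includes one hub variant affecting 55
proteins, so the pleiotropy machinery is exercised), and donor-level
biological noise (s.d. 0.42). 60% of proteins are targeted on both
platforms; platform B occasionally (10%) carries two assays for a shared
target.

**Measurements.** Measured log level = true level + epitope term ×
dosage (one platform only) + plate effect + platform noise; raw level =
exp(log level). Platform noise s.d. defaults are 0.164 (A) and 0.099 (B),
chosen so duplicate-based CVs land near 16.5% and 9.9% — the regime of
interest for the precision comparison; plate s.d. 0.05/0.08; donors fill
96-well plates sequentially; 3% of donors are re-measured on the same
plate with symmetric duplicate links. Per-assay LODs are set at the 5% (A)
and 1% (B) quantiles of the measured distribution; censored values are
retained. Epitope protein-altering variants (probability 0.1 per shared
target) shift measured levels of one platform by ±[0.5, 1.0] per allele
and never touch true levels — the generative definition of an assay
artifact.

**Phenotypes.** Binary phenotypes follow a liability threshold on a
weighted sum of standardized true protein levels plus standard-normal
noise, thresholded at the quantile matching the stated prevalence;
quantitative traits are linear with Gaussian noise. A trait-hit catalogue
(the synthetic analogue of a GWAS catalogue) lists each phenotype's causal
variants as inherited through the weighted proteins, with catalogue-style
p-values and effect directions.

All draws derive from one `numpy` Generator seeded by the config; fixing
the seed fixes every output byte, which the determinism tests verify by
byte comparison of written artifacts.

**What the generator does not emulate.** Relatedness and population
stratification (hence OLS), platform-specific proteoform targeting (the
main driver of the modest real-world inter-platform correlation — the
synthetic matched-assay correlation is high because both platforms measure
the same true levels), normalization pipelines beyond SMP, sample
handling/storage interactions, and genotyping/imputation error (info
scores are 1). Passing tests therefore demonstrate the correctness and
calibration of the estimators under the stated model, not the
reproduction of any particular cohort's headline numbers.

## Problem sizes

The shared defaults (2,000 donors, 250 variants in 10 blocks, 60 proteins,
~100 assays) were chosen so a full pipeline pass — simulation, QC,
concordance, two-platform pQTL mapping, correspondence and tiers — is a
desk-scale computation, while keeping per-assay power high enough that
planted cis effects of |beta| ≳ 0.3 are discovered at 1.8e-9. Calibration
suites use 500 fine-mapped loci, 20 colocalization seeds per hypothesis,
and 200–1,000 simulated effects for interval coverage.

## Known limitations

* Single-causal fine-mapping only; credible sets are miscalibrated when a
  locus truly carries multiple causal variants.
* Greedy LD clumping is order-dependent where LD chains; the closure
  comparison quantifies this.
* The MAD-based CV estimator is robust but noisier than the sample s.d.;
  at sigma = 0.5 its typical relative error at 500 pairs is a few
  percent, with occasional larger excursions.
* The liability-model threshold uses the theoretical liability s.d., so
  realized prevalence fluctuates binomially around the target.
* The batch-susceptibility ratio follows the main-text definition only.
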
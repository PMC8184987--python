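# Methods

This note documents the statistical models the package implements, the
generative models behind the synthetic data, the defaults and why they were
chosen, and what the tests do and do not establish.

## Estimators

**Logistic regression** (`statcore.logistic_fit`) maximizes the Bernoulli
likelihood by iteratively reweighted least squares; convergence is declared
when the score max-norm falls below 1e-8, with a cap of 25 iterations
(standard GLM defaults; deterministic). Wald standard errors come from the
observed information at the optimum. Rank-deficient designs raise a
`SingularDesignError`. Perfectly separated data are reported as
non-converged rather than silently returning a penalized or truncated fit:
separation is detected when the Wald se explodes relative to its
coefficient (se > 100·(1+|β|)), which is how a vanishing score at an
infinite MLE manifests. Firth or otherwise penalized regression is out of
scope; tiny strata fail loudly instead.

**Cox proportional hazards** (`statcore.cox_ph_fit`) maximizes the Breslow
partial likelihood by Newton-Raphson. Breslow's treatment of ties is used
because onset ages recorded in whole years guarantee heavy ties and it is
the simplest well-defined convention; the test suite cross-checks against
lifelines on tie-free data, where Breslow and Efron coincide, and against a
brute-force grid maximizer on a tied toy dataset. Rows are internally
sorted by a canonical (time, event, covariates) key so results are
bit-identical under input permutation. Monotone likelihoods (e.g. one
group's events all preceding another's) are flagged non-converged by the
same divergence guard as above.

**Wilcoxon rank-sum** (`statcore.wilcoxon_rank_sum`) reports the rank-sum
of the first sample and a two-sided p-value: exact enumeration is
auto-selected for n1+n2 ≤ 12 without ties, otherwise a normal approximation
with tie and continuity corrections (scipy's Mann-Whitney machinery). Both
modes can be forced, since published analyses rarely state which was used.
In the regime where the approximation is actually applied (n1+n2 > 12) it
agrees with exact enumeration to within 0.015; at the very smallest sizes
the approximation would be off by up to ~0.09, which is why exact mode is
the default there.

**Hardy-Weinberg exact test** (`statcore.hwe_exact_test`) is the exact
conditional test: given the allele counts, it sums the probabilities of all
heterozygote counts no more probable than the observed one. The test suite
verifies it against an independent integer-arithmetic enumeration for every
genotype table with up to 200 alleles.

**Quantiles** (`statcore.quantile_boundaries`) use linear interpolation
between order statistics (numpy's default). The convention matters because
percentile-bin membership near a boundary depends on it; bin assignment is
right-closed (a score exactly on a cut-point goes to the lower bin, the
lowest bin is closed on both ends), and out-of-range scores clamp to the
extreme bins so assignment is total.

## Summary statistics and meta-analysis

Files are tab-separated with canonical columns CHR, BP, SNP, A1
(effect allele), A2, FRQ_A1, BETA or OR (optionally OR_L/OR_U bounds), SE,
P, N, INFO; coordinates are 1-based GRCh37 and gzip is transparent. Odds
ratios are converted to log scale on read; a missing SE is reconstructed
from a 95% CI assuming log-scale symmetry, se = (ln U − ln L)/(2·1.96); a
missing P is filled from the Wald z. Malformed rows are collected with
reasons, never silently dropped.

Harmonization aligns effect alleles to a reference keyed by chrom:pos,
negating β and complementing the frequency on flips and resolving strand
with base complements. Palindromic (A/T, C/G) variants with effect-allele
frequency in [0.40, 0.60] are dropped as strand-unresolvable — the
conventional window; the cut is a documented choice, not an empirical fact.

By-proxy effect estimates are rescaled to the case-control scale by
doubling β and se (z preserved exactly). The factor 2 reflects that a
genotyped offspring shares half of each parent's genome, so a parental
phenotype regression attenuates the per-allele effect by half; it is
configuration, not a constant, because published proxy pipelines differ in
where the rescaling is applied. Records carry a `rescaled` flag and a
second application is an error.

Variant QC applies independent rules — call rate > 0.95, MAF > 0.01, HWE
exact p ≥ 1e-4 in controls (on hard-called genotypes: dosages further than
0.1 from an integer are treated as missing for this rule only), no
differential missingness between cases and controls, and imputation
R² ≥ 0.30 when an INFO map is supplied. The differential-missingness
statistic is a two-sided Fisher exact test at p < 1e-6; the rule is
standard but its statistic and cut-off are rarely published, so both are
explicit package choices.

Fixed-effects IVW pooling follows the precision-weighted-mean algebra given
in the README; Cochran's Q is computed and reported but never used to
filter (fixed effects throughout; random-effects models are out of scope).
Clumping is greedy on ascending p (ties break toward the smaller
coordinate), with inclusive windows; a forced-sentinel list lets a region
like *APOE* be represented by designated variants (rs429358/rs7412) rather
than whatever clumping would pick. Pairwise LD is the squared dosage
correlation; D′ comes from EM haplotype-frequency estimation on hard calls.
Missing LD values for in-window pairs default to r² = 0 with a log (or can
be made a hard error).

Reconstructed p-values for published loci are deliberately not compared
against printed ones: inputs rounded to two decimals perturb a p-value by
orders of magnitude while moving the combined odds ratio by well under
0.015, so reproduction is asserted on the odds-ratio scale only.

## PRS and stratification

Scores are weighted dosage sums; missing dosages are mean-imputed as twice
the in-sample effect-allele frequency (preserves the score expectation).
Standardization defaults to the mean/SD of all analyzed individuals, with
an n−1 denominator; a controls-only reference is available by argument
because published analyses seldom state which convention they used.

The packaged 39-variant weight table mirrors the canonical score's
structure (39 genome-wide-significant loci, *APOE* excluded, columns SNP,
A1, WEIGHT, SOURCE plus CHR/BP/MAF for simulation). Its values are
synthetic placeholders of realistic magnitude — the original weight table
is not redistributable — and nothing quantitative in the package depends on
the specific numbers.

Survival-bias-corrected percentiles anchor bin boundaries on controls aged
≤ 55 and assign everyone by those boundaries. Combined strata split each
pooled *APOE* group into its configured number of PRS bins (canonically
7/25/15/3), anchoring within-group boundaries on the group's young controls
when that anchor is at least as large as the bin count and falling back to
all group members otherwise (tiny strata). The ε2ε4 genotype is pooled with
ε3ε4 even though ε2 and ε4 act in opposite directions — matching the
analysis design this package reproduces — and the double heterozygote at
rs429358/rs7412 is called ε2ε4 under the convention that the rare ε1
haplotype is absent. The case-only Cox model centers the PRS so *APOE* main
effects are at-mean-PRS effects, with ε2ε2/ε2ε3 as the reference level.
Because published onset-by-age curves could be either nonparametric or
model-based, `survival_curves` exports both: Kaplan-Meier per group (the
empirical onset CDF, as all cases are events) and Breslow-baseline Cox
curves at each group's mean linear predictor, labelled by method.

## The synthetic-data generator

`synthdata.simulate_cohort` draws, per individual: variant dosages
(Binomial(2, maf) under HWE), an *APOE* genotype from configured genotype
probabilities, a standard-normal polygenic score z independent of the
variants, four standard-normal ancestry components and sex. Disease status
follows the logistic liability

    logit P(case) = α + Σᵢ ln(ORᵢ)(gᵢ − 2 mafᵢ) + ln(OR_APOE[group])
                  + ln(OR_perSD)·z,

with α solved numerically so the expected case count matches the
configured size. Case AAO is drawn from a normal with sd 8 years truncated
to [40, 105], whose median depends on the individual's stratum: within each
*APOE* group, the stratum is the population-quantile PRS bin of z, and bin
medians interpolate linearly in bin index between configured extreme-bin
medians (the interior shape is unconstrained by the published extremes;
linear is the least-structured choice). Control examination ages are a
two-part uniform mixture — (40, 55) and (56, 90) — placing the configured
fraction of controls at or below the 55-year anchor.

Default study conditions: 6,331 cases and 6,055 controls with 3,546
controls aged ≤ 55; *APOE* genotype probabilities reproduce the pooled
group sizes 998/7611/3399/382 (the published pooled totals sum to 12,390
against a cohort of 12,386; probabilities are normalized), split within
pooled groups by conventional population ratios (ε2ε2 0.5%, ε2ε4 2%);
per-SD OR 1.27; extreme-bin AAO medians (82, 83) for ε2ε2/ε2ε3, (82, 81)
for ε3ε3, (81, 77) for ε2ε4/ε3ε4, (78.5, 73) for ε4ε4; concomitant-
pathology rates 84% (any) and 48.8% (more than one) among cases; 60%
female. The *APOE* odds ratios {0.6, 1, 3, 12} versus ε3ε3 are
order-of-magnitude literature-style placeholders shipped as editable
configuration — the source analysis prints none — and no reproduced
quantity depends on them.

Summary statistics are simulated as β̂ ~ Normal(ln OR_true, se) with
se = (2·maf·(1−maf)·n_eff)^(−1/2), n_eff = 4/(1/n_cases + 1/n_controls);
proxy studies emit β̂/2 and se/2 so the rescaling step restores the
case-control scale with z unchanged. LD blocks use a copy-with-mutation
haplotype scheme: each member haplotype copies the tag allele with
probability √r² and redraws Bernoulli(maf) otherwise, giving exactly the
target allele-level correlation with the tag while preserving the marginal
frequency. Everything is deterministic given (config, seed).

**Two purpose-built configurations.**
`GeneratorConfig.prs_validation` isolates the polygenic term (no variant
effects, all *APOE* ORs 1). This is the configuration for per-SD recovery
studies, for a substantive reason: the logistic odds ratio is not
collapsible, so with additional independent liability components present
the marginal per-SD estimate is attenuated below the generative conditional
value (≈1.21 recovered for a generative 1.27 under the full default
configuration). Recovery of a generative marginal effect is therefore only
well-posed when that effect is the sole liability term.
`GeneratorConfig.aao_recovery` enriches the *APOE* genotype frequencies so
the extreme combined strata each hold thousands of cases, and sets the
polygenic score's status effect to zero so the young-control anchor is
representative of the population score distribution and bin boundaries are
recovered without selection shift; the score then drives only the onset-age
strata, which is the machinery under test.

**What the generator does not emulate:** realistic genome-wide LD (only
block-local correlation), linkage between the score variants and *APOE*,
genotyping/imputation error beyond optional dosage missingness, family
structure, age-dependent incidence in controls, and secular or site effects.
Passing recovery tests therefore demonstrates that the pipeline's
estimators and assignment logic are correct under the stated models — not
that the published estimates are themselves unbiased in real data.

## Problem sizes and numerical choices

The replication recipes run 200 cohort replicates at the 12,386-individual
scale for the per-SD and extreme-percentile recoveries, 500 replicates at
the 1,718-individual case-series scale, and 8 cohorts with ≥ 5,000 cases
per extreme stratum for the onset-age gaps (averaging replicate gaps brings
the Monte-Carlo error of a median difference to ~0.1 years). These sizes
were chosen so each replicate-mean's Monte-Carlo error is several times
smaller than the quantity's reproduction tolerance. All child seeds derive
from a single seed via numpy's SeedSequence.

Tolerances used in tests mirror each quantity's identifiable precision:
±0.015 on odds ratios reconstructed from 2-decimal printed inputs (the
rounding bound), replicate-mean bands of ±0.02/±0.03 on per-SD odds
ratios, and ±0.5 years on median onset gaps.

## Known limitations

Logistic and Cox fits assume complete-case data; no penalized fallback for
separated strata; clumping assumes the LD provider covers in-window pairs
(missing pairs default to independence); the P+T sweep clumps once at the
strict settings rather than re-clumping per threshold (equivalent under a
fixed LD reference, cheaper, and guarantees nesting); D′ assumes
random-mating phase frequencies via EM; the CLI handles the packaged
tab-separated layouts only.
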
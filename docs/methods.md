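# Methods

This note documents the statistical machinery in `popmeth`: the models each
stage fits, the defaults and why, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was open.

## Scales and conventions

Methylation is stored as β (methylated fraction, in [0, 1]) and analysed as
M = log₂(β/(1−β)). M values have near-constant variance across the dynamic
range and behave well in linear models; β values are retained for effect
sizes because a "5% methylation difference" is directly interpretable.
β at or beyond {0, 1} is clamped to [10⁻⁶, 1−10⁻⁶] before the logit — a
perturbation below measurement precision that keeps M finite.

Genotypes are additive dosages counting the **derived** allele where the
ancestral state is annotated (falling back to the alternate allele,
flagged). Positions are 1-based in memory and TSV; BED output is 0-based
half-open. The two populations are labelled AFB and EUB throughout
(African- and European-ancestry groups of 78 donors each, the cohort layout
the generator defaults to); signed population quantities are AFB − EUB for
methylation (`delta_beta`) and EUB − AFB for allele frequencies
(`delta_daf`), with the direction always carried alongside
(`hyper_in`, explicit column names).

## Differential methylation (diffmeth)

Per CpG: OLS of M on an intercept, a population indicator, age, and the
supplied covariates (surrogate variables, genotype PCs). Residual variances
are shrunk by empirical Bayes: the observed s² are modelled as scaled-F
draws around a prior (d₀, s₀²) estimated by moment-matching the log
variances (digamma/trigamma expressions), the posterior variance is the
precision-weighted blend (d₀s₀² + df·s²)/(d₀ + df), and the moderated t has
df + d₀ degrees of freedom. When the log-variance dispersion is no larger
than sampling noise the prior df is infinite and the posterior collapses to
the common (geometric-mean) variance, so homogeneous inputs reduce exactly
to the ordinary t. p-values are BH-adjusted; a differentially methylated
site (DMS) requires adjusted p < 0.01 **and** |Δβ| > 0.05, where Δβ is the
difference of raw group means of β — deliberately unadjusted for
covariates, because the β-scale threshold is an effect-size filter, not a
test.

## QTL/QTM mapping (qtlmap)

**cis tests.** Every SNP within 100 kb of the feature anchor (CpG position,
or gene TSS for expression) with MAF ≥ 5% in the analysed samples is tested
twice: (a) an additive linear model with covariates, computed by
Frisch–Waugh–Lovell residualization (feature and dosage both residualized
on the covariates; the partial correlation converts to the exact
covariate-adjusted t with n − k − 1 df), and (b) a Kruskal–Wallis rank test
across genotype classes. KW cannot absorb covariates, so values are
residualized by OLS before ranking — this keeps the non-parametric guard
while honouring the covariate set. A significant association must pass
both thresholds; requiring both can only shrink the discovery set.
Mapping runs jointly (all samples, ancestry as a covariate) and per
population; downstream summaries use the union.

**Permutation FDR.** Thresholds are calibrated per test family by shuffling
the molecular matrix within each population (genotypes and covariates stay
fixed), re-running the mapping, and keeping the per-feature minimum p.
FDR(t) = mean permuted count of features with min-p ≤ t over the observed
count; the reported p\* is the largest value on the candidate grid
{1, 5}×10⁻ᵏ (k = 2…12) with FDR ≤ 5%. The grid covers the thresholds this
family of analyses conventionally lands on (10⁻⁵ cis, 10⁻⁹ trans,
5×10⁻⁵ eQTM/eQTL, 5×10⁻⁶ reQTL). 100 permutations by default; a sentinel
(no threshold attainable) is returned rather than extrapolating.

**Stepwise conditioning.** The feature is residualized on its lead SNP and
the window re-mapped; a new lead is promoted if it passes p\* on both
tests, to a maximum rank of 5 (bounded runtime; in practice independent
cis signals beyond rank 3 are rare in a 156-sample design). Lead-SNP
tie-breaking is deterministic: smallest linear p, then largest |effect|,
then smallest |distance|.

**trans mapping.** To bound the test burden, candidate SNPs are restricted
to cis-eQTL SNPs of transcription-factor genes plus all SNPs within 10 kb
of a TF TSS; each candidate is KW-tested against every CpG ≥ 1 Mb away or
on another chromosome, on ancestry- and covariate-residualized M values.

**eQTM / response-QTM.** Spearman rank correlation of expression (or the
log₂ fold-change response, computed with a +1 pseudocount:
diff = log₂((1+FPKM_stim)/(1+FPKM_ns))) against CpG M values within 100 kb
of the TSS, with the gene-level permutation FDR above. Rank correlation
needs no covariate model and is invariant to monotone transforms of either
variable.

## Population genetics (popgen)

FST uses the two-population Hudson closed form
(p₁−p₂)²/(p₁(1−p₂)+p₂(1−p₁)), algebraically 1 − H_w/H_b with plugin
frequencies: symmetric, exactly 0 for identical frequencies, 1 for a fixed
difference, undefined when both populations are monomorphic for the same
allele. No finite-sample correction is applied; at n = 78+78 per-SNP
sampling noise dominates any bias correction, and the uncorrected form
keeps the boundary identities exact.

ExpDiff = β·ΔDAF/ΔMeth estimates the share of an observed population
methylation difference attributable to a meQTL, where β is the effect of
the derived allele on the allele-frequency scale (twice the per-copy dosage
coefficient, so a fully genetic difference gives a ratio of 1). The ratio
is intentionally unbounded — opposing environmental or secondary genetic
effects push it outside [0, 1] — and records with ΔMeth = 0 are flagged and
excluded from summary means. The ratio is only meaningful over DMS-like
CpGs; for near-zero denominators it is noise-dominated.

Population specificity compares three Gaussian linear models of a CpG's M
values — common SNP effect + population intercept; SNP active only in EUB;
SNP active only in AFB — by their maximized (profiled-variance)
log-likelihoods. All three have identical dimension, so with equal priors
the posteriors are the softmax of the log-likelihoods and no complexity
penalty is needed. A specific call requires posterior > 0.9; "shared" is
assigned whenever the common-effect model merely tops the posterior,
mirroring the asymmetric use of the 0.9 threshold for specific calls only.

## Enrichment (enrich)

Context odds ratios compare a CpG set's in/out-of-category odds against the
**general distribution** of the full annotated background (reference column
counts all CpGs, query included), with Fisher's exact p on that table and a
Woolf-logit 95% CI (Haldane–Anscombe 0.5 correction on zero cells,
flagged). GWAS enrichment LD-prunes query and background greedily (keep a
SNP iff R² < 0.8 with everything already kept, visiting by ascending p),
then draws |query| background SNPs matching the query's pooled
allele-frequency histogram in 5% bins, 10,000 times. Fold = observed /
resample mean; the one-sided (enrichment) p comes from a method-of-moments
normal fit to the resample counts, and the 95% CI from bootstrap resampling
of the query on an independent seeded stream. Pooled-sample frequencies
are used for binning — the neutral choice when the matching population is
unspecified — and the null and bootstrap streams are independent by
construction.

## Mediation (mediate)

Trios are formed by intersection: a SNP joins a gene's trio iff it is an
eQTL of the gene and a meQTL of a CpG that is an eQTM of the same gene;
all qualifying members group into one trio per gene. Multi-member sides
collapse to a per-sample summary via elastic net (mixing 0.5, 10-fold CV,
λ by the 1-SE rule with a flagged fall-back to λ_min if everything is
zeroed); single members are used raw.

The mediator (M ~ G + covariates) and outcome (Y ~ G + M + covariates)
models are fit by OLS; coefficient vectors are drawn from the
multivariate-normal sampling distribution at the estimates (quasi-Bayesian
approximation; no residual resampling). Per draw, ACME = a·b and ADE = τ;
point estimates are draw means, and total = ACME + ADE, which makes the
linear decomposition identity exact by construction. The two-sided p for
"a·b = 0" comes from a normal fit (mean/sd) to the ACME draws — centred on
the draw mean — and BH correction across trios flags mediated genes at
FDR 5%. Marginal R²s of expression on methylation and on genotype are
reported alongside. The closed-form calibration ACME → √α·√(γβ) holds
when the treatment is standardized (per-sd slopes); the benchmark and
tests standardize genotype accordingly. Reverse causation (expression
driving methylation) is outside the model.

The partial-correlation comparator is the first-order pcor of E and M
given G with the t-transform p on n − 3 df; it equals the correlation of
the two OLS residual vectors, which the tests verify to 10⁻¹².
`benchmark_mediation` simulates each grid cell half with the cell's
parameters and half with the mediated share zeroed (direct-only null),
scores both tests by −log₁₀ p, and reports per-cell ROC AUCs plus
sensitivity/specificity at p < 0.05.

## Synthetic data (simdata)

`simulate_causal_trio` implements the standardized construction literally
(genotype binomial(2, f), default f = 0.3; standard-normal residuals;
monomorphic draws resampled, or an error on request). With β + τ = 1 the
expression noise weight is √(1−γ) exactly; with γ = 0.25, 75% of
expression variance is unexplained by construction — the package's
headline machine check.

`simulate_cohort` draws per-population genotypes from supplied
derived-allele frequency profiles with LD inside 1-Mb blocks via a
Gaussian-copula AR(1) haplotype model (latent correlation e^(−d/L),
default L = 20 kb): marginal frequencies are exact and LD decays with
distance. Methylation is built on the M scale — baseline per CpG uniform
on (−3, 3), planted cis/trans genetic effects in M-units per derived
allele, population shifts sized on the β scale at the baseline and applied
to AFB, Gaussian noise (default sd 0.5 M-units, 0.3 in the
differential-methylation recovery settings) — then stored as β.
Expression is log₂-scale: baseline uniform (2, 6), planted eQTL effects
per allele and eQTM couplings per sd of M, noise sd 0.5; the stimulated
condition adds a per-gene response (mean 1, sd 0.5 log₂ units) plus
planted methylation-coupled response effects. Surrogate-variable
covariates are independent standard normals. Defaults: 78 + 78 samples,
ages uniform 20–50, MAF-testable frequency profiles with 20% of SNPs
population-differentiated (|Δf| 0.2–0.5).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: EPIC probe chemistry and detection-p generation
(a configurable failure rate only), realistic human LD maps and
recombination hotspots, cell-composition heterogeneity, batch structure
beyond generic covariates, non-linear age effects, and any coupling
between the GWAS catalog fixture and real trait architecture. Recovery
rates measured here are upper bounds for cohorts with these additional
noise sources.

## Problem sizes and determinism

Validation runs at deliberately modest scale: null calibrations use ≥10⁴
features/tests per family, recovery checks use the 78 + 78 design with
50–150 planted effects, the mediation grid uses 9 (α, β) cells with 200
replicates at n = 156 and 20 replicates at n = 5000, and the resampling
enrichment null uses a 20,000-SNP background with 10,000 resamples. All
stochastic entry points take an explicit seed and are bit-reproducible for
a fixed (parameters, seed) pair; permutation, resampling, and bootstrap
streams are seeded independently.

## Known limitations

- The Kruskal–Wallis covariate handling (residualize-then-rank) is a
  pragmatic hybrid; its null distribution is asymptotic and slightly
  anti-conservative for heavy covariate sets at small n.
- The permutation FDR inherits the granularity of the candidate grid; the
  true 5% threshold may lie between grid points.
- Specificity posteriors compare only the three stated models; a partially
  shared effect (present in both populations with different sizes) has no
  dedicated model and lands on whichever of the three fits best.
- Mediation p-values assume the normal approximation to the product-draw
  distribution, which is conservative when both paths are weak.
- The trans scan is quadratic in (candidate SNPs × CpGs) and is meant for
  restricted candidate sets, not genome-wide universes.
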
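# Methods

This note documents the statistical models implemented in `exwas`, the
choices made where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## Synthetic cohort generator

The generator produces every input the pipeline consumes, with the structure
a large joint-called exome cohort exhibits, and nothing more.

**Frequency spectrum.** Each variant is, with probability `singleton_mass`
(default 0.4686, the singleton share of a 450k-exome coding-variant
catalogue), a singleton: exactly one heterozygous carrier, frequency 1/(2N).
Otherwise its allele frequency is log-uniform on `log10_maf_range` (default
10⁻³·⁵–10⁻²) and genotypes are Binomial(2, MAF) per sample, re-drawn into the
≥ 2-carrier stratum so that the realized singleton fraction tracks the
requested mass at any cohort size. Every variant has MAC ≥ 1.

**Consequence classes.** Drawn from a class mix defaulting to the observed
composition of a 450k-exome catalogue (28% synonymous, 64% missense, 0.6%
in-frame indel, 7.4% pLOF split over its six subclasses). Missense
deleteriousness votes (0–5 algorithms) default to 19.4% zero votes / 22.7%
five votes, the remainder spread evenly over 1–4.

**Read evidence.** Depth is negative-binomial (mean 35, dispersion 8 —
variance mean + mean²/dispersion); alternate-allele depth is binomial given
depth at allele balance 0.5 for germline heterozygotes. These two parameters
are a deliberately minimal overdispersed model; they are this package's
defaults, not estimates of any particular cohort's depth distribution.
Somatic (CHIP-like) variants carry a VAF parameter outside [0.35, 0.65]
(default 0.2) and a carrier probability logistic in age (configurable slope
and midpoint), emulating clonal haematopoiesis in blood-derived DNA.

**Phenotypes.** Binary traits: logit(p) = μ + Gβ + covariate terms, with μ
solved by Brent root-finding so that mean(p) equals the target prevalence K
(tolerance 10⁻⁸ in prevalence, on the realized genotype/covariate sample).
Quantitative traits: Gaussian about the genetic + covariate mean with unit
residual variance. Effect-map keys may be variant ids or gene ids; gene keys
act on the collapsed protein-altering burden dosage.

**What is not emulated.** Linkage disequilibrium, phasing, relatedness,
population structure and polygenic background are absent by design; samples
and variants are independent. Tests passing on these cohorts therefore
validate the analytical machinery — filters, collapsing rules, test
statistics, calibration — not robustness to confounding, which the original
whole-genome-regression framework addresses and this package deliberately
does not re-implement.

## Quality control

Genotype-level: SNV calls with DP < 7 and indel calls with DP < 10 become
no-calls. Variant-level: retain only variants with ≥ 1 hom-alt carrier or
≥ 1 heterozygote at allele balance ≥ 0.15 (SNV) / ≥ 0.20 (indel). Site-level,
in order: variant missingness > 0.1, exact Hardy–Weinberg p < 10⁻¹⁵,
monomorphic, then sample missingness > 0.1. All inequalities are strict, as
stated. The HWE test is the exact conditional (SNP-HWE) test without mid-p
correction, computed in the log domain for stability at large counts. All
filters are idempotent and log machine-readable exclusion reasons.

The somatic screen reports (not classifies): the fraction of heterozygous
carriers with VAF outside [0.35, 0.65] (hom-alt calls excluded — the
rationale targets putative heterozygotes) and the logistic-regression
coefficient of carrier status on age with its p-value. Fewer than two
carriers yields a flagged report with undefined regression fields.

## Masks and collapsing

Missense tiers: 5 votes → likely deleterious, 1–4 → possibly deleterious,
0 → likely benign. M1 = pLOF; M3 = pLOF + likely-deleterious missense.
Frequency bins use in-sample post-QC MAF; the singleton bin is carrier-count
based (exactly one carrier sample, including a lone minor-allele homozygote).
Collapsing is the capped per-sample maximum: 2 if hom-alt at any subset
variant, else 1 if het at any, else 0. Missing genotypes are treated as
hom-ref for collapsing (switchable via `missing_as_ref`) and the per-sample
count of non-missing contributing calls is recorded; treating no-calls as
reference is the conservative choice for burden dosage and the convention is
documented because upstream tools do not state one. Collapsed burdens (and
single variants) with MAC < 5 are skipped. chrX dosage compensation (males:
hom-ref 0, any alt call 2) is applied by a sex-aware encoder before
collapsing; pseudoautosomal handling is out of scope for the single synthetic
chromosome.

## Association testing

Quantitative traits are averaged across visits, screened by the
mode-fraction rules (mode ≥ 20% of samples → reject; mode in [0.5%, 20%)
with < 100 or > 10,000 unique values → reject), then rank-inverse-normal
transformed with the Blom offset (r − 3/8)/(n + 1/4) and average ranks for
ties. Blom-with-average-ties is this package's documented convention; other
offsets change results negligibly at these sample sizes. Binary traits with
fewer than 100 cases are rejected.

The binary test is a Rao score test against the covariate-only null; when
the score p falls below the fallback threshold (default 0.05, configurable)
the model is refitted by exact Firth penalized likelihood — Newton iterations
on the Jeffreys-penalized score with step-halving on the penalized
log-likelihood, tolerance 10⁻⁸, 100-iteration cap — and the Firth log-OR,
Wald SE, Wald p and CI are reported. Exact Firth (not a fast approximation)
is used as the defensible reference form; its estimates are finite under
complete separation. The Wald p on the penalized fit agrees closely with the
score test away from separation (verified at n = 50,000 in the suite).

Plain covariate adjustment replaces whole-genome LOCO regression: with no
polygenic background or relatedness in the synthetic cohorts the LOCO
predictor is identically zero, so the two are equivalent at desk scale.
Conditional analysis appends common-variant dosage vectors to the
covariates; an empty conditioning set is bit-identical to the unconditional
test, and a conditioning vector collinear with the test dosage returns a
flagged null result (effect 0, p 1) rather than crashing, since the
conditioning absorbs the signal entirely.

## Power

Empirical power follows the simulation design of the source framework: 10
marker replicates × 100 phenotype replicates (1,000 total) per grid cell,
prospective sampling (population model, not retrospective case-control
draws), score test with Firth fallback at 0.05, power = fraction of
replicates with p ≤ α with an exact binomial CI. The Monte-Carlo SE treats
markers as the independent units — power varies with each marker's realized
allele count, so the between-marker variance dominates at rare EAF — with an
Agresti–Coull floor so boundary outcomes (all replicates significant) retain
a non-zero SE. The full discovery-scale grid (N = 430,998, α = 2.18 × 10⁻¹¹)
is reachable through configuration; defaults are desk scale (N = 50,000,
α = 10⁻³), chosen so a grid cell runs in tens of seconds.

Theoretical power evaluates the 1-df noncentral chi-square tail at the score
NCP η = 2N₀N₁(p′ − p)²/((N₀+N₁)p̄(1−p̄)). The case EAF p′ derives from the
per-allele odds identity p′/(1−p′) = OR·p/(1−p), using the stated
approximation control EAF ≈ population EAF. At rare EAF (MAC ≈ 100) the
asymptotic formula is a percentage point or so optimistic relative to
simulation; the agreement tests compare within Monte-Carlo error.

## GWAS-locus enrichment

Sentinels are pruned greedily by ascending p-value, dropping any signal
within 10 Mb of a kept signal on the same chromosome (the selection order is
this package's choice; only the separation criterion is prescribed). Gene
distance is base pairs to the closed gene interval (0 if the sentinel is
inside), not TSS. Gene sets: within-d windows, k-nearest, or nearest.
Per-trait folds are (a/b)/(c/d) with undefined folds flagged, never
Haldane-corrected; the Mantel–Haenszel combination (statsmodels
`StratifiedTable`: pooled OR, uncorrected 1-df chi-square by default with a
continuity-corrected variant behind a flag, Robins–Breslow–Greenland CI)
tolerates zero cells naturally. `expected_by_chance` optionally rounds p̂ to
3 significant figures — off in library use, on when reproducing printed
arithmetic, because the printed value rounds before multiplying (3,736 vs
3,735 unrounded).

Trait→disease matching takes a genetic-correlation table as input (rg
estimation itself is out of scope), selects per trait the disease with the
smallest rg p among those Bonferroni-significant at 0.05/357, and the
protective screen applies the four-step filter (known beneficial direction →
favourable effect direction → matched disease exists → protective disease
association at 0.05/129), reporting survivors at each step.

## Scaling models

Carrier saturation: per-gene carrier counts are beta-binomial; a mixture is
fitted by EM with log-domain responsibilities. The M-step is a bounded
Nelder-Mead improvement step from the current shapes (generalized EM), so
the log-likelihood trace is non-decreasing by construction — asserted in the
tests at every iteration. Components 1–5 are selected by BIC in auto mode
with 10 seeded restarts (quantile-sliced method-of-moments initialization,
jittered). The mixture-fitting procedure is a reconstruction: no equations
are published for the original, so component count and initialization are
documented package choices. Projection to a larger cohort is empirical
Bayes: conditioning on each gene's observed count k of N, the within
component posterior Beta(αⱼ+k, βⱼ+N−k) gives a beta-binomial predictive over
the N′−N new samples, mixed over posterior component responsibilities; the
expected number of genes with ≥ K carriers is the sum of per-gene
probabilities. Heterozygous and homozygous carrier processes are modelled
independently. At N′ = N the projection reproduces the observed qualifying
gene counts exactly, and the fitted marginal matches the observed ≥ 1-carrier
count within 5% on 15,000 synthetic genes.

Imputation accuracy: r² ≈ c/(1 + exp(−(a + b·log n))), fitted by nonlinear
least squares on the log-panel-size scale (the log-n parameterization is
essential for stable extrapolation); the two-parameter model fixes c = 1,
the three-parameter model bounds c ≤ 1 (trust-region solver, tolerances
10⁻¹⁴). Extrapolations carry delta-method 95% CIs from the Jacobian-based
covariance, computed on the untransformed r² scale and truncated to [0, 1].
Near the c = 1 boundary the likelihood surface is flat in c, so the two- and
three-parameter fits coincide only to practical optimizer precision (~10⁻³).

## Problem sizes and numerical choices

Default test and acceptance problem sizes — cohorts of 400–5,000 samples,
power grids at N = 20,000–50,000 with 1,000 replicates per cell, 15,000
genes for mixture recovery, 100 seeded runs for Mantel–Haenszel coverage —
are chosen so the whole suite completes in a few minutes on one CPU while
leaving each statistical check adequately powered. Degenerate inputs
(monomorphic variants, empty masks, all-missing traits, single-carrier
somatic screens, all-degenerate strata) return flagged results or typed
errors rather than silent corrections. Known limitations: no LD or
relatedness anywhere, so conditional analysis is exercised only against
independent common variants; the Firth p-value and CI are Wald-based on the
penalized fit (no profile-likelihood CI is implemented); and the saturation
projections on synthetic tables validate the machinery, not any real
cohort's carrier landscape.
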
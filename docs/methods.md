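# Methods

This note records the statistical models implemented in `admixkit`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions that affect results.

## Synthetic admixed cohorts

The generator follows the exchangeable pulse-admixture tract model.
Each individual draws global proportions `q ~ Dirichlet(alpha)`; each of
the two haplotypes is cut by a Poisson process of ancestry switches at
rate `g` per Morgan (`g` = generations since admixture), and every
inter-switch segment's ancestry is drawn i.i.d. from `q`. Consequently
interior tract lengths are Exponential with mean `1/g` Morgans and the
marker-averaged dosage converges to `2q` — both are asserted by tests.

Defaults, chosen once as a realistic desk-scale stand-in for a four-way
admixed Polynesian cohort:

| parameter | default | rationale |
|---|---|---|
| ancestries | PNS, EUR, EAS, AFR | the four-way mixture of the target population |
| `dirichlet_alpha` | (4.02, 2.96, 2.90, 0.12) | mean proportions (0.402, 0.296, 0.290, 0.012) matching reported cohort averages, concentration 10 giving a realistic spread of individual admixture fractions |
| `generations` | 10 /Morgan | recent (post-contact, ~250 y) admixture |
| genome | 2 chromosomes x 50 Mb, 2,000 markers | desk scale; large enough for tract statistics, small enough for permutation studies |
| map | constant 1 cM/Mb | local-ancestry inference is robust to a flat map, and it makes cM and Mb tract lengths proportional |
| binary trait prevalence | 0.171 | the type-2 diabetes prevalence used in the power analysis |

Phenotypes are linear (quantitative) or logistic (binary) in global
ancestry, an optional local causal variant dosage, questionnaire-style
covariates, and a census-tract random intercept; the logistic intercept
is solved numerically (Brent) so the expected prevalence equals its
target. Covariates cluster by census tract: each tract carries a latent
SES score that determines the shared nSES quintile and shifts the
education distribution, mimicking area-based SES assignment.

What the generator does **not** emulate: linkage disequilibrium beyond
ancestry-induced correlation, genotyping/imputation error structure
(INFO scores are assigned, not earned), local-ancestry inference error
(posterior degradation is placed uniformly at random), assortative
mating, and selection. Tests passing on these cohorts therefore
demonstrate correctness of the estimators under the assumed model, not
robustness to real-data artifacts.

## Global ancestry

Per individual, tract genetic lengths (cM, interpolated on the marker
map) are summed per ancestry over both haplotypes after excluding every
tract whose posterior probability is below the threshold (default 0.9);
proportions are renormalized to sum to 1. Renormalization is required
because downstream regressions use K-1 proportions against a baseline.
Exclusion is tract-level (the whole tract is dropped), and lengths are
genetic rather than physical so the estimate is invariant to marker
density; under the default constant map the two are proportional. A
threshold of 0 (no filter) is accepted so that the no-filter identity
with raw tract fractions is testable. Individuals retaining zero length
become NA rather than being silently dropped.

## Global-ancestry association

Covariate screening regresses the trait univariately on each candidate;
age and sex are always retained (sex keeps its full coding — the
level-collapsing step applies only to screened categoricals, where
levels whose level-vs-reference contrast has `P >= 0.05` merge into the
reference, reproducing binary/ternary education codings). Quantitative
traits are residualized on the retained covariates and transformed by
the rank-based inverse normal with Blom offset 3/8; a plain z-score
variant is available (`standardize_only=True`) since both conventions
appear in practice, with the inverse normal as default. Binary traits
keep covariates in the joint logistic fit. The ancestry model regresses
the outcome jointly on `q_PNS, q_EAS, q_AFR` (European baseline); all
coefficient P-values are Wald. A reporting flag marks
`P < 0.05/14` (Bonferroni for a 14-trait panel).

The nSES adjustment adds the quintile as a fixed effect and the census
tract as a random intercept. Linear traits use REML via
`statsmodels.MixedLM`. Binary traits use the variational-Bayes binomial
mixed model (`BinomialBayesMixedGLM`) — the only mixed logistic model in
the dependency stack; its posterior s.d. is reported as the standard
error, adequate for the confounding-assessment role this model plays.

## Admixture mapping

The scan regresses the (transformed) trait on the local PNS dosage at
each marker with the other three global proportions as covariates
(individual-level covariates are added for binary traits, which are
scanned by per-marker logistic regression). The linear scan uses the
Frisch-Waugh-Lovell reduction: with a shared covariate block, the
per-marker coefficient, standard error, and t-based P are identical to
marker-by-marker OLS (asserted to 1e-8 against a brute-force oracle)
but computed by one matrix product, which is what makes the permutation
studies cheap. Markers with missing dosage (posterior masking) fall back
to a per-marker complete-case loop.

Genome-wide significance is the 5% lower quantile (inverted-CDF, i.e.
the ceil(0.05 n)-th smallest) of per-permutation minimum P-values, each
permutation drawing a fresh standard-normal phenotype independent of all
data and re-running the linear scan. This controls the family-wise error
rate at 5% given the cohort's local-ancestry correlation. Binary traits
are calibrated with the same normal-phenotype linear procedure (a single
calibration for all traits), not by case-label shuffling. A preset
genome-wide threshold of 2.2e-5 — the published permutation-derived
value for a ~3,400-person four-way cohort at array scale — is offered as
a CLI default but is always recomputable.

Signal regions are maximal runs of consecutive markers with P strictly
below the threshold; boundaries sit on marker positions (no
interpolation) and ties at the threshold do not qualify. Broad regions
grow from each signal region by absorbing markers with −log10 P > 4
within 5 Mb of the growing region (so chains of suggestive segments at
most 5 Mb apart merge in), and overlapping broad regions merge. Every
signal region is nested in exactly one broad region.

Conditional scans append user-supplied variant dosages to the covariate
block, dropping columns that are rank-deficient against the existing
design (tolerance 1e-8) with a warning.

## Mixed-model fine-mapping

Relatedness enters through the VanRaden GRM (frequency-standardized
dosage cross-product averaged over polymorphic variants; at least 50
required) with a 1e-6 diagonal ridge for PSD safety; population
structure through the GRM's top-10 eigenvector scores (root-eigenvalue
scaled, sign fixed so the largest-magnitude loading is positive). This
plain GRM + PCA stands in for ancestry-robust kinship estimators: on
synthetic cohorts without genotyping artifacts, admixture-induced
kinship bias — the problem those estimators solve — does not arise.

The association is the EMMAX two-step: (1) REML for
`lambda = sigma_g^2 / sigma_e^2` under the null, profiled on the GRM
eigenbasis and optimized in one dimension (coarse grid on
log-lambda in [-12, 8], then bounded Brent; the lambda = 0 boundary is
checked explicitly); (2) per-variant Wald t-tests by GLS with the
fitted covariance held fixed, computed for all variants at once on
whitened data. With an identity GRM this reduces exactly to OLS.
Binary traits are analyzed as 0/1 outcomes on the linear scale, the
standard EMMAX practice; effect sizes are also reported as `exp(beta)`
on the odds-ratio scale. Wald rather than score statistics were chosen;
at the regional scale the two are practically indistinguishable and
Wald yields the effect estimate directly.

Variant QC before testing: imputation INFO >= 0.4 and MAF >= 1%.
Regional significance permutes null-model residuals (after projecting
out covariates), re-runs the scan, and takes the 5% quantile of minimum
P; the reported top variant is the region's minimum-P variant, flagged
significant if it beats that regional threshold.

A validation note: when tested variants are themselves part of the GRM,
the random effect absorbs part of each variant's own signal and the
test becomes conservative at desk scale (n comparable to the number of
GRM variants). The calibration experiments therefore build the GRM from
a disjoint background variant set — the usual leave-out/LOCO practice —
under which the mixed model holds its 5% level while naive OLS is
inflated.

## Selection

nSL is computed from phased 0/1 haplotypes: for every haplotype pair
within the derived-allele class and within the ancestral class, the
shared run around the focal site is counted in markers (left + right +
focal), each direction capped at `max_extend = 100` markers — the common
selscan default. The statistic is the log ratio of mean pair lengths;
the default orientation is positive = longer derived-class haplotypes,
configurable and logged, since both sign conventions circulate.
Standardization subtracts bin means and divides by bin s.d. within
derived-allele-frequency bins (default 50 equal-width bins; bins with
fewer than 20 values merge leftward). Empirical significance compares
the focal statistic with all variants inside a DAF window and an INFO
window (defaults 0.23-0.25 and 0.77-0.97, the matching used for a
Polynesian-enriched candidate allele), using the add-one estimator
`P = (r+1)/(n+1)`, which can never return 0; both raw and standardized
versions are emitted because either can be the basis of a one-sided
empirical test.

## Replication power

The one-stage GAS/CaTS computation: Hardy-Weinberg genotype frequencies
at the risk-allele frequency, multiplicative penetrances
`f_g = f_0 * GRR^g` scaled so the population prevalence matches, expected
risk-allele frequencies in cases and in unaffected controls, and a
two-sided two-proportion test on 2N allele counts. Power uses the
normal approximation with the standard error evaluated at the
alternative frequencies for both the critical value and the shift
(`power = Phi(-z + d/SE) + Phi(-z - d/SE)`), which is the calculator's
formulation and returns exactly alpha at GRR = 1. The seeded
Monte-Carlo oracle draws binomial allele counts at the design
frequencies and applies the fixed level-alpha rejection region with the
design SE — i.e. it checks the normal approximation itself. Plug-in-SE
Wald tests have slightly different finite-sample power (lower with the
unpooled estimate, higher with the pooled one, bracketing the analytic
value at the default design); that is a property of the plug-in tests,
not an error of the formula.

## Problem sizes and tolerances in the test suite

Simulation studies run at desk scale, chosen to keep the full suite
fast while leaving clear statistical margins: threshold calibration
uses n = 500 with 2,000 markers, 1,000 permutations, and 200 null
scans; recovery studies use 100 replicates at n = 400-600; the
relatedness calibration uses 120 sibling pairs and 2,400 null tests.
Exact identities (oracle equivalence, round trips) are asserted at
1e-8-1e-12; stochastic checks use binomial or chi-square bounds at
their stated levels.

## Known limitations

* Marker grids for local ancestry and variant dosages are harmonized by
  exact (chromosome, bp) match; no interpolation between grids.
* Missing data are handled per trait by complete-case analysis.
* The admixture scan assumes unrelated individuals; relatedness is
  addressed only in the fine-mapping stage.
* No coalescent-level realism in the simulator (see above); no
  phasing, imputation, or liftover anywhere in the package.
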
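# Methods

This note documents the statistical models the package implements, the
choices made where the published analyses leave the design open, and
what the synthetic-data tests do and do not establish.

## Association models

One biallelic SNP enters every model as the additive dosage
*G* ∈ {0,1,2} (count of the effect allele). Quantitative traits are fit
by ordinary least squares with the unbiased residual-variance estimator
and t-reference two-sided Wald p-values; binary traits by
maximum-likelihood logistic regression (Newton, tolerance 1e-10 on the
parameter step, 100-iteration budget) with normal Wald p-values. The
published analyses do not state their test construction; t for linear
and normal for logistic are the conventions of the regression tooling
they cite. Analyses are complete-case per model — rows missing any
model variable are dropped and the rows used are reported — matching
the trait-varying per-stratum sample sizes of the published screen.
Categorical covariates (study site, education) expand to indicator
columns against a first-level reference; ancestry principal components
are ordinary numeric covariates supplied with the cohort, never
computed here. Degenerate inputs raise explicit errors (rank-deficient
design naming the collinear columns, monomorphic dosage, constant
trait, perfect separation); nothing is silently dropped or imputed.

No family-relatedness correction is applied; cohorts containing
relatives will have mildly anti-conservative standard errors. This is a
known limitation.

## Meta-analysis

Fixed effects: wᵢ = 1/seᵢ², β̂ = Σwᵢβᵢ/Σwᵢ, se = (Σwᵢ)^(−1/2), p from
the two-sided normal. Heterogeneity: Q = Σwᵢ(βᵢ−β̂)², df = k−1,
I² = max(0, (Q−df)/Q)·100 (reported in percent and floored at zero, so
Q < df prints 0.0). Random effects: the DerSimonian–Laird moment
estimator τ̂² = max(0, (Q−df)/C) with C = Σw − Σw²/Σw, then
fixed-effects algebra with weights 1/(seᵢ²+τ̂²). The truncation at zero
means the random-effects result equals the fixed-effects result
whenever Q ≤ df, and the random-effects SE never falls below the
fixed-effects SE. Inputs are consumed at full precision; when published
*rounded* (β, SE) rows are re-combined, the result can differ from the
published combination in the last printed digit (observed: 2.4235 vs a
printed 2.424, and 2.207 vs a printed 2.209 where between-stratum
variance is large) — an input-rounding artifact, not an estimator
discrepancy.

## Trans-ethnic Bayes factor

Population-stratum estimates (βᵢ, seᵢ) are modelled as
βᵢ | μ_{c(i)} ~ N(μ_{c(i)}, seᵢ²), where c(·) assigns populations to
effect-sharing clusters and each cluster effect has the prior
μ ~ N(0, σ²). The marginal likelihood of a cluster is the closed-form
Gaussian integral; a partition's marginal is the product over its
clusters; the model evidence averages over all set partitions of the K
populations (exact enumeration, Bell(K) terms, guarded at K ≤ 10); the
null pins every effect at zero. The log₁₀ Bayes factor compares the two
in log-sum-exp arithmetic. With K = 1 this is exactly Wakefield's
approximate Bayes factor.

Design choices, since the published screen's software settings are not
recoverable: the partition prior is uniform over partitions (an
optional hook accepts a pairwise population-distance matrix and a
concentration parameter, down-weighting partitions that merge distant
populations — the role genome-wide allele-frequency divergence plays in
the original method); the effect-prior scale σ defaults to 0.2 × the
trait SD in pipeline use and is always explicit in the API. Published
BF columns are therefore treated as qualitative references (ordering,
thresholds), never as numeric targets; on the 27-trait screen the
package's BFs rank-correlate with the published column at r ≈ 0.95.

## Mediation

Difference in coefficients: Model 1 regresses the outcome on dosage and
covariates; Model 2 adds the mediator; the mediation estimate is the
change in the dosage coefficient, both models fit on the identical
complete-case subset. In the generating linear structural model this
difference converges to −a·b, minus the indirect effect, which is what
the synthetic tests assert (recovery at n = 5000 within 3 SE).

Uncertainty: B = 1000 nonparametric pairs-bootstrap resamples of whole
subject rows within stratum (preserving the joint distribution of
genotype, mediator, covariates and outcome). Intervals are
bias-corrected (BC, no acceleration constant — an acceleration hook is
the natural extension if BCa is wanted): z₀ = Φ⁻¹((#{θ* < θ̂} +
½#{θ* = θ̂})/B), endpoints at the empirical quantiles
Φ(2z₀ + z_{α/2}), Φ(2z₀ + z_{1−α/2}) (linear-interpolation quantiles).
The two-sided p-value is the smallest α whose BC interval excludes
zero, found by bisection to tolerance 1/B and floored at 1/B (the
bootstrap's resolution). Resamples with singular designs (e.g. a
monomorphic resampled dosage) are redrawn, capped at 10% of B. The
bootstrap is vectorised as multinomial row weights with batched
weighted normal-equation solves, which is what makes the 500-replicate
calibration tests affordable.

Across strata the per-stratum differences are combined by fixed-effects
meta-analysis using each stratum's bootstrap SD as its standard error —
the only uncertainty measure the bootstrap construction provides, and
therefore the only self-consistent weighting.

Calibration established on synthetic data: 95% BC intervals cover the
true −a·b 95.4% of the time over 500 replicates (n = 1000, B = 1000);
the combined mediation p rejects a true null (a = 0) at 2.8–5% at
nominal 5% (mildly conservative at stratum n = 400); and a confounder
driving both mediator and outcome produces apparent mediation under
basic adjustment that vanishes under full adjustment — the qualitative
pattern that motivates reporting both adjustment sets.

## Survival

Cox proportional hazards by Newton maximization of the partial
likelihood; convergence requires max |score| < 1e-8; standard errors
from the inverse observed information. Breslow tie handling is the
default (Efron available via `ties="efron"`; the trials' convention is
unstated, and the two coincide on the continuous event times the
generator produces). Step-halving guards the ascent with a tolerance
relative to |log L| (the partial likelihood moves at float-noise scale
near the optimum); diverging coefficients or a failed ascent raise a
monotone-likelihood error rather than returning a half-converged fit.
Pooled analyses across population strata include stratum indicator
covariates, the analogue of the trials' region adjustment. The endpoint
column is configurable — distinguishing composite definitions (MCE vs
MACE) is a column-selection concern, not a modelling one.

The treatment × SNP product term tests whether the randomized arm
modifies the per-allele log hazard ratio; its Wald test is nominal on
null simulations (500 replicates, n = 10⁴) and recovers a true
interaction of 0.3 within sampling error.

## Synthetic cohorts

The generator's defaults are the study conditions, chosen once from the
published participant tables: four strata (2470/2507/2071/758 subjects;
effect-allele frequencies 0.18/0.62/0.35/0.57), genotypes under
Hardy–Weinberg equilibrium (only allele frequencies are published, not
genotype counts), a mediator calibrated to Lp-PLA₂ activity (stratum
intercepts near the published medians, residual SD 37 nmol/min/ml from
the published IQRs, per-allele effect a = 2.4 matching the combined
estimate), an outcome calibrated to common-carotid IMT (residual SD
0.17 mm; direct effect c′ = 0.0098 and mediator effect b = 5e-4 per
nmol/min/ml, so the total SNP effect is ≈ 0.011 mm and the indirect
effect ≈ 0.0012 mm — the scales of the published association and
mediation tables), and binary events with prevalences
12.7/11.0/12.1/8.4%. Trial presets use the published trial stratum
sizes and allele frequencies, a baseline hazard of 0.028/y, and
administrative censoring C ~ Uniform(0, 2h) with horizons h = 3.7 y and
2.5 y (the trials' median follow-ups). Trait distributions are Gaussian
by default — the published tables report only medians/IQRs — with a
log-normal residual hook (shape 0.5, rescaled to the stated mean and
SD) for right-skewed biomarkers.

Per-stratum random streams are keyed by (master seed, CRC32 of the
stratum label), so stratum order and the presence of other strata never
change a stratum's rows, and identical (spec, seed) calls are
byte-identical. Missingness is an optional MCAR injector (default 0)
to exercise complete-case handling.

What the generator does *not* emulate — and what passing tests
therefore do not establish about real data: linkage disequilibrium and
multi-SNP structure, genuine population stratification (the "PC"
covariates are plain Gaussians), family relatedness, measurement error
in biomarkers, informative censoring, and non-proportional hazards.
The calibration results are statements about the estimators under a
correctly specified generating model.

## Pipeline and multiple testing

The screen analyses the registered trait panel (27 traits by default:
nine biomarkers, eight plasma phospholipid fatty acids, ten fatty-acid
ratios; the DPA/EPA ratio is square-root transformed), applies
Bonferroni at family-wise 0.05 (0.05/27 ≤ 0.0019), and carries a trait
forward to mediation when its fixed-effects meta p reaches the
threshold **or** its trans-ethnic log₁₀ BF exceeds 1.5. Applied to the
published screen this rule selects Lp-PLA₂ activity and the DPA/EPA
ratio; the original report's narrative instead names DHA/EPA (p = 0.008,
BF = 1.09), an internal inconsistency of that report which the pipeline
surfaces in its log rather than resolving. A second internal
inconsistency surfaced the same way: the published sICAM-1 combined
effect prints −0.371 while its own per-stratum rows combine to +0.370.

Outputs carry the run seed and a SHA-256 hash of the configuration
(excluding the output directory); identical (config, seed) runs are
byte-identical, which the test suite asserts at the file level.

## Problem sizes in the test suite

Simulation-based checks run at: recovery tests n = 5000 (single
stratum) or 4 × 2500 (trials); BC-bootstrap calibration 500 replicates
of n = 1000 with B = 1000; mediation type-I error 500 replicates of
four strata of n = 400; interaction type-I error 500 replicates of
4 × 2500; permutation null 600 replicates of n = 600. These sizes give
binomial 3·SE bands of about ±3 percentage points on a 5% rate, tight
enough to detect meaningful miscalibration while keeping the full suite
under a few minutes.
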
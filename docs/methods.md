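# Methods

This note documents the statistical models implemented in `hetfit`, the
choices made where conventions differ, and what the synthetic-data generator
does and does not emulate.

## Data model

Four tables drive every analysis. Genotypes are two positive integer allele
codes per locus per individual; codes are opaque labels (fragment lengths or
arbitrary integers) — all statistics depend only on allele identity, never on
size. A genotype is missing iff both allele fields are missing; half-missing
cells are rejected at read time. The individual table is one row per
(individual, year) with phenotypes, the mating-pair id, and the recruitment
outcome; recruitment in year *t* is 1 iff the individual is recaptured
breeding in *any* study plot in year *t* + 1, so the final monitored year is
undefined and automatically excluded from fitness models. `derive_recruitment`
implements strictly this next-year coding; individuals that skip a year and
return later still count as non-recruited for the skipped transition.

## Marker statistics

Allelic richness is the raw count of distinct alleles among typed individuals
(no rarefaction): all loci are typed on essentially the same individuals, so
rarefaction would only add noise. Expected heterozygosity uses the plug-in
estimator E_l = 1 − Σ p̂² from all typed allele copies pooled across years,
giving one HL weighting per locus for the whole study; a per-year weighting
can be obtained by subsetting the genotype matrix before `marker_summary`.

Hardy–Weinberg screening is a Monte Carlo test: the observed allele copies
are re-paired at random B times (default 999) and the heterozygote count
compared with its permutation distribution, two-sided by doubling the smaller
tail. Linkage-disequilibrium screening permutes one locus's genotypes among
individuals and uses the G statistic of the two-locus genotype table. Both
tests return p in [1/(B+1), 1] and are deterministic given a seed. These are
screening tools; no multiple-testing correction is applied inside the module
because the screen asks whether any locus deviates *consistently*, not
whether any single test is significant.

## Individual heterozygosity

HL weights each typed locus's contribution to homozygosity by E_l, so
homozygosity at a highly variable locus (more informative about inbreeding)
counts more. Missing loci are excluded from numerator and denominator; an
individual typed at no subset locus gets an undefined value and a warning.
With equal weights, 1 − HL reduces exactly to the proportion of typed loci
that are heterozygous (unweighted MLH), which is the degenerate case used in
several tests. Single-locus heterozygosities are standardized per locus by
z-scoring with the n−1 variance; dividing by the column mean is available via
`scale="mean"` since "normalized" admits both readings. Zero-variance columns
cannot be standardized and are dropped with a warning.

## Identity disequilibrium

The complete-data g² is the definitional ratio of within-individual to
between-individual cross-locus heterozygosity products, A/B − 1. The
missing-data version averages over *observed* pairs with matching per-term
denominators and reduces exactly to the complete-data formula when nothing is
missing; both are regression-tested against brute-force double sums
(complete and masked) to 1e−12. The permutation null shuffles each locus
column independently among individuals, destroying across-locus correlation
while preserving each locus's heterozygote frequency. The test is one-sided
(greater) by default because identity disequilibrium is a positive-deviation
hypothesis; a two-sided flag exists. B defaults to 1000. Under the generator's
inbreeding mixture the closed form E[g²] = Var(f)/(1 − E[f])² holds exactly
for indicator data, which the recovery tests exploit.

## Model machinery

Fixed-effects logistic regression is Newton/IRLS with step-halving,
convergence |Δ loglik| < 1e−10, and SEs from the observed information. Columns
linearly dependent on earlier ones are dropped with a warning. Complete
separation is reported as an error naming the offending term (detected either
mid-iteration from diverging linear predictors or post hoc from a vanishing
deviance with runaway coefficients).

The mating-pair random intercept model is fitted by maximum likelihood with
one-dimensional adaptive Gauss–Hermite quadrature (25 nodes by default): each
cluster's integrand is centred at its conditional mode (vectorized Newton,
warm-started between evaluations) and scaled by its curvature. The score used
by the optimizer is the quadrature posterior expectation of the complete-data
score; the observed information comes from central differences of that score.
The variance parameter is optimized as log σ with a lower bound of e⁻¹⁰,
where the marginal likelihood coincides with the fixed-effects likelihood to
well below 1e−6. On frozen test data the fit matches `lme4::glmer` (nAGQ=25)
to about 1e−5 in coefficients, SEs, σ, and log-likelihood.

AICc is −2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting fixed effects plus the
random-intercept variance, and n the number of observations, not clusters —
the standard convention in the multimodel-averaging literature, flagged here
because alternatives exist. Model selection enumerates **all subsets** of the
candidate covariates (intercept, the always-included factors, and the random
intercept forced into every model), capped at 4096 models. Averaging is
*natural*: restricted to ΔAICc ≤ 2 models with renormalized weights,
per-term estimates averaged over the models containing the term,
USE = Σ w̃ √(SE² + (θ − θ̄)²), Σωᵢ the renormalized weight mass of models
containing the term, and 95% CIs as ±1.96·USE. Zero-substitution (shrinkage)
averaging is deliberately not implemented.

The MLH-vs-SLH comparison uses linear-model residual sums of squares on the
0/1 outcome, F = [(RSS_MLH − RSS_SLH)/(L−1)] / [RSS_SLH/(n − p_base − L − 1)]
— the decomposition is formulated for linear models, and the binary outcome
makes this a large-sample approximation, which the calibration tests bear out.

## Pipeline choices

Body condition is the within-year OLS residual of body mass on laying date,
wing and tarsus length. Single-locus models include the same nongenetic
covariates as the multilocus models (a het-only mode exists); the per-locus
effect size is the partial correlation approximated as r = z/√n. "Sequential
Bonferroni" is implemented as Holm's step-down procedure, verified against the
brute-force definition; correction is applied across the year's loci by
default, with `correct=False` allowing an external correction across all
year × locus tests. Heterozygosity × plot and heterozygosity × sex
interactions are fitted as separate post-hoc models, not inside the subset
enumeration. The pooled analysis stacks all years with year as a fixed factor
and keeps the pair random intercept.

Rows with missing modeled covariates are deleted row-wise per year with
logged counts, and each year must retain at least 20 modeled rows (the floor
is configurable).

## Selection and environment

The harshness window is July 1 of the focal year through March 31 of the
next, inclusive; strict mode errors on missing days. "Days outside the
thermal neutral zone" applies the hot bound (≥ 35 °C) to the daily maximum
and the cold bound (≤ 15 °C) to the daily minimum — the physiologically
binding extremes — because the underlying daily statistic is not fixed by
convention; a daily-mean mode is provided. Freezing-degree days count
tmin < 0 °C strictly. S uses the denominator-n covariance so that it equals
the recruits' mean heterozygosity minus the population mean exactly
(denominator n−1 via flag). Yearly series are related by ordinary
least-squares regression with Pearson r and a t-based two-sided p on n−2 df.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: ~150 breeders
per season over 7 monitored years (6 recruitment transitions), 26 loci split
14 neutral / 12 functional, allele counts uniform on 4–16 with flat-Dirichlet
frequencies drawn once (closed population). Inbreeding is a two-point
mixture — a fraction π = 0.2 of individuals with f = 0.25, the rest outbred —
because consanguineous matings in an otherwise outbred population are the
plausible source of ID in such systems and the mixture gives the clean closed
form E[g²] = Var(f)/(1 − E[f])² ≈ 0.0111 for recovery tests. Genotypes are
autozygous (one draw duplicated) with probability f, else two independent
draws.

Recruitment is Bernoulli with logit P = β₀ + β₁(year)·(het − 0.78), where
het is the individual's realized 1 − HL under the true locus weights and
β₁(year) = β₁base + β₁precip · z(precip) rises in wetter winters
(β₀ = −0.5, β₁base = 3, β₁precip = 5 by default). Centring the
heterozygosity term keeps yearly recruitment rates in a realistic 20–50%
band while β₁ varies only the strength (and, in dry years, the sign) of
selection. Recruits carry their genotype into the next season with age
incremented, and fresh individuals top the population back up, so sustained
positive selection enriches heterozygosity over time.

Weather is a daily sinusoid (July mean 25 °C, January 5 °C, diurnal range
12 °C, N(0, 3²) noise) with Bernoulli(0.18) rain occurrence, gamma
magnitudes (mean 9 mm), and a lognormal per-season wetness multiplier
(σ = 0.33) giving July–March accumulated precipitation a ~450 mm mean and
~160 mm interannual SD — a Mediterranean climate with 300–600 mm annual
rainfall. All randomness derives from one root seed through fixed,
name-registered substreams, so the weather simulated standalone is identical
to the weather inside a full study.

What the generator does **not** emulate: linkage between loci and local
effects of particular markers (loci are independent given f), pedigree
structure or heritability of heterozygosity, missing-data mechanisms beyond
missing-completely-at-random, observation error in recapture (capture effort
is implicitly 100%), and spatial structure between plots. Passing tests
therefore demonstrate correctness of the estimators and the detectability of
general-effect HFC under ID — not robustness to local effects, pedigree
confounding, or imperfect detection.

## Problem sizes used in tests

Brute-force g² equivalence runs on 100 random matrices with n ≤ 8, L ≤ 5; g²
recovery on 200 replicates of n = 2000, L = 26; permutation-test calibration
on 400 replicates at B = 200 (a scaled-down iteration count with the same
attainable p-grid as larger B); random-intercept SD recovery on 100
replicates of 200 clusters of 2; HFC slope recovery and coverage on 100
replicates of single years at n = 300; end-to-end direction checks on 100
replicate 6-transition studies. These sizes give Monte Carlo standard errors
small enough for 3-SE acceptance bands while keeping the default test run
fast.

## Known limitations

* The random-intercept model supports one grouping factor only (mating pair);
  crossed or nested random effects are out of scope.
* AICc model averaging reports natural averages; terms absent from every
  top-set model are omitted rather than shrunk toward zero, so Σωᵢ cannot be
  compared across tables with different top sets.
* The quadrature mixed model assumes a Gaussian random intercept; with very
  large cluster variance and tiny clusters the likelihood is flat in σ and
  estimates near the boundary should be interpreted cautiously (the fit
  reports σ and convergence status for exactly this reason).
* The F-ratio MLH/SLH test treats a binary outcome with a linear model, as
  the source decomposition prescribes; a deviance-based analogue is available
  (`mlh_vs_slh_ftest` operates on any numeric outcome, so deviance residuals
  can be passed instead).
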
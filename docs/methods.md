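# Methods

This note records the statistical procedures implemented in `abxgut`, the
conventions and defaults chosen where the design was open, what the
synthetic-data generator does and does not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Exposure construction from register records

One dispensed prescription is one course; duplicate (participant, ATC,
date) rows are treated as register artifacts and dropped. ATC codes are
classified by longest-prefix match into 11 classes (tetracyclines J01A,
extended-spectrum penicillins J01CA, penicillin V J01CE, flucloxacillin
J01CF, amoxicillin–clavulanic acid J01CR, cephalosporins J01DB/DC/DD,
sulfonamides–trimethoprim J01E, macrolides J01FA, clindamycin J01FF,
fluoroquinolones J01MA, nitrofurantoin J01XE01). Other J01 codes count for
washout and the negative control but not as predictors; non-J01 codes are
ignored.

Windows are day-based and half-open, with 1 year = 365.25 days and 1 month
= 30.4375 days, so every record falls in exactly one of the three periods
([0, 365.25), [365.25, 1461), [1461, 2922) days before sampling) and in
exactly one of 96 months. Fixed day lengths make boundaries exactly
testable; the alternative (calendar-month arithmetic) would make period
membership depend on the sampling date's day-of-month.

Eligibility: participants are excluded for any J01 dispense within the
washout (30 days by default; 0/182/365 as sensitivity settings), for
long-term-user regimens (methenamine within 91 days; nitrofurantoin or
trimethoprim ≥22.5 DDD in 84 days; any 40 mg doxycycline in 84 days;
100 mg doxycycline ≥84/56/42 DDD in 84/56/42 days; tetracycline or
lymecycline ≥42/28/21 DDD in the same windows), for IBD or chronic
pulmonary diagnosis flags, for a dispense between the two test-center
visits, for a visit interval over 60 days, and for sampling earlier than
8 years after register start (incomplete history). "3 months" is
implemented as 91 days and "12/8/6 weeks" as 84/56/42 days exactly. The
DDD thresholds are taken as stated conventions, not re-derived from WHO DDD
arithmetic. The audit log records every fired rule per participant, so the
exclusion flow is reproducible row by row.

## Microbiome preparation

Diversity (Shannon in nats, richness, inverse Simpson) is computed on
counts rarefied by a multivariate-hypergeometric draw to a fixed depth (by
default the per-cohort minimum row total). Species models use unrarefied
relative abundances (rows normalized to 100). The CLR uses a single global
pseudo-value — the smallest strictly positive entry of the matrix — added
before the log transform; entries that were zero before the transform are
then replaced by the per-species minimum CLR value among originally
non-zero entries, so all initial zeros of one species share one value. The
pooled-prevalence filter (>2% of all participants, strictly) runs before
the CLR; a per-cohort variant is available as a configuration switch, with
pooled the default reading of "present in >2% of the participants in the
three cohorts".

A deliberate approximation: rarefaction is applied to species counts
directly. In the motivating study design, rarefaction operates on gene
counts upstream of species profiling; with only species tables as input,
rarefying them is the closest available operation and preserves the
purpose (equalizing detection effort across samples).

## Association models

Per cohort, each outcome is regressed on the 33 course-count terms plus
covariates. The basic covariate set is age, sex, education, smoking,
country of birth and analysis plate; the full set adds BMI, a
comorbidity-index flag, polypharmacy and six medication flags. Cohorts
without family structure use OLS; the family-structured cohort uses a
linear model with a family random intercept fitted by REML (statsmodels
`MixedLM`; the design is standardized internally for optimizer stability
and mapped back, a pure reparameterization). Fits are complete-case.
Exposure terms with no exposed individuals in a cohort are dropped from
that cohort's model; in stratified analyses a term needs more than 5
exposed individuals (more than 10 for the age-interaction analysis, and
more than 5 per sex for the sex interaction) to enter.

Restricted cubic splines use the Harrell parameterization with 3 knots at
the 10th/50th/90th percentiles of the course-count distribution, collapsed
to the nearest distinct observed values (an error if fewer than three
distinct values exist). Estimated marginal means fix the target period's
pooled course count at 0–4 and average predictions over the observed
covariate rows — for a linear model this equals frequency-weighting
categorical covariates and setting continuous ones to their means. Pairwise
EMM contrasts use delta-method standard errors from the fit covariance,
with BH correction within the contrast family. The 0–4 grid reflects the
range over which dose–response is displayed; points beyond the observed
maximum trigger an extrapolation warning.

GVIF is computed as det(R11)·det(R22)/det(R) on the correlation matrix of
the centered model matrix, reported with GVIF^(1/(2d)). Interaction tests
compare full and reduced ML fits (REML likelihoods are not comparable
across fixed-effect structures) with a chi-square reference, df = number of
added interaction terms (3 per class); per-cohort p-values combine by
Fisher's method. Partial Spearman correlations are Pearson correlations of
rank residuals after regressing the ranked variables on the ranked
covariates; BMI leaves the covariate set when BMI is the marker.

FDR families are kept separate: the diversity family (classes × periods ×
3 metrics), the species family (classes × periods × species), the EMM
pairwise family and the interaction family are each corrected on their own.

## Meta-analysis and robustness

Fixed-effect pooling uses inverse-variance weights; the pooled z is
referred to a normal distribution (conventional for this estimator and
consistent with large per-cohort n). I² = max(0, (Q − (k−1))/Q)·100.
The influence screen is triggered for associations with q < 0.05 and
Cochran's Q p < 0.05: in each cohort the observation with the largest
|dfbeta| for the flagged term is removed (closed-form leave-one-out for
least squares; for the random-intercept cohort, candidates are the 50
highest residual-leverage observations, evaluated by GLS with the variance
parameters held at their full-fit REML estimates, followed by one true
REML refit of the chosen removal), the models are refitted, and the
cohort estimates re-pooled; an updated p > 0.05 marks the association
non-robust. "Highest dfbeta" is read as the maximum absolute value. If
removing the observation makes the term inestimable in a cohort (its only
exposed individual), that cohort drops out of the updated pooling.

## Functional regression

β_j(t) for each class is expanded in a cubic B-spline basis on [0, 96]
months — 6 basis functions by default (2 interior knots, about one basis
function per 16 months), evaluated at month midpoints. Each participant's
contribution reduces to per-basis projected scores Σ_t X_j(t)φ_k(t), so the
fit is one multiple regression of the outcome on all classes' scores plus
covariates; no roughness penalty is applied by default (a ridge option
exists but is off). The five rarely prescribed classes (cephalosporins,
macrolides, amoxicillin–clavulanic acid, sulfamethoxazole–trimethoprim,
nitrofurantoin) merge into one predictor by monthly OR before fitting; all
7 predictors enter jointly, mirroring the mutual adjustment of the main
models. Pointwise standard errors come from a participant-level bootstrap
(B = 200 by default; whole families are resampled where a family grouping
exists), and months are pooled across cohorts with the same fixed-effect
estimator as the main analysis. With one indicator basis function per
month the model reproduces the unsmoothed per-month regression exactly,
which the tests verify.

## The synthetic generator

The generator emulates the structure the pipeline assumes: three cohorts
(by default sized 8,488 / 4,784 / 1,707, with age ranges 50–65, 70–76 and
20–65; the third cohort carries family structure), per-class monthly
Bernoulli prescription histories over 96 months with per-class rates whose
implied one-year user shares approximate a published register tabulation
(e.g. ~6.6%/year for penicillin V), comorbidity confounding (a Charlson-
like flag multiplies prescription rates by 1 + strength and shifts the
microbiome), per-plate and per-family species effects, and planted
antibiotic effects that decay as 2^(−lag/halflife). Species counts follow
a log-normal–Poisson model (overdispersed, realistically zero-inflated for
the CLR zero path). The planted diversity effect operates by stochastically
zeroing present species with probability D/richness, so the expected
richness loss per course equals the planted decrement exactly; default
decrements (clindamycin 47, flucloxacillin 21, fluoroquinolones 20 species
at lag 0) mirror the magnitudes reported for the strongest register-linked
associations, and the default half-life of 24 months is a free parameter —
no quantitative recovery half-life is claimed for real data. A sampling
date equals the second visit date, the fallback used when collection dates
are unrecorded.

What the generator does not emulate — and hence what passing tests do not
show about real data: sequencing reads, strain dynamics or resistance
genes; dose and duration variation within courses; bursty prescription
episodes (the monthly Bernoulli process matches the functional model's
binarized input rather than real refill behavior); correlated species
interactions; and homoscedastic outcome noise. The zeroing mechanism ties
residual variance to exposure, so with large planted effects the
homoscedastic interaction LRT becomes anti-conservative for purely
variance-related reasons; its null calibration is therefore assessed under
the generator's global null, and the LRT machinery is separately verified
calibrated on homoscedastic data. Similarly, when the planted cumulative
decrement approaches the species count the effect saturates (a sample is
never emptied below one species), so calibration and recovery studies use
species tables large enough to stay in the linear regime.

## Problem sizes and numerical choices

Test and acceptance runs use reduced sizes chosen to keep planted effects
in the linear regime while exercising every stage: recovery of a planted
40-species decrement at n = 3,000 in the large cohort (300 species, depth
30,000); decay-shape recovery at n = 5,000; null calibration over 20
replicates of three cohorts totalling 800 participants; interaction-LRT
calibration over 100 replicates at n = 600; bootstrap-CI coverage over 200
replicates at n = 400 with B = 60. Seeds are explicit everywhere;
generators are bit-reproducible; rarefaction, bootstrap and simulation each
draw from independent seeded streams. Degenerate inputs fail loudly:
all-zero abundance rows, all-zero species columns entering the CLR,
rank-deficient designs (aliased terms are listed), rarefaction depths
exceeding row totals, and non-positive meta-analysis standard errors all
raise with context.

## Known limitations

Mixed-model influence diagnostics use a fixed-variance GLS approximation
for candidate ranking (documented above) rather than full REML
leave-one-out. The EMM model pools cohorts in a single fixed-effect fit
with plate labels nested within cohort rather than meta-analyzing
per-cohort EMMs. The generator's confounding is a single scalar mechanism;
real confounding by indication is richer. Whether washout-window
prescriptions should also count toward the "<1 year" exposure in
no-exclusion sensitivity runs is ambiguous; all in-window records are
counted, which is the more conservative reading for attenuation checks.
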
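# abxgut

Register-based analysis of long-term antibiotic effects on the gut
microbiome: a tested, reusable Python pipeline linking individual-level
prescription histories (ATC/DDD dispensing records over 8 years) to
metagenomic species diversity and abundance across multiple cohorts.

## The problem

Oral antibiotics disrupt the gut microbiome, but most evidence concerns the
weeks after a course. Prescription registers make it possible to ask a
longer question: is antibiotic use one, four, or eight years ago still
visible in today's microbiome? Answering it requires a chain of careful
steps — exposure windowing and eligibility rules on register records,
compositional preparation of species count tables, confounder-adjusted
regression within cohorts, meta-analytic pooling across cohorts, and a
functional model of the time-course of recovery. `abxgut` implements that
chain end to end, together with a synthetic-data generator that plants known
effects so every stage can be verified.

## The model

For each participant, dispensed prescriptions with ATC code J01 are
classified into 11 antibiotic classes and counted in three half-open
look-back windows before fecal sampling (<1 year, 1–4 years, 4–8 years,
with 1 year = 365.25 days). Each diversity metric or CLR-transformed
species abundance *y* is modeled per cohort as

```
y = abx1_4-8y + abx1_1-4y + abx1_<1y + … + abx11_<1y + covariates
```

with the 33 course counts as continuous predictors — ordinary least squares
in unrelated cohorts, a family-level random intercept (REML) in the
family-structured cohort. Cohort coefficients are pooled by
inverse-variance fixed-effect meta-analysis (Cochran's Q and I² for
heterogeneity), with Benjamini–Hochberg FDR control and a dfbeta influence
screen for significant-but-heterogeneous hits. Dose–response in total
courses is summarized with 3-knot restricted cubic splines and estimated
marginal means. The recovery time-course is estimated by scalar-on-function
regression: each class's 96-month binary exposure history X(t) enters via a
cubic B-spline expansion of its coefficient function β(t), with bootstrap
pointwise standard errors and per-month meta-analysis.

Alpha diversity follows the standard conventions — Shannon index (nats),
species richness, inverse Simpson — computed on counts rarefied without
replacement. Species abundances are centered log-ratio transformed after a
global pseudo-count, with initial zeros of each species mapped to one shared
value, and filtered at >2% pooled prevalence.

## Worked example

```python
from abxgut import RunConfig, SimConfig, run_study, summarize

cfg = RunConfig(
    sim=SimConfig(n_per_cohort=(500, 400, 300), species_count=80,
                  sequencing_depth=8000, seed=2),
    funreg_bootstrap=30, seed=2,
)
print(summarize(run_study(cfg)))
```

Output (abridged) from this configuration:

```
=== study summary ===
participants: 1200 (1132 eligible after 68 exclusions)
diversity: 21/99 class-period-metric associations at FDR 5%
  richness ~ clindamycin_lt1y: beta=-31.74 (se 0.78), q=0.00e+00, I2=36%
  richness ~ clindamycin_1to4y: beta=-17.39 (se 0.42), q=0.00e+00, I2=64%
  richness ~ flucloxacillin_1to4y: beta=-8.90 (se 0.34), q=8.07e-152, I2=66%
species: 582 significant associations; by class: clindamycin=196,
  flucloxacillin=177, fluoroquinolones=138, ...
negative control (post-sampling use): 0/3 significant
```

Reading this: the generator plants its largest richness decrement on recent
clindamycin courses, and the pipeline recovers exactly that ordering — the
strongest pooled coefficient is the per-course richness loss for clindamycin
use <1 year before sampling, effects attenuate for older exposure windows,
the planted species-level shifts for the three broad-impact classes
dominate the significant-association tally, and the post-sampling
negative-control exposure (which cannot cause the outcome) shows no
association, indicating the covariate adjustment controls the planted
confounding.

The same stages are exposed on the command line:

```bash
abxgut simulate --out-dir data --seed 1
abxgut exposure --register data/register.tsv --participants data/participants.tsv --out work
abxgut run-all --out-dir work --seed 1
```

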
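# emaswb

Within- and between-person analysis of subjective well-being (SWB) and
alcohol behavior in ecological momentary assessment (EMA) cohorts, with a
calibrated synthetic cohort generator.

EMA studies prompt participants on their smartphones up to several times a
day over multi-week waves: how many standard drinks they had in the past
24 hours, whether they drank alone or with others, momentary affect
ratings (valence, stress, burnout), a short free-text description of how
they are currently feeling, and baseline scales (AUDIT, PANAS, Cantril
ladder, PHQ-9, UCLA-3). Disentangling the *social* from the *problematic*
side of drinking needs both levels of analysis at once: between persons,
heavier and especially solitary drinkers report lower well-being, while
within persons, people report *higher* well-being on the days they drink
more — and lower on the days they drink alone. This package implements
that full analysis stack for researchers in behavioral/epidemiological
alcohol research and computational psychometrics.

## What it computes

* **Composite SWB**: `SWB = avg(momentary, baseline)` with
  `momentary = z(valence) − avg(z(stress), z(burnout))` and
  `baseline = avg(z(PA), z(Cantril)) − avg(z(NA), z(PHQ-9))`,
  missing components dropped from the enclosing mean; reliability via
  Cronbach's α, McDonald's ω (one-factor), ICC(1), test-retest r.
* **Day records**: first-report-of-day drink counts, Anscombe transform
  `2√(x + 3/8)`, minimum-days exclusions, next-day ("tonight") lagging,
  per-person drinking-alone fractions.
* **Inference**: person-mean-centered pooled correlations (≡ stage-wise
  multilevel fixed effects), within-person permutation p-values
  (N = 20,000), Steiger tests for dependent correlations, group-deviation
  t tests, standardized multiple regression, Benjamini–Hochberg FDR.
* **Language**: LDA topic usage (200 topics / 75 stop words / 750
  iterations in the full profile), document embeddings via a pluggable
  encoder, ridge regression with grouped 10-fold cross-validation and
  training-only feature selection + PCA, and topic–outcome partial
  correlations controlled for age and gender.
* **Synthetic cohorts**: a latent-trait generator whose drink-count,
  solitary-drinking, rating-reliability and effect-size structure is
  calibrated to published descriptive statistics (per-person mean drinks
  1.86 ± 2.05, median 1.29, skewness 1.89; 31% of drinking days alone,
  0.8 fewer drinks when alone; valence/stress/burnout ICCs .34/.61/.65;
  between-person r(SWB, alone fraction) ≈ −.29), so every stage of the
  pipeline is testable against known ground truth. See
  `docs/methods.md` for the model and calibration details.

## Worked example

Run the full pipeline on a small synthetic cohort (200 participants,
"fast" language profile):

```
emaswb all --outdir demo --seed 3 --n-participants 200
```

or equivalently from Python:

```python
from emaswb.pipeline import RunConfig, run
from emaswb.synthetic_data import CohortConfig

run(RunConfig(outdir="demo", profile="fast", seed=3,
              cohort=CohortConfig(n_participants=200, seed=3)))
```

`demo/fig1_correlations.csv` then holds the correlation panel (excerpt):

```
var1,var2,level,r,p,n
swb,mean_drinks,between,-0.156,0.036,181
swb,alone_fraction,between,-0.451,0.003,40
audit,mean_drinks,between,0.657,1.0e-23,181
momentary_swb,drinks,within_tonight,0.033,0.156,2164
momentary_swb,drinks,within_yesterday,-0.014,0.493,2712
momentary_swb,drinking_alone,within_tonight,-0.125,0.052,294
```

Read: across participants, SWB is mildly negatively related to mean
drinking (r = −.16) but much more strongly to the fraction of drinking
days spent alone (r = −.45 here; the population target is −.29 and the
small alone-analysis subsample, n = 40, is noisy). Within participants,
days of higher momentary SWB precede drinking *tonight* (r = +.03 at this
cohort size; +.07 at scale) while drinking-alone evenings follow
lower-SWB days (r = −.13). The permutation p-values come from shuffling
each participant's own days.

`demo/fig1d_accuracies.csv` holds the language-based accuracies:

```
outcome,level,feature_set,r,n
drinks,between,embeddings,0.452,181
drinking_alone,between,embeddings+fs_pca,0.380,40
swb,between,embeddings,0.537,181
drinks,within_yesterday,embeddings,0.303,2712
```

i.e. aggregated language predicts a person's mean drinking (r = .45) and
drinking-alone fraction (r = .38) better than the SWB rating correlations
above, and day-level language predicts yesterday's drinking at r = .30 —
the pattern the pipeline is designed to expose. `demo/report.md`
collects all tables, including the Table-1-style drinking-alone group
deviations and the Table-2-style standardized regression of SWB on
drinks, AUDIT and drinking alone.

## Layout

```
src/emaswb/
  synthetic_data.py   cohort generator (latent model, text, encoder)
  preprocess.py       day records, exclusions, Anscombe, lagging
  scoring.py          composite SWB, alpha/omega/ICC/test-retest
  stats.py            centering, permutation, Steiger, regression, BH
  language.py         tokenization, LDA, embeddings
  prediction.py       grouped ridge CV, feature selection + PCA
  associations.py     topic-outcome partial correlations
  pipeline.py, cli.py orchestration (`emaswb` console command)
```
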
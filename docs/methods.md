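# Methods

`emaswb` implements a complete within/between-person analysis pipeline for
ecological momentary assessment (EMA) studies of subjective well-being
(SWB) and alcohol behavior, together with a synthetic cohort generator
calibrated so that every analysis stage has recoverable signal and known
ground truth. This note documents the models, the calibration, the
numerical choices, and what the synthetic cohort does and does not
emulate.

## 1. The latent cohort model

Each participant *i* carries four latent traits:

* `t_i` — stable SWB trait, standard normal;
* `u_i` — drinking propensity, `u_i = a·(−t_i) + √(1−a²)·ζ_i`;
* `w_i` — solitary-drinking propensity, `w_i = c·(−t_i) + √(1−c²)·ξ_i`;
* a drawn abstainer indicator with probability π = 0.177.

Each calendar day *d* has an i.i.d. standard-normal affect deviation
`e_id`. Drinks consumed on the evening of day *d* are reported on day
*d+1* ("How many standard drinks did you have yesterday?"), so the affect
of day *d* couples with the drinks reported on day *d+1* — this is what
makes "drinking tonight" (day-n affect vs. day-n+1 report) the causally
aligned pairing, while "drinking yesterday" (same-day report) is linked
only through a small hangover penalty subtracted from the day's effective
affect.

### Drink counts

Day counts are zero-inflated negative binomial: an abstainer mass at the
person level, a Bernoulli drinking-day gate with probability
`expit(logit(p_i) + b_e·e_id)`, and an amount `1 + NegBin` with mean
`1 + (μ_i − 1)·exp(c_e·e_id − c_e²/2)` on drinking days (shape 4.0).
Rather than parameterizing `p_i` and `μ_i` independently, each drinker's
target mean daily drinks is constructed through a gamma quantile map

    M_i = θ · F⁻¹_Gamma(Φ(u_i); k)^s ,   k = 1.281, θ = 1.811, s = 0.984,

then split into frequency `p_i = min(expit(0.3 + 0.8·u_i), M_i)` and
amount `μ_i = M_i / p_i`. The quantile map makes the distribution of
per-person mean drinks gamma-shaped by construction; the published
descriptive statistics (mean 1.86, SD 2.05, median 1.29, skewness 1.89,
kurtosis 5.34 drinks/day, and post-Anscombe skewness 0.94) sit almost
exactly on a zero-inflated gamma with these parameters, which is what
motivated the construction. A printed median of 1.29 is impossible for
integer day counts, so these statistics are interpreted — and calibrated —
as the distribution of **per-person mean** daily drinks; day counts remain
integers.

All structural constants were fit once by Nelder-Mead moment matching
(simulated objective, common random numbers, 2–3·10⁵ person-days per
evaluation) against the full target set and then frozen. They should be
re-fit jointly if the model structure changes, never tweaked one at a
time.

### Drinking alone

Conditional on a drinking evening, solitary drinking follows
`P(alone) = expit(−1.32 + 1.95·w_i − 0.40·e_id)`, and the expected amount
on alone evenings is multiplied by δ = 0.745, renormalized by
`1/(0.69 + 0.31·δ)` so the reduction is mean-preserving at the calibrated
31% marginal alone share. The day-affect slope 0.40 reproduces a
within-person correlation of roughly −.12 between momentary SWB and
drinking alone *tonight*, while leaving the association with having drunk
alone *yesterday* near zero — matching the asymmetry seen in real EMA
cohorts (people feel worse on the days they go on to drink alone, not the
day after). The alone status exists latently on every drinking evening
but is only observed in waves 2 and 3, as in the emulated protocol.

### Effect-size targets and attenuation constants

`CohortConfig` exposes correlation targets (`r_between_drinks` = −.10,
`r_between_alone` = −.29, `r_within_drinks` = .07) rather than raw
loadings. Observed correlations are attenuated versions of the latent
couplings (measurement noise in the SWB composite, sampling noise in
person means, the nonlinear count model), so the loadings are derived as
`load = |target| / κ` with attenuation constants measured once from the
full pipeline at large n:

| constant | value | meaning |
|---|---|---|
| κ_between_drinks | 0.610 | observed r per unit loading of u on −t |
| κ_between_alone | 0.787 | observed r per unit loading of w on −t |
| κ_within | 0.0930 | within r gained per unit day-coupling scale |
| r₀_within | 0.0077 | baseline within r from the alone channel |

The linear mapping is accurate near the calibration point; configured
targets are recovered within ±0.04 at n = 5,000 persons (tested).
Targets whose implied loading would exceed 1 are rejected at
construction.

### Ratings

Valence is continuous on a 0–100 affect grid (`50 + 15·latent`, clipped);
stress and burnout are 1–5 ordinal, discretized at fixed normal quantile
cuts, and asked only on the first and last prompt of the day. Each
rating's latent is `√ICC·trait + √(1−ICC)·(state + prompt noise)`, which
makes the intraclass correlation exact at the prompt level. Because day
means average prompt noise and ordinal discretization attenuates
variance components, the latent ICCs carry small frozen compensation
factors (valence ×0.931, stress ×1.06, burnout ×1.05) so the *observed*
day-level ICCs land on the targets (.34/.61/.65).

### Baseline instruments

AUDIT (0–40), PANAS positive/negative (5–25), Cantril (0–10), PHQ-9
(0–27) and UCLA-3 (3–9) are emitted as rounded, clipped scale totals:
`loading·trait + √(1−loading²)·(√κ·stable_i + √(1−κ)·wave noise)`, with
the stable share κ solved per scale from its target test-retest
correlation. AUDIT loads 0.84 on the drinking propensity `u_i` (the
largest loading compatible with a .72 retest and a fully stable trait);
the SWB scales load 0.45–0.60 on `t_i` with signs matching their
constructs. Item-level responses are not simulated; scale totals are all
the pipeline consumes.

### Free text

Documents are token lists drawn from a planted mixture of seven topics
(friends-dinner, sad-anxious, hangover, work-routine, annoyed-irritated,
calm-content, drink-urge) plus high-frequency filler words. Token-level
mixture weights are a softmax of topic scores

    score_k = Σ_f loading_{k,f} · feature_f + style_{i,k} + ε_doc,k

over the features (day affect, SWB trait, last evening's Anscombe
drinks, drinking propensity, alone propensity). Two idiosyncratic
components are essential: per-document topic noise (sd 1.3) and a stable
per-person topic "style" (sd 0.9). Without them the planted signal is
nearly deterministic and language-based prediction saturates near r = 1;
with them, recovered accuracies fall in the empirically plausible range
(between-person drinks ≈ .48, AUDIT ≈ .37, alone fraction ≈ .2–.35;
within-person tonight ≈ .05, yesterday ≈ .30). Documents are 36 tokens,
a proxy for the 200-character minimum of the emulated instrument.

The synthetic encoder maps a document to a fixed random projection of its
planted-topic count vector (scaled to √length, plus token-keyed noise),
giving a deterministic, information-preserving stand-in for a transformer
embedding at configurable width (1536 by default, mirroring two
concatenated 768-wide hidden layers). A transformer adapter interface
exists but raises a capability error unless the optional stack is
installed; it is never a silent fallback.

## 2. Analysis stages

* **Preprocessing** — first non-missing drink report per day; day-mean
  ratings; texts concatenated in prompt order; participants with < 4
  recorded days excluded; Anscombe transform `2√(x+3/8)` of counts;
  "tonight" pairs join day-n features to day-n+1 reports for consecutive
  days within a wave; the drinking-alone fraction requires ≥ 3 observed
  drinking days.
* **Scoring** — composite SWB per the standard definition
  (`momentary = z_val − mean(z_stress, z_burn)`;
  `baseline = mean(z_PA, z_Cantril) − mean(z_NA, z_PHQ9)`;
  `SWB = mean(momentary, baseline)`), with missing parts dropped from the
  enclosing mean. `zscore` uses the population sd (ddof = 0); sample
  moments use ddof = 1. Reliability: Cronbach's α; McDonald's ω-total
  from a one-factor ML fit (Heywood loadings clipped); one-way ICC(1)
  with the unbalanced k₀; test-retest Pearson r over matched
  participants.
* **Inference** — within-person centering; the pooled centered Pearson r
  (identical to the standardized pooled-OLS slope, tested to 1e-10);
  permutation p-values that shuffle the outcome within each person's own
  days (the statistic is |Σxᵢyᵢ| since centering and scale are
  permutation-invariant; p = (1+hits)/(n_perm+1)); Steiger's Z for
  dependent correlations sharing a variable (Fisher z with the pooled-r
  covariance term; accuracy comparisons use |r| and the floor of the mean
  n); one-sample t group-deviation tests with SE = sd/√n; standardized
  multiple regression via the correlation-matrix solve; Benjamini-
  Hochberg step-up correction per outcome-by-level family.
* **Language features** — LDA on 1-gram counts after removing the most
  frequent corpus words; inference is batch variational EM
  (scikit-learn) with symmetric priors α = min(50/k, 1), η = 0.01,
  deterministic given the seed. The full profile uses k = 200 topics,
  750 iterations and a 75-word stop list; the fast profile (default CLI)
  uses k = 25 / 150 / 20 because the synthetic vocabulary is far smaller
  than a natural-language corpus. Person-level topic usage is the
  token-weighted mean of document usages (rows sum to 1).
* **Prediction** — ridge regression with 10-fold cross-validation;
  within-person analyses group folds by participant; standardization,
  univariate feature selection, PCA and the penalty choice (inner
  grouped CV over a log grid 10⁻³…10⁵) all use training rows only;
  accuracy is the Pearson r between pooled out-of-fold predictions and
  the outcome. An `as_written` mode that evaluates the best fold model on
  its own single held-out fold is provided for comparison but is not the
  default, being higher-variance and selection-biased.
* **Associations** — per-topic partial correlations with age and gender
  as covariates at the between level; within-person associations center
  usage and outcome per person first (demographic constants drop out of
  the centering) and apply no further adjustment; BH flags per family;
  zero-variance topics are skipped and reported as untested.

## 3. Problem sizes and reproducibility

The default pipeline cohort is 908 participants; the bundled test suite
and the acceptance script use 150–7,143 participants depending on the
statistic's Monte-Carlo noise: drink-distribution moments are checked on
a complete 14-day protocol at ~10⁵ person-days (isolating the behavioral
distribution from missingness), the drinking-alone structure and
correlation targets on the realistic multi-wave protocol at 6,000
participants. Every stochastic component takes an explicit seed; two
runs with the same configuration produce byte-identical tables and
file hashes (tested).

## 4. What the generator does not emulate

* No natural language: documents are bags of planted-topic tokens, so
  topic models recover the planted structure far more cleanly than they
  would real text, and transformer embeddings are emulated by a random
  projection. Passing language tests demonstrate the *pipeline* is
  correct, not that the effect sizes would survive real language.
* No within-person autocorrelation in affect (day deviations are
  i.i.d.), no weekday/weekend structure, no recruitment-wave overlap
  percentages (wave membership probabilities are configurable but
  independent of the latents).
* Compliance is missing-completely-at-random (a per-person Beta rate
  with a low-compliance mixture component); real missingness is likely
  related to drinking itself.
* The correlation between the solitary-drinking propensity and the
  drinking propensity beyond their shared SWB loading is unknown in the
  emulated literature; it is exposed as a free parameter
  (`r_alone_drink_extra`, default 0).

## 5. Numerical conventions

Sample sd uses n−1 except `zscore` (population sd, documented above);
skewness/kurtosis are the Fisher moment estimators g₁ and excess g₂, with
the convention that a constant vector has skewness and kurtosis 0;
frequency ties in the stop-word cut and weight ties in topic word
rankings break lexicographically; ICC is floored at −1; the Steiger test
rejects non-positive-definite correlation triples; BH rejects nothing on
an empty family.
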
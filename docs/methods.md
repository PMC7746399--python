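# Methods

`paitraj` is a self-contained pipeline for a question from life-course
epidemiology: does the way a child talks about physical activity — their
*physical activity identity* (PAI) — predict how active they are as an adult?
The original study design uses short essays written at age 11 about the
writer's imagined adult life, binary self-reports of weekly exercise at ages
23, 33, 42, 50 and 55, and a rich set of childhood controls.  Because the
underlying cohort data are restricted-access, the package ships a synthetic
cohort generator whose defaults encode the published study conditions; every
estimator can therefore be validated against known ground truth.

## 1. The synthetic cohort generator

The generator (`paitraj.simulate`) draws, per person:

* **sex** — Bernoulli(`female_frac`), default 0.495;
* **PAI gold labels** — a four-way mention split per sex: active-only /
  active-and-spectator / spectator-only / no mention, with default
  probabilities 20.6 / 15.7 / 5.9% for males and 28.1 / 2.2 / 3.2% for
  females (so 42.2% of males and 33.5% of females mention activity at all);
* **an essay** — template filler sentences about home, work and family,
  interleaved with 1–2 sentences embedding a phrase from the active lexicon
  (*swimming, football, play, horse, team, swim, dance, tennis, riding,
  footballer*) iff `active01 = 1`, and from a disjoint spectator lexicon
  (*watching, stadium, supporters, …*) iff `spectator01 = 1`.  Anonymization
  placeholders `<name>`/`<xxxx>` appear in some sentences.  Spelling noise is
  a random single-character substitution applied per token at
  `corruption_rate` (default 0.01); by default it spares lexicon tokens so
  that gold labels remain exactly recoverable from text, and a hard-mode
  flag (`corrupt_lexicon_tokens`) removes that protection.  The filler
  vocabulary is validated to be disjoint from both lexica, making
  *gold label ⇔ lexicon presence* an exact invariant at corruption 0;
* **a latent trajectory class** — multinomial logit over K classes with
  linear predictor `log π_sex + β_active·active01 + β_spectator·spectator01`,
  the first ("always active") class being the baseline with coefficients 0.
  Default class probabilities are the published per-sex four-class shares:
  males (0.60, 0.05, 0.19, 0.16), females (0.49, 0.26, 0.19, 0.06) for
  (always active, fluctuating/increasing, declining, always inactive), and
  the default β are the published fully-adjusted log relative-risk ratios
  (e.g. active PAI on always-inactive: log 0.659 for males);
* **the activity panel** — independent Bernoulli(ρ[class, wave]) given class,
  i.e. local independence holds by construction.  The class-conditional
  response curves ρ are not printed in the source report (only the class
  names and shares), so they are fixed here once at sharp, well-separated
  values: always active ≈ 0.93 at every adult wave, always inactive ≈ 0.04,
  the increasing class rising 0.05 → 0.96 and the declining class falling
  0.95 → 0.05 across ages 33–55.  The age-23 row is calibrated so the male
  marginal ≈ 43% plays sport weekly; the large published male–female gap at
  23 cannot be reproduced with class-conditional probabilities shared across
  sex (the female class mix alone pins the female marginal), a deliberate
  simplification;
* **childhood controls** — birthweight (kg), maternal smoking, father's
  social class (5 levels), BMI, enuresis, poor coordination, behaviour
  scores, general ability, school days missed, hospital admissions — from
  simple parametric families with plausible moments; and self-reported
  childhood sport (1–3), whose distribution shifts upward with the PAI
  labels to induce the small positive rank correlations (ρ ≈ 0.1) seen in
  the source data;
* **missingness** — each panel cell is deleted independently with
  probability `expit(logit(base_p_wave) + Σ γ_j x_j)` where the `x_j` are
  always-observed covariates, i.e. missing at random by construction.  The
  source reports no per-wave missingness rates; defaults rise with age from
  5% (age 23) to 18% (age 55) and are fully configurable;
* **a two-rater coding table** — each synthetic rater reports the gold code
  flipped with probability 0.023 (active) / 0.020 (spectator), rates chosen
  analytically so the expected Cohen's κ of the simulated manual coding sits
  near the published 0.90 / 0.82 at the default mention prevalences.

What the generator does **not** emulate: realistic child language (essays are
templates, so classifier accuracy is near-ceiling rather than the published
74.5 / 87.2%), correlation between controls and trajectory class, item-level
response styles, and non-ignorable dropout.  Passing tests therefore
demonstrate the *estimators* are correct under the stated model, not that
the pipeline would achieve any particular accuracy on historical essays.

## 2. Text features and the PAI classifier

Essays are lower-cased and tokenized on runs of letters/digits/apostrophes
with `<name>`/`<xxxx>` kept as tokens; spelling is never corrected.  Features
are binary presence indicators of all 1–3-grams occurring in at least
`ceil(min_doc_frac · n_docs)` documents (default 2%), in deterministic
lexicographic order.  Two classifiers (active, spectator) are trained
independently: linear large-margin models with an L1 penalty, solved by
liblinear, which pairs L1 with the squared hinge; the objective is scaled
per observation,

    min_w  λ‖w‖₁ + (1/n) Σᵢ max(0, 1 − yᵢ(w·xᵢ + b))²,

so duplicating the training set leaves the solution unchanged.  λ is chosen
by inner cross-validated accuracy on each training fold over a logarithmic
grid 10⁻³…10², ties broken toward larger λ (sparser model); the decision
threshold is fixed at score 0.  Evaluation uses stratified 10-fold CV
(seeded shuffle + per-class balancing via scikit-learn's StratifiedKFold)
with pooled held-out accuracy (fold-mean also reported) and the ROC/AUC,
where AUC is the normalized Mann–Whitney U (ties counted ½).  A
manual-lexicon baseline (predict 1 iff any lexicon phrase occurs) and a
sensitivity/specificity comparison table are provided; on generator output
the baseline is perfect by construction, and a dedicated test exercises the
ambiguous-context case ("play tennis" vs "watch them play on television")
where the learned model beats the lexicon on specificity.

## 3. Latent trajectory classes

The trajectory model is a finite mixture for the age 33–55 binary panel
(the age-23 item, asked differently, is excluded from trajectories): person
*i* belongs to class *k* with probability π_k and, given class, the wave
indicators are independent Bernoulli(ρ[k,t]).  Persons contribute likelihood
factors only for observed waves (full-information ML, valid under MAR);
persons with no observed trajectory wave are excluded with a logged count.

Estimation is EM on the collapsed table of distinct response patterns (≤ 3^T
rows, so cost is independent of n): E-step by Bayes' rule over observed
waves, M-step posterior-weighted means, ρ clamped to [1e-6, 1−1e-6],
convergence when the relative log-likelihood gain drops below 1e-8
(max 1,000 iterations), best of 20 seeded random starts (π ~ flat Dirichlet,
ρ ~ U[0.2, 0.8]).  The per-iteration log-likelihood path is retained and
asserted non-decreasing (1e-9 slack).  Label switching is resolved by
sorting classes by descending mean ρ (stable sort on ties), so class 1 is
always the most-active class and serves as the regression baseline; the two
middle classes of a 4-class fit have similar *mean* activity and are
distinguished for reporting by trajectory trend (late minus early activity).
Model selection fits K = 2…6 and tabulates log-likelihood, AIC, BIC and the
relative entropy 1 − (−Σᵢₖ p_ik log p_ik)/(n log K); the default
recommendation minimizes BIC and is reported, never silently applied.

**Identifiability.**  With T = 4 binary waves a K-class model has
(K−1) + 4K free parameters against 2⁴ − 1 = 15 degrees of freedom in the
response-pattern distribution.  K = 3 (14 parameters) is estimable and is
recovered accurately in simulation; **K = 4 (19 parameters) is not
identified** — the maximum-likelihood fit is a ridge, and the multi-start EM
legitimately attains log-likelihoods *above* the true parameter point while
landing elsewhere on the ridge.  In 4-class recovery experiments at
n = 8,000 the class-share estimates deviate from truth by up to ~0.05–0.09
even though the fitted pattern distribution is essentially correct.  This
mirrors the original design (a four-class model on four binary indicators)
and is a property of the model, not of this implementation; consequences:
4-class parameter estimates and the derived class shares should be read as
one representation of the fitted pattern distribution, modal classes remain
useful as a data partition, and downstream regression checks are designed
around quantities that survive this (null effects, injected-effect CIs).

## 4. Association models

*Per wave*: logistic regression of each adult indicator on the two PAI
indicators plus controls, fitted by Newton ML (statsmodels), reported as
odds ratios with Wald 95% CIs, exp(β ± 1.96·SE) — symmetric on the log
scale.  Complete separation is detected and reported with the offending
column where one exists; rank-deficient designs are rejected.  *Trajectory*:
the two-step procedure fits the latent class model per sex, assigns each
person their modal class (ties to the lower index) and fits a multinomial
logit of modal class on PAI (+ controls) with "always active" as baseline,
reported as relative risk ratios.  Three model tags are produced: univariate,
fully adjusted, and fully adjusted excluding childhood self-reported sport.
Modal assignment ignores classification uncertainty, which attenuates
effects toward 1 when entropy is moderate — the known cost of the two-step
approach, visible in the effect-recovery experiments.  Categorical controls
enter as indicator contrasts against the most frequent level; no
multiple-testing adjustment is applied.  Descriptives: per-sex per-wave
proportions with Wald CIs, the 1-df two-sample proportion chi-square (pooled
variance, no continuity correction), and Spearman rank correlations with
average ranks for ties.

## 5. Missing data

Chained-equations multiple imputation (`paitraj.impute`): variables with
missing cells are imputed cyclically (ascending missingness fraction) for
`n_iter` sweeps in each of M independent chains, from conditional models on
all other variables (categoricals one-hot in the predictor matrix).  Draws
are *approximate proper*: coefficients are perturbed by a normal draw from
their estimated sampling covariance; for continuous variables the residual
variance is first drawn as RSS/χ²(n−p) and residual noise added; binary and
categorical variables are drawn Bernoulli/multinomial from the perturbed
linear predictor.  If a logistic/multinomial conditional fit fails (e.g.
perfect separation inside a chain) that sweep falls back to an
observed-margin draw.  Defaults M = 20, n_iter = 10 follow common practice
(the source reports neither).  Observed cells are never altered; everything
is deterministic given (seed, M, n_iter).  Estimates across completed
datasets are combined by Rubin's rules: Q̄ = mean, Ū = mean within-variance,
B = sample between-variance, T = Ū + (1 + 1/M)B, df =
(M−1)(1 + Ū/((1+1/M)B))² (infinite when B = 0), t-based 95% CI.  In the
pipeline, the trajectory model uses FIML directly while the per-wave
regressions run on the imputed datasets and are pooled — matching the
division of labour in the source analysis.

## 6. Validation experiments and problem sizes

The test suite validates each stage against an independent oracle:
brute-force pairwise AUC (≤ 50 instances), a dense 5-parameter grid search
(resolution 0.02) for a 6-person/2-wave/2-class EM instance, saturated
closed forms for the 2×2 logistic OR and one-covariate multinomial RRR, the
2-class multinomial = logistic identity, and hand-computed κ, chi-square and
Rubin examples.  Monte-Carlo experiments use: class-frequency and
response-probability calibration at n = 100,000 / 50,000; BIC selection of
a true 3-class model at n = 5,000 over 20 replicates; null-effect CI
coverage over 200 replicates at n = 2,000; injected-effect (RRR 0.66)
recovery at n = 8,000 over 3 replicates; MI unbiasedness over 50 replicates
at n = 2,000 with M = 10.  These sizes keep the full suite to a few minutes
on one core while leaving Monte-Carlo error well inside the asserted bands.
The 4-class recovery experiment (n = 8,000, tolerances ±0.02 on π and ±0.03
on ρ) fails by design of the model — see the identifiability note above —
and is retained as an executable record of that limit.

## 7. Known limitations

Template essays make the text-classification task easier than historical
handwriting transcriptions; accuracy ceilings here say nothing about
real-corpus accuracy.  The two-step class regression attenuates effects when
posterior entropy is moderate; bias-adjusted three-step estimators are out
of scope.  The 4-class/4-wave mixture is under-identified (above).  MICE
draws are approximate-proper rather than fully Bayesian, and predictive mean
matching is not implemented.  Wald intervals are used throughout; profile
likelihood may behave better in small cells.
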
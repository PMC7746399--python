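# paitraj

Does a child's *physical activity identity* — writing about doing sport when
asked to imagine their adult life — predict how active they actually are
decades later?  `paitraj` implements the full analysis pipeline for that
question as a tested, reusable Python package: machine-coding of short
essays, latent trajectory classes for adult activity, and the regressions
linking the two.  Because the cohort data such studies use are
restricted-access, the package includes a synthetic cohort generator with
all true parameters known, so every stage is verifiable end-to-end without
any download.  It is aimed at epidemiologists and methodologists who want to
study, extend or stress-test this class of "text-to-trajectory" designs.

## The models

**PAI classifier.**  Each essay is a binary bag of 1–3-grams (kept if
present in ≥ 2% of essays).  Two sparse linear classifiers — active mentions
and spectator mentions — are fitted with an L1 ("lasso") penalty,

&nbsp;&nbsp;min<sub>w</sub> λ‖w‖₁ + (1/n) Σᵢ max(0, 1 − yᵢ(w·xᵢ + b))²,

with λ chosen by inner cross-validation and performance assessed by
stratified 10-fold CV (accuracy, ROC/AUC).  Cohen's κ quantifies the
agreement of the two raters who code the training set.

**Latent trajectory classes.**  Adult activity y<sub>it</sub> ∈ {0,1} at
ages 33–55 follows a K-class mixture with local independence,

&nbsp;&nbsp;P(yᵢ) = Σₖ π<sub>k</sub> Π<sub>t observed</sub>
ρ<sub>kt</sub><sup>y<sub>it</sub></sup>(1−ρ<sub>kt</sub>)<sup>1−y<sub>it</sub></sup>,

estimated by multi-start EM with full-information ML over missing waves,
and selected over K = 2…6 by BIC/AIC/entropy.  The API follows the
Model/Results convention: `LatentClassModel(panel, k_classes).fit()` returns
a `LatentClassResults` with `summary()`, `predict_posterior()` and fit
statistics.

**Association.**  Per-wave logistic regressions give odds ratios for PAI on
each adult wave (pooled across multiply-imputed datasets by Rubin's rules);
a two-step multinomial logit of the modal trajectory class on PAI and
childhood controls gives relative risk ratios against the "always active"
baseline.

## Worked example

```python
from paitraj import CohortConfig, generate_cohort, LatentClassModel, two_step

cohort = generate_cohort(CohortConfig(n_persons=2000, seed=1))
males = cohort.pa_panel.subset_sex("male").subset_ages((33, 42, 50, 55))
print(LatentClassModel(males, k_classes=4).fit(seed=0).summary())
```

```
Latent class model (binary indicators, local independence, FIML)
  n = 1007, waves = [33, 42, 50, 55], K = 4
  log-likelihood = -1678.1166   AIC = 3394.23   BIC = 3487.61
  relative entropy = 0.7657   converged = True (iter 478, 20 starts)
  class  pi      rho(age 33)  rho(age 42)  rho(age 50)  rho(age 55)
      1  0.5427      0.9457      0.9509      0.9939      0.9452
      2  0.0749      0.3095      0.3579      0.9370      0.9841
      3  0.2436      0.9000      0.8778      0.1563      0.2066
      4  0.1388      0.1032      0.0515      0.0276      0.0000
```

Class 1 is "always active" (high activity at every wave, 54% of these men),
class 2 rises, class 3 declines, class 4 is "always inactive".  The
two-step regression then asks whether an active PAI at age 11 shifts class
membership:

```python
out = two_step(cohort.pa_panel, cohort.gold_labels, cohort.covariates,
               k_classes=4, n_starts=10, seed=0)
tab = out["male"]["models"]["fully_adjusted"].table
print(tab[tab.term == "active01"][["outcome_class", "rrr", "ci_low", "ci_high", "p"]])
```

```
 outcome_class      rrr   ci_low  ci_high        p
             2 0.818910 0.512861 1.307592 0.402743
             3 1.157891 0.825881 1.623370 0.395141
             4 0.638286 0.410997 0.991268 0.045607
```

Boys who wrote about doing sport have a relative risk ratio of 0.64
(95% CI 0.41–0.99) of being "always inactive" rather than "always active"
as adults — the generator injected a true RRR of 0.659 on that class, so
the pipeline recovers the signal at this sample size.

The same analysis runs from the shell with a single TOML config:

```bash
paitraj run-all examples/demo.toml outdir/
```

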
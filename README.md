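# bprsig — Bayesian probit gene signatures for blood-based IPF diagnosis

Idiopathic pulmonary fibrosis (IPF) is ordinarily diagnosed by integrating
clinical, radiological and pathological evidence; a peripheral-blood
transcriptomic classifier offers a far less invasive route. `bprsig`
implements the complete analysis used to build and validate such a
*functional gene signature* — a fitted predictive model, not a mere gene
list — from normalized microarray expression of blood samples:

1. **Stratified systematic split.** Cases are stratified by
   pulmonary-function severity (mild: FVC% ≥ 75 and DLCO% ≥ 65; severe:
   FVC% ≤ 50 and DLCO% ≤ 35; otherwise moderate; unknown when neither
   measure exists), controls form their own stratum, and every third sample
   per stratum is reserved for independent validation.
2. **Exploration.** Coefficient-of-variation filtering (top 10% of genes by
   sd/|mean|), PCA of samples, and UPGMA clustering under the Pearson
   correlation distance 1 − r.
3. **Signature core.** For signature size *k*: select the top-*k* genes by
   the pooled-variance two-sample t statistic; summarize the k-gene training
   submatrix by the first two factors of an SVD of the centered data
   ("metagenes"), giving each sample factor scores f = U₂ᵀ(x − μ); fit the
   Bayesian probit regression

   P(IPF | f) = Φ(β₀ + β₁f₁ + β₂f₂),  β ~ N(0, 10⁶·I),

   by the Albert–Chib latent-variable Gibbs sampler. A new sample's score is
   the posterior mean of Φ(β₀ + βᵀf) over the retained draws, with a central
   95% credible interval.
4. **Size tuning.** Fully nested leave-one-out cross-validation (gene
   selection, factorization and the probit fit are all redone inside every
   fold) over sizes 50–250; the chosen size maximizes LOOCV ROC AUC, with
   ties broken by the smaller sum of deviance SOD = Σᵢ |yᵢ − pᵢ| and then
   the smaller k.
5. **Validation.** ROC AUC, the Youden-index threshold
   (J = sensitivity + specificity − 1, calls at p ≥ t), confusion-matrix
   rates, and a Wilcoxon rank-sum test of association between predicted
   probability and phenotype.

A synthetic-cohort generator reproduces the statistical shape of the study
data (22,078 log2-intensity features; 89 IPF / 26 controls; a small DE
fraction with per-gene-sd effect sizes; severity strata consistent with the
drawn FVC/DLCO), so the entire pipeline runs and is tested without any
external download.

## Worked example

```python
import numpy as np
from bprsig import (SyntheticConfig, generate_cohort, annotate_severity,
                    stratified_systematic_split, tune_signature_size,
                    SignatureModel, McmcConfig, evaluate_predictions)

config = SyntheticConfig(seed=42, n_features=3000, n_ipf=60, n_normal=30,
                         de_fraction=0.02, effect_size_sd=2.0)
matrix, annotations, truth = generate_cohort(config)
annotate_severity(annotations)
split = stratified_systematic_split(annotations)
by_id = {a.sample_id: a for a in annotations}
train = matrix.select_samples(list(split.training_ids))
valid = matrix.select_samples(list(split.validation_ids))
y_train = np.array([by_id[s].label for s in split.training_ids])
y_valid = np.array([by_id[s].label for s in split.validation_ids])

curve = tune_signature_size(train, y_train, k_min=50, k_max=120, k_step=10,
                            seed=7, mcmc=McmcConfig(2000, 500))
results = SignatureModel(train, y_train, curve.chosen_k).fit(seed=7)
print(results.summary())
preds = results.predict(valid)
report = evaluate_predictions(preds["probability"].to_numpy(), y_valid)
print(f"chosen k = {curve.chosen_k}, validation AUC = {report.auc:.3f}, "
      f"threshold = {report.threshold:.3f}")
```

which prints (60 training / 30 validation samples, 60 true DE genes):

```
Bayesian probit gene signature
==============================================
Signature size (genes):   60
Training samples:         60 (40 IPF / 20 normal)
Retained draws:           5000
Decision threshold:       0.500
----------------------------------------------
coef              mean       sd    [2.5%   97.5%]
intercept       2.6492   2.6301  -2.1050   7.4012
factor1         1.7346   0.3500   1.0252   2.4764
factor2        -0.5623   1.1460  -2.4639   1.5335
==============================================
chosen k = 60, validation AUC = 1.000, threshold = 0.997
```

On this strong-signal cohort the tuning curve is essentially flat at LOOCV
AUC 1.0, ties resolve by the smaller sum of deviance (here k = 60), and the
independent validation set is classified perfectly — the expected behavior
at a 2-per-gene-sd effect on 2% of genes. The `factor1` coefficient carries
the class separation; its 95% credible interval (1.03, 2.48) excludes 0,
while `factor2` is indistinguishable from noise.

The same run is scriptable from the shell via the `bprsig` entry point
(`bprsig simulate | split | filter | explore | tune | train | predict |
evaluate | run`).

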
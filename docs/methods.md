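# Methods

## The model

`bprsig` builds two-class diagnostic classifiers from normalized log2
expression matrices (features × samples). The classifier has three fitted
components, all estimated on the training cohort only:

**Gene selection.** For each gene, the pooled-variance two-sample Student
t statistic between cases and controls, oriented as mean(IPF) − mean(normal).
The top *k* genes by |t| form the signature's feature list; ties are broken
lexicographically by feature id, and the pooled sd is floored at 1e−8 so a
pathologically constant gene yields a finite (and necessarily selected)
statistic rather than a division error.

**Metagene summarization.** The k-gene training submatrix is centered per
gene (centers μ are retained) and decomposed as X = U D Vᵀ. The first two
left singular vectors U₂ and singular values d₁ > d₂ summarize each sample
by factor scores f = U₂ᵀ(x − μ) — for training columns these equal the rows
of V D, so scores are on the D-scale. The alternative unit-scale (rows of
V) differs only by a per-factor rescaling that the regression coefficients
absorb; the D-scale is used because it makes the out-of-sample projection
identical to the stored training scores with no extra bookkeeping. Loading
signs are fixed deterministically (largest-magnitude element of each column
positive) so factorizations are reproducible across platforms. Exactly two
factors are used; the size of the expansion is not configurable.

**Probit regression.** P(y = 1 | f) = Φ(β₀ + β₁f₁ + β₂f₂) with a proper but
diffuse prior β ~ N(0, 10⁶·I) and the latent variance fixed at 1 (an
ordinary probit, not a scaled probit; freeing the latent scale is
unidentified jointly with ‖β‖ and is deliberately not offered). Fitting is
by the Albert–Chib data-augmentation Gibbs sampler: z_i | β is normal with
mean x_iᵀβ, variance 1, truncated to the positive half-line when y_i = 1
and the negative when y_i = 0; β | z is multivariate normal with covariance
(XᵀX + 10⁻⁶ I)⁻¹. Truncated normals are drawn by inverse-CDF sampling with
the uniform argument clipped to [1e−15, 1 − 1e−15], which keeps the chain
finite under extreme separation. Defaults: 6,000 iterations, 1,000 burn-in,
single chain, β initialized at 0; the seed is a required argument, and the
chain is bit-reproducible given (seed, settings, data). A batch-means
Geweke comparison of the early and late chain segments issues a
RuntimeWarning (never an error) at z > 4 on β₁; near-separated fits
genuinely mix slowly and do trigger it, which is information the user
should see.

**Prediction.** A new sample is projected onto the training loadings and
scored per retained draw as Φ(β₀ + βᵀf); the reported probability is the
mean over draws and the credible interval the central 95% of the per-draw
probabilities. A sample is called IPF at probability ≥ threshold, so a
published cutoff is itself attainable.

## Size tuning and honesty

Signature sizes are compared by fully nested leave-one-out
cross-validation: for each held-out sample, gene selection, factorization
and the probit fit are all recomputed from the remaining n − 1 samples.
Fold i uses seed (seed + i), so folds have independent chains but the whole
sweep is deterministic and parallelizes across k without changing results.
Sizes are scored by LOOCV ROC AUC (rank/Mann–Whitney form, ties counting
half) with ties broken by the smaller sum of deviance and then the smaller
k. The sum of deviance is Σᵢ |yᵢ − pᵢ| — the distance of each predicted
probability from the ideal probability 1 of the true phenotype; a binomial
alternative −2Σ[y log p + (1 − y) log(1 − p)] is available via
`sod_kind="binomial"` for users who prefer the likelihood-scale aggregate.
The default grid is every size in [50, 250]; a `k_step` parameter exposes
coarser grids, and the package's own study-shaped runs (tests and the
acceptance script) use steps of 10–50, which changes only the resolution of
the tuning curve, not the selection rule.

Two deliberate honesty devices: `loocv_probabilities(..., nested=False)`
selects genes once on the full cohort — labels included — and exists purely
to demonstrate selection-bias leakage (on null data it inflates LOOCV AUC
from ~0.5 to ~1.0); and the pipeline refuses to evaluate any sample whose
id appeared in training.

A known property of honest nested LOOCV with aggressive selection at small
n is a *pessimistic* bias: each fold's selected genes separate the fold's
classes by construction, and the held-out sample — excluded from its own
class mean — tends to land on the wrong side, so per-seed null AUC is
noisy (roughly 0.1–0.7 at n = 40 with 2,000 null genes) and its mean sits
at or slightly below 0.5. This is a property of the procedure, not a leak;
the leaky variant errs in the opposite (optimistic) direction.

## Evaluation

ROC AUC uses the rank statistic; the Youden threshold maximizes
J = sensitivity + specificity − 1 over the observed probabilities with ties
resolved toward the larger (specificity-favoring) cutoff; confusion-matrix
rates with empty denominators are reported as absent rather than 0; the
Wilcoxon rank-sum test is exact when both groups have ≤ 10 tie-free
observations and otherwise uses the tie-corrected normal approximation
without continuity correction (so perfectly symmetric data yields p = 1).

## Severity and splitting

Severity cutoffs (% predicted): mild requires FVC ≥ 75 and DLCO ≥ 65,
severe requires FVC ≤ 50 and DLCO ≤ 35, every other combination is
moderate; with a single available measure that measure's cutoffs apply
alone, and with neither the severity is unknown. The training/validation
split sorts each stratum (controls, plus cases by severity) by sample id
and sends 1-based positions 3, 6, 9, … to validation. The enumeration
order and starting offset of the original design are not recoverable from
the published counts — no fixed offset reproduces them jointly — so the
offset (1, 2 or 3) is a configuration option and 3 is the documented
default.

## The synthetic cohort generator

`generate_cohort` draws, per gene, a baseline mean uniform on (6, 14) log2
units and an sd uniform on (0.2, 1.5); a `de_fraction` subset of genes
(default 2%) receives a class-mean shift of `effect_size_sd` × its own sd
with random sign in the IPF class; noise is Gaussian; optional batch
offsets are N(0, batch_sd²) per gene × batch (default 0, matching the
absence of detectable batch structure in the kind of data emulated).
Cohort composition defaults to 89 cases / 26 controls with case severities
drawn 23:44:14:8 across mild/moderate/severe/unknown; FVC/DLCO values are
drawn inside ranges that the severity rule maps back to the sampled
stratum, so the two annotations are consistent by construction; family
history among cases is sporadic:familial ≈ 48:41. Everything is
bit-reproducible given the seed.

What the generator does **not** emulate: gene–gene correlation (each gene
is independent given class and batch), heavy-tailed intensity noise,
probe-level artifacts, and any severity-linked expression structure.
Consequences worth keeping in mind: PCA of a synthetic cohort explains far
less variance in two components than correlated real data does, and
passing power/honesty tests on synthetic cohorts demonstrates the
pipeline's statistical machinery, not the clinical performance of any
particular signature on real blood transcriptomes.

## Problem sizes and numerical choices

The packaged study-shaped runs use the full 22,078-feature, 115-sample
cohort with a coarse tuning grid (step 25 over 50–250) and shortened
chains for the LOOCV sweep (2,000 iterations, 500 burn-in), with the final
signature refitted at 6,000/1,000; simulation-based checks (null honesty,
sampler coverage) use 2,000-feature or factor-level problems with
2,000–2,500-iteration chains. These sizes were chosen to keep a full
reproduction comfortably on a laptop; the statistical procedure is
identical at every scale. Other numerical conventions: CoV = sd/|mean| on
the supplied log2 scale with sample (n − 1) sds, retaining exactly
⌈fraction × n⌉ genes; PCA centers per gene and never scales to unit
variance (CoV filtering has already equalized dispersion); UPGMA merges
follow the correlation distance 1 − r, which is invariant to the variance
convention since r is scale-free; rank-deficient factorizations, one-class
label vectors, zero-variance items in clustering, and CoV of a zero-mean
gene are all hard errors rather than silent repairs.

## Limitations

The signature's validity on real cohorts depends on normalization choices
upstream of this package (it consumes pre-normalized matrices and
deliberately contains no array-processing code). The LOOCV tuning curve is
noisy at small n, so the chosen size can move by a grid step across MCMC
seeds even when performance is flat — the AUC-then-SOD-then-smallest-k rule
makes the choice deterministic, not more certain. Credible intervals on
predicted probabilities reflect posterior uncertainty in β only, not
uncertainty in the selected gene list or the factorization.
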
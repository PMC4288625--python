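"""The functional gene signature core.

A signature is built in three steps on a training cohort:

1. rank genes by the two-sample Student t statistic (IPF vs normal) and keep
   the top *k* by absolute value;
2. summarize the k-gene submatrix by the first two factors of a singular
   value decomposition of the centered training data ("metagenes"), giving
   each sample a 2-vector of factor scores;
3. fit a Bayesian probit regression P(IPF | f) = Phi(b0 + b1 f1 + b2 f2) by
   the Albert-Chib latent-variable Gibbs sampler under a diffuse normal
   prior, and score new samples by projecting them onto the training
   loadings and averaging Phi(linear predictor) over the posterior draws.

:class:`SignatureModel` / :class:`SignatureResults` wrap these steps in the
model/results idiom: construct the model from data, ``fit`` it, and use the
results object for prediction, summaries and serialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .io import ExpressionMatrix, Phenotype, SampleAnnotation, SignatureModelRecord

__all__ = [
    "FeatureSelection",
    "MetageneFactorization",
    "McmcConfig",
    "BprPosterior",
    "select_features",
    "factorize",
    "project",
    "fit_bpr",
    "predict_record",
    "SignatureModel",
    "SignatureResults",
]

_SD_FLOOR = 1e-8          # pooled-sd floor for degenerate zero-variance genes
_PROB_EPS = 1e-15         # clip for inverse-CDF truncated-normal sampling
_COEF_NAMES = ("intercept", "factor1", "factor2")


@dataclass(frozen=True)
class FeatureSelection:
    """Top-|t| genes, ordered by decreasing absolute t statistic."""

    feature_ids: tuple[str, ...]
    t_statistics: np.ndarray
    k: int

    def __post_init__(self) -> None:
        t = np.asarray(self.t_statistics, dtype=float)
        object.__setattr__(self, "t_statistics", t)
        if len(self.feature_ids) != self.k or t.shape != (self.k,):
            raise ValueError("k must equal the number of selected features")
        if np.any(np.diff(np.abs(t)) > 1e-12):
            raise ValueError("|t| must be non-increasing along the selection")


def student_t_statistics(matrix: ExpressionMatrix, labels: Sequence[int]) -> np.ndarray:
    """Pooled-variance two-sample t per gene, oriented as mean(y=1) - mean(y=0)."""
    y = np.asarray(labels, dtype=int)
    if y.shape != (matrix.n_samples,):
        raise ValueError("labels length must match sample count")
    if not (np.all((y == 0) | (y == 1)) and 0 in y and 1 in y):
        raise ValueError("labels must be binary with both classes present")
    x1 = matrix.values[:, y == 1]
    x0 = matrix.values[:, y == 0]
    n1, n0 = x1.shape[1], x0.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValueError("each class needs >= 2 samples for a pooled variance")
    pooled_var = ((n1 - 1) * x1.var(axis=1, ddof=1)
                  + (n0 - 1) * x0.var(axis=1, ddof=1)) / (n1 + n0 - 2)
    sd = np.maximum(np.sqrt(pooled_var), _SD_FLOOR)
    return (x1.mean(axis=1) - x0.mean(axis=1)) / (sd * np.sqrt(1.0 / n1 + 1.0 / n0))


def select_features(matrix: ExpressionMatrix, labels: Sequence[int],
                    k: int) -> FeatureSelection:
    """Select the *k* genes with the largest |t|, ties broken by feature id."""
    if not 1 <= k <= matrix.n_features:
        raise ValueError(f"k must be in [1, {matrix.n_features}]")
    t = student_t_statistics(matrix, labels)
    order = sorted(range(matrix.n_features),
                   key=lambda i: (-abs(t[i]), matrix.feature_ids[i]))
    top = order[:k]
    return FeatureSelection(tuple(matrix.feature_ids[i] for i in top), t[top], k)


@dataclass(frozen=True)
class MetageneFactorization:
    """Two-factor SVD summary of a k-gene training submatrix.

    With per-gene centers mu and centered data X = U D V', the stored pieces
    are U2 (k x 2 loadings), d (top two singular values) and the training
    factor scores F = U2' (x_j - mu), i.e. the rows of V D — so projecting a
    training column reproduces its stored score exactly.
    """

    feature_ids: tuple[str, ...]
    gene_centers: np.ndarray         # (k,)
    loadings: np.ndarray             # (k, 2)
    singular_values: np.ndarray      # (2,)
    factor_scores: np.ndarray        # (n, 2)

    def __post_init__(self) -> None:
        if not np.allclose(self.loadings.T @ self.loadings, np.eye(2), atol=1e-8):
            raise ValueError("loadings are not orthonormal")


def factorize(sub_matrix: ExpressionMatrix) -> MetageneFactorization:
    """Per-gene centering followed by a rank-2 SVD of the training submatrix."""
    if sub_matrix.n_samples < 2 or sub_matrix.n_features < 2:
        raise ValueError("need >= 2 genes and >= 2 samples to factorize")
    centers = sub_matrix.values.mean(axis=1)
    centered = sub_matrix.values - centers[:, None]
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if np.sum(s > max(s[0], 1.0) * 1e-12) < 2:
        raise ValueError("centered training matrix has rank < 2")
    # fix signs deterministically: largest-|entry| loading element positive
    u2 = u[:, :2].copy()
    for c in range(2):
        pivot = np.argmax(np.abs(u2[:, c]))
        if u2[pivot, c] < 0:
            u2[:, c] = -u2[:, c]
    scores = centered.T @ u2           # rows of V D under the fixed signs
    return MetageneFactorization(sub_matrix.feature_ids, centers, u2,
                                 s[:2].copy(), scores)


def project(fac: MetageneFactorization, sample_vector: np.ndarray) -> np.ndarray:
    """Factor scores of a new sample: U2' (x - gene_centers)."""
    x = np.asarray(sample_vector, dtype=float)
    if x.shape != (len(fac.feature_ids),):
        raise ValueError(
            f"sample vector length {x.shape} does not match {len(fac.feature_ids)} features"
        )
    return fac.loadings.T @ (x - fac.gene_centers)


@dataclass(frozen=True)
class McmcConfig:
    """Gibbs sampler settings; the seed must be supplied for any fit."""

    iterations: int = 6000
    burn_in: int = 1000
    prior_variance: float = 1e6

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.iterations - self.burn_in < 1:
            raise ValueError("at least one retained draw required")


@dataclass(frozen=True)
class BprPosterior:
    """Retained post-burn-in draws of (intercept, factor1, factor2)."""

    draws: np.ndarray            # (m, 3)
    burn_in: int
    seed: int
    summary: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.summary is None:
            object.__setattr__(self, "summary", summarize_draws(self.draws))

    @property
    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)


def summarize_draws(draws: np.ndarray) -> pd.DataFrame:
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {"mean": draws.mean(axis=0), "sd": draws.std(axis=0, ddof=1),
         "ci_lo": lo, "ci_hi": hi},
        index=list(_COEF_NAMES),
    )


def _mean_se_batch(x: np.ndarray, n_batches: int = 20) -> float:
    """Standard error of the chain mean by batch means (autocorrelation-robust)."""
    n_batches = min(n_batches, max(x.size // 2, 1))
    usable = (x.size // n_batches) * n_batches
    means = x[:usable].reshape(n_batches, -1).mean(axis=1)
    if n_batches < 2:
        return float("inf")
    return float(np.sqrt(means.var(ddof=1) / n_batches))


def _geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    a = x[: max(int(first * x.size), 4)]
    b = x[-max(int(last * x.size), 4):]
    denom = np.hypot(_mean_se_batch(a), _mean_se_batch(b))
    return float(abs(a.mean() - b.mean()) / denom) if 0 < denom < np.inf else 0.0


def fit_bpr(factors: np.ndarray, labels: Sequence[int], *, seed: int,
            config: McmcConfig = McmcConfig()) -> BprPosterior:
    """Albert-Chib data-augmentation Gibbs sampler for the probit model.

    Latent z_i ~ N(x_i'beta, 1) truncated to the half-line given by y_i;
    beta | z is multivariate normal under the diffuse N(0, prior_variance I)
    prior. Truncated normals are drawn by the inverse-CDF method. The chain
    is deterministic given (seed, config, data).
    """
    f = np.atleast_2d(np.asarray(factors, dtype=float))
    y = np.asarray(labels, dtype=int)
    n = y.size
    if f.shape != (n, 2):
        raise ValueError("factors must be an (n, 2) array")
    if n < 4 or not (0 in y and 1 in y):
        raise ValueError("need n >= 4 with both classes present")

    x = np.column_stack([np.ones(n), f])
    prec = x.T @ x + np.eye(3) / config.prior_variance
    cov = np.linalg.inv(prec)
    chol = np.linalg.cholesky(cov)
    pos = y == 1

    rng = np.random.default_rng(seed)
    retained = config.iterations - config.burn_in
    draws = np.empty((retained, 3))
    beta = np.zeros(3)
    for it in range(config.iterations):
        eta = x @ beta
        a = ndtr(-eta)                      # P(z < 0 | eta), the truncation mass
        u = rng.random(n)
        p = np.where(pos, a + u * (1.0 - a), u * a)
        z = eta + ndtri(np.clip(p, _PROB_EPS, 1.0 - _PROB_EPS))
        beta = cov @ (x.T @ z) + chol @ rng.standard_normal(3)
        if it >= config.burn_in:
            draws[it - config.burn_in] = beta

    z1 = _geweke_z(draws[:, 1])
    if z1 > 4.0:
        warnings.warn(
            f"probit Gibbs chain may not have converged (Geweke z = {z1:.2f} "
            "on the first factor coefficient)", RuntimeWarning, stacklevel=2,
        )
    return BprPosterior(draws, config.burn_in, seed)


def _draw_probabilities(draws: np.ndarray, factors: np.ndarray) -> np.ndarray:
    """Per-draw class probabilities Phi(b0 + b.f), shape (n_samples, n_draws)."""
    x = np.column_stack([np.ones(len(factors)), factors])
    return ndtr(x @ draws.T)


def _prediction_frame(sample_ids: Sequence[str], probs: np.ndarray,
                      threshold: float) -> pd.DataFrame:
    mean = probs.mean(axis=1)
    lo, hi = np.percentile(probs, [2.5, 97.5], axis=1)
    return pd.DataFrame({
        "sample_id": list(sample_ids),
        "probability": mean,
        "ci_lo": np.minimum(lo, mean),
        "ci_hi": np.maximum(hi, mean),
        "predicted_class": np.where(mean >= threshold, Phenotype.IPF.value,
                                    Phenotype.NORMAL.value),
    })


def predict_record(record: SignatureModelRecord, matrix: ExpressionMatrix,
                   threshold: Optional[float] = None) -> pd.DataFrame:
    """Score samples with a serialized signature.

    Returns one row per sample: posterior-mean probability of IPF, central
    95% credible interval over the retained draws, and the thresholded call.
    """
    if record.posterior_draws is None:
        raise ValueError("record carries no posterior draws; cannot predict")
    missing = [f for f in record.feature_ids if f not in set(matrix.feature_ids)]
    if missing:
        raise KeyError(f"matrix lacks {len(missing)} model features, e.g. {missing[:5]}")
    sub = matrix.select_features(list(record.feature_ids))
    factors = (sub.values - record.gene_centers[:, None]).T @ record.loadings
    probs = _draw_probabilities(record.posterior_draws, factors)
    t = record.threshold if threshold is None else float(threshold)
    return _prediction_frame(matrix.sample_ids, probs, t)


class SignatureModel:
    """A k-gene Bayesian probit signature specified on a training cohort.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Normalized log2 expression of the training samples (all features;
        selection happens inside ``fit``).
    labels : sequence of {0, 1}
        1 for IPF, 0 for normal, aligned with ``matrix.sample_ids``.
    k : int
        Signature size (number of genes kept by the t filter).
    mcmc : McmcConfig, optional
        Sampler settings; defaults to 6000 iterations with 1000 burn-in.
    """

    def __init__(self, matrix: ExpressionMatrix, labels: Sequence[int], k: int,
                 mcmc: McmcConfig = McmcConfig()):
        self.matrix = matrix
        self.labels = np.asarray(labels, dtype=int)
        if self.labels.shape != (matrix.n_samples,):
            raise ValueError("labels must align with matrix samples")
        self.k = int(k)
        self.mcmc = mcmc

    @classmethod
    def from_annotations(cls, matrix: ExpressionMatrix,
                         annotations: Sequence[SampleAnnotation], k: int,
                         mcmc: McmcConfig = McmcConfig()) -> "SignatureModel":
        """Align phenotype labels to the matrix columns by sample id."""
        by_id = {a.sample_id: a for a in annotations}
        missing = [s for s in matrix.sample_ids if s not in by_id]
        if missing:
            raise KeyError(f"annotations missing for samples: {missing[:5]}")
        labels = [by_id[s].label for s in matrix.sample_ids]
        return cls(matrix, labels, k, mcmc)

    def fit(self, seed: int) -> "SignatureResults":
        """Run selection, factorization and the Gibbs sampler; return results."""
        selection = select_features(self.matrix, self.labels, self.k)
        sub = self.matrix.select_features(list(selection.feature_ids))
        fac = factorize(sub)
        posterior = fit_bpr(fac.factor_scores, self.labels, seed=seed,
                            config=self.mcmc)
        return SignatureResults(self, selection, fac, posterior)


class SignatureResults:
    """Fitted signature: posterior, diagnostics, prediction and serialization."""

    def __init__(self, model: SignatureModel, selection: FeatureSelection,
                 factorization: MetageneFactorization, posterior: BprPosterior,
                 threshold: float = 0.5):
        self.model = model
        self.selection = selection
        self.factorization = factorization
        self.posterior = posterior
        self.threshold = float(threshold)

    @property
    def params(self) -> pd.Series:
        """Posterior means of (intercept, factor1, factor2)."""
        return pd.Series(self.posterior.mean, index=list(_COEF_NAMES))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        lo, hi = np.percentile(self.posterior.draws,
                               [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
        return pd.DataFrame({"lower": lo, "upper": hi}, index=list(_COEF_NAMES))

    @property
    def fittedvalues(self) -> pd.Series:
        """Posterior-mean in-sample probabilities of IPF for the training cohort."""
        probs = _draw_probabilities(self.posterior.draws,
                                    self.factorization.factor_scores)
        return pd.Series(probs.mean(axis=1), index=list(self.model.matrix.sample_ids))

    def predict(self, matrix: ExpressionMatrix,
                threshold: Optional[float] = None) -> pd.DataFrame:
        """Score new samples; see :func:`predict_record`."""
        return predict_record(self.to_record(), matrix, threshold=threshold)

    def to_record(self, threshold: Optional[float] = None,
                  keep_draws: bool = True) -> SignatureModelRecord:
        summary = {
            name: {"mean": float(row["mean"]), "ci_lo": float(row["ci_lo"]),
                   "ci_hi": float(row["ci_hi"])}
            for name, row in self.posterior.summary.iterrows()
        }
        return SignatureModelRecord(
            feature_ids=self.selection.feature_ids,
            gene_centers=self.factorization.gene_centers,
            loadings=self.factorization.loadings,
            singular_values=self.factorization.singular_values,
            coefficient_summary=summary,
            threshold=self.threshold if threshold is None else float(threshold),
            posterior_draws=self.posterior.draws if keep_draws else None,
            training_metadata={
                "k": self.model.k,
                "seed": self.posterior.seed,
                "iterations": self.model.mcmc.iterations,
                "burn_in": self.posterior.burn_in,
                "n_training_samples": self.model.matrix.n_samples,
            },
        )

    def summary(self) -> str:
        """Plain-text fit summary in the model-results idiom."""
        lines = [
            "Bayesian probit gene signature",
            "=" * 46,
            f"Signature size (genes):   {self.model.k}",
            f"Training samples:         {self.model.matrix.n_samples} "
            f"({int(self.model.labels.sum())} IPF / "
            f"{int((1 - self.model.labels).sum())} normal)",
            f"Retained draws:           {self.posterior.draws.shape[0]}",
            f"Decision threshold:       {self.threshold:.3f}",
            "-" * 46,
            f"{'coef':<12}{'mean':>10}{'sd':>9}{'[2.5%':>9}{'97.5%]':>9}",
        ]
        for name, row in self.posterior.summary.iterrows():
            lines.append(f"{name:<12}{row['mean']:>10.4f}{row['sd']:>9.4f}"
                         f"{row['ci_lo']:>9.4f}{row['ci_hi']:>9.4f}")
        lines.append("=" * 46)
        return "\n".join(lines)
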
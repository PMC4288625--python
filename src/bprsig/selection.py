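"""Signature-size tuning by fully nested leave-one-out cross-validation.

For every candidate size k the whole construction — t-statistic gene
selection, SVD factorization, probit Gibbs fit — is repeated with each
sample held out in turn, so the held-out label never influences the genes
or factors used to score it. Candidate sizes are scored by LOOCV ROC AUC,
ties broken by the smaller sum of deviance and then by the smaller k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from joblib import Parallel, delayed

from .io import ExpressionMatrix
from .metrics import roc_auc
from .signature import (McmcConfig, _draw_probabilities, factorize, fit_bpr,
                        project, select_features)

__all__ = ["TuningCurve", "loocv_probabilities", "sum_of_deviance", "tune_signature_size"]


def loocv_probabilities(matrix: ExpressionMatrix, labels: Sequence[int], k: int,
                        *, seed: int, mcmc: McmcConfig = McmcConfig(),
                        nested: bool = True) -> np.ndarray:
    """Leave-one-out predicted probabilities of IPF at signature size *k*.

    For each fold the remaining n-1 samples drive feature selection,
    factorization and the probit fit; the held-out sample is projected onto
    the fold's loadings and scored by the posterior-mean probability. Fold i
    uses seed ``seed + i`` so chains are independent but reproducible.

    ``nested=False`` deliberately breaks the nesting (features are selected
    once on the full cohort, labels included) — a diagnostic for
    demonstrating selection-bias leakage, never for reporting performance.
    """
    y = np.asarray(labels, dtype=int)
    n = matrix.n_samples
    if y.shape != (n,):
        raise ValueError("labels must align with matrix samples")
    if n < 6 or y.sum() < 3 or (1 - y).sum() < 3:
        raise ValueError("LOOCV needs n >= 6 with at least 3 samples per class")

    leaky_features: Optional[list[str]] = None
    if not nested:
        leaky_features = list(select_features(matrix, y, k).feature_ids)

    probs = np.empty(n)
    all_ids = list(matrix.sample_ids)
    for i in range(n):
        keep = [s for j, s in enumerate(all_ids) if j != i]
        y_train = np.delete(y, i)
        if y_train.sum() < 2 or (1 - y_train).sum() < 2:
            raise ValueError(f"fold {i} leaves a class with < 2 samples")
        train = matrix.select_samples(keep)
        if leaky_features is None:
            features = list(select_features(train, y_train, k).feature_ids)
        else:
            features = leaky_features
        sub = train.select_features(features)
        fac = factorize(sub)
        posterior = fit_bpr(fac.factor_scores, y_train, seed=seed + i, config=mcmc)
        held_out = matrix.select_features(features).values[:, i]
        f = project(fac, held_out)
        probs[i] = float(_draw_probabilities(posterior.draws, f[None, :]).mean())
    return probs


def sum_of_deviance(probs: Sequence[float], labels: Sequence[int],
                    kind: str = "absolute") -> float:
    """Aggregate deviance between predicted probabilities and the true phenotype.

    ``absolute`` (default): sum of |y - p|, the distance of each predicted
    probability from the ideal probability 1 of the true class.
    ``binomial``: -2 sum [y log p + (1-y) log(1-p)], clipped at 1e-12.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probs and labels must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if kind == "absolute":
        return float(np.sum(np.abs(y - p)))
    if kind == "binomial":
        pc = np.clip(p, 1e-12, 1 - 1e-12)
        return float(-2.0 * np.sum(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
    raise ValueError(f"unknown deviance kind {kind!r}")


@dataclass(frozen=True)
class TuningCurve:
    """Per-size LOOCV performance and the selected signature size."""

    k_values: tuple[int, ...]
    loocv_auc: np.ndarray
    sod: np.ndarray
    chosen_k: int
    probabilities: dict = field(default_factory=dict)   # k -> (n,) array

    def __post_init__(self) -> None:
        if self.chosen_k not in self.k_values:
            raise ValueError("chosen_k must be one of k_values")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "k": list(self.k_values),
            "loocv_auc": self.loocv_auc,
            "sod": self.sod,
            "chosen": [k == self.chosen_k for k in self.k_values],
        })

    def plot(self, ax=None):
        """AUC and sum-of-deviance against signature size, chosen k marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.k_values, self.loocv_auc, "o-", label="LOOCV AUC")
        ax.set_xlabel("signature size (genes)")
        ax.set_ylabel("LOOCV AUC")
        ax2 = ax.twinx()
        ax2.plot(self.k_values, self.sod, "s--", color="tab:red", label="SOD")
        ax2.set_ylabel("sum of deviance")
        ax.axvline(self.chosen_k, color="grey", ls=":")
        return ax


def choose_k(k_values: Sequence[int], aucs: Sequence[float],
             sods: Sequence[float]) -> int:
    """Selection rule: maximal AUC, then minimal SOD, then smallest k."""
    triples = sorted(zip(k_values, aucs, sods),
                     key=lambda t: (-t[1], t[2], t[0]))
    return int(triples[0][0])


def tune_signature_size(matrix: ExpressionMatrix, labels: Sequence[int], *,
                        k_min: int = 50, k_max: int = 250, k_step: int = 1,
                        seed: int, mcmc: McmcConfig = McmcConfig(),
                        sod_kind: str = "absolute", n_jobs: int = 1,
                        nested: bool = True) -> TuningCurve:
    """Sweep signature sizes and pick the best by the AUC-then-SOD rule.

    Every k in ``range(k_min, k_max + 1, k_step)`` gets a full nested-LOOCV
    evaluation; the sweep parallelizes across k (each k keeps its own
    per-fold seeds, so results are identical for any ``n_jobs``).
    """
    if k_max < k_min or k_min < 1:
        raise ValueError("need 1 <= k_min <= k_max")
    if k_max > matrix.n_features:
        raise ValueError(f"k_max={k_max} exceeds {matrix.n_features} features")
    y = np.asarray(labels, dtype=int)
    k_values = tuple(range(k_min, k_max + 1, k_step))

    def one_k(k: int) -> np.ndarray:
        return loocv_probabilities(matrix, y, k, seed=seed, mcmc=mcmc, nested=nested)

    prob_list = Parallel(n_jobs=n_jobs)(delayed(one_k)(k) for k in k_values)
    aucs = np.array([roc_auc(p, y) for p in prob_list])
    sods = np.array([sum_of_deviance(p, y, kind=sod_kind) for p in prob_list])
    chosen = choose_k(k_values, aucs, sods)
    return TuningCurve(k_values, aucs, sods, chosen,
                       {k: p for k, p in zip(k_values, prob_list)})
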
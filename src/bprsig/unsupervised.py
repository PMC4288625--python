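"""Exploratory structure checks: PCA of samples and average-linkage clustering.

These mirror the global quality-control views used before model building:
a PCA of the CoV-filtered matrix to look for batch / severity / family-history
structure, and UPGMA dendrograms of samples or genes under the Pearson
correlation distance 1 - r.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

__all__ = ["PcaResult", "Dendrogram", "Axis", "pca", "hcluster"]


class Axis(str, enum.Enum):
    SAMPLES = "SAMPLES"
    FEATURES = "FEATURES"


@dataclass(frozen=True)
class PcaResult:
    """Sample scores and explained-variance fractions of a centered-data PCA."""

    sample_scores: np.ndarray        # (n_samples, n_components)
    variance_fractions: np.ndarray   # (n_components,)
    component_count: int

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fractions, dtype=float)
        if np.any(np.diff(vf) > 1e-12) or vf.sum() > 1 + 1e-9:
            raise ValueError("variance fractions must be non-increasing and sum to <= 1")


def pca(matrix: ExpressionMatrix, n_components: int) -> PcaResult:
    """Principal component analysis of the samples.

    Each feature is centered across samples (no variance scaling, the
    convention for expression data already equalized by CoV filtering); the
    scores are the SVD projections of the samples and the variance fractions
    are squared singular values over the total centered variance.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(matrix.n_features, matrix.n_samples):
        raise ValueError(
            f"n_components={n_components} exceeds min(features, samples)="
            f"{min(matrix.n_features, matrix.n_samples)}"
        )
    centered = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    # samples are observations: SVD of the (samples x features) view
    u, s, _ = np.linalg.svd(centered.T, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    total = float(np.sum(s**2))
    scores = u[:, :n_components] * s[:n_components]
    fractions = s[:n_components] ** 2 / total
    return PcaResult(scores, fractions, n_components)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative clustering result: merge triples over the given leaves.

    ``merges`` lists (node_i, node_j, height); leaves are numbered
    0..n-1 in ``leaf_ids`` order and internal node m is created by the m-th
    merge and numbered n + m, the scipy linkage convention.
    """

    merges: tuple[tuple[int, int, float], ...]
    leaf_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    def to_linkage(self) -> np.ndarray:
        """Scipy-style linkage matrix (for plotting or cutting)."""
        n = len(self.leaf_ids)
        sizes = {}
        z = np.zeros((n - 1, 4))
        for m, (i, j, h) in enumerate(self.merges):
            si = sizes.get(i, 1)
            sj = sizes.get(j, 1)
            sizes[n + m] = si + sj
            z[m] = (i, j, h, si + sj)
        return z

    def to_newick(self) -> str:
        """Nested-parenthesis text export with branch lengths from merge heights."""
        n = len(self.leaf_ids)
        height = {i: 0.0 for i in range(n)}
        text = {i: self.leaf_ids[i] for i in range(n)}
        for m, (i, j, h) in enumerate(self.merges):
            node = n + m
            bi = h - height[i]
            bj = h - height[j]
            text[node] = f"({text[i]}:{bi:.6g},{text[j]}:{bj:.6g})"
            height[node] = h
        return text[n + len(self.merges) - 1] + ";"


def _correlation_distance(items: np.ndarray, ids: tuple[str, ...]) -> np.ndarray:
    sds = items.std(axis=1, ddof=1)
    if np.any(sds == 0):
        bad = ids[int(np.nonzero(sds == 0)[0][0])]
        raise ValueError(f"item {bad!r} has zero variance: correlation undefined")
    r = np.corrcoef(items)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def hcluster(matrix: ExpressionMatrix, axis: Axis | str = Axis.SAMPLES) -> Dendrogram:
    """UPGMA (average linkage) clustering under Pearson correlation distance.

    Distance between items is d = 1 - r; merges follow scipy's agglomerative
    ordering, deterministic for a given input.
    """
    axis = Axis(axis)
    if axis is Axis.SAMPLES:
        items = matrix.values.T
        ids = matrix.sample_ids
    else:
        items = matrix.values
        ids = matrix.feature_ids
    if items.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    d = _correlation_distance(items, ids)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    merges = tuple((int(min(a, b)), int(max(a, b)), float(h)) for a, b, h, _ in z)
    return Dendrogram(merges, tuple(ids))
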
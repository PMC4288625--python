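"""Severity classification, coefficient-of-variation filtering and cohort splitting.

The splitting scheme mirrors the study design: cases are stratified by
pulmonary-function severity (controls form their own stratum) and every third
sample within each stratum is reserved for independent validation, so both
cohorts keep the same severity composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import Cohort, ExpressionMatrix, Phenotype, SampleAnnotation, Severity

__all__ = [
    "SeverityRule",
    "CohortSplit",
    "classify_severity",
    "annotate_severity",
    "cov_filter",
    "stratified_systematic_split",
]


@dataclass(frozen=True)
class SeverityRule:
    """Percent-predicted pulmonary-function cutoffs for disease severity.

    Mild disease requires FVC >= ``mild_fvc_min`` and DLCO >= ``mild_dlco_min``;
    severe disease requires FVC <= ``severe_fvc_max`` and DLCO <= ``severe_dlco_max``;
    every other combination is moderate.
    """

    mild_fvc_min: float = 75.0
    mild_dlco_min: float = 65.0
    severe_fvc_max: float = 50.0
    severe_dlco_max: float = 35.0

    def __post_init__(self) -> None:
        if not (self.mild_fvc_min > self.severe_fvc_max
                and self.mild_dlco_min > self.severe_dlco_max):
            raise ValueError("mild cutoffs must exceed severe cutoffs")


def classify_severity(fvc_pct: Optional[float], dlco_pct: Optional[float],
                      rule: SeverityRule = SeverityRule()) -> Severity:
    """Classify disease severity from percent-predicted FVC and DLCO.

    When only one measurement is available, its cutoffs are applied alone;
    when neither is available the severity is UNKNOWN. Cutoffs are inclusive.
    """
    for name, v in (("fvc_pct", fvc_pct), ("dlco_pct", dlco_pct)):
        if v is not None:
            if not math.isfinite(float(v)) or float(v) < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
    if fvc_pct is None and dlco_pct is None:
        return Severity.UNKNOWN

    mild_checks = []
    severe_checks = []
    if fvc_pct is not None:
        mild_checks.append(fvc_pct >= rule.mild_fvc_min)
        severe_checks.append(fvc_pct <= rule.severe_fvc_max)
    if dlco_pct is not None:
        mild_checks.append(dlco_pct >= rule.mild_dlco_min)
        severe_checks.append(dlco_pct <= rule.severe_dlco_max)
    if all(mild_checks):
        return Severity.MILD
    if all(severe_checks):
        return Severity.SEVERE
    return Severity.MODERATE


def annotate_severity(annotations: Sequence[SampleAnnotation],
                      rule: SeverityRule = SeverityRule()) -> list[SampleAnnotation]:
    """Return annotations with severity filled in from FVC/DLCO in place."""
    for a in annotations:
        a.severity = classify_severity(a.fvc_pct, a.dlco_pct, rule)
    return list(annotations)


def cov_filter(matrix: ExpressionMatrix, top_fraction: float = 0.10) -> ExpressionMatrix:
    """Retain the most variable genes by coefficient of variation.

    Keeps exactly ``ceil(top_fraction * n_features)`` features with the
    largest CoV = sd / |mean| (sample sd, across all samples, on the supplied
    log2 scale). Retained features are ordered by descending CoV with ties
    broken lexicographically by feature id.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must lie strictly between 0 and 1")
    values = matrix.values
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1) if matrix.n_samples > 1 else np.zeros(matrix.n_features)
    zero_mean = (means == 0.0) & (sds > 0.0)
    if np.any(zero_mean):
        bad = matrix.feature_ids[int(np.nonzero(zero_mean)[0][0])]
        raise ValueError(f"feature {bad!r} has zero mean and nonzero sd: CoV undefined")
    with np.errstate(invalid="ignore"):
        cov = np.where((means == 0.0) & (sds == 0.0), 0.0, sds / np.abs(means))
    n_keep = math.ceil(top_fraction * matrix.n_features)
    order = sorted(range(matrix.n_features),
                   key=lambda i: (-cov[i], matrix.feature_ids[i]))
    kept = [matrix.feature_ids[i] for i in order[:n_keep]]
    return matrix.select_features(kept)


@dataclass(frozen=True)
class CohortSplit:
    """Disjoint training/validation assignment with the strata that produced it."""

    training_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    strata: dict = field(default_factory=dict)   # label -> ordered sample ids

    def __post_init__(self) -> None:
        overlap = set(self.training_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"training and validation overlap: {sorted(overlap)[:5]}")


def _stratum_label(a: SampleAnnotation) -> str:
    if a.phenotype is Phenotype.NORMAL:
        return "NORMAL"
    return f"IPF_{a.severity.value}"


def stratified_systematic_split(annotations: Sequence[SampleAnnotation],
                                offset: int = 3) -> CohortSplit:
    """Assign every third sample per stratum to the validation cohort.

    Strata are the control group plus the four severity groups of cases.
    Within each stratum samples are ordered by sample id and 1-based
    positions ``offset, offset+3, offset+6, ...`` go to validation
    (``offset`` in {1, 2, 3}; the study does not state its enumeration
    order, so the starting offset is configurable). Deterministic given the
    annotation content. Cohort fields of the annotations are updated in place.
    """
    if not annotations:
        raise ValueError("no annotations supplied")
    if offset not in (1, 2, 3):
        raise ValueError("offset must be 1, 2 or 3")
    strata: dict[str, list[str]] = {}
    by_id = {}
    for a in annotations:
        strata.setdefault(_stratum_label(a), []).append(a.sample_id)
        by_id[a.sample_id] = a
    training: list[str] = []
    validation: list[str] = []
    for label in sorted(strata):
        ids = sorted(strata[label])
        strata[label] = ids
        for pos, sid in enumerate(ids, start=1):
            if pos >= offset and (pos - offset) % 3 == 0:
                validation.append(sid)
            else:
                training.append(sid)
    for sid in training:
        by_id[sid].cohort = Cohort.TRAINING
    for sid in validation:
        by_id[sid].cohort = Cohort.VALIDATION
    return CohortSplit(tuple(training), tuple(validation),
                       {k: tuple(v) for k, v in sorted(strata.items())})
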
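"""Synthetic microarray cohorts with the structure the pipeline assumes.

The generator emulates a normalized one-color array study of peripheral
blood: ~22,000 log2-intensity features, two phenotype classes with unequal
prevalence (89 IPF vs 26 controls by default), a small fraction of
differentially expressed genes with moderate per-gene-sd shifts, per-gene
heteroscedastic Gaussian noise, optional additive batch offsets, and
pulmonary-function values drawn to be consistent with a sampled severity
stratum. It supplies every pipeline stage with ground truth and removes any
need for the original accession.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io import (Cohort, ExpressionMatrix, FamilyHistory, Phenotype,
                 SampleAnnotation, Severity, save_annotations, save_expression)
from .preprocess import SeverityRule, classify_severity

__all__ = ["SyntheticConfig", "generate_cohort", "generate_worked_example"]

# severity composition of the IPF cases, mirroring the study's 23:44:14:8
_DEFAULT_SEVERITY_MIX = {
    Severity.MILD: 23 / 89,
    Severity.MODERATE: 44 / 89,
    Severity.SEVERE: 14 / 89,
    Severity.UNKNOWN: 8 / 89,
}

# percent-predicted (FVC, DLCO) ranges that classify_severity maps back
# to each stratum under the default cutoffs (mild >=75/>=65, severe <=50/<=35)
_PF_RANGES = {
    Severity.MILD: ((76.0, 110.0), (66.0, 100.0)),
    Severity.MODERATE: ((52.0, 74.0), (37.0, 64.0)),
    Severity.SEVERE: ((20.0, 50.0), (12.0, 35.0)),
}
_NORMAL_PF = ((85.0, 120.0), (75.0, 110.0))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-shaped simulation settings.

    Defaults reproduce the study conditions: 22,078 features, 89 IPF and 26
    control samples, 2% differentially expressed genes shifted by one
    per-gene sd, log2 baselines in (6, 14), per-gene sds in (0.2, 1.5), six
    batches with no batch effect, and the study's severity composition among
    cases. ``seed`` is required; generation is bit-reproducible given it.
    """

    seed: int
    n_features: int = 22078
    n_ipf: int = 89
    n_normal: int = 26
    de_fraction: float = 0.02
    effect_size_sd: float = 1.0
    baseline_mean_range: tuple[float, float] = (6.0, 14.0)
    gene_sd_range: tuple[float, float] = (0.2, 1.5)
    n_batches: int = 6
    batch_sd: float = 0.0
    severity_mix: dict = field(default_factory=lambda: dict(_DEFAULT_SEVERITY_MIX))
    sporadic_familial_odds: tuple[float, float] = (48.0, 41.0)

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_ipf < 1 or self.n_normal < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.effect_size_sd < 0 or self.batch_sd < 0:
            raise ValueError("effect_size_sd and batch_sd must be >= 0")
        for lo, hi in (self.baseline_mean_range, self.gene_sd_range):
            if not lo < hi:
                raise ValueError("ranges must be ordered (lo, hi)")
        total = sum(self.severity_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"severity_mix must sum to 1, got {total}")
        if self.effect_size_sd > 0 and 0 < self.de_fraction * self.n_features < 1:
            raise ValueError("de_fraction too small: no DE gene would be generated")


def _draw_pf(rng: np.random.Generator, severity: Severity,
             rule: SeverityRule) -> tuple[Optional[float], Optional[float]]:
    if severity is Severity.UNKNOWN:
        return None, None
    (f_lo, f_hi), (d_lo, d_hi) = _PF_RANGES[severity]
    fvc = float(np.round(rng.uniform(f_lo, f_hi), 1))
    dlco = float(np.round(rng.uniform(d_lo, d_hi), 1))
    assert classify_severity(fvc, dlco, rule) is severity
    return fvc, dlco


def generate_cohort(config: SyntheticConfig) -> tuple[ExpressionMatrix,
                                                      list[SampleAnnotation],
                                                      tuple[str, ...]]:
    """Simulate a two-class cohort; returns (matrix, annotations, true DE gene ids).

    Expression model per gene g and sample j:
    ``x_gj = mu_g + delta_g * 1[j is IPF] + b_{g,batch(j)} + eps``, with
    mu_g ~ U(baseline range), per-gene sd sigma_g ~ U(sd range),
    eps ~ N(0, sigma_g^2), batch offsets b ~ N(0, batch_sd^2), and
    delta_g = effect_size_sd * sigma_g with a random sign for the DE subset
    (zero elsewhere).
    """
    rng = np.random.default_rng(config.seed)
    rule = SeverityRule()
    n = config.n_ipf + config.n_normal
    g = config.n_features

    width = len(str(n))
    sample_ids = [f"S{j + 1:0{width}d}" for j in range(n)]
    phenotypes = [Phenotype.IPF] * config.n_ipf + [Phenotype.NORMAL] * config.n_normal
    phenotypes = [phenotypes[i] for i in rng.permutation(n)]

    feature_ids = tuple(f"G{i + 1:06d}" for i in range(g))
    mu = rng.uniform(*config.baseline_mean_range, size=g)
    sigma = rng.uniform(*config.gene_sd_range, size=g)

    n_de = int(round(config.de_fraction * g)) if config.effect_size_sd > 0 else 0
    de_idx = np.sort(rng.choice(g, size=n_de, replace=False)) if n_de else np.array([], int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    delta = np.zeros(g)
    delta[de_idx] = config.effect_size_sd * sigma[de_idx] * signs

    is_ipf = np.array([p is Phenotype.IPF for p in phenotypes], dtype=bool)
    values = mu[:, None] + rng.standard_normal((g, n)) * sigma[:, None]
    values[:, is_ipf] += delta[:, None]

    batches = rng.integers(0, config.n_batches, size=n)
    if config.batch_sd > 0:
        offsets = rng.normal(0.0, config.batch_sd, size=(g, config.n_batches))
        values += offsets[:, batches]

    mix_levels = list(config.severity_mix.keys())
    severities = [mix_levels[i] for i in rng.choice(
        len(mix_levels), size=config.n_ipf, p=list(config.severity_mix.values()))]
    odds = np.asarray(config.sporadic_familial_odds, dtype=float)
    hist_levels = (FamilyHistory.SPORADIC, FamilyHistory.FAMILIAL)
    histories = [hist_levels[i] for i in rng.choice(
        2, size=config.n_ipf, p=odds / odds.sum())]

    annotations: list[SampleAnnotation] = []
    ipf_counter = 0
    for j, sid in enumerate(sample_ids):
        if is_ipf[j]:
            severity = severities[ipf_counter]
            history = histories[ipf_counter]
            ipf_counter += 1
            fvc, dlco = _draw_pf(rng, severity, rule)
        else:
            history = FamilyHistory.NONE
            fvc = float(np.round(rng.uniform(*_NORMAL_PF[0]), 1))
            dlco = float(np.round(rng.uniform(*_NORMAL_PF[1]), 1))
            severity = classify_severity(fvc, dlco, rule)
        annotations.append(SampleAnnotation(
            sample_id=sid, phenotype=phenotypes[j],
            family_history=history, fvc_pct=fvc, dlco_pct=dlco,
            batch=f"batch{batches[j] + 1}", severity=severity,
            cohort=Cohort.UNASSIGNED,
        ))

    matrix = ExpressionMatrix(feature_ids, tuple(sample_ids), values)
    truth = tuple(feature_ids[i] for i in de_idx)
    return matrix, annotations, truth


def generate_worked_example(out_dir: str | Path | None = None, seed: int = 20140902,
                            with_outputs: bool = False):
    """A small fixed-seed cohort (300 genes x 40 samples) for demos and tests.

    Strong signal (1.5 sd shifts on 10% of genes) so that every pipeline
    stage produces interpretable output at desk scale. When ``out_dir`` is
    given, writes matrix.tsv, annotations.csv and truth.tsv there; with
    ``with_outputs=True`` it additionally runs the analysis at k=30 and
    writes the expected downstream results (selected_features.tsv,
    factor_scores.tsv, loocv_probabilities.tsv), making the bundle a
    self-contained regression fixture.
    """
    config = SyntheticConfig(seed=seed, n_features=300, n_ipf=24, n_normal=16,
                             de_fraction=0.10, effect_size_sd=1.5)
    matrix, annotations, truth = generate_cohort(config)
    outputs = None
    if with_outputs:
        from .selection import loocv_probabilities
        from .signature import McmcConfig, factorize, select_features

        labels = [a.label for a in annotations]
        selection = select_features(matrix, labels, 30)
        factorization = factorize(matrix.select_features(list(selection.feature_ids)))
        mcmc = McmcConfig(iterations=2000, burn_in=500)
        probs = loocv_probabilities(matrix, labels, 30, seed=seed % (2**31 - 1),
                                    mcmc=mcmc)
        outputs = {"selection": selection, "factorization": factorization,
                   "loocv_probabilities": probs}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_expression(matrix, out / "matrix.tsv")
        save_annotations(annotations, out / "annotations.csv")
        (out / "truth.tsv").write_text("\n".join(truth) + "\n")
        if outputs is not None:
            sel = outputs["selection"]
            (out / "selected_features.tsv").write_text(
                "feature_id\tt_statistic\n" + "".join(
                    f"{f}\t{t:.12g}\n"
                    for f, t in zip(sel.feature_ids, sel.t_statistics)))
            fac = outputs["factorization"]
            (out / "factor_scores.tsv").write_text(
                "sample_id\tfactor1\tfactor2\n" + "".join(
                    f"{s}\t{f1:.12g}\t{f2:.12g}\n"
                    for s, (f1, f2) in zip(matrix.sample_ids, fac.factor_scores)))
            (out / "loocv_probabilities.tsv").write_text(
                "sample_id\tprobability\n" + "".join(
                    f"{s}\t{p:.12g}\n"
                    for s, p in zip(matrix.sample_ids,
                                    outputs["loocv_probabilities"])))
    if with_outputs:
        return matrix, annotations, truth, outputs
    return matrix, annotations, truth
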
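"""End-to-end orchestration: split -> explore -> tune -> train -> predict -> evaluate.

One :class:`RunConfig` drives the whole analysis plan; re-running with an
identical config reproduces identical outputs, and every output file is
stamped with the config hash and seed that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import __version__
from .io import load_annotations, load_expression, save_model
from .metrics import evaluate_predictions
from .preprocess import annotate_severity, cov_filter, stratified_systematic_split
from .selection import tune_signature_size
from .signature import McmcConfig, SignatureModel
from .unsupervised import Axis, hcluster, pca

__all__ = ["RunConfig", "run_full_pipeline"]

logger = logging.getLogger("bprsig")


@dataclass(frozen=True)
class RunConfig:
    """Everything a full reproduction run needs, auditably in one place."""

    matrix_path: str
    annotations_path: str
    out_dir: str
    seed: int
    split_offset: int = 3
    k_min: int = 50
    k_max: int = 250
    k_step: int = 1
    n_jobs: int = 1
    mcmc_iterations: int = 6000
    mcmc_burn_in: int = 1000
    tune_mcmc_iterations: Optional[int] = None   # default: same as mcmc_iterations
    tune_mcmc_burn_in: Optional[int] = None
    threshold: Union[str, float] = "youden"      # "youden" or a fixed cutoff
    cov_top_fraction: float = 0.10
    explore: bool = True
    sod_kind: str = "absolute"

    def __post_init__(self) -> None:
        if isinstance(self.threshold, str):
            if self.threshold != "youden":
                raise ValueError("threshold must be 'youden' or a number in [0, 1]")
        elif not 0.0 <= float(self.threshold) <= 1.0:
            raise ValueError("fixed threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def hash(self) -> str:
        """Hash of the analysis-relevant settings (the output location is not one)."""
        doc = dataclasses.asdict(self)
        doc.pop("out_dir")
        payload = json.dumps(doc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stamp(config: RunConfig) -> str:
    return f"# bprsig {__version__} config_hash={config.hash()} seed={config.seed}\n"


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis plan; returns the report dict.

    Writes to ``config.out_dir``: ``split.json``, ``pca.tsv`` and
    ``dendrogram_training.nwk`` (when exploring), ``curve.tsv``,
    ``model.txt``, ``preds.tsv``, ``report.json`` and ``pipeline.log``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "load"
    try:
        logger.info("config hash %s seed %d", config.hash(), config.seed)
        matrix = load_expression(config.matrix_path)
        annotations = load_annotations(config.annotations_path)
        missing = [s for s in matrix.sample_ids
                   if s not in {a.sample_id for a in annotations}]
        if missing:
            raise ValueError(f"annotations missing for samples {missing[:5]}")
        annotate_severity(annotations)

        stage = "split"
        split = stratified_systematic_split(annotations, offset=config.split_offset)
        (out / "split.json").write_text(json.dumps({
            "config_hash": config.hash(), "seed": config.seed,
            "training_ids": list(split.training_ids),
            "validation_ids": list(split.validation_ids),
            "strata": {k: list(v) for k, v in split.strata.items()},
        }, indent=1))
        by_id = {a.sample_id: a for a in annotations}
        train_ids = [s for s in matrix.sample_ids if s in set(split.training_ids)]
        valid_ids = [s for s in matrix.sample_ids if s in set(split.validation_ids)]
        train = matrix.select_samples(train_ids)
        valid = matrix.select_samples(valid_ids)
        y_train = np.array([by_id[s].label for s in train_ids])
        y_valid = np.array([by_id[s].label for s in valid_ids])
        logger.info("split: %d training / %d validation", len(train_ids), len(valid_ids))

        if config.explore:
            stage = "explore"
            filtered = cov_filter(matrix, config.cov_top_fraction)
            result = pca(filtered, 2)
            with open(out / "pca.tsv", "w") as fh:
                fh.write(_stamp(config))
                fh.write("sample_id\tpc1\tpc2\tvariance_fraction_pc1\t"
                         "variance_fraction_pc2\n")
                for i, sid in enumerate(matrix.sample_ids):
                    fh.write(f"{sid}\t{result.sample_scores[i, 0]:.6g}\t"
                             f"{result.sample_scores[i, 1]:.6g}\t"
                             f"{result.variance_fractions[0]:.6g}\t"
                             f"{result.variance_fractions[1]:.6g}\n")
            dendro = hcluster(cov_filter(train, config.cov_top_fraction), Axis.SAMPLES)
            (out / "dendrogram_training.nwk").write_text(dendro.to_newick() + "\n")
            logger.info("explore: PC1+PC2 variance %.1f%%",
                        100 * result.variance_fractions.sum())

        stage = "tune"
        tune_mcmc = McmcConfig(
            iterations=config.tune_mcmc_iterations or config.mcmc_iterations,
            burn_in=(config.tune_mcmc_burn_in
                     if config.tune_mcmc_burn_in is not None else config.mcmc_burn_in),
        )
        curve = tune_signature_size(
            train, y_train, k_min=config.k_min, k_max=config.k_max,
            k_step=config.k_step, seed=config.seed, mcmc=tune_mcmc,
            sod_kind=config.sod_kind, n_jobs=config.n_jobs,
        )
        with open(out / "curve.tsv", "w") as fh:
            fh.write(_stamp(config))
            curve.to_frame().to_csv(fh, sep="\t", index=False)
        logger.info("tune: chosen k=%d (AUC %.3f, SOD %.3f)", curve.chosen_k,
                    curve.loocv_auc[curve.k_values.index(curve.chosen_k)],
                    curve.sod[curve.k_values.index(curve.chosen_k)])

        stage = "train"
        mcmc = McmcConfig(iterations=config.mcmc_iterations,
                          burn_in=config.mcmc_burn_in)
        results = SignatureModel(train, y_train, curve.chosen_k, mcmc).fit(config.seed)

        stage = "predict"
        overlap = set(train_ids) & set(valid_ids)
        if overlap:
            raise ValueError(f"validation samples seen in training: {sorted(overlap)[:5]}")
        preds = results.predict(valid)

        stage = "evaluate"
        fixed = None if config.threshold == "youden" else float(config.threshold)
        report = evaluate_predictions(preds["probability"].to_numpy(), y_valid,
                                      threshold=fixed)
        results.threshold = report.threshold
        record = results.to_record()
        record.training_metadata.update({"config_hash": config.hash(),
                                         "bprsig_version": __version__})
        save_model(record, out / "model.txt")
        preds = results.predict(valid)        # calls under the final threshold
        with open(out / "preds.tsv", "w") as fh:
            fh.write(_stamp(config))
            preds.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        report_doc = {
            "config_hash": config.hash(), "seed": config.seed,
            "bprsig_version": __version__,
            "chosen_k": curve.chosen_k,
            "loocv_auc": float(curve.loocv_auc[curve.k_values.index(curve.chosen_k)]),
            "loocv_sod": float(curve.sod[curve.k_values.index(curve.chosen_k)]),
            "n_training": len(train_ids), "n_validation": len(valid_ids),
            "threshold_source": ("youden" if fixed is None else "fixed"),
            **report.to_dict(),
        }
        (out / "report.json").write_text(json.dumps(report_doc, indent=1))
        logger.info("evaluate: AUC %.3f threshold %.3f accuracy %s",
                    report.auc, report.threshold, report.accuracy)
        return report_doc
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
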
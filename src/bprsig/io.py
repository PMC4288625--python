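"""Reading and writing expression matrices, sample annotations and signature models.

The on-disk conventions follow the GEO series-matrix style the deposited blood
cohorts use: expression is a tab-delimited features-by-samples table of
normalized log2 intensities, annotations are a CSV with fixed column names,
and a fitted signature is a versioned, human-readable JSON document.
All loaders validate at the boundary — missing or non-numeric expression
values are a hard error, never silently imputed.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MODEL_FORMAT_VERSION = 1

__all__ = [
    "Phenotype",
    "FamilyHistory",
    "Severity",
    "Cohort",
    "ExpressionMatrix",
    "SampleAnnotation",
    "SignatureModelRecord",
    "load_expression",
    "save_expression",
    "load_annotations",
    "save_annotations",
    "load_model",
    "save_model",
]


class Phenotype(str, enum.Enum):
    IPF = "IPF"
    NORMAL = "NORMAL"


class FamilyHistory(str, enum.Enum):
    SPORADIC = "SPORADIC"
    FAMILIAL = "FAMILIAL"
    NONE = "NONE"


class Severity(str, enum.Enum):
    MILD = "MILD"
    MODERATE = "MODERATE"
    SEVERE = "SEVERE"
    UNKNOWN = "UNKNOWN"


class Cohort(str, enum.Enum):
    TRAINING = "TRAINING"
    VALIDATION = "VALIDATION"
    UNASSIGNED = "UNASSIGNED"


class DataFormatError(ValueError):
    """Raised when an input file violates the expected layout or invariants."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized log2 expression, features x samples.

    Invariants (enforced on construction): unique feature and sample ids whose
    lengths match the value matrix, and all values finite.
    """

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise DataFormatError("expression values must be a 2-D matrix")
        if values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise DataFormatError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
                raise DataFormatError(f"duplicate {name} id: {dup!r}")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise DataFormatError(
                f"non-finite value at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(tuple(map(str, frame.index)), tuple(map(str, frame.columns)),
                   frame.to_numpy(dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=list(self.feature_ids),
                            columns=list(self.sample_ids))

    def select_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        """Row subset in the given order; unknown ids raise listing the missing."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:10]}")
        rows = [index[f] for f in feature_ids]
        return ExpressionMatrix(tuple(feature_ids), self.sample_ids, self.values[rows])

    def select_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:10]}")
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(self.feature_ids, tuple(sample_ids), self.values[:, cols])


@dataclass
class SampleAnnotation:
    """Clinical annotation for one blood sample.

    ``fvc_pct`` and ``dlco_pct`` are percent-predicted pulmonary function
    values; severity stays UNKNOWN until classified from them.
    """

    sample_id: str
    phenotype: Phenotype
    family_history: FamilyHistory = FamilyHistory.NONE
    fvc_pct: Optional[float] = None
    dlco_pct: Optional[float] = None
    batch: Optional[str] = None
    severity: Severity = Severity.UNKNOWN
    cohort: Cohort = Cohort.UNASSIGNED

    def __post_init__(self) -> None:
        self.phenotype = Phenotype(self.phenotype)
        self.family_history = FamilyHistory(self.family_history)
        self.severity = Severity(self.severity)
        self.cohort = Cohort(self.cohort)
        for name in ("fvc_pct", "dlco_pct"):
            v = getattr(self, name)
            if v is not None:
                v = float(v)
                if not math.isfinite(v) or v < 0:
                    raise ValueError(f"{name} must be a non-negative real, got {v}")
                setattr(self, name, v)
        if self.phenotype is Phenotype.NORMAL and self.family_history is not FamilyHistory.NONE:
            raise ValueError(
                f"sample {self.sample_id!r}: NORMAL samples must have family_history NONE"
            )

    @property
    def label(self) -> int:
        """Binary class label: 1 for IPF, 0 for normal."""
        return int(self.phenotype is Phenotype.IPF)


ANNOTATION_COLUMNS = ("sample_id", "phenotype", "family_history", "fvc_pct",
                      "dlco_pct", "batch", "severity", "cohort")


def load_expression(path: str | Path) -> ExpressionMatrix:
    """Load a tab-delimited features-by-samples expression table.

    First column holds feature ids, header row holds sample ids. Row and
    column order are preserved exactly; missing or non-numeric cells are
    rejected with their location.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                        keep_default_na=False)
    if frame.shape[1] == 0:
        raise DataFormatError(f"{path}: no sample columns found")
    values = np.empty(frame.shape, dtype=float)
    raw = frame.to_numpy()
    for j, col in enumerate(frame.columns):
        converted = pd.to_numeric(frame.iloc[:, j], errors="coerce").to_numpy()
        bad = np.nonzero(~np.isfinite(converted))[0]
        if bad.size:
            i = bad[0]
            raise DataFormatError(
                f"{path}: invalid expression value {raw[i, j]!r} at "
                f"feature {frame.index[i]!r}, sample {col!r}"
            )
        values[:, j] = converted
    return ExpressionMatrix(tuple(map(str, frame.index)),
                            tuple(map(str, frame.columns)), values)


def save_expression(matrix: ExpressionMatrix, path: str | Path,
                    float_format: str = "%.12g") -> None:
    frame = matrix.to_frame()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t", float_format=float_format)


def load_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Load the annotation CSV; one :class:`SampleAnnotation` per row.

    Required columns: sample_id, phenotype. Optional: family_history,
    fvc_pct, dlco_pct, batch, severity, cohort. Empty pulmonary-function
    cells mean "not measured".
    """
    frame = pd.read_csv(path, dtype=str)
    frame.columns = [c.strip().lower() for c in frame.columns]
    for required in ("sample_id", "phenotype"):
        if required not in frame.columns:
            raise DataFormatError(f"{path}: missing required column {required!r}")
    records: list[SampleAnnotation] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        sid = str(row["sample_id"]).strip()
        if sid in seen:
            raise DataFormatError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)

        def get(col: str) -> Optional[str]:
            v = row.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            v = str(v).strip()
            return v or None

        phenotype = get("phenotype")
        try:
            records.append(SampleAnnotation(
                sample_id=sid,
                phenotype=Phenotype(str(phenotype).upper()),
                family_history=FamilyHistory((get("family_history") or "NONE").upper()),
                fvc_pct=get("fvc_pct"),
                dlco_pct=get("dlco_pct"),
                batch=get("batch"),
                severity=Severity((get("severity") or "UNKNOWN").upper()),
                cohort=Cohort((get("cohort") or "UNASSIGNED").upper()),
            ))
        except ValueError as exc:
            raise DataFormatError(f"{path}: sample {sid!r}: {exc}") from exc
    return records


def save_annotations(annotations: Sequence[SampleAnnotation], path: str | Path) -> None:
    rows = []
    for a in annotations:
        rows.append({
            "sample_id": a.sample_id,
            "phenotype": a.phenotype.value,
            "family_history": a.family_history.value,
            "fvc_pct": a.fvc_pct,
            "dlco_pct": a.dlco_pct,
            "batch": a.batch,
            "severity": a.severity.value,
            "cohort": a.cohort.value,
        })
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(path, index=False)


@dataclass
class SignatureModelRecord:
    """The portable functional gene signature.

    Everything needed to score a new sample: the selected features, the
    per-gene centering values and two-factor SVD loadings from the training
    set, the probit posterior (summary plus retained draws) and the decision
    threshold on the posterior-mean probability of IPF.
    """

    feature_ids: tuple[str, ...]
    gene_centers: np.ndarray          # (k,)
    loadings: np.ndarray              # (k, 2), orthonormal columns
    singular_values: np.ndarray       # (2,), strictly decreasing, positive
    coefficient_summary: dict         # name -> {mean, ci_lo, ci_hi}
    threshold: float = 0.5
    posterior_draws: Optional[np.ndarray] = None   # (m, 3)
    training_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.feature_ids = tuple(str(f) for f in self.feature_ids)
        self.gene_centers = np.asarray(self.gene_centers, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        if self.posterior_draws is not None:
            self.posterior_draws = np.asarray(self.posterior_draws, dtype=float)
        k = len(self.feature_ids)
        if self.gene_centers.shape != (k,):
            raise ValueError("gene_centers length must match feature_ids")
        if self.loadings.shape != (k, 2):
            raise ValueError(f"loadings must be ({k}, 2)")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(2), atol=1e-6):
            raise ValueError("loadings columns are not orthonormal")
        d = self.singular_values
        if d.shape != (2,) or not (d[0] > d[1] > 0):
            raise ValueError("singular_values must be 2 strictly decreasing positives")
        if not 0.0 <= float(self.threshold) <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


def _matrix_to_json(a: Optional[np.ndarray]):
    return None if a is None else [[float(x) for x in row] for row in np.atleast_2d(a)]


def save_model(record: SignatureModelRecord, path: str | Path) -> None:
    """Serialize a signature to versioned, human-readable JSON text."""
    doc = {
        "format": "bprsig-signature",
        "format_version": MODEL_FORMAT_VERSION,
        "feature_ids": list(record.feature_ids),
        "gene_centers": [float(x) for x in record.gene_centers],
        "loadings": _matrix_to_json(record.loadings),
        "singular_values": [float(x) for x in record.singular_values],
        "coefficient_summary": record.coefficient_summary,
        "threshold": float(record.threshold),
        "posterior_draws": _matrix_to_json(record.posterior_draws),
        "training_metadata": record.training_metadata,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> SignatureModelRecord:
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DataFormatError(f"{path}: corrupted or truncated model file: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != "bprsig-signature":
        raise DataFormatError(f"{path}: not a bprsig signature file")
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise DataFormatError(
            f"{path}: unsupported model format version {version!r} "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    draws = doc.get("posterior_draws")
    return SignatureModelRecord(
        feature_ids=tuple(doc["feature_ids"]),
        gene_centers=np.asarray(doc["gene_centers"], dtype=float),
        loadings=np.asarray(doc["loadings"], dtype=float),
        singular_values=np.asarray(doc["singular_values"], dtype=float),
        coefficient_summary=doc["coefficient_summary"],
        threshold=float(doc["threshold"]),
        posterior_draws=None if draws is None else np.asarray(draws, dtype=float),
        training_metadata=doc.get("training_metadata", {}),
    )
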
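"""Reading, writing and validation of count matrices, labels and fitted models.

Count matrices are held genes x samples (rows = genes), the dominant
convention for expression matrices. Delimited text (TSV/CSV) is used for
counts and labels; fitted models are serialized to a versioned JSON schema.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("nblda")

MODEL_SCHEMA_VERSION = 1


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates a contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        Integer array of shape (G, n); ``counts[g, i]`` is the number of
        reads mapped to gene g in sample i.
    gene_ids, sample_ids
        Unique string identifiers matching the two matrix dimensions.
    """

    counts: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = _validate_count_array(self.counts, "counts")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        G, n = self.counts.shape
        if G < 1 or n < 1:
            raise ValidationError("count matrix must have at least one gene and one sample")
        if len(self.gene_ids) != G:
            raise ValidationError(f"{len(self.gene_ids)} gene ids for {G} rows")
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample ids for {n} columns")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def sample(self, i: int) -> "TestSample":
        """Extract column i as a test sample (shares gene identifiers)."""
        return TestSample(counts=self.counts[:, i].copy(), gene_ids=list(self.gene_ids))


@dataclass
class LabelVector:
    """Per-sample class assignment with classes indexed 1..K.

    ``labels[i]`` is the class index of sample i; ``class_names[k-1]`` is the
    original name of class k. Every class in 1..K appears at least once.
    """

    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.class_names = [str(c) for c in self.class_names]
        K = len(self.class_names)
        if K < 1:
            raise ValidationError("at least one class required")
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValidationError("labels must be a non-empty 1-D vector")
        present = np.unique(self.labels)
        if present.min() < 1 or present.max() > K:
            raise ValidationError(f"class indices must lie in 1..{K}, got {present}")
        if len(present) != K:
            missing = sorted(set(range(1, K + 1)) - set(present.tolist()))
            raise ValidationError(f"classes with no samples: {missing}")
        if K == 1:
            warnings.warn("all samples share a single class (K=1)", stacklevel=3)

    @property
    def K(self) -> int:
        return len(self.class_names)

    @property
    def n(self) -> int:
        return self.labels.size

    def class_sizes(self) -> np.ndarray:
        """n_k for k = 1..K."""
        return np.bincount(self.labels, minlength=self.K + 1)[1:]


@dataclass
class TestSample:
    """Count vector for one unlabeled sample, aligned to training genes."""

    counts: np.ndarray
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 1:
            raise ValidationError("test sample counts must be a 1-D vector")
        self.counts = _validate_count_array(arr.reshape(-1, 1), "test counts").ravel()
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.gene_ids and len(self.gene_ids) != self.counts.size:
            raise ValidationError("gene id list does not match count vector length")


# ---------------------------------------------------------------------------
# Validation helpers
# ---------------------------------------------------------------------------


def _validate_count_array(arr: np.ndarray, what: str) -> np.ndarray:
    a = np.asarray(arr)
    if a.ndim != 2:
        raise ValidationError(f"{what} must be 2-D, got {a.ndim}-D")
    if a.dtype.kind == "f":
        if not np.all(np.isfinite(a)):
            raise ValidationError(f"{what} contains non-finite entries")
        if not np.all(a == np.floor(a)):
            bad = np.argwhere(a != np.floor(a))[0]
            raise ValidationError(
                f"{what} entry at row {bad[0]}, column {bad[1]} is not an integer"
            )
        a = a.astype(np.int64)
    elif a.dtype.kind not in "iu":
        raise ValidationError(f"{what} has non-numeric dtype {a.dtype}")
    a = a.astype(np.int64)
    if np.any(a < 0):
        bad = np.argwhere(a < 0)[0]
        raise ValidationError(f"{what} entry at row {bad[0]}, column {bad[1]} is negative")
    return a


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


def _detect_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# Counts I/O
# ---------------------------------------------------------------------------


def read_counts(
    path: str | Path,
    orientation: str = "genes_by_samples",
    sep: str | None = None,
) -> CountMatrix:
    """Read a delimited count table with a header row and identifier column.

    ``orientation`` names the layout of the *file*; the returned matrix is
    always genes x samples, transposing if the file is samples x genes.
    The delimiter is inferred from the extension (.csv -> comma, otherwise
    tab) unless ``sep`` is given.
    """
    path = Path(path)
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_detect_sep(path, sep), index_col=0)
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise ValidationError(f"{path}: empty count table")
    try:
        arr = _validate_count_array(df.to_numpy(), str(path))
    except ValidationError:
        # re-raise with row/column names rather than positions
        raw = df.to_numpy()
        num = pd.to_numeric(pd.Series(raw.ravel()), errors="coerce").to_numpy()
        flat_bad = np.where(~np.isfinite(num) | (num < 0) | (num != np.floor(num)))[0]
        if flat_bad.size:
            r, c = divmod(int(flat_bad[0]), raw.shape[1])
            raise ValidationError(
                f"{path}: invalid count {raw[r, c]!r} at row {df.index[r]!r}, "
                f"column {df.columns[c]!r}"
            ) from None
        raise
    if orientation == "samples_by_genes":
        arr = arr.T
        gene_ids, sample_ids = list(df.columns), list(df.index)
    else:
        gene_ids, sample_ids = list(df.index), list(df.columns)
    return CountMatrix(counts=arr, gene_ids=gene_ids, sample_ids=sample_ids)


def write_counts(
    cm: CountMatrix,
    path: str | Path,
    orientation: str = "genes_by_samples",
    sep: str | None = None,
) -> None:
    """Write a count matrix as delimited text (inverse of :func:`read_counts`)."""
    path = Path(path)
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = cm.to_frame()
    if orientation == "samples_by_genes":
        df = df.T
    df.to_csv(path, sep=_detect_sep(path, sep))


# ---------------------------------------------------------------------------
# Labels I/O
# ---------------------------------------------------------------------------


def read_labels(path: str | Path, sample_ids: Sequence[str], sep: str | None = None) -> LabelVector:
    """Read a two-column (sample_id, class) file aligned to ``sample_ids``.

    Class names are mapped to indices 1..K in lexicographic order of name,
    making the index assignment deterministic and independent of row order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep), header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (sample_id, class)")
    mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    if len(mapping) != len(df):
        raise ValidationError(f"{path}: duplicate sample identifiers in label file")
    unknown = set(mapping) - set(map(str, sample_ids))
    if unknown:
        raise ValidationError(f"{path}: labels for unknown samples: {sorted(unknown)}")
    missing = [s for s in map(str, sample_ids) if s not in mapping]
    if missing:
        raise ValidationError(f"{path}: samples without a label: {missing}")
    return labels_from_names([mapping[str(s)] for s in sample_ids])


def labels_from_names(names: Sequence[str]) -> LabelVector:
    """Build a LabelVector from raw class names (lexicographic index order)."""
    names = [str(c) for c in names]
    class_names = sorted(set(names))
    index = {c: k + 1 for k, c in enumerate(class_names)}
    return LabelVector(
        labels=np.array([index[c] for c in names], dtype=np.int64),
        class_names=class_names,
    )


def write_labels(lv: LabelVector, sample_ids: Sequence[str], path: str | Path,
                 sep: str | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "sample_id": list(map(str, sample_ids)),
            "class": [lv.class_names[k - 1] for k in lv.labels],
        }
    )
    df.to_csv(path, sep=_detect_sep(path, sep), index=False)


# ---------------------------------------------------------------------------
# Model serialization (JSON schema, versioned)
# ---------------------------------------------------------------------------


def serialize_model(model, path: str | Path) -> None:
    """Write a fitted model to JSON at full floating precision.

    Floats are stored via ``repr`` round-trippable JSON numbers, so
    deserialization reproduces every field bit-for-bit.
    """
    from .classifier import NBLDAModel  # local import to avoid cycle

    if not isinstance(model, NBLDAModel):
        raise TypeError("serialize_model expects an NBLDAModel")
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "lambda_g": _float_list(model.lambda_g),
        "d_kg": [_float_list(row) for row in model.d_kg],
        "pi_k": _float_list(model.pi_k),
        "phi_hat": _float_list(model.phi_hat),
        "size_factors": _float_list(model.sf.s),
        "size_factor_method": model.sf.method,
        "size_factor_denominator": float(model.sf.denominator),
        "geo_means": None if model.sf.geo_means is None else _float_list(model.sf.geo_means),
        "class_names": list(model.class_names),
        "gene_ids": list(model.gene_ids),
    }
    Path(path).write_text(json.dumps(payload))


def deserialize_model(path: str | Path):
    """Read a model written by :func:`serialize_model`; lossless round trip."""
    from .classifier import NBLDAModel
    from .normalization import SizeFactors

    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: not valid model JSON ({exc})") from exc
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValidationError(
            f"{path}: unsupported model schema version {version!r} "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    required = [
        "lambda_g", "d_kg", "pi_k", "phi_hat", "size_factors",
        "size_factor_method", "size_factor_denominator", "class_names", "gene_ids",
    ]
    missing = [k for k in required if k not in payload]
    if missing:
        raise ValidationError(f"{path}: model file missing fields: {missing}")
    geo = payload.get("geo_means")
    sf = SizeFactors(
        s=np.array(payload["size_factors"], dtype=float),
        method=payload["size_factor_method"],
        denominator=float(payload["size_factor_denominator"]),
        geo_means=None if geo is None else np.array(geo, dtype=float),
    )
    return NBLDAModel(
        lambda_g=np.array(payload["lambda_g"], dtype=float),
        d_kg=np.array(payload["d_kg"], dtype=float),
        pi_k=np.array(payload["pi_k"], dtype=float),
        phi_hat=np.array(payload["phi_hat"], dtype=float),
        sf=sf,
        class_names=list(payload["class_names"]),
        gene_ids=list(payload["gene_ids"]),
    )


def _float_list(arr) -> list[float]:
    return [float(x) for x in np.asarray(arr, dtype=float).ravel()]
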
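"""Core data types and text-format readers/writers.

Expression matrices are tab-separated text (first column gene id, header
row sample ids, log2-scale values). Gene sets use the Broad GMT dialect.
Marker lists are one id per line with ``#`` comments. Trained models are
serialized to single-file JSON with an explicit ``schema_version``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CMS_CLASSES: tuple[str, ...] = ("CMS1", "CMS2", "CMS3", "CMS4")

MODEL_SCHEMA_VERSION = 1


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class ModelIOError(ValueError):
    """Raised when a serialized model cannot be loaded."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ParseError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Dense genes x samples matrix of log2-scale expression values.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique row identifiers.
    sample_ids : sequence of str
        Unique column identifiers.
    values : ndarray of shape (n_genes, n_samples)
        Finite expression values, genes in rows.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Row indices for ``genes``; raises KeyError listing the missing."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            shown = ", ".join(missing[:10])
            more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
            raise KeyError(f"genes absent from matrix: {shown}{more}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[idx])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise KeyError(f"samples absent from matrix: {', '.join(missing[:10])}")
        idx = np.array([lookup[s] for s in samples], dtype=int)
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def to_tsv(self, path: str | Path, id_column: str = "gene_id") -> None:
        df = self.to_frame()
        df.index.name = id_column
        df.to_csv(path, sep="\t", float_format="%.17g")


@dataclass
class GeneSetCollection:
    """Ordered, named, non-empty gene sets."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, genes in self.sets.items():
                desc = self.descriptions.get(name, "na")
                fh.write("\t".join([name, desc, *genes]) + "\n")


@dataclass
class MarkerGeneList:
    """Hepatocyte-enriched marker gene ids (the background-score indicator set)."""

    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("marker gene list is empty")
        _check_unique(self.genes, "marker gene")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# hepatocyte marker genes\n")
            for g in self.genes:
                fh.write(g + "\n")


SAMPLE_TYPES = ("primary", "metastasis", "normal_liver")


@dataclass
class SampleAnnotation:
    """Per-sample metadata table.

    Wraps a DataFrame with columns ``sample_id``, ``patient_id``,
    ``lesion_id``, ``sample_type`` and optional ``treated``,
    ``survival_time`` (months), ``event``.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "patient_id", "lesion_id", "sample_type")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dup))}")
        bad_type = set(self.table["sample_type"]) - set(SAMPLE_TYPES)
        if bad_type:
            raise ValueError(f"unknown sample_type values: {sorted(bad_type)}")
        if "survival_time" in self.table.columns:
            t = pd.to_numeric(self.table["survival_time"], errors="coerce")
            if (t.dropna() < 0).any():
                raise ValueError("negative survival_time")

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleAnnotation":
        return cls(pd.read_csv(path, sep="\t", dtype={c: str for c in cls.REQUIRED}))


@dataclass
class CMSLabel:
    """A single subtype call with optional posterior vector.

    ``label`` is "NA" when the maximum posterior fell below the
    confidence cutoff; ``nearest_label`` is always a concrete class.
    """

    label: str
    nearest_label: str
    posterior: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.label not in CMS_CLASSES + ("NA",):
            raise ValueError(f"invalid label {self.label!r}")
        if self.nearest_label not in CMS_CLASSES:
            raise ValueError(f"invalid nearest_label {self.nearest_label!r}")
        if self.posterior is not None:
            p = np.asarray(self.posterior, dtype=float)
            if p.shape != (len(CMS_CLASSES),):
                raise ValueError("posterior must have one entry per class")
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("posterior must be non-negative and sum to 1")
            self.posterior = p


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(
    path: str | Path, orientation: str = "genes-in-rows"
) -> ExpressionMatrix:
    """Read a TSV expression matrix.

    Parameters
    ----------
    path : str or Path
    orientation : {"genes-in-rows", "samples-in-rows"}
        Layout of the file; never guessed from content.
    """
    if orientation not in ("genes-in-rows", "samples-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.columns.size == 0:
        raise ParseError(f"{path}: no data columns (malformed header?)")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate column id: {dup!r}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate row id: {dup!r}")
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise ParseError(f"{path}: missing value in row {row!r}")
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell: {exc}") from exc
    if orientation == "samples-in-rows":
        return ExpressionMatrix(list(df.columns), list(df.index), values.T)
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def write_expression_matrix(x: ExpressionMatrix, path: str | Path) -> None:
    x.to_tsv(path)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name, description, gene ids."""
    sets: dict[str, list[str]] = {}
    descs: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >=3"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not genes:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
            descs[name] = desc
    return GeneSetCollection(sets, descs)


def read_marker_list(path: str | Path) -> MarkerGeneList:
    """Read a one-id-per-line marker list; '#' starts a comment."""
    genes: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                genes.append(token)
    if not genes:
        raise ParseError(f"{path}: no marker genes found")
    return MarkerGeneList(genes)


# ---------------------------------------------------------------------------
# model serialization (CentroidModel / PCAModel register here)


def serialize_model(model, path: str | Path) -> None:
    """Write a trained model to single-file JSON."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "model_type": type(model).__name__,
        "payload": model.to_dict(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def deserialize_model(path: str | Path):
    """Load a model written by :func:`serialize_model`."""
    # imported here to avoid a circular import at module load
    from metacms.classifier import CentroidModel
    from metacms.projection import PCAModel

    registry = {"CentroidModel": CentroidModel, "PCAModel": PCAModel}
    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelIOError(f"cannot load model from {path}: {exc}") from exc
    if not isinstance(payload, Mapping) or "schema_version" not in payload:
        raise ModelIOError(f"{path}: not a serialized model")
    if payload["schema_version"] != MODEL_SCHEMA_VERSION:
        raise ModelIOError(
            f"{path}: schema version {payload['schema_version']} "
            f"unsupported (expected {MODEL_SCHEMA_VERSION})"
        )
    cls = registry.get(payload.get("model_type"))
    if cls is None:
        raise ModelIOError(f"{path}: unknown model type {payload.get('model_type')!r}")
    try:
        return cls.from_dict(payload["payload"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelIOError(f"{path}: truncated or corrupt model: {exc}") from exc
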
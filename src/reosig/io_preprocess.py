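"""Reading and writing expression matrices, labels and gene sets.

Expression data live in a genes-by-samples :class:`ExpressionMatrix` backed by
a :class:`pandas.DataFrame`.  Matrices are exchanged as plain TSV (row 1 is the
sample header, column 1 the gene identifier); the GEO series-matrix dialect
(a probe-by-sample table wrapped in a ``!series_matrix_table_begin`` /
``!series_matrix_table_end`` envelope with quoted identifiers) is supported
read-only.  Gene sets use the standard GMT format.

Probe-level matrices are collapsed to gene level with the conventional rules
for oligonucleotide arrays: probes mapping to zero genes or to more than one
gene are discarded, and a gene's value per sample is the arithmetic mean of
its surviving probes.  No normalisation or log transform is ever applied here:
the downstream relative-ordering statistics are invariant to any within-sample
monotone transform, and averaging is performed on the values as stored.

Gene identifiers are opaque strings matched exactly and case-sensitively;
missing values are represented by empty cells or the token ``NA``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "collapse_probes",
    "read_gmt",
    "write_gmt",
]

MISSING_TOKENS = ("", "NA")


class MatrixParseError(ValueError):
    """Raised when an expression-matrix file cannot be parsed."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with optional per-sample class labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with sample IDs as columns.  ``NaN``
        marks a missing measurement.
    labels
        Optional Series mapping sample ID to a class label string.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes[:5]}")
        self.values = self.values.astype(float)
        if self.labels is not None:
            missing = [s for s in self.values.columns if s not in self.labels.index]
            if missing:
                raise ValueError(f"labels missing for samples: {missing[:5]}")
            self.labels = self.labels.reindex(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        unknown = [g for g in genes if g not in self.values.index]
        if unknown:
            raise KeyError(f"unknown genes: {unknown[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.labels)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        unknown = [s for s in samples if s not in self.values.columns]
        if unknown:
            raise KeyError(f"unknown samples: {unknown[:5]}")
        labels = self.labels.loc[list(samples)] if self.labels is not None else None
        return ExpressionMatrix(self.values[list(samples)], labels)

    def class_samples(self, label: str) -> list[str]:
        if self.labels is None:
            raise ValueError("matrix carries no labels")
        return [s for s, v in self.labels.items() if v == label]


def _validate_rectangular(lines: list[str], source: str) -> None:
    width = None
    for lineno, line in enumerate(lines, start=1):
        ncol = line.count("\t") + 1
        if width is None:
            width = ncol
        elif ncol != width:
            raise MatrixParseError(
                f"{source}: ragged row at line {lineno} ({ncol} fields, expected {width})"
            )


def _strip_geo_envelope(lines: list[str], source: str) -> list[str]:
    begin = end = None
    for i, line in enumerate(lines):
        if line.startswith("!series_matrix_table_begin"):
            begin = i
        elif line.startswith("!series_matrix_table_end"):
            end = i
    if begin is None or end is None or end <= begin:
        raise MatrixParseError(f"{source}: series-matrix table envelope not found")
    table = lines[begin + 1 : end]
    return [line.replace('"', "") for line in table]


def read_matrix(path: str | Path, dialect: str = "plain_tsv") -> ExpressionMatrix:
    """Read a genes x samples TSV matrix.

    ``dialect`` is ``"plain_tsv"`` or ``"geo_series_matrix"``; the GEO dialect
    strips the table envelope and identifier quotes before parsing.
    """
    path = Path(path)
    raw = path.read_text()
    lines = [ln for ln in raw.splitlines() if ln != ""]
    if dialect == "geo_series_matrix":
        lines = _strip_geo_envelope(lines, str(path))
    elif dialect != "plain_tsv":
        raise ValueError(f"unknown dialect: {dialect!r}")
    if not lines:
        raise MatrixParseError(f"{path}: empty matrix file")
    _validate_rectangular(lines, str(path))

    header = lines[0].split("\t")[1:]
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        gene_ids.append(fields[0])
        row = []
        for col, cell in enumerate(fields[1:], start=2):
            if cell in MISSING_TOKENS:
                row.append(np.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise MatrixParseError(
                    f"{path}: non-numeric cell {cell!r} at line {lineno}, column {col}"
                ) from None
        rows.append(row)
    frame = pd.DataFrame(rows, index=gene_ids, columns=header, dtype=float)
    try:
        return ExpressionMatrix(frame)
    except ValueError as exc:
        raise MatrixParseError(f"{path}: {exc}") from None


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = matrix.values.copy()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", na_rep="NA")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV (``sample_id``, ``label``) with header."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] != 2:
        raise MatrixParseError(f"{path}: expected two columns, got {frame.shape[1]}")
    series = pd.Series(frame.iloc[:, 1].values, index=frame.iloc[:, 0].values, name="label")
    if series.index.has_duplicates:
        raise MatrixParseError(f"{path}: duplicate sample IDs")
    return series


def write_labels(labels: pd.Series, path: str | Path) -> None:
    frame = pd.DataFrame({"sample_id": labels.index, "label": labels.values})
    frame.to_csv(path, sep="\t", index=False)


def collapse_probes(
    probe_matrix: ExpressionMatrix, annotation: Mapping[str, Iterable[str]]
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    Probes mapping to zero or to multiple genes are eliminated; each gene's
    value per sample is the mean over its surviving probes, missing values
    excluded from the mean.  Output genes are sorted by gene ID.
    """
    gene_of: dict[str, str] = {}
    for probe in probe_matrix.gene_ids:
        genes = set(annotation.get(probe, ()))
        if len(genes) == 1:
            gene_of[probe] = next(iter(genes))
    if not gene_of:
        raise ValueError("no probe maps to exactly one gene; nothing to collapse")
    kept = probe_matrix.values.loc[list(gene_of)]
    grouped = kept.groupby(by=lambda probe: gene_of[probe]).mean()  # skips NaN
    grouped = grouped.sort_index()
    return ExpressionMatrix(grouped, probe_matrix.labels)


@dataclass
class GeneSetCollection:
    """Named, ordered gene sets (GMT semantics).

    ``sets`` maps set name to the ordered list of member gene IDs (duplicates
    within a set are collapsed on load, order preserved); ``descriptions``
    carries the GMT description field.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> set[str]:
        return set(self.sets[name])

    def union(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out.update(members)
        return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\t").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno}: GMT needs name, description, >=1 member")
        name, desc, *members = fields
        if name in sets:
            raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
        seen: list[str] = []
        for g in members:
            if g and g not in seen:
                seen.append(g)
        sets[name] = seen
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, members in collection.sets.items():
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")
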
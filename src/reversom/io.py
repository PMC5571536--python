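"""Readers and writers for every external representation the pipeline touches.

Expression data travel as a genes x samples FPKM matrix (TSV, header row of
sample ids, first column of gene ids) plus a sample metadata table mapping
each sample to a tissue and an experimental group.  Gene sets use the
standard GMT dialect (name, description, then members, tab-separated).
Result tables are written as TSV with at least six significant digits so a
round-trip through disk is value-preserving.

Gene and sample identifiers are opaque, case-sensitive strings; no
symbol-to-accession mapping is attempted here or anywhere downstream.
Missing values are not representable: an FPKM exists for every gene in
every sample, and absence of expression is encoded as 0.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, FormatError

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "read_expression_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "write_table",
]

METADATA_COLUMNS = ("sample_id", "tissue", "group")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples FPKM values with per-sample (tissue, group) labels.

    ``values`` is a float DataFrame indexed by gene id with sample ids as
    columns; ``metadata`` is indexed by sample id with columns ``tissue``
    and ``group``.  Construction validates the invariants: non-negative
    finite values, no duplicate identifiers, and a one-to-one match
    between matrix columns and metadata rows.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values
        meta = self.metadata
        if vals.index.has_duplicates:
            dup = vals.index[vals.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if vals.columns.has_duplicates:
            dup = vals.columns[vals.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        arr = vals.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise FormatError("expression values must be finite")
        if arr.size and (arr < 0).any():
            gi, si = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative FPKM at gene {vals.index[gi]!r}, sample {vals.columns[si]!r}"
            )
        if meta.index.has_duplicates:
            dup = meta.index[meta.index.duplicated()][0]
            raise ConsistencyError(f"duplicate metadata record for sample {dup!r}")
        matrix_samples = set(vals.columns)
        meta_samples = set(meta.index)
        if matrix_samples != meta_samples:
            missing = sorted(matrix_samples - meta_samples)
            extra = sorted(meta_samples - matrix_samples)
            parts = []
            if missing:
                parts.append(f"samples without metadata: {missing}")
            if extra:
                parts.append(f"metadata for unknown samples: {extra}")
            raise ConsistencyError("; ".join(parts))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def tissues(self) -> list[str]:
        return sorted(self.metadata["tissue"].unique())

    @property
    def groups(self) -> list[str]:
        return sorted(self.metadata["group"].unique())

    def samples_for(self, tissue: str, group: str) -> list[str]:
        """Sample ids belonging to one tissue x group condition, in column order."""
        meta = self.metadata
        keep = set(meta.index[(meta["tissue"] == tissue) & (meta["group"] == group)])
        return [s for s in self.values.columns if s in keep]

    def condition_means(
        self, conditions: Sequence[tuple[str, str]]
    ) -> pd.DataFrame:
        """Mean FPKM per gene for each (tissue, group) condition.

        Columns are labelled ``"{tissue} {group}"`` in the order given.
        """
        from .exceptions import ConfigurationError

        cols = {}
        for tissue, group in conditions:
            samples = self.samples_for(tissue, group)
            if not samples:
                raise ConfigurationError(
                    f"no samples for condition ({tissue!r}, {group!r})"
                )
            cols[f"{tissue} {group}"] = self.values[samples].mean(axis=1)
        return pd.DataFrame(cols, index=self.values.index)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets, e.g. pathways or planted co-expression modules."""

    sets: Mapping[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ConsistencyError(f"key {name!r} does not match set name {gs.name!r}")
            if not gs.members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)


def read_expression_matrix(matrix_path, metadata_path) -> ExpressionMatrix:
    """Read an FPKM matrix and its sample metadata from TSV files.

    The matrix file has a header row of sample ids and a first column of
    gene ids; the metadata file has columns ``sample_id``, ``tissue``,
    ``group``.  Parsing is locale-independent (decimal point only);
    non-numeric or negative cells raise :class:`FormatError` with the
    offending coordinates, and any mismatch between matrix columns and
    metadata rows raises :class:`ConsistencyError`.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bool(bad.to_numpy().any()):
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric value {raw.iat[gi, si]!r} at gene {raw.index[gi]!r}, "
            f"sample {raw.columns[si]!r} in {matrix_path}"
        )
    if bool(numeric.isna().to_numpy().any()):
        gi, si = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"missing value at gene {raw.index[gi]!r}, sample {raw.columns[si]!r}"
        )
    numeric = numeric.astype(float)
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise FormatError(f"metadata missing columns {missing_cols} in {metadata_path}")
    meta = meta.set_index("sample_id")[["tissue", "group"]]
    return ExpressionMatrix(values=numeric, metadata=meta)


def write_expression_matrix(matrix: ExpressionMatrix, matrix_path, metadata_path) -> None:
    """Inverse of :func:`read_expression_matrix` (values to 8 significant digits)."""
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t", float_format="%.8g")
    meta = matrix.metadata.reset_index()
    meta.columns = list(METADATA_COLUMNS)
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_gene_sets(gmt_path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Duplicate members within one line are dropped; member order carries no
    meaning.  Lines with fewer than three fields or a repeated set name
    raise :class:`FormatError` naming the line.
    """
    sets: dict[str, GeneSet] = {}
    with open(gmt_path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{gmt_path}:{lineno}: expected name, description and >=1 member, "
                    f"got {len(fields)} field(s)"
                )
            name, description = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"{gmt_path}:{lineno}: set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{gmt_path}:{lineno}: duplicate set name {name!r}")
            sets[name] = GeneSet(name=name, description=description, members=members)
    return GeneSetCollection(sets=sets)


def write_gene_sets(collection: GeneSetCollection, gmt_path) -> None:
    """Write a collection as GMT; members are sorted for a stable byte stream."""
    with open(gmt_path, "wt", encoding="utf-8") as fh:
        for name in collection.names:
            gs = collection[name]
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def write_table(records: pd.DataFrame, path) -> None:
    """Write a rectangular result table as TSV with a header row.

    Floats are rendered with 8 significant digits so reading the file back
    reproduces every value to at least 6 significant digits.  Labels (column
    names and string cells) must not contain tabs — the dialect has no
    quoting.
    """
    for col in records.columns:
        if "\t" in str(col):
            raise FormatError(f"column label {col!r} contains a tab")
    for col in records.columns:
        if records[col].dtype == object:
            cells = records[col].astype(str)
            if cells.str.contains("\t").any():
                offender = cells[cells.str.contains("\t")].iloc[0]
                raise FormatError(f"value {offender!r} in column {col!r} contains a tab")
    records.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_table(path) -> pd.DataFrame:
    """Read back a table produced by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
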
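"""TSV readers and writers for associations, ontology edges, and matrices.

Formats
-------
associations : two tab-separated columns ``disease_id<TAB>mirna_id``;
    lines starting with ``#`` are ignored; an optional header line is
    detected and skipped.
ontology : two tab-separated columns ``child_term<TAB>parent_term``.
matrix : header row ``id<TAB>col1<TAB>...`` followed by one row per
    row id; ``.`` decimal separator.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import AssociationDataset, LabeledMatrix, OntologyForest

__all__ = [
    "read_associations",
    "read_ontology",
    "read_matrix",
    "write_associations",
    "write_ontology",
    "write_matrix",
]

logger = logging.getLogger(__name__)


def _read_pair_rows(path: str | Path, kind: str) -> list[tuple[str, str]]:
    """Parse a two-column TSV, skipping comments and an optional header."""
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated "
                    f"fields, got {len(fields)}"
                )
            rows.append((fields[0].strip(), fields[1].strip()))
    if rows and rows[0] in _HEADER_ALIASES.get(kind, set()):
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: no {kind} rows found")
    return rows


_HEADER_ALIASES = {
    "association": {
        ("disease_id", "mirna_id"),
        ("disease", "mirna"),
        ("disease", "miRNA"),
    },
    "ontology": {("child_term", "parent_term"), ("child", "parent")},
}


def read_associations(path: str | Path) -> AssociationDataset:
    """Read a disease-miRNA association edge list.

    Duplicate pairs are collapsed to a single entry with a logged
    warning; identifiers are sorted lexicographically so the matrix is
    independent of input row order.
    """
    rows = _read_pair_rows(path, "association")
    if len(set(rows)) < len(rows):
        logger.warning(
            "%s: %d duplicate association rows collapsed",
            path,
            len(rows) - len(set(rows)),
        )
    return AssociationDataset.from_pairs(rows)


def read_ontology(
    path: str | Path,
    disease_to_term: Mapping[str, str] | None = None,
    mapping_path: str | Path | None = None,
) -> OntologyForest:
    """Read a child->parent term edge list into an ontology forest.

    By default a disease id is taken to be its own ontology term; an
    explicit mapping (in memory or as a two-column TSV
    ``disease_id<TAB>term_id``) overrides that convention.  Cyclic edge
    sets are rejected.
    """
    rows = _read_pair_rows(path, "ontology")
    terms = frozenset(t for pair in rows for t in pair)
    mapping: dict[str, str] = dict(disease_to_term or {})
    if mapping_path is not None:
        for d, t in _read_pair_rows(mapping_path, "ontology"):
            mapping[d] = t
    return OntologyForest(
        terms=terms, parent_edges=frozenset(rows), disease_to_term=mapping
    )


def read_matrix(path: str | Path, symmetric: bool = False) -> LabeledMatrix:
    """Read a labelled numeric matrix.

    With ``symmetric=True`` the file must be square with matching row
    and column ids and symmetric values (checked to 1e-8).
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty matrix file") from None
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        bad = df.map(lambda x: isinstance(x, str))
        coords = list(zip(*np.nonzero(bad.to_numpy())))
        if coords:
            i, j = coords[0]
            raise ValueError(
                f"{path}: non-numeric cell at row {df.index[i]!r}, "
                f"column {df.columns[j]!r}"
            ) from exc
        raise
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path}: missing/ragged cell at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    m = LabeledMatrix(
        tuple(str(r) for r in df.index),
        tuple(str(c) for c in df.columns),
        values,
    )
    if symmetric:
        if not m.is_square:
            raise ValueError(f"{path}: symmetric matrix requires matching ids")
        if not np.allclose(m.values, m.values.T, atol=1e-8):
            raise ValueError(f"{path}: matrix declared symmetric is not")
    return m


def write_matrix(m: LabeledMatrix, path: str | Path) -> None:
    """Write a labelled matrix; round-trips to 12 significant digits."""
    df = pd.DataFrame(m.values, index=list(m.row_ids), columns=list(m.col_ids))
    df.to_csv(path, sep="\t", index_label="id", float_format="%.12g")


def write_associations(dataset: AssociationDataset, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease_id\tmirna_id\n")
        for i, j in zip(*np.nonzero(dataset.A)):
            fh.write(f"{dataset.disease_ids[i]}\t{dataset.mirna_ids[j]}\n")


def write_ontology(forest: OntologyForest, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("child_term\tparent_term\n")
        for c, p in sorted(forest.parent_edges):
            fh.write(f"{c}\t{p}\n")
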
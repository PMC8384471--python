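"""Core containers shared across the package.

All matrices are dense numpy arrays.  Diseases index rows of the
association matrix ``A`` and miRNAs index its columns; identifier lists
are kept in lexicographic order so every derived quantity is independent
of input row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "AssociationDataset",
    "OntologyForest",
    "DiseaseDAG",
    "LabeledMatrix",
]


@dataclass(frozen=True)
class AssociationDataset:
    """Binary disease-miRNA association matrix with labelled axes.

    Parameters
    ----------
    disease_ids : tuple of str
        Unique disease identifiers; row labels of ``A``.
    mirna_ids : tuple of str
        Unique miRNA identifiers; column labels of ``A``.
    A : ndarray of shape (n_diseases, n_mirnas)
        ``A[i, j] == 1`` iff miRNA ``j`` is known to be associated with
        disease ``i``, else 0.
    """

    disease_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]
    A: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=np.float64)
        object.__setattr__(self, "A", A)
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease identifiers")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA identifiers")
        if A.shape != (len(self.disease_ids), len(self.mirna_ids)):
            raise ValueError(
                f"matrix shape {A.shape} does not match id lists "
                f"({len(self.disease_ids)}, {len(self.mirna_ids)})"
            )
        if not np.isin(A, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        A.setflags(write=False)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @cached_property
    def _disease_index(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.disease_ids)}

    @cached_property
    def _mirna_index(self) -> dict[str, int]:
        return {m: j for j, m in enumerate(self.mirna_ids)}

    def disease_index(self, disease: str) -> int:
        try:
            return self._disease_index[disease]
        except KeyError:
            raise KeyError(f"unknown disease id: {disease!r}") from None

    def mirna_index(self, mirna: str) -> int:
        try:
            return self._mirna_index[mirna]
        except KeyError:
            raise KeyError(f"unknown miRNA id: {mirna!r}") from None

    def known_mirnas(self, disease: str) -> tuple[str, ...]:
        """miRNA ids with a known association to ``disease``."""
        row = self.A[self.disease_index(disease)]
        return tuple(self.mirna_ids[j] for j in np.flatnonzero(row))

    def mask_pair(self, disease: str, mirna: str) -> "AssociationDataset":
        """Return a copy with one known association set to 0."""
        i, j = self.disease_index(disease), self.mirna_index(mirna)
        if self.A[i, j] != 1:
            raise ValueError(f"({disease}, {mirna}) is not a known association")
        A = self.A.copy()
        A[i, j] = 0.0
        return AssociationDataset(self.disease_ids, self.mirna_ids, A)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]]
    ) -> "AssociationDataset":
        """Build a dataset from (disease, miRNA) pairs.

        Identifiers are sorted lexicographically so the result does not
        depend on the order of the input pairs; duplicate pairs collapse
        to a single entry.
        """
        pair_set = set(pairs)
        if not pair_set:
            raise ValueError("no association pairs supplied")
        diseases = tuple(sorted({d for d, _ in pair_set}))
        mirnas = tuple(sorted({m for _, m in pair_set}))
        d_idx = {d: i for i, d in enumerate(diseases)}
        m_idx = {m: j for j, m in enumerate(mirnas)}
        A = np.zeros((len(diseases), len(mirnas)))
        for d, m in pair_set:
            A[d_idx[d], m_idx[m]] = 1.0
        return cls(diseases, mirnas, A)


@dataclass(frozen=True)
class DiseaseDAG:
    """The ancestor closure of one disease in the ontology.

    ``root`` is the disease's own term; ``terms`` is T(D), the term plus
    all its ancestors; ``edges`` is E(D), the (child, parent) pairs among
    those terms.
    """

    root: str
    terms: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.root not in self.terms:
            raise ValueError("DAG root missing from its own term set")

    def children_of(self, term: str) -> tuple[str, ...]:
        """Terms one step closer to the root (reverse of the parent edges)."""
        return tuple(c for c, p in self.edges if p == term)

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class OntologyForest:
    """Acyclic child->parent term hierarchy plus a disease-to-term map."""

    terms: frozenset[str]
    parent_edges: frozenset[tuple[str, str]]
    disease_to_term: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.parent_edges)
        missing = {t for e in self.parent_edges for t in e} - set(self.terms)
        if missing:
            raise ValueError(f"edge references unknown terms: {sorted(missing)}")
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            pass
        else:
            raise ValueError(f"ontology contains a cycle: {cycle}")
        for disease, term in self.disease_to_term.items():
            if term not in self.terms:
                raise ValueError(
                    f"disease {disease!r} maps to unknown term {term!r}"
                )
        object.__setattr__(self, "_graph", g)

    def term_for(self, disease: str) -> str | None:
        """The ontology term of a disease; identity unless remapped."""
        if disease in self.disease_to_term:
            return self.disease_to_term[disease]
        return disease if disease in self.terms else None

    def dag(self, disease: str) -> DiseaseDAG | None:
        """Ancestor DAG of ``disease``, or None if it has no term."""
        term = self.term_for(disease)
        if term is None:
            return None
        g: nx.DiGraph = self._graph  # type: ignore[attr-defined]
        terms = frozenset(nx.descendants(g, term) | {term})
        edges = frozenset(
            (c, p) for c, p in self.parent_edges if c in terms and p in terms
        )
        return DiseaseDAG(root=term, terms=terms, edges=edges)


@dataclass(frozen=True)
class LabeledMatrix:
    """A real matrix with string row/column labels (TSV carrier type)."""

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"matrix shape {v.shape} does not match id lists "
                f"({len(self.row_ids)}, {len(self.col_ids)})"
            )

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids

    @cached_property
    def _row_index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.row_ids)}

    @cached_property
    def _col_index(self) -> dict[str, int]:
        return {c: j for j, c in enumerate(self.col_ids)}

    def get(self, row: str, col: str) -> float:
        return float(self.values[self._row_index[row], self._col_index[col]])

    def reindex(
        self, row_ids: Iterable[str], col_ids: Iterable[str] | None = None
    ) -> "LabeledMatrix":
        """Reorder/subset to the given labels (labels must exist)."""
        rows = tuple(row_ids)
        cols = tuple(col_ids) if col_ids is not None else rows
        ri = [self._row_index[r] for r in rows]
        ci = [self._col_index[c] for c in cols]
        return LabeledMatrix(rows, cols, self.values[np.ix_(ri, ci)])
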
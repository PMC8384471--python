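"""Disease and miRNA similarity layers.

Two DAG-based semantic similarity models for diseases, the Gaussian
interaction profile (GIP) kernel for both node types, and the rule that
merges them into the integrated similarity matrices ``SD`` and ``SM``.

Semantic model 1 scores a term by how far it sits above the disease of
interest: the disease itself contributes 1 and each ancestor level decays
the contribution by a factor ``delta``, taking the maximum over downward
paths.  Semantic model 2 instead scores a term by its specificity across
the whole disease corpus, ``-log(fraction of disease DAGs containing the
term)``, so ubiquitous terms (e.g. the ontology root) contribute nothing.
Both models turn term contributions into a pairwise similarity by
comparing the mass of shared terms against the total semantic value of
the two diseases.

The GIP kernel compares two binary association profiles with a Gaussian
on their Hamming distance, with the bandwidth normalised by the mean
squared profile norm so that it adapts to the density of the association
matrix.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .datatypes import AssociationDataset, DiseaseDAG, LabeledMatrix, OntologyForest

__all__ = [
    "SemanticParams",
    "GipParams",
    "SimilarityBundle",
    "semantic_contributions_model1",
    "semantic_similarity_model1",
    "semantic_contributions_model2",
    "semantic_similarity_model2",
    "gip_similarity",
    "integrate_disease_similarity",
    "integrate_mirna_similarity",
    "compute_bundle",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SemanticParams:
    """Parameters of the two semantic models.

    delta : per-level decay of the ancestor contribution in model 1,
        in (0, 1).  Default 0.5, the convention of the miRNA
        functional-similarity literature this construction follows.
    log_base : base of the specificity logarithm in model 2; must be
        > 1.  Natural log by default.  One global base is used for the
        whole corpus.
    """

    delta: float = 0.5
    log_base: float = math.e

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError(f"delta must be in (0, 1), got {self.delta}")
        if self.log_base <= 1.0:
            raise ValueError(f"log_base must exceed 1, got {self.log_base}")


@dataclass(frozen=True)
class GipParams:
    """Raw GIP bandwidths before density normalisation (both > 0)."""

    gamma_d_prime: float = 1.0
    gamma_m_prime: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_d_prime <= 0 or self.gamma_m_prime <= 0:
            raise ValueError("GIP bandwidth parameters must be positive")


def semantic_contributions_model1(
    dag: DiseaseDAG, delta: float
) -> dict[str, float]:
    """Model-1 contribution of every term in a disease DAG.

    The disease term contributes 1; every other term contributes
    ``delta`` times the largest contribution among its children in the
    DAG (i.e. the max over downward paths of ``delta**path_length``).
    """
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must be in (0, 1), got {delta}")
    contrib: dict[str, float] = {dag.root: 1.0}
    # A term resolves once all of its in-DAG children have; the DAG is
    # finite and acyclic so either the loop drains or a term is
    # unreachable from the root.
    pending = set(dag.terms) - {dag.root}
    while pending:
        ready = [
            t
            for t in sorted(pending)
            if dag.children_of(t) and all(c in contrib for c in dag.children_of(t))
        ]
        if not ready:
            raise ValueError(
                f"terms unreachable from {dag.root!r} by reverse edges: "
                f"{sorted(pending)}"
            )
        for term in ready:
            contrib[term] = delta * max(
                contrib[c] for c in dag.children_of(term)
            )
            pending.discard(term)
    return contrib


def _dv(contributions: dict[str, float]) -> float:
    return float(sum(contributions.values()))


def semantic_similarity_model1(
    dag_i: DiseaseDAG, dag_j: DiseaseDAG, delta: float
) -> float:
    """Model-1 semantic similarity between two diseases in [0, 1]."""
    ci = semantic_contributions_model1(dag_i, delta)
    cj = semantic_contributions_model1(dag_j, delta)
    shared = dag_i.terms & dag_j.terms
    if not shared:
        return 0.0
    num = sum(ci[t] + cj[t] for t in shared)
    return float(num / (_dv(ci) + _dv(cj)))


def semantic_contributions_model2(
    dags: dict[str, DiseaseDAG], log_base: float = math.e
) -> dict[str, float]:
    """Corpus-level specificity contribution of every ontology term.

    ``contribution(t) = -log_b(n_DAGs_containing_t / n_diseases)``;
    a term present in every DAG contributes exactly 0.
    """
    if not dags:
        raise ValueError("model 2 requires at least one disease DAG")
    n = len(dags)
    counts: dict[str, int] = {}
    for dag in dags.values():
        for t in dag.terms:
            counts[t] = counts.get(t, 0) + 1
    log_b = math.log(log_base)
    return {t: -math.log(c / n) / log_b for t, c in counts.items()}


def semantic_similarity_model2(
    dag_i: DiseaseDAG,
    dag_j: DiseaseDAG,
    contributions: dict[str, float],
) -> float:
    """Model-2 semantic similarity between two diseases in [0, 1]."""
    missing = (dag_i.terms | dag_j.terms) - contributions.keys()
    if missing:
        raise ValueError(
            f"no model-2 contribution for terms: {sorted(missing)}"
        )
    shared = dag_i.terms & dag_j.terms
    if not shared:
        return 0.0
    dv_i = sum(contributions[t] for t in dag_i.terms)
    dv_j = sum(contributions[t] for t in dag_j.terms)
    if dv_i + dv_j == 0.0:
        warnings.warn(
            "both diseases have zero model-2 semantic value "
            "(all their terms are ubiquitous); returning 0",
            stacklevel=2,
        )
        return 0.0
    num = sum(2.0 * contributions[t] for t in shared)
    return float(num / (dv_i + dv_j))


def gip_similarity(profiles: np.ndarray, gamma_prime: float) -> np.ndarray:
    """Gaussian interaction profile kernel over binary profile rows.

    The effective bandwidth is ``gamma_prime`` divided by the mean
    squared norm of the profiles, and the kernel is
    ``exp(-gamma * ||p_u - p_v||^2)``.

    Raises
    ------
    ValueError
        If every profile is all-zero (the bandwidth normalisation would
        divide by zero).
    """
    profiles = np.asarray(profiles, dtype=np.float64)
    mean_sq_norm = float(np.mean(np.sum(profiles**2, axis=1)))
    if mean_sq_norm == 0.0:
        raise ValueError(
            "all interaction profiles are zero; GIP bandwidth undefined"
        )
    gamma = gamma_prime / mean_sq_norm
    if profiles.shape[0] == 1:
        return np.ones((1, 1))
    sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    return np.exp(-gamma * sq_dists)


def integrate_disease_similarity(
    SS1: np.ndarray,
    SS2: np.ndarray,
    KD: np.ndarray,
    has_semantic: np.ndarray,
) -> np.ndarray:
    """Merge the semantic models with the GIP kernel: per pair, the mean
    of the two semantic scores where semantic similarity is defined,
    otherwise the GIP kernel value."""
    for name, m in {"SS1": SS1, "SS2": SS2, "KD": KD}.items():
        if m.shape != KD.shape:
            raise ValueError(f"dimension mismatch: {name} has shape {m.shape}")
    return np.where(has_semantic, (SS1 + SS2) / 2.0, KD)


def integrate_mirna_similarity(
    FS: np.ndarray, KM: np.ndarray, has_functional: np.ndarray
) -> np.ndarray:
    """Functional similarity where supplied, GIP kernel elsewhere."""
    if FS.shape != KM.shape:
        raise ValueError(
            f"dimension mismatch: FS {FS.shape} vs KM {KM.shape}"
        )
    return np.where(has_functional, FS, KM)


@dataclass(frozen=True)
class SimilarityBundle:
    """All similarity layers for one dataset, on its id ordering.

    ``has_semantic`` marks disease pairs where both members have a
    nonempty ontology DAG; ``has_functional`` marks miRNA pairs present
    in the supplied functional-similarity matrix.
    """

    disease_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]
    SS1: np.ndarray
    SS2: np.ndarray
    KD: np.ndarray
    KM: np.ndarray
    FS: np.ndarray
    SD: np.ndarray
    SM: np.ndarray
    has_semantic: np.ndarray = field(repr=False, default=None)  # type: ignore
    has_functional: np.ndarray = field(repr=False, default=None)  # type: ignore

    def as_labeled(self, name: str) -> LabeledMatrix:
        ids = self.disease_ids if name in {"SS1", "SS2", "KD", "SD"} else self.mirna_ids
        return LabeledMatrix(ids, ids, getattr(self, name))


def compute_bundle(
    dataset: AssociationDataset,
    forest: OntologyForest | None = None,
    FS: LabeledMatrix | None = None,
    semantic: SemanticParams | None = None,
    gip: GipParams | None = None,
) -> SimilarityBundle:
    """Compute every similarity layer and the integrated SD and SM.

    Parameters
    ----------
    dataset : AssociationDataset
        The binary association matrix supplying GIP profiles (rows for
        diseases, columns for miRNAs).
    forest : OntologyForest, optional
        Ontology supplying disease DAGs; diseases without a term fall
        back to the GIP kernel in SD.
    FS : LabeledMatrix, optional
        Precomputed miRNA functional similarity.  miRNAs missing from it
        fall back to the GIP kernel in SM.
    """
    semantic = semantic or SemanticParams()
    gip = gip or GipParams()
    nd, nm = dataset.n_diseases, dataset.n_mirnas

    KD = gip_similarity(dataset.A, gip.gamma_d_prime)
    KM = gip_similarity(dataset.A.T, gip.gamma_m_prime)

    dags: dict[str, DiseaseDAG] = {}
    if forest is not None:
        for d in dataset.disease_ids:
            dag = forest.dag(d)
            if dag is not None:
                dags[d] = dag
    SS1 = np.zeros((nd, nd))
    SS2 = np.zeros((nd, nd))
    has_dag = np.array([d in dags for d in dataset.disease_ids])
    has_semantic = has_dag[:, None] & has_dag[None, :]
    if dags:
        contrib1 = {
            d: semantic_contributions_model1(dag, semantic.delta)
            for d, dag in dags.items()
        }
        contrib2 = semantic_contributions_model2(dags, semantic.log_base)
        dv1 = {d: _dv(c) for d, c in contrib1.items()}
        dv2 = {
            d: sum(contrib2[t] for t in dag.terms) for d, dag in dags.items()
        }
        ids = dataset.disease_ids
        for i, di in enumerate(ids):
            if di not in dags:
                continue
            for j in range(i, nd):
                dj = ids[j]
                if dj not in dags:
                    continue
                shared = dags[di].terms & dags[dj].terms
                if shared:
                    n1 = sum(contrib1[di][t] + contrib1[dj][t] for t in shared)
                    SS1[i, j] = SS1[j, i] = n1 / (dv1[di] + dv1[dj])
                    den2 = dv2[di] + dv2[dj]
                    if den2 > 0:
                        n2 = sum(2.0 * contrib2[t] for t in shared)
                        SS2[i, j] = SS2[j, i] = n2 / den2

    FS_mat = np.zeros((nm, nm))
    has_functional = np.zeros((nm, nm), dtype=bool)
    if FS is not None:
        present = [m for m in dataset.mirna_ids if m in set(FS.row_ids)]
        if present:
            sub = FS.reindex(present)
            idx = np.array([dataset.mirna_index(m) for m in present])
            FS_mat[np.ix_(idx, idx)] = sub.values
            has_functional[np.ix_(idx, idx)] = True

    SD = integrate_disease_similarity(SS1, SS2, KD, has_semantic)
    SM = integrate_mirna_similarity(FS_mat, KM, has_functional)
    return SimilarityBundle(
        disease_ids=dataset.disease_ids,
        mirna_ids=dataset.mirna_ids,
        SS1=SS1,
        SS2=SS2,
        KD=KD,
        KM=KM,
        FS=FS_mat,
        SD=SD,
        SM=SM,
        has_semantic=has_semantic,
        has_functional=has_functional,
    )
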
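"""Seeded synthetic benchmark data for the whole pipeline.

The generator plants ``k`` co-clusters of diseases and miRNAs:
associations are Bernoulli(``p_in``) inside a cluster and
Bernoulli(``p_out``) across clusters, each cluster's diseases hang off a
shared ancestor chain in a small ontology forest (so same-cluster
diseases have correlated DAGs), and the miRNA functional-similarity
matrix carries the same block structure plus symmetric truncated-
Gaussian noise.  Everything is reproducible from a single seed.

The default configuration — 40 diseases and 60 miRNAs in 4 clusters,
within/between association probabilities 0.5 / 0.02, functional-
similarity signal 0.8 with noise scale 0.1, ontology chains of depth 3 —
is the planted-signal benchmark the test suite evaluates recovery on.
It targets testability (hand-checkable similarities, strong planted
signal), not the degree distribution of real association databases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AssociationDataset, LabeledMatrix, OntologyForest

__all__ = ["SyntheticConfig", "SyntheticData", "generate", "holdout_split"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults define the planted benchmark."""

    n_d: int = 40
    n_m: int = 60
    k: int = 4
    p_in: float = 0.5
    p_out: float = 0.02
    fs_signal: float = 0.8
    fs_noise: float = 0.1
    dag_depth: int = 3
    seed: int = 0
    ensure_connected: bool = True
    max_retries: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValueError(
                f"need 0 <= p_out <= p_in <= 1, got p_in={self.p_in}, "
                f"p_out={self.p_out}"
            )
        if self.k > min(self.n_d, self.n_m) or self.k < 1:
            raise ValueError("cluster count must be in [1, min(n_d, n_m)]")
        if self.dag_depth < 1:
            raise ValueError("dag_depth must be at least 1")


@dataclass(frozen=True)
class SyntheticData:
    dataset: AssociationDataset
    forest: OntologyForest
    fs: LabeledMatrix
    disease_labels: dict[str, int]
    mirna_labels: dict[str, int]


def _cluster_labels(n: int, k: int) -> np.ndarray:
    """Contiguous, near-equal cluster blocks over n sorted ids."""
    return (np.arange(n) * k) // n


def generate(config: SyntheticConfig) -> SyntheticData:
    """Draw one synthetic dataset (associations, ontology, FS).

    With ``ensure_connected`` the association matrix is redrawn (up to
    ``max_retries`` times) until every disease has at least one
    association, since diseases with empty profiles can neither seed a
    walk nor contribute a GIP profile.
    """
    rng = np.random.default_rng(config.seed)
    disease_ids = tuple(f"d{i:03d}" for i in range(config.n_d))
    mirna_ids = tuple(f"m{j:03d}" for j in range(config.n_m))
    d_labels = _cluster_labels(config.n_d, config.k)
    m_labels = _cluster_labels(config.n_m, config.k)

    probs = np.where(
        d_labels[:, None] == m_labels[None, :], config.p_in, config.p_out
    )
    for attempt in range(config.max_retries + 1):
        A = (rng.random((config.n_d, config.n_m)) < probs).astype(float)
        if not config.ensure_connected or (A.sum(axis=1) > 0).all():
            break
    else:
        raise RuntimeError(
            f"could not draw an association matrix with no empty disease "
            f"row in {config.max_retries} retries; raise p_in/p_out"
        )
    dataset = AssociationDataset(disease_ids, mirna_ids, A)

    # Ontology: per-cluster ancestor chain c{c}_a1 .. c{c}_a{depth}
    # hanging off a global root; each disease's own term parents the
    # deepest chain node of its cluster.
    edges: set[tuple[str, str]] = set()
    terms: set[str] = {"root"}
    for c in range(config.k):
        chain = [f"c{c}_a{l}" for l in range(1, config.dag_depth + 1)]
        terms.update(chain)
        for child, parent in zip(chain, chain[1:]):
            edges.add((child, parent))
        edges.add((chain[-1], "root"))
    for i, d in enumerate(disease_ids):
        terms.add(d)
        edges.add((d, f"c{d_labels[i]}_a1"))
    forest = OntologyForest(
        terms=frozenset(terms), parent_edges=frozenset(edges)
    )

    base = np.where(
        m_labels[:, None] == m_labels[None, :], config.fs_signal, 0.0
    )
    noise = rng.normal(0.0, config.fs_noise, size=(config.n_m, config.n_m))
    noise = (noise + noise.T) / 2.0
    fs_values = np.clip(base + noise, 0.0, 1.0)
    np.fill_diagonal(fs_values, 1.0)
    fs = LabeledMatrix(mirna_ids, mirna_ids, fs_values)

    return SyntheticData(
        dataset=dataset,
        forest=forest,
        fs=fs,
        disease_labels={d: int(c) for d, c in zip(disease_ids, d_labels)},
        mirna_labels={m: int(c) for m, c in zip(mirna_ids, m_labels)},
    )


def holdout_split(
    dataset: AssociationDataset, fraction: float, seed: int
) -> tuple[AssociationDataset, list[tuple[str, str]]]:
    """Remove a random fraction of the known associations.

    No disease is allowed to lose all of its associations (an orphaned
    disease could not be queried afterwards).  Raises if the requested
    fraction cannot be removed under that constraint.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    ones = np.argwhere(dataset.A == 1)
    target = int(round(fraction * len(ones)))
    order = rng.permutation(len(ones))
    counts = dataset.A.sum(axis=1).astype(int)
    A = dataset.A.copy()
    removed: list[tuple[str, str]] = []
    for idx in order:
        if len(removed) == target:
            break
        i, j = ones[idx]
        if counts[i] >= 2:
            A[i, j] = 0.0
            counts[i] -= 1
            removed.append((dataset.disease_ids[i], dataset.mirna_ids[j]))
    if len(removed) < target:
        raise ValueError(
            f"cannot hold out {target} associations without orphaning a "
            f"disease; only {len(removed)} removable"
        )
    train = AssociationDataset(dataset.disease_ids, dataset.mirna_ids, A)
    return train, removed
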
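"""Heterogeneous network assembly and the degree-biased transition matrix.

The network has two layers — diseases connected by integrated disease
similarity ``Wdd`` and miRNAs connected by integrated miRNA similarity
``Wmm`` — bridged by the binary association block ``Wdm``.  A walker
moves with probabilities proportional to edge weight times a per-target
bias ``f_j`` (here the target's degree), staying in its layer with
probability ``1 - lambda_`` and jumping across with probability
``lambda_`` whenever it has a bridge edge.

Block structure of the row-stochastic transition matrix ``M``::

    M = [[Mdd, Mdm],
         [Mmd, Mmm]]

A disease with no associations keeps all its mass in the disease layer
(its ``Mdm`` row is zero and its ``Mdd`` row is left unscaled), and
symmetrically for miRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AssociationDataset

__all__ = [
    "HeteroNetwork",
    "BiasVectors",
    "TransitionMatrix",
    "build_network",
    "degree_vectors",
    "constant_bias",
    "build_transition",
]


@dataclass(frozen=True)
class HeteroNetwork:
    """2x2 block weight matrix over nd disease + nm miRNA nodes."""

    disease_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]
    Wdd: np.ndarray
    Wmm: np.ndarray
    Wdm: np.ndarray

    def __post_init__(self) -> None:
        nd, nm = len(self.disease_ids), len(self.mirna_ids)
        if self.Wdd.shape != (nd, nd):
            raise ValueError(f"Wdd shape {self.Wdd.shape}, expected ({nd},{nd})")
        if self.Wmm.shape != (nm, nm):
            raise ValueError(f"Wmm shape {self.Wmm.shape}, expected ({nm},{nm})")
        if self.Wdm.shape != (nd, nm):
            raise ValueError(f"Wdm shape {self.Wdm.shape}, expected ({nd},{nm})")
        for name, w in (("Wdd", self.Wdd), ("Wmm", self.Wmm)):
            if not np.allclose(w, w.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if (w < 0).any():
                raise ValueError(f"{name} must be nonnegative")

    @property
    def Wmd(self) -> np.ndarray:
        return self.Wdm.T

    @property
    def n_nodes(self) -> int:
        return len(self.disease_ids) + len(self.mirna_ids)

    @property
    def node_ids(self) -> tuple[str, ...]:
        """Full node labelling, diseases first, prefixed by layer."""
        return tuple(f"d:{d}" for d in self.disease_ids) + tuple(
            f"m:{m}" for m in self.mirna_ids
        )

    @property
    def W(self) -> np.ndarray:
        """The full (nd+nm) x (nd+nm) block weight matrix."""
        top = np.hstack([self.Wdd, self.Wdm])
        bottom = np.hstack([self.Wmd, self.Wmm])
        return np.vstack([top, bottom])


@dataclass(frozen=True)
class BiasVectors:
    """Per-node bias values, one vector per transition context.

    ``disease_layer`` / ``mirna_layer`` bias within-layer moves;
    ``cross_to_mirna`` / ``cross_to_disease`` bias layer jumps.  With
    degree bias these are column sums of the corresponding blocks.
    """

    disease_layer: np.ndarray
    mirna_layer: np.ndarray
    cross_to_mirna: np.ndarray
    cross_to_disease: np.ndarray

    def __post_init__(self) -> None:
        for name in (
            "disease_layer",
            "mirna_layer",
            "cross_to_mirna",
            "cross_to_disease",
        ):
            v = np.asarray(getattr(self, name), dtype=np.float64)
            object.__setattr__(self, name, v)
            if (v < 0).any():
                raise ValueError(f"bias vector {name} has negative entries")


def degree_vectors(net: HeteroNetwork) -> BiasVectors:
    """Degree bias: within-layer degrees are column sums of Wdd/Wmm,
    cross-layer degrees are column/row sums of the association block."""
    return BiasVectors(
        disease_layer=net.Wdd.sum(axis=0),
        mirna_layer=net.Wmm.sum(axis=0),
        cross_to_mirna=net.Wdm.sum(axis=0),
        cross_to_disease=net.Wdm.sum(axis=1),
    )


def constant_bias(net: HeteroNetwork, value: float = 1.0) -> BiasVectors:
    """A flat bias; makes the biased walk coincide with plain RWR."""
    nd, nm = len(net.disease_ids), len(net.mirna_ids)
    return BiasVectors(
        disease_layer=np.full(nd, value),
        mirna_layer=np.full(nm, value),
        cross_to_mirna=np.full(nm, value),
        cross_to_disease=np.full(nd, value),
    )


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic biased transition matrix with its block views."""

    node_ids: tuple[str, ...]
    M: np.ndarray
    n_diseases: int
    lambda_: float

    @property
    def Mdd(self) -> np.ndarray:
        nd = self.n_diseases
        return self.M[:nd, :nd]

    @property
    def Mdm(self) -> np.ndarray:
        nd = self.n_diseases
        return self.M[:nd, nd:]

    @property
    def Mmd(self) -> np.ndarray:
        nd = self.n_diseases
        return self.M[nd:, :nd]

    @property
    def Mmm(self) -> np.ndarray:
        nd = self.n_diseases
        return self.M[nd:, nd:]


def build_network(
    SD: np.ndarray,
    SM: np.ndarray,
    dataset: AssociationDataset,
    zero_diagonal: bool = False,
) -> HeteroNetwork:
    """Assemble the heterogeneous network from similarity layers and
    the association matrix.

    ``zero_diagonal=True`` removes the self-loops that the unit
    similarity diagonals otherwise induce.
    """
    Wdd = np.array(SD, dtype=np.float64)
    Wmm = np.array(SM, dtype=np.float64)
    if zero_diagonal:
        np.fill_diagonal(Wdd, 0.0)
        np.fill_diagonal(Wmm, 0.0)
    return HeteroNetwork(
        disease_ids=dataset.disease_ids,
        mirna_ids=dataset.mirna_ids,
        Wdd=Wdd,
        Wmm=Wmm,
        Wdm=np.array(dataset.A, dtype=np.float64),
    )


def _biased_rows(W: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Row-normalise ``W(i, j) * f_j``; rows with zero mass become zero
    rows here and are validated by the caller."""
    num = W * f[None, :]
    den = num.sum(axis=1)
    out = np.zeros_like(num)
    nonzero = den > 0
    out[nonzero] = num[nonzero] / den[nonzero, None]
    return out


def build_transition(
    net: HeteroNetwork,
    bias: BiasVectors | None = None,
    lambda_: float = 0.5,
) -> TransitionMatrix:
    """Build the degree-biased row-stochastic transition matrix.

    Within-layer rows of nodes that have at least one association are
    scaled by ``1 - lambda_`` with the remaining ``lambda_`` distributed
    across the bridge block; nodes without associations keep all mass
    within their layer.

    Raises
    ------
    ValueError
        If ``lambda_`` is outside [0, 1], or some node has zero biased
        mass in both of its row blocks (it would have nowhere to walk).
    """
    if not 0.0 <= lambda_ <= 1.0:
        raise ValueError(f"lambda_ must be in [0, 1], got {lambda_}")
    if bias is None:
        bias = degree_vectors(net)
    nd, nm = len(net.disease_ids), len(net.mirna_ids)

    d_has_assoc = net.Wdm.sum(axis=1) > 0  # per disease
    m_has_assoc = net.Wdm.sum(axis=0) > 0  # per miRNA

    Mdd = _biased_rows(net.Wdd, bias.disease_layer)
    Mmm = _biased_rows(net.Wmm, bias.mirna_layer)
    Mdm = _biased_rows(net.Wdm, bias.cross_to_mirna)
    Mmd = _biased_rows(net.Wmd, bias.cross_to_disease)

    Mdd = np.where(d_has_assoc[:, None], (1.0 - lambda_) * Mdd, Mdd)
    Mmm = np.where(m_has_assoc[:, None], (1.0 - lambda_) * Mmm, Mmm)
    Mdm = lambda_ * Mdm * d_has_assoc[:, None]
    Mmd = lambda_ * Mmd * m_has_assoc[:, None]

    M = np.vstack(
        [np.hstack([Mdd, Mdm]), np.hstack([Mmd, Mmm])]
    )
    row_sums = M.sum(axis=1)
    dead = np.flatnonzero(np.abs(row_sums) < 1e-12)
    if dead.size:
        raise ValueError(
            f"node {net.node_ids[dead[0]]!r} has zero biased mass in "
            "every outgoing block; cannot build a stochastic row"
        )
    # λ = 1 with an associated node leaves only the cross block, λ = 0
    # only the within block; both already sum to 1.  The general case
    # sums to (1-λ) + λ.  Guard against float drift anyway.
    bad = np.flatnonzero(np.abs(row_sums - 1.0) > 1e-9)
    if bad.size:
        raise ValueError(
            f"row {net.node_ids[bad[0]]!r} sums to {row_sums[bad[0]]!r}"
        )
    return TransitionMatrix(
        node_ids=net.node_ids, M=M, n_diseases=nd, lambda_=lambda_
    )
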
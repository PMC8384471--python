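"""Seed construction, the restart iteration, and candidate ranking.

The walker restarts to a fixed seed distribution ``p0`` with probability
``delta`` at every step and otherwise follows the biased transition
matrix:

    p_{t+1} = (1 - delta) * M^T p_t + delta * p0

``M`` is defined row-wise (row i holds the probabilities of moving from
node i), so propagating forward means multiplying by its transpose; a
``literal_orientation`` switch multiplies by ``M`` itself instead for
comparison with formulations that write the product the other way
around.  Because ``(1 - delta) < 1`` the map is a contraction in L1 and
the iteration converges geometrically to the unique fixed point
``delta * (I - (1 - delta) M^T)^{-1} p0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import AssociationDataset
from .network import TransitionMatrix

__all__ = [
    "WalkParams",
    "Ranking",
    "ConvergenceError",
    "seed_vector",
    "iterate",
    "solve_stationary",
    "rank_candidates",
]


@dataclass(frozen=True)
class WalkParams:
    """Restart-walk hyperparameters.

    delta : restart probability in (0, 1); larger values keep the
        stationary distribution closer to the seeds.
    alpha : weight of the disease-layer seed versus the miRNA-layer
        seeds, in [0, 1].
    tol : L1 convergence tolerance on successive iterates.
    max_iter : iteration cap; exceeded only if tol is set absurdly low.
    literal_orientation : propagate with ``M`` instead of ``M^T``.
    """

    delta: float = 0.7
    alpha: float = 0.5
    tol: float = 1e-6
    max_iter: int = 1000
    literal_orientation: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError(f"delta must be in (0, 1), got {self.delta}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


class ConvergenceError(RuntimeError):
    """Raised when the iteration hits max_iter; carries the last state."""

    def __init__(self, message: str, last_p: np.ndarray, residual: float):
        super().__init__(message)
        self.last_p = last_p
        self.residual = residual


def seed_vector(
    dataset: AssociationDataset, disease: str, alpha: float = 0.5
) -> np.ndarray:
    """Initial probability vector for a query disease.

    The disease block is an indicator of the query weighted ``alpha``;
    the miRNA block spreads ``1 - alpha`` uniformly over the disease's
    known miRNAs.  A disease with no known miRNAs cannot seed the miRNA
    layer — candidate prediction for such "new" diseases is undefined
    in this model.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    i = dataset.disease_index(disease)
    known = np.flatnonzero(dataset.A[i])
    if known.size == 0:
        raise ValueError(
            f"disease {disease!r} has no known associated miRNAs "
            "(new disease); cannot construct a seed vector"
        )
    u0 = np.zeros(dataset.n_diseases)
    u0[i] = 1.0
    v0 = np.zeros(dataset.n_mirnas)
    v0[known] = 1.0 / known.size
    return np.concatenate([alpha * u0, (1.0 - alpha) * v0])


def _propagator(M: TransitionMatrix, params: WalkParams) -> np.ndarray:
    return M.M if params.literal_orientation else M.M.T


def iterate(
    M: TransitionMatrix, p0: np.ndarray, params: WalkParams | None = None
) -> tuple[np.ndarray, int]:
    """Run the restart iteration to convergence.

    Returns the converged probability vector (the walk's ``p_inf``) and
    the number of iterations performed.
    """
    params = params or WalkParams()
    T = _propagator(M, params)
    p = np.asarray(p0, dtype=np.float64)
    for t in range(1, params.max_iter + 1):
        p_next = (1.0 - params.delta) * (T @ p) + params.delta * p0
        residual = float(np.abs(p_next - p).sum())
        if residual < params.tol:
            return p_next, t
        p = p_next
    raise ConvergenceError(
        f"restart iteration did not converge within {params.max_iter} "
        f"iterations (last L1 residual {residual:.3e})",
        last_p=p,
        residual=residual,
    )


def solve_stationary(
    M: TransitionMatrix, p0: np.ndarray, delta: float,
    literal_orientation: bool = False,
) -> np.ndarray:
    """Closed-form fixed point ``delta (I - (1-delta) M^T)^{-1} p0``.

    The system is always nonsingular: ``(1-delta) M^T`` has spectral
    radius below 1 for a stochastic ``M`` and ``delta`` in (0, 1).
    """
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must be in (0, 1), got {delta}")
    T = M.M if literal_orientation else M.M.T
    n = T.shape[0]
    system = np.eye(n) - (1.0 - delta) * T
    return delta * np.linalg.solve(system, np.asarray(p0, dtype=np.float64))


@dataclass(frozen=True)
class Ranking:
    """Ordered candidate miRNAs for one query disease.

    ``entries`` is a list of (miRNA id, stationary score, rank) with
    rank 1 the highest score; equal scores are ordered by miRNA id.
    miRNAs already known for the disease are listed in ``excluded``.
    """

    disease: str
    entries: tuple[tuple[str, float, int], ...]
    excluded: tuple[str, ...] = field(default_factory=tuple)

    @property
    def mirna_ids(self) -> tuple[str, ...]:
        return tuple(m for m, _, _ in self.entries)

    def top(self, k: int) -> tuple[tuple[str, float, int], ...]:
        return self.entries[:k]


def rank_candidates(
    p_inf: np.ndarray, dataset: AssociationDataset, disease: str
) -> Ranking:
    """Extract miRNA-block scores and rank the candidate miRNAs.

    miRNAs with a known association to the query disease are excluded;
    the rest are sorted by descending score with ties broken by id.
    """
    nd = dataset.n_diseases
    scores = np.asarray(p_inf)[nd:]
    if scores.shape[0] != dataset.n_mirnas:
        raise ValueError("probability vector length does not match dataset")
    i = dataset.disease_index(disease)
    known = set(np.flatnonzero(dataset.A[i]))
    candidates = [
        (dataset.mirna_ids[j], float(scores[j]))
        for j in range(dataset.n_mirnas)
        if j not in known
    ]
    candidates.sort(key=lambda item: (-item[1], item[0]))
    entries = tuple(
        (m, s, rank) for rank, (m, s) in enumerate(candidates, start=1)
    )
    excluded = tuple(dataset.mirna_ids[j] for j in sorted(known))
    return Ranking(disease=disease, entries=entries, excluded=excluded)
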
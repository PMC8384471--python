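"""Local leave-one-out cross-validation with rank-based ROC and AUC.

Each known association is removed in turn, the walk is re-run for its
disease, and the held-out miRNA is ranked among all miRNAs unobserved
for that disease (including itself).  A fold's quality is summarised by
the held-out item's average rank ``r`` among ``N`` candidates; the
per-fold AUC ``(N - r) / (N - 1)`` is the probability that the held-out
positive outscores a random negative candidate (ties counted one half),
and the reported AUC is its mean over folds — the per-fold-uniform
Mann-Whitney pooling.  Fold candidate sets have different sizes, so the
pooled ROC sweeps a normalised rank-percentile threshold rather than a
raw rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .datatypes import AssociationDataset, LabeledMatrix, OntologyForest
from .network import BiasVectors, build_network, build_transition, degree_vectors
from .pipeline import ModelConfig, fit_model
from .walk import iterate, seed_vector

__all__ = [
    "Fold",
    "LoocvResult",
    "run_local_loocv",
    "evaluate_holdout",
    "pooled_roc",
    "auc",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Fold:
    """One held-out association and where its miRNA ranked.

    rank : average rank (midrank for ties) of the held-out miRNA among
        ``n_candidates`` scored items, 1 = best.
    """

    disease: str
    mirna: str
    rank: float
    n_candidates: int

    def __post_init__(self) -> None:
        if self.n_candidates < 2:
            raise ValueError("a fold needs at least 2 candidates")
        if not 1.0 <= self.rank <= self.n_candidates:
            raise ValueError(
                f"rank {self.rank} outside [1, {self.n_candidates}]"
            )

    @property
    def fold_auc(self) -> float:
        return (self.n_candidates - self.rank) / (self.n_candidates - 1)


@dataclass(frozen=True)
class LoocvResult:
    folds: tuple[Fold, ...]
    roc: np.ndarray  # (k, 2) columns (FPR, TPR)
    auc: float
    skipped_diseases: tuple[str, ...] = ()


def auc(folds: list[Fold] | tuple[Fold, ...]) -> float:
    """Mean per-fold Mann-Whitney AUC, ``mean((N - r) / (N - 1))``."""
    if not folds:
        raise ValueError("AUC of zero folds is undefined")
    return float(np.mean([f.fold_auc for f in folds]))


def pooled_roc(
    folds: list[Fold] | tuple[Fold, ...], grid: int = 200
) -> np.ndarray:
    """Pooled ROC over folds of unequal candidate counts.

    The threshold sweeps the normalised rank percentile t in [0, 1]:
    a fold is a true positive at t once ``(r - 1)/(N - 1) <= t``, and
    its contribution to the false positive rate is the fraction of its
    negatives at or above the same percentile cut.  Each fold carries
    equal weight.  Endpoints (0,0) and (1,1) are included.
    """
    if not folds:
        raise ValueError("ROC of zero folds is undefined")
    percentiles = np.array([(f.rank - 1) / (f.n_candidates - 1) for f in folds])
    ns = np.array([f.n_candidates for f in folds])
    ts = np.unique(
        np.concatenate([[0.0, 1.0], np.linspace(0, 1, grid), percentiles])
    )
    tpr = np.empty_like(ts)
    fpr = np.empty_like(ts)
    for k, t in enumerate(ts):
        tpr[k] = float(np.mean(percentiles <= t + 1e-12))
        # positions with percentile <= t per fold, minus the positive
        # when it falls inside the cut
        cut = np.floor(t * (ns - 1) + 1e-9) + 1
        neg_in = cut - (percentiles <= t + 1e-12)
        fpr[k] = float(np.mean(neg_in / (ns - 1)))
    points = np.column_stack([fpr, tpr])
    points = points[np.lexsort((points[:, 1], points[:, 0]))]
    if not np.allclose(points[0], [0.0, 0.0]):
        points = np.vstack([[0.0, 0.0], points])
    if not np.allclose(points[-1], [1.0, 1.0]):
        points = np.vstack([points, [1.0, 1.0]])
    return points


def _rank_of(scores: np.ndarray, index: int) -> float:
    """Average rank (1 = best) of one entry within a score vector."""
    return float(rankdata(-scores, method="average")[index])


def run_local_loocv(
    dataset: AssociationDataset,
    forest: OntologyForest | None = None,
    FS: LabeledMatrix | None = None,
    config: ModelConfig | None = None,
    recompute_gip: bool = True,
    bias: BiasVectors | None = None,
) -> LoocvResult:
    """Leave each known association out in turn and rank it back.

    Diseases with a single known miRNA are skipped (removing their only
    association would leave no seed) and reported in
    ``skipped_diseases``.  With ``recompute_gip=True`` (default) the
    GIP kernels — and hence SD/SM — are recomputed from the masked
    association matrix for every fold, honouring the data dependency;
    ``recompute_gip=False`` freezes the similarity layers computed on
    the full matrix and only the association block changes per fold.
    """
    config = config or ModelConfig()
    frozen = None
    if not recompute_gip:
        frozen = fit_model(dataset, forest, FS, config, bias=bias).bundle

    folds: list[Fold] = []
    skipped: list[str] = []
    for disease in dataset.disease_ids:
        known = dataset.known_mirnas(disease)
        if len(known) == 0:
            continue
        if len(known) == 1:
            skipped.append(disease)
            logger.info(
                "skipping disease %r: a single known miRNA leaves no "
                "seed after masking",
                disease,
            )
            continue
        for mirna in known:
            masked = dataset.mask_pair(disease, mirna)
            if frozen is None:
                transition = fit_model(
                    masked, forest, FS, config, bias=bias
                ).transition
            else:
                net = build_network(
                    frozen.SD, frozen.SM, masked,
                    zero_diagonal=config.zero_diagonal,
                )
                b = bias if bias is not None else degree_vectors(net)
                transition = build_transition(net, bias=b, lambda_=config.lambda_)
            p0 = seed_vector(masked, disease, config.walk.alpha)
            p_inf, _ = iterate(transition, p0, config.walk)
            folds.append(
                _fold_from_scores(p_inf, masked, disease, mirna)
            )
    if not folds:
        raise ValueError(
            "no eligible folds: every disease has fewer than 2 known miRNAs"
        )
    folds_t = tuple(folds)
    return LoocvResult(
        folds=folds_t,
        roc=pooled_roc(folds_t),
        auc=auc(folds_t),
        skipped_diseases=tuple(skipped),
    )


def _fold_from_scores(
    p_inf: np.ndarray,
    masked: AssociationDataset,
    disease: str,
    held_out: str,
) -> Fold:
    """Rank the held-out miRNA among the disease's unobserved miRNAs."""
    nd = masked.n_diseases
    scores = np.asarray(p_inf)[nd:]
    i = masked.disease_index(disease)
    candidate_idx = np.flatnonzero(masked.A[i] == 0)
    held_j = masked.mirna_index(held_out)
    pos = int(np.flatnonzero(candidate_idx == held_j)[0])
    cand_scores = scores[candidate_idx]
    return Fold(
        disease=disease,
        mirna=held_out,
        rank=_rank_of(cand_scores, pos),
        n_candidates=len(candidate_idx),
    )


def evaluate_holdout(
    train: AssociationDataset,
    held_out: list[tuple[str, str]],
    forest: OntologyForest | None = None,
    FS: LabeledMatrix | None = None,
    config: ModelConfig | None = None,
    bias: BiasVectors | None = None,
) -> LoocvResult:
    """Rank a batch of held-out pairs against a fixed training matrix.

    All held-out pairs were removed from ``train`` beforehand (see
    ``synthetic.holdout_split``), so one fitted model and one walk per
    query disease suffice.
    """
    config = config or ModelConfig()
    model = fit_model(train, forest, FS, config, bias=bias)
    by_disease: dict[str, list[str]] = {}
    for d, m in held_out:
        by_disease.setdefault(d, []).append(m)

    folds: list[Fold] = []
    skipped: list[str] = []
    for disease, mirnas in by_disease.items():
        if len(train.known_mirnas(disease)) == 0:
            skipped.append(disease)
            continue
        p0 = seed_vector(train, disease, config.walk.alpha)
        p_inf, _ = iterate(model.transition, p0, config.walk)
        for mirna in mirnas:
            folds.append(_fold_from_scores(p_inf, train, disease, mirna))
    if not folds:
        raise ValueError("no held-out pair could be evaluated")
    folds_t = tuple(folds)
    return LoocvResult(
        folds=folds_t,
        roc=pooled_roc(folds_t),
        auc=auc(folds_t),
        skipped_diseases=tuple(skipped),
    )
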
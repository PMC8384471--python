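"""End-to-end convenience layer: data -> similarities -> network -> walk."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AssociationDataset, LabeledMatrix, OntologyForest
from .network import (
    BiasVectors,
    HeteroNetwork,
    TransitionMatrix,
    build_network,
    build_transition,
    degree_vectors,
)
from .similarity import GipParams, SemanticParams, SimilarityBundle, compute_bundle
from .walk import Ranking, WalkParams, iterate, rank_candidates, seed_vector

__all__ = ["ModelConfig", "FittedModel", "fit_model", "predict_disease"]


@dataclass(frozen=True)
class ModelConfig:
    """All tunable parameters of the full prediction pipeline."""

    semantic: SemanticParams = SemanticParams()
    gip: GipParams = GipParams()
    walk: WalkParams = WalkParams()
    lambda_: float = 0.5
    zero_diagonal: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_ <= 1.0:
            raise ValueError(f"lambda_ must be in [0, 1], got {self.lambda_}")


@dataclass(frozen=True)
class FittedModel:
    """Similarities, network, and transition matrix for one dataset."""

    dataset: AssociationDataset
    bundle: SimilarityBundle
    network: HeteroNetwork
    transition: TransitionMatrix
    config: ModelConfig


def fit_model(
    dataset: AssociationDataset,
    forest: OntologyForest | None = None,
    FS: LabeledMatrix | None = None,
    config: ModelConfig | None = None,
    bias: BiasVectors | None = None,
) -> FittedModel:
    """Compute similarities, assemble the network, build the transition
    matrix.  ``bias=None`` uses degree bias."""
    config = config or ModelConfig()
    bundle = compute_bundle(
        dataset, forest=forest, FS=FS, semantic=config.semantic, gip=config.gip
    )
    net = build_network(
        bundle.SD, bundle.SM, dataset, zero_diagonal=config.zero_diagonal
    )
    if bias is None:
        bias = degree_vectors(net)
    M = build_transition(net, bias=bias, lambda_=config.lambda_)
    return FittedModel(
        dataset=dataset, bundle=bundle, network=net, transition=M, config=config
    )


def predict_disease(model: FittedModel, disease: str) -> Ranking:
    """Rank candidate miRNAs for one query disease on a fitted model."""
    p0 = seed_vector(model.dataset, disease, model.config.walk.alpha)
    p_inf, _ = iterate(model.transition, p0, model.config.walk)
    return rank_candidates(p_inf, model.dataset, disease)


def stationary_scores(model: FittedModel, disease: str) -> np.ndarray:
    """Raw stationary probabilities (disease block then miRNA block)."""
    p0 = seed_vector(model.dataset, disease, model.config.walk.alpha)
    p_inf, _ = iterate(model.transition, p0, model.config.walk)
    return p_inf
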
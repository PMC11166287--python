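"""End-to-end inference: time series + reference networks -> Boolean network.

Orchestrates the full method: regulator ranking from the continuous data,
multi-objective search over candidate influence graphs guided by the
ranking and by topological expectations from the references, binarization,
rule inference on the first Pareto front and final-network selection by
dynamic accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boolean import (
    BinarizedSeries,
    BooleanNetwork,
    binarize,
    select_final,
)
from .evolve import EvolutionResult, GAConfig, evolve
from .netcore import DirectedNetwork
from .objectives import (
    ObjectiveWeights,
    RankMatrix,
    extract_reference_features,
)
from .ranking import TimeSeriesSet, rank_regulations

__all__ = ["InferenceResult", "infer"]


@dataclass
class InferenceResult:
    """Everything a run produces.

    ``network`` is the selected Boolean network (its ``influence`` attribute
    is the inferred influence graph); ``first_front`` the Pareto-optimal
    candidate influence graphs; ``selection`` the bookkeeping of the final
    choice (per-candidate dynamic accuracies, donor index, ...); ``trace``
    the per-generation objective log.
    """

    network: BooleanNetwork
    binarized: BinarizedSeries
    ranks: RankMatrix
    evolution: EvolutionResult
    selection: dict = field(default_factory=dict)

    @property
    def influence(self) -> DirectedNetwork:
        return self.network.influence

    @property
    def first_front(self) -> list[DirectedNetwork]:
        return [ind.net for ind in self.evolution.first_front]

    @property
    def trace(self) -> list[dict]:
        return self.evolution.trace


def infer(
    ts: TimeSeriesSet,
    references: list[DirectedNetwork],
    config: GAConfig | None = None,
    weights: ObjectiveWeights | None = None,
    ranks: RankMatrix | None = None,
    ranking_trees: int = 100,
    ranking_decay: float = 0.02,
) -> InferenceResult:
    """Run the whole pipeline and return the selected Boolean network.

    ``ranks`` may be supplied to skip the built-in random-forest ranking
    (e.g. when an external base method produced the weights).  All
    randomness derives from ``config.seed``.
    """
    cfg = config or GAConfig()
    if ranks is None:
        ranks = rank_regulations(
            ts, trees=ranking_trees, decay=ranking_decay, seed=cfg.seed
        )
    ref_features = extract_reference_features(references)
    evolution = evolve(
        ranks,
        ref_features,
        cfg,
        weights=weights,
        refs_exact=references if cfg.init_mode == "reference_exact" else None,
        gene_names=list(ts.gene_names),
    )
    binarized = binarize(ts)
    front = evolution.first_front
    candidates = [ind.net for ind in front]
    objectives = [ind.objectives for ind in front]
    network, selection = select_final(candidates, objectives, binarized)
    return InferenceResult(
        network=network,
        binarized=binarized,
        ranks=ranks,
        evolution=evolution,
        selection=selection,
    )
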
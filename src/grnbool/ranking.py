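"""Regulator ranking from continuous time series.

Candidate regulations are scored in the spirit of tree-ensemble network
inference on time series: for each target gene an ensemble regressor is fit
to predict the finite-difference derivative of the target (plus a linear
decay term) from the expression of all other genes at the previous time
point.  Feature importances become regulatory weights, and weights are
reduced to a dense total order of ordered gene pairs — the only thing the
downstream objective consumes, since raw importances carry no statistical
meaning.

The interface is pluggable: an externally computed weight matrix (e.g. from
the original dynGENIE3 implementation) can be converted with
``weights_to_ranks`` and used in place of the built-in ranker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .objectives import RankMatrix

__all__ = ["TimeSeriesSet", "rank_regulations", "weights_to_ranks"]

DEFAULT_TREES = 100
DEFAULT_DECAY = 0.02


@dataclass
class TimeSeriesSet:
    """One or more expression time series over a shared gene order.

    ``series[s]`` is a (T_s x n) real matrix; ``times[s]`` the matching
    strictly increasing time vector.  ``gene_names`` applies to all series.
    """

    series: list[np.ndarray]
    times: list[np.ndarray]
    gene_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError("at least one time series is required")
        if len(self.series) != len(self.times):
            raise ValueError("series and times must align")
        self.series = [np.asarray(s, dtype=float) for s in self.series]
        self.times = [np.asarray(t, dtype=float) for t in self.times]
        n = self.series[0].shape[1]
        for s, t in zip(self.series, self.times):
            if s.ndim != 2 or s.shape[1] != n:
                raise ValueError("all series must share the gene count")
            if s.shape[0] != t.shape[0]:
                raise ValueError("time vector length must match series rows")
            if s.shape[0] < 2:
                raise ValueError("each series needs at least two time points")
            if np.any(np.diff(t) <= 0):
                raise ValueError("time vectors must be strictly increasing")
        if not self.gene_names:
            self.gene_names = [f"G{i + 1}" for i in range(n)]
        if len(self.gene_names) != n:
            raise ValueError("gene_names length must match the gene count")

    @property
    def n_genes(self) -> int:
        return self.series[0].shape[1]

    def transitions(self) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """(X_t, X_{t+1}, dt) blocks per series, for one-step learning."""
        out = []
        for s, t in zip(self.series, self.times):
            out.append((s[:-1], s[1:], np.diff(t)))
        return out


def weights_to_ranks(weights: np.ndarray) -> RankMatrix:
    """Convert a regulator-by-target weight matrix to dense ranks.

    Rank 1 goes to the largest weight.  Ties break by (source index, target
    index), which makes the conversion deterministic and invariant under
    positive affine transformations of the weights.  The diagonal is ignored.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if np.isnan(w[~np.eye(w.shape[0], dtype=bool)]).any():
        raise ValueError("weight matrix contains NaN")
    n = w.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    pairs.sort(key=lambda p: (-w[p], p[0], p[1]))
    ranks = np.zeros((n, n), dtype=np.int64)
    for rank, (i, j) in enumerate(pairs, start=1):
        ranks[i, j] = rank
    return RankMatrix(ranks)


def importance_weights(
    ts: TimeSeriesSet,
    trees: int = DEFAULT_TREES,
    decay: float = DEFAULT_DECAY,
    seed: int = 0,
) -> np.ndarray:
    """Raw regulator-by-target importance matrix from the ensemble fits.

    For target j the response is (x_j(t+dt) - x_j(t)) / dt + decay * x_j(t)
    and the predictors are all other genes at time t; (input, response)
    pairs from all series are stacked before fitting.
    """
    n = ts.n_genes
    blocks = ts.transitions()
    x_prev = np.vstack([b[0] for b in blocks])
    x_next = np.vstack([b[1] for b in blocks])
    dt = np.concatenate([b[2] for b in blocks])
    weights = np.zeros((n, n))
    for j in range(n):
        y = (x_next[:, j] - x_prev[:, j]) / dt + decay * x_prev[:, j]
        predictors = [i for i in range(n) if i != j]
        model = RandomForestRegressor(
            n_estimators=trees,
            max_features="sqrt",
            random_state=(seed + j) % 2**31,
            n_jobs=1,
        )
        model.fit(x_prev[:, predictors], y)
        weights[predictors, j] = model.feature_importances_
    return weights


def rank_regulations(
    ts: TimeSeriesSet,
    trees: int = DEFAULT_TREES,
    decay: float = DEFAULT_DECAY,
    seed: int = 0,
) -> RankMatrix:
    """Rank every ordered gene pair as a candidate regulation.

    Deterministic for a fixed seed; returns a dense total order with rank 1
    the strongest candidate regulation.
    """
    return weights_to_ranks(importance_weights(ts, trees=trees, decay=decay, seed=seed))
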
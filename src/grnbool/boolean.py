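"""Boolean-network inference from binarized time series.

The final stage of the pipeline: continuous trajectories are binarized by
per-gene two-means clustering, one-step transitions populate a generalized
truth table for every gene given its regulators in a candidate influence
graph, and each table is compressed to a minimal disjunctive normal form
with the Quine–McCluskey procedure (unobserved input combinations are
don't-cares).  Candidate Boolean networks are compared by their dynamic
accuracy — the fraction of one-step gene-state predictions that match the
data — and the best one is selected, with ties broken by distance to the
ideal point in normalized objective space.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .netcore import DirectedNetwork
from .objectives import ObjectiveVector
from .ranking import TimeSeriesSet

__all__ = [
    "BinarizedSeries",
    "GeneralizedTruthTable",
    "BooleanRule",
    "BooleanNetwork",
    "binarize",
    "build_truth_table",
    "minimize_qm",
    "infer_boolean_network",
    "simulate",
    "dynamic_accuracy",
    "normalize_objectives",
    "select_final",
    "replace_constants",
]

MAX_RULE_REGULATORS = 10


# ---------------------------------------------------------------------------
# binarization


@dataclass
class BinarizedSeries:
    """Per-gene binarized counterpart of a TimeSeriesSet.

    ``series[s]`` is a (T_s x n) 0/1 matrix; ``thresholds[g]`` records the
    cut between the two clusters of gene g for auditing (NaN for constant
    genes, which binarize to all zeros).
    """

    series: list[np.ndarray]
    thresholds: np.ndarray
    gene_names: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return self.series[0].shape[1]


def _two_means_split(values: np.ndarray) -> float:
    """Optimal 1-D two-cluster split, returned as a threshold.

    Exact two-means via the sorted prefix-sum sweep: every contiguous split
    of the sorted values is scored by within-cluster sum of squares and the
    best is kept (deterministic, invariant to increasing affine maps).
    Samples >= threshold belong to the higher-mean cluster.
    """
    x = np.sort(values.astype(float))
    t = x.size
    ps = np.concatenate([[0.0], np.cumsum(x)])
    ps2 = np.concatenate([[0.0], np.cumsum(x * x)])
    best_k, best_sse = 1, np.inf
    for k in range(1, t):
        sse_lo = ps2[k] - ps[k] ** 2 / k
        sse_hi = (ps2[t] - ps2[k]) - (ps[t] - ps[k]) ** 2 / (t - k)
        sse = sse_lo + sse_hi
        if sse < best_sse - 1e-12:
            best_sse, best_k = sse, k
    return (x[best_k - 1] + x[best_k]) / 2.0


def binarize(ts: TimeSeriesSet) -> BinarizedSeries:
    """Binarize every gene by two-means clustering of its pooled values.

    The higher-mean cluster maps to 1.  Constant genes cannot be split and
    binarize to all zeros (a warning is emitted).
    """
    n = ts.n_genes
    pooled = np.vstack(ts.series)
    thresholds = np.full(n, np.nan)
    for g in range(n):
        vals = pooled[:, g]
        if np.ptp(vals) == 0:
            warnings.warn(
                f"gene {ts.gene_names[g]!r} is constant; binarized to all zeros",
                stacklevel=2,
            )
            continue
        thresholds[g] = _two_means_split(vals)
    out = []
    for s in ts.series:
        b = np.zeros_like(s, dtype=np.int8)
        for g in range(n):
            if not np.isnan(thresholds[g]):
                b[:, g] = (s[:, g] >= thresholds[g]).astype(np.int8)
        out.append(b)
    return BinarizedSeries(out, thresholds, list(ts.gene_names))


def apply_thresholds(ts: TimeSeriesSet, thresholds: np.ndarray) -> BinarizedSeries:
    """Binarize new series with previously learned per-gene thresholds.

    Used for held-out evaluation: thresholds come from the training data.
    Genes whose training threshold is NaN (constant in training) binarize to
    all zeros.
    """
    out = []
    for s in ts.series:
        b = np.zeros_like(s, dtype=np.int8)
        for g in range(s.shape[1]):
            if not np.isnan(thresholds[g]):
                b[:, g] = (s[:, g] >= thresholds[g]).astype(np.int8)
        out.append(b)
    return BinarizedSeries(out, thresholds.copy(), list(ts.gene_names))


# ---------------------------------------------------------------------------
# generalized truth tables


@dataclass
class GeneralizedTruthTable:
    """Observed input/output rows of one gene's update function.

    ``rows`` maps the regulator-state word (bit i = state of
    ``regulators[i]``) to the majority output over all observed one-step
    transitions; unobserved words are don't-cares.  ``tallies`` keeps the
    raw (zeros, ones) counts per row for auditing conflicts.
    """

    target: int
    regulators: tuple[int, ...]
    rows: dict[int, int]
    tallies: dict[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_vars(self) -> int:
        return len(self.regulators)


def _pack_states(states: np.ndarray) -> np.ndarray:
    """Binary state rows -> integer words, bit i = column i."""
    if states.shape[1] == 0:
        return np.zeros(states.shape[0], dtype=np.int64)
    return states @ (1 << np.arange(states.shape[1], dtype=np.int64))


def build_truth_table(
    binarized: BinarizedSeries, target: int, regulators: tuple[int, ...] | list[int]
) -> GeneralizedTruthTable:
    """Collect one-step transitions into a generalized truth table.

    Each consecutive pair (t, t+1) within a series contributes one row:
    regulator states at t map to the target state at t+1 (series are never
    chained across their seams).  Conflicting observations resolve by
    majority, ties to 1.
    """
    regulators = tuple(int(r) for r in regulators)
    if len(regulators) > MAX_RULE_REGULATORS:
        raise ValueError(
            f"{len(regulators)} regulators exceed the cap of {MAX_RULE_REGULATORS}"
        )
    tallies: dict[int, list[int]] = {}
    for s in binarized.series:
        if s.shape[0] < 2:
            continue
        words = _pack_states(s[:-1][:, list(regulators)].astype(np.int64))
        outs = s[1:, target]
        for w, o in zip(words.tolist(), outs.tolist()):
            tallies.setdefault(w, [0, 0])[o] += 1
    rows = {
        w: (1 if ones >= zeros else 0) for w, (zeros, ones) in tallies.items()
    }
    return GeneralizedTruthTable(
        target=int(target),
        regulators=regulators,
        rows=rows,
        tallies={w: (z, o) for w, (z, o) in tallies.items()},
    )


# ---------------------------------------------------------------------------
# Quine–McCluskey minimization


@dataclass(frozen=True)
class _Implicant:
    """Product term over r variables: (bits, mask); mask bits are wildcards."""

    bits: int
    mask: int

    def covers(self, minterm: int) -> bool:
        return (minterm & ~self.mask) == self.bits

    def literals(self, n_vars: int) -> list[tuple[int, bool]]:
        """(variable index, positive?) pairs of the non-wildcard positions."""
        out = []
        for i in range(n_vars):
            if not (self.mask >> i) & 1:
                out.append((i, bool((self.bits >> i) & 1)))
        return out


def _prime_implicants(terms: set[int], n_vars: int) -> list[_Implicant]:
    """All prime implicants of the 1/don't-care set via iterative merging."""
    current = {(t, 0) for t in terms}
    primes: set[tuple[int, int]] = set()
    while current:
        merged: set[tuple[int, int]] = set()
        used: set[tuple[int, int]] = set()
        by_mask: dict[int, list[tuple[int, int]]] = {}
        for imp in current:
            by_mask.setdefault(imp[1], []).append(imp)
        for mask, group in by_mask.items():
            group_set = set(g[0] for g in group)
            for bits in group_set:
                for i in range(n_vars):
                    bit = 1 << i
                    if mask & bit:
                        continue
                    partner = bits ^ bit
                    if partner in group_set and not bits & bit:
                        merged.add((bits, mask | bit))
                        used.add((bits, mask))
                        used.add((partner, mask))
        primes |= current - used
        current = merged
    return [_Implicant(b, m) for b, m in sorted(primes)]


def _cover(primes: list[_Implicant], minterms: set[int]) -> list[_Implicant]:
    """Minimum-cardinality cover of the minterms by prime implicants.

    Essential primes first; the residual cover is solved exactly by
    branch-and-bound when small and greedily (most-coverage, deterministic
    tie-break) otherwise.
    """
    remaining = set(minterms)
    chosen: list[_Implicant] = []
    # essential prime implicants
    changed = True
    while changed and remaining:
        changed = False
        for m in sorted(remaining):
            covering = [p for p in primes if p.covers(m)]
            if len(covering) == 1:
                p = covering[0]
                chosen.append(p)
                remaining -= {x for x in remaining if p.covers(x)}
                changed = True
                break
    if not remaining:
        return chosen
    candidates = [p for p in primes if any(p.covers(m) for m in remaining)]
    if len(candidates) <= 16:
        best: list[_Implicant] | None = None
        for size in range(1, len(candidates) + 1):
            for combo in itertools.combinations(candidates, size):
                covered = set()
                for p in combo:
                    covered |= {m for m in remaining if p.covers(m)}
                if covered == remaining:
                    best = list(combo)
                    break
            if best is not None:
                break
        return chosen + (best or [])
    while remaining:
        candidates.sort(
            key=lambda p: (-sum(p.covers(m) for m in remaining), p.bits, p.mask)
        )
        p = candidates[0]
        chosen.append(p)
        remaining -= {m for m in remaining if p.covers(m)}
    return chosen


@dataclass
class BooleanRule:
    """Minimal-DNF update rule of one gene (or a constant).

    ``terms`` is a list of product terms as (bits, mask) words over
    ``regulators``; the rule fires when any term matches.  ``constant`` is
    0/1 for constant rules (then ``terms`` is empty).
    """

    target: int
    regulators: tuple[int, ...]
    terms: list[_Implicant] = field(default_factory=list)
    constant: int | None = None

    @property
    def is_constant(self) -> bool:
        return self.constant is not None

    def evaluate_words(self, words: np.ndarray) -> np.ndarray:
        """Vectorized evaluation on packed regulator-state words."""
        if self.constant is not None:
            return np.full(words.shape, self.constant, dtype=np.int8)
        out = np.zeros(words.shape, dtype=np.int8)
        for imp in self.terms:
            out |= ((words & ~imp.mask) == imp.bits).astype(np.int8)
        return out

    def evaluate(self, state: np.ndarray) -> int:
        """Evaluate on a full network state vector (one time point)."""
        if self.constant is not None:
            return int(self.constant)
        word = 0
        for i, r in enumerate(self.regulators):
            word |= int(state[r]) << i
        return int(self.evaluate_words(np.array([word]))[0])

    def to_string(self, gene_names: list[str]) -> str:
        """Human-readable DNF using !, & and | operators."""
        if self.constant is not None:
            return str(self.constant)
        parts = []
        for imp in self.terms:
            lits = [
                ("" if pos else "!") + gene_names[self.regulators[i]]
                for i, pos in imp.literals(len(self.regulators))
            ]
            parts.append("(" + " & ".join(lits) + ")" if len(lits) > 1 else lits[0])
        return " | ".join(parts)


def minimize_qm(tt: GeneralizedTruthTable) -> BooleanRule:
    """Quine–McCluskey minimization of a generalized truth table.

    The minimal sum-of-products covers every observed 1-row, excludes every
    observed 0-row and may use the don't-cares freely.  An empty table (no
    observed transitions) yields the constant 0.  Rules that reduce to a
    tautology or contradiction are returned as constants.
    """
    r = tt.n_vars
    ones = {w for w, o in tt.rows.items() if o == 1}
    zeros = {w for w, o in tt.rows.items() if o == 0}
    if not ones:
        return BooleanRule(tt.target, tt.regulators, constant=0)
    dontcares = set(range(1 << r)) - ones - zeros
    if not zeros:
        return BooleanRule(tt.target, tt.regulators, constant=1)
    primes = _prime_implicants(ones | dontcares, r)
    terms = _cover(primes, ones)
    terms.sort(key=lambda p: (p.bits, p.mask))
    if len(terms) == 1 and terms[0].mask == (1 << r) - 1:
        return BooleanRule(tt.target, tt.regulators, constant=1)
    return BooleanRule(tt.target, tt.regulators, terms=terms)


# ---------------------------------------------------------------------------
# Boolean networks


@dataclass
class BooleanNetwork:
    """Per-gene minimal-DNF update rules plus the influence graph they came from."""

    rules: list[BooleanRule]
    gene_names: list[str]
    influence: DirectedNetwork | None = None

    @property
    def n_genes(self) -> int:
        return len(self.rules)

    def rule_strings(self) -> dict[str, str]:
        return {
            self.gene_names[r.target]: r.to_string(self.gene_names)
            for r in self.rules
        }


def infer_boolean_network(
    net: DirectedNetwork, binarized: BinarizedSeries
) -> BooleanNetwork:
    """Infer minimal-DNF rules for every gene of an influence graph."""
    rules = []
    for target in range(net.n):
        regulators = tuple(np.nonzero(net.adjacency[:, target])[0].tolist())
        tt = build_truth_table(binarized, target, regulators)
        rules.append(minimize_qm(tt))
    return BooleanNetwork(rules, list(net.gene_names), influence=net)


def simulate(bn: BooleanNetwork, state: np.ndarray, steps: int) -> np.ndarray:
    """Synchronous trajectory of ``steps`` updates (returns steps+1 states)."""
    state = np.asarray(state, dtype=np.int8)
    if state.shape != (bn.n_genes,):
        raise ValueError("state length must match the gene count")
    traj = np.zeros((steps + 1, bn.n_genes), dtype=np.int8)
    traj[0] = state
    for t in range(steps):
        for rule in bn.rules:
            traj[t + 1, rule.target] = rule.evaluate(traj[t])
    return traj


def dynamic_accuracy(bn: BooleanNetwork, binarized: BinarizedSeries) -> float:
    """Fraction of correct one-step gene-state predictions.

    Every consecutive pair (t, t+1) of every series is scored per gene: the
    rule predicts the state at t+1 from the observed state at t.
    """
    correct = 0
    total = 0
    for s in binarized.series:
        if s.shape[0] < 2:
            continue
        prev, nxt = s[:-1], s[1:]
        for rule in bn.rules:
            words = _pack_states(prev[:, list(rule.regulators)].astype(np.int64))
            pred = rule.evaluate_words(words)
            correct += int((pred == nxt[:, rule.target]).sum())
            total += pred.size
    if total == 0:
        raise ValueError("no transitions to score")
    return correct / total


# ---------------------------------------------------------------------------
# final-network selection


def normalize_objectives(objectives: list[ObjectiveVector]) -> np.ndarray:
    """Min-max normalize each objective axis over a front to [0, 1].

    Degenerate axes (zmax == zmin) contribute 0.  The ideal point of the
    normalized space is the origin.
    """
    z = np.array([[o.z1, o.z2] for o in objectives], dtype=float)
    zmin = z.min(axis=0)
    span = z.max(axis=0) - zmin
    out = np.zeros_like(z)
    for axis in range(2):
        if span[axis] > 0:
            out[:, axis] = (z[:, axis] - zmin[axis]) / span[axis]
    return out


def select_final(
    candidates: list[DirectedNetwork],
    objectives: list[ObjectiveVector],
    binarized: BinarizedSeries,
) -> tuple[BooleanNetwork, dict]:
    """Select the final Boolean network from the first Pareto front.

    Rules are inferred for every candidate; the one with the best dynamic
    accuracy wins, ties broken by the smallest Euclidean distance to the
    ideal point in normalized objective space.  Constant rules in the winner
    are then replaced from the candidate nearest the ideal point (the
    best-compromise network).
    """
    if not candidates:
        raise ValueError("empty candidate front")
    if len(candidates) != len(objectives):
        raise ValueError("candidates and objectives must align")
    norm = normalize_objectives(objectives)
    dist = np.hypot(norm[:, 0], norm[:, 1])
    networks = [infer_boolean_network(c, binarized) for c in candidates]
    accuracy = np.array([dynamic_accuracy(bn, binarized) for bn in networks])
    order = sorted(
        range(len(candidates)), key=lambda i: (-accuracy[i], dist[i], i)
    )
    best = order[0]
    donor_idx = int(np.argmin(dist))  # ties resolve to the first index
    selected = replace_constants(networks[best], networks[donor_idx])
    info = {
        "selected_index": best,
        "donor_index": donor_idx,
        "dynamic_accuracy": float(accuracy[best]),
        "distance_to_ideal": float(dist[best]),
        "accuracies": accuracy.tolist(),
    }
    return selected, info


def replace_constants(
    selected: BooleanNetwork, donor: BooleanNetwork
) -> BooleanNetwork:
    """Replace constant rules with the donor's non-constant rule per gene.

    When the donor's rule for the same gene is also constant, the constant
    is retained and a warning emitted.
    """
    rules = []
    for rule in selected.rules:
        if not rule.is_constant:
            rules.append(rule)
            continue
        donor_rule = donor.rules[rule.target]
        if donor_rule.is_constant:
            warnings.warn(
                f"gene {selected.gene_names[rule.target]!r}: donor rule is also "
                "constant; keeping the constant",
                stacklevel=2,
            )
            rules.append(rule)
        else:
            rules.append(donor_rule)
    return BooleanNetwork(rules, list(selected.gene_names), influence=selected.influence)
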
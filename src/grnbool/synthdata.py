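"""Synthetic gene-regulatory benchmarks with known ground truth.

Emulates the kind of in-silico benchmark data produced by network
simulators: a directed regulatory topology with a heavy-tailed out-degree
distribution and a restricted in-degree (biological GRNs have hub
regulators but few inputs per gene), random non-constant Boolean update
rules consistent with that topology, and noisy continuous expression
trajectories obtained by mapping synchronous Boolean dynamics onto [0, 1]
with additive Gaussian noise.  Defaults produce 10 series of 56 time steps
each, the shape of the standard in-silico benchmark time courses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boolean import BooleanNetwork, BooleanRule, GeneralizedTruthTable, minimize_qm
from .netcore import DirectedNetwork
from .ranking import TimeSeriesSet

__all__ = [
    "SynthConfig",
    "generate_network",
    "generate_rules",
    "simulate_continuous",
    "generate_benchmark",
]


@dataclass
class SynthConfig:
    """Generator settings.

    ``density`` is the target edge probability over ordered pairs (n^2
    denominator); ``gamma`` the out-degree power-law exponent; ``noise_sd``
    the standard deviation of the Gaussian noise added to the continuous
    mapping of Boolean states (low relative to the 0.8 gap between the OFF
    level 0.1 and the ON level 0.9).
    """

    n_genes: int = 16
    density: float | None = None
    mean_in_degree: float = 2.0
    max_in_degree: int = 10
    gamma: float = 2.5
    rule_family: str = "dnf"  # "dnf" | "threshold"
    n_series: int = 10
    series_length: int = 56
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("need at least 3 genes")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if not 1.0 < self.gamma < 4.0:
            raise ValueError("power-law exponent must lie in (1, 4)")
        if self.rule_family not in ("dnf", "threshold"):
            raise ValueError(f"unknown rule family {self.rule_family!r}")

    @property
    def target_edges(self) -> int:
        if self.density is not None:
            return int(round(self.density * self.n_genes**2))
        return int(round(self.mean_in_degree * self.n_genes))


def generate_network(cfg: SynthConfig) -> DirectedNetwork:
    """Random GRN-like topology: power-law out-degrees, capped in-degrees.

    Out-degree propensities follow a truncated power law with exponent
    ``gamma``; each gene draws its regulator count from a truncated
    geometric distribution (capped at ``max_in_degree``) and picks that many
    distinct regulators weighted by propensity.  The in-degree vector is
    resampled (up to 200 tries, deterministic per seed) until the edge total
    lands within 10% of the target, so the realized density tracks the
    requested one.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    target = max(n, cfg.target_edges)
    kmax = min(cfg.max_in_degree, n - 1)
    mean_k = target / n
    # truncated geometric over 1..kmax with the requested mean
    p = min(max(1.0 / mean_k, 1e-6), 0.999)
    support = np.arange(1, kmax + 1)
    pmf = (1 - p) ** (support - 1) * p
    pmf /= pmf.sum()
    for attempt in range(200):
        ks = rng.choice(support, size=n, p=pmf)
        if abs(int(ks.sum()) - target) <= max(1, int(0.1 * target)):
            break
    # scale-free-ish out-degree propensity (Zipf weights over a random order)
    propensity = rng.permutation(np.arange(1, n + 1) ** (-1.0 / (cfg.gamma - 1.0)))
    adj = np.zeros((n, n), dtype=np.int8)
    for gene in range(n):
        w = propensity.copy()
        w[gene] = 0.0
        w /= w.sum()
        regs = rng.choice(n, size=int(ks[gene]), replace=False, p=w)
        adj[regs, gene] = 1
    return DirectedNetwork(adj, max_regulators=max(cfg.max_in_degree, 10))


def _random_nonconstant_rule(
    target: int, regulators: tuple[int, ...], rng: np.random.Generator, family: str
) -> BooleanRule:
    """Random update rule using exactly the given regulators."""
    k = len(regulators)
    if k == 0:
        return BooleanRule(target, (), constant=int(rng.integers(2)))
    for _ in range(100):
        if family == "threshold":
            signs = rng.choice([-1, 1], size=k)
            thresh = rng.integers(0, int(np.sum(signs == 1)) + 1)
            outputs = {
                w: int(
                    sum(s if (w >> i) & 1 else 0 for i, s in enumerate(signs))
                    >= thresh
                )
                for w in range(1 << k)
            }
        else:
            outputs = {w: int(rng.integers(2)) for w in range(1 << k)}
        vals = set(outputs.values())
        if vals != {0, 1}:
            continue
        rule = minimize_qm(
            GeneralizedTruthTable(target, regulators, rows=outputs)
        )
        # minimization may drop a redundant regulator; keep only rules that
        # genuinely depend on every declared parent
        used = {regulators[i] for t in rule.terms for i, _ in t.literals(k)}
        if used == set(regulators):
            return rule
    # fall back to OR of all regulators, which always depends on each parent
    tt = GeneralizedTruthTable(
        target, regulators, rows={w: int(w != 0) for w in range(1 << k)}
    )
    return minimize_qm(tt)


def generate_rules(net: DirectedNetwork, cfg: SynthConfig) -> BooleanNetwork:
    """Random non-constant rules consistent with the influence graph.

    Every rule depends on all of its gene's regulators (so the graph is the
    exact dependency structure of the dynamics); parentless genes get a
    random constant.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    rules = []
    for target in range(net.n):
        regulators = tuple(np.nonzero(net.adjacency[:, target])[0].tolist())
        rules.append(
            _random_nonconstant_rule(target, regulators, rng, cfg.rule_family)
        )
    return BooleanNetwork(rules, list(net.gene_names), influence=net)


def simulate_continuous(bn: BooleanNetwork, cfg: SynthConfig) -> TimeSeriesSet:
    """Noisy continuous trajectories of the Boolean dynamics.

    Each series starts from a random Boolean state and runs synchronously;
    states map to 0.1 (OFF) / 0.9 (ON) plus Gaussian noise, clipped to
    [0, 1].  Times are the integer step indices.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    n = bn.n_genes
    series, times = [], []
    for _ in range(cfg.n_series):
        traj = np.zeros((cfg.series_length, n), dtype=np.int8)
        traj[0] = rng.integers(0, 2, size=n)
        for t in range(1, cfg.series_length):
            for rule in bn.rules:
                traj[t, rule.target] = rule.evaluate(traj[t - 1])
        cont = 0.1 + 0.8 * traj.astype(float)
        if cfg.noise_sd > 0:
            cont = cont + rng.normal(0.0, cfg.noise_sd, size=cont.shape)
        series.append(np.clip(cont, 0.0, 1.0))
        times.append(np.arange(cfg.series_length, dtype=float))
    return TimeSeriesSet(series, times, list(bn.gene_names))


def generate_benchmark(
    cfg: SynthConfig,
) -> tuple[DirectedNetwork, BooleanNetwork, TimeSeriesSet]:
    """Ground-truth network, its Boolean rules and noisy trajectories."""
    net = generate_network(cfg)
    bn = generate_rules(net, cfg)
    ts = simulate_continuous(bn, cfg)
    return net, bn, ts
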
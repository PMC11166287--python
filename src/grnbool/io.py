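"""Readers and writers for the pipeline's plain-text formats.

Time series are tab-separated tables with a leading ``Time`` column and one
column per gene (the common in-silico benchmark layout); one file holds one
series.  Networks travel either as two-column edge lists
(regulator<TAB>target) or as dense adjacency CSV with a gene-name header
row and column; the reader auto-detects the layout.  Boolean rules are
exported as a two-column "targets,factors" table with !, & and |
operators, a format shared by common Boolean-network analysis tools.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .boolean import BooleanNetwork
from .netcore import DirectedNetwork
from .ranking import TimeSeriesSet

__all__ = [
    "read_timeseries",
    "read_network",
    "write_network",
    "write_rules",
    "write_trace",
    "write_outputs",
]


def read_timeseries(paths: str | Path | Sequence[str | Path]) -> TimeSeriesSet:
    """Read one or more series files into a TimeSeriesSet.

    Each file must be a TSV whose first column is named ``Time``
    (case-insensitive) followed by one column per gene; all files must share
    the same gene columns.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    series, times, gene_names = [], [], None
    for path in paths:
        df = pd.read_csv(path, sep="\t")
        if df.shape[0] < 2:
            raise ValueError(f"{path}: a time series needs at least two rows")
        if df.columns[0].strip().lower() != "time":
            raise ValueError(
                f"{path}: first column must be named 'Time', got {df.columns[0]!r}"
            )
        t = df.iloc[:, 0].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise ValueError(
                f"{path}: time column not strictly increasing at row {bad[0] + 3}"
            )
        names = list(df.columns[1:])
        if gene_names is None:
            gene_names = names
        elif names != gene_names:
            raise ValueError(f"{path}: gene columns differ from the first series")
        series.append(df.iloc[:, 1:].to_numpy(dtype=float))
        times.append(t)
    return TimeSeriesSet(series, times, gene_names)


def write_timeseries(ts: TimeSeriesSet, paths: Sequence[str | Path]) -> None:
    if len(paths) != len(ts.series):
        raise ValueError("one output path per series is required")
    for s, t, path in zip(ts.series, ts.times, paths):
        df = pd.DataFrame(s, columns=ts.gene_names)
        df.insert(0, "Time", t)
        df.to_csv(path, sep="\t", index=False)


def _read_adjacency_csv(path: Path) -> DirectedNetwork:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: adjacency header row and column must match")
    return DirectedNetwork(
        df.to_numpy(dtype=np.int8), [str(g) for g in df.columns]
    )


def read_network(
    path: str | Path, gene_names: Iterable[str] | None = None
) -> DirectedNetwork:
    """Read a directed network from an edge-list TSV or adjacency CSV.

    Edge lists are regulator<TAB>target with an optional header; the gene
    set is the union of named endpoints unless ``gene_names`` pins the full
    ordered universe (needed when some genes are isolated).
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_adjacency_csv(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs two tab-separated columns")
    first = df.iloc[0]
    if str(first[0]).strip().lower() in ("regulator", "source", "from"):
        df = df.iloc[1:]
    edges = [(str(r).strip(), str(t).strip()) for r, t in zip(df[0], df[1])]
    if gene_names is None:
        seen: dict[str, None] = {}
        for r, t in edges:
            seen.setdefault(r)
            seen.setdefault(t)
        gene_names = list(seen)
    else:
        gene_names = list(gene_names)
    index = {g: i for i, g in enumerate(gene_names)}
    n = len(gene_names)
    adj = np.zeros((n, n), dtype=np.int8)
    for r, t in edges:
        if r not in index or t not in index:
            raise ValueError(f"{path}: edge ({r}, {t}) names an unknown gene")
        adj[index[r], index[t]] = 1
    return DirectedNetwork(adj, gene_names)


def write_network(net: DirectedNetwork, path: str | Path, fmt: str = "edgelist") -> None:
    path = Path(path)
    if fmt == "adjacency":
        pd.DataFrame(
            net.adjacency, index=net.gene_names, columns=net.gene_names
        ).to_csv(path)
        return
    with open(path, "w") as fh:
        for r, t in net.edges():
            fh.write(f"{net.gene_names[r]}\t{net.gene_names[t]}\n")


def write_rules(bn: BooleanNetwork, path: str | Path) -> None:
    """Write the rule table in the two-column "targets,factors" format."""
    with open(path, "w") as fh:
        fh.write("targets,factors\n")
        for gene, rule in bn.rule_strings().items():
            fh.write(f"{gene},{rule}\n")


def write_trace(trace: list[dict], path: str | Path) -> None:
    pd.DataFrame(trace).to_csv(path, sep="\t", index=False)


def write_outputs(result, out_dir: str | Path, run_config: dict | None = None) -> None:
    """Write the standard output bundle of an inference run.

    rules table, influence edge list, per-generation objective trace,
    selection metadata JSON, and a run log echoing the configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_rules(result.network, out / "rules.csv")
    write_network(result.influence, out / "influence_edges.tsv")
    write_trace(result.trace, out / "objective_trace.tsv")
    with open(out / "selection.json", "w") as fh:
        json.dump(result.selection, fh, indent=2)
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_config or {}, fh, indent=2)
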
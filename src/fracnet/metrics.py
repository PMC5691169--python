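"""Global topology metrics of binary brain graphs.

Clustering coefficient (CC), characteristic path length (CPL) and
global efficiency (GE), plus degree-preserving rewired null networks
and the small-worldness ratio

    sigma = (CC / C_rand) / (CPL / L_rand),

where C_rand and L_rand are ensemble means over rewired graphs with
the same degree sequence.  sigma > 1 indicates small-world
organization.

Conventions for sparse, possibly disconnected graphs: nodes of degree
< 2 contribute 0 to CC; CPL averages shortest paths over *connected*
node pairs only and reports the unreachable-pair fraction alongside;
GE treats unreachable pairs as zero efficiency (1/inf = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .network import BinaryGraph

__all__ = [
    "clustering_coefficient",
    "PathLength",
    "characteristic_path_length",
    "global_efficiency",
    "rewire_null",
    "NullEnsemble",
    "null_ensemble",
    "small_worldness",
    "MetricRecord",
    "graph_metrics",
    "metric_table",
]


def _adjacency(g) -> np.ndarray:
    if isinstance(g, BinaryGraph):
        return g.adjacency
    return BinaryGraph(adjacency=np.asarray(g), density=1.0).adjacency


def _to_networkx(g) -> nx.Graph:
    return nx.from_numpy_array(_adjacency(g).astype(np.int64))


def _distances(adj: np.ndarray) -> np.ndarray:
    d = shortest_path(csr_array(adj), method="D", directed=False, unweighted=True)
    return d


def clustering_coefficient(g) -> float:
    """Mean over nodes of the realized fraction of neighbor pairs that
    are themselves connected; degree < 2 nodes contribute 0."""
    return float(nx.average_clustering(_to_networkx(g)))


class PathLength(NamedTuple):
    """CPL over connected pairs, with the unreachable-pair fraction."""

    value: float
    unreachable_fraction: float


def characteristic_path_length(g) -> PathLength:
    """Mean shortest-path length over connected node pairs.

    Raises on an edgeless graph.  When the graph is disconnected the
    mean is taken over reachable pairs only and the fraction of
    unreachable pairs is returned as an explicit flag.
    """
    adj = _adjacency(g)
    if adj.sum() == 0:
        raise ValueError("characteristic path length is undefined on an edgeless graph")
    d = _distances(adj)
    n = adj.shape[0]
    iu = np.triu_indices(n, 1)
    du = d[iu]
    finite = np.isfinite(du)
    unreachable = 1.0 - finite.mean()
    return PathLength(float(du[finite].mean()), float(unreachable))


def global_efficiency(g) -> float:
    """Mean inverse shortest-path length over all node pairs, with
    unreachable pairs contributing zero.  Empty graph -> 0."""
    adj = _adjacency(g)
    n = adj.shape[0]
    if n < 2:
        return 0.0
    if adj.sum() == 0:
        return 0.0
    d = _distances(adj)
    iu = np.triu_indices(n, 1)
    du = d[iu]
    inv = np.zeros_like(du)
    finite = np.isfinite(du) & (du > 0)
    inv[finite] = 1.0 / du[finite]
    return float(inv.mean())


def rewire_null(g, swaps_per_edge: int = 10, seed: int | None = None) -> BinaryGraph:
    """Degree-preserving randomization by double-edge swaps.

    Attempts ``swaps_per_edge`` successful swaps per edge.  Graphs
    admitting no valid swap (e.g. a triangle) are returned unchanged
    with a warning.  The result is always a simple graph with exactly
    the input's degree sequence.
    """
    src = g if isinstance(g, BinaryGraph) else BinaryGraph(np.asarray(g), 1.0)
    if src.n_edges < 2:
        raise ValueError("rewiring requires at least 2 edges")
    if swaps_per_edge < 0:
        raise ValueError("swaps_per_edge must be nonnegative")
    if swaps_per_edge == 0:
        return BinaryGraph(src.adjacency.copy(), src.density, src.labels)
    nxg = _to_networkx(src)
    nswap = swaps_per_edge * src.n_edges
    try:
        nx.double_edge_swap(nxg, nswap=nswap, max_tries=100 * nswap, seed=seed)
    except nx.NetworkXError as err:
        warnings.warn(f"no valid degree-preserving swap ({err}); returning the input")
        return BinaryGraph(src.adjacency.copy(), src.density, src.labels)
    adj = nx.to_numpy_array(nxg, nodelist=range(src.n), dtype=np.int8)
    return BinaryGraph(adjacency=adj, density=src.density, labels=src.labels)


@dataclass(frozen=True)
class NullEnsemble:
    """Summary of K degree-matched rewired graphs."""

    c_rand: float
    l_rand: float
    cc_values: np.ndarray = field(repr=False)
    cpl_values: np.ndarray = field(repr=False)

    @property
    def k(self) -> int:
        return len(self.cc_values)


def null_ensemble(
    g, k: int = 100, swaps_per_edge: int = 10, seed: int | None = None
) -> NullEnsemble:
    """Mean clustering and path length over K independent rewirings."""
    if k < 1:
        raise ValueError("ensemble size must be >= 1")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=k)
    ccs, cpls = [], []
    for s in child_seeds:
        null = rewire_null(g, swaps_per_edge=swaps_per_edge, seed=int(s))
        ccs.append(clustering_coefficient(null))
        cpls.append(characteristic_path_length(null).value)
    ccs = np.asarray(ccs)
    cpls = np.asarray(cpls)
    return NullEnsemble(
        c_rand=float(ccs.mean()), l_rand=float(cpls.mean()),
        cc_values=ccs, cpl_values=cpls,
    )


def small_worldness(g, nulls: NullEnsemble) -> float:
    """sigma = (CC / C_rand) / (CPL / L_rand)."""
    if nulls.c_rand <= 0:
        raise ValueError("null ensemble has zero mean clustering; sigma is undefined")
    if nulls.l_rand <= 0:
        raise ValueError("null ensemble has zero mean path length; sigma is undefined")
    cc = clustering_coefficient(g)
    cpl = characteristic_path_length(g).value
    return float((cc / nulls.c_rand) / (cpl / nulls.l_rand))


@dataclass(frozen=True)
class MetricRecord:
    """Topology metrics of one (subject, measure, density) graph."""

    cc: float
    cpl: float
    ge: float
    unreachable_fraction: float
    density: float
    measure: str = ""
    subject: str = ""
    sigma: float | None = None


def graph_metrics(
    g: BinaryGraph, measure: str = "", subject: str = "", nulls: NullEnsemble | None = None
) -> MetricRecord:
    """Compute CC, CPL, GE (and optionally sigma) for one graph."""
    cpl = characteristic_path_length(g)
    sigma = small_worldness(g, nulls) if nulls is not None else None
    return MetricRecord(
        cc=clustering_coefficient(g),
        cpl=cpl.value,
        ge=global_efficiency(g),
        unreachable_fraction=cpl.unreachable_fraction,
        density=g.density,
        measure=measure,
        subject=subject,
        sigma=sigma,
    )


def metric_table(records) -> pd.DataFrame:
    """Tidy table of metric records, one row per (subject, measure,
    density)."""
    rows = []
    for r in records:
        rows.append(
            {
                "subject": r.subject,
                "measure": r.measure,
                "density": r.density,
                "cc": r.cc,
                "cpl": r.cpl,
                "ge": r.ge,
                "unreachable_fraction": r.unreachable_fraction,
                "sigma": r.sigma if r.sigma is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)
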
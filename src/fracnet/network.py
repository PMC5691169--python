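"""From ROI time-series matrices to weighted and binary graphs.

A subject is represented by an N_roi x N_time matrix of BOLD time
series (one row per atlas region).  A chosen pairwise measure turns it
into a symmetric weighted connectivity matrix; proportional
thresholding then keeps the strongest fraction of connections as the
edges of an undirected binary graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .similarity import MEASURES, get_measure

__all__ = [
    "ROITimeSeries",
    "WeightedMatrix",
    "BinaryGraph",
    "connectivity_matrix",
    "proportional_threshold",
    "threshold_sweep",
    "edge_count",
    "DEFAULT_DENSITIES",
]

#: connection densities customarily explored, 10% to 50% of the
#: strongest connections in steps of 10%
DEFAULT_DENSITIES = (0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class ROITimeSeries:
    """One subject's region-by-time BOLD matrix with ROI labels."""

    values: np.ndarray
    labels: tuple

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        labels = tuple(str(l) for l in self.labels)
        object.__setattr__(self, "labels", labels)
        if values.ndim != 2:
            raise ValueError("time-series matrix must be 2-D (ROIs x time)")
        if values.shape[0] < 2:
            raise ValueError("need at least 2 ROIs")
        if len(labels) != values.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for {values.shape[0]} ROI rows"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("ROI labels must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("time series contain non-finite values")
        flat = np.ptp(values, axis=1) == 0
        if np.any(flat):
            bad = [labels[i] for i in np.flatnonzero(flat)]
            raise ValueError(f"constant time series for ROI(s): {', '.join(bad)}")

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class WeightedMatrix:
    """Symmetric nonnegative connectivity weights with zero diagonal."""

    values: np.ndarray
    labels: tuple
    measure: str

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        n = values.shape[0]
        if values.ndim != 2 or values.shape != (n, n):
            raise ValueError("weight matrix must be square")
        if len(self.labels) != n:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(values, values.T, atol=1e-12, rtol=0.0):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(values) != 0.0):
            raise ValueError("weight matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected simple graph as a 0/1 adjacency with its density."""

    adjacency: np.ndarray
    density: float
    labels: tuple = ()

    def __post_init__(self):
        adj = np.asarray(self.adjacency)
        if adj.dtype != np.int8:
            adj = adj.astype(np.int8)
        object.__setattr__(self, "adjacency", adj)
        n = adj.shape[0]
        if adj.ndim != 2 or adj.shape != (n, n):
            raise ValueError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        if self.labels:
            object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
            if len(self.labels) != n:
                raise ValueError("label count does not match adjacency size")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())


def connectivity_matrix(ts: ROITimeSeries, measure: str, **params) -> WeightedMatrix:
    """Apply a pairwise measure to every ROI pair of one subject.

    The linear-correlation matrix is the only one containing negative
    entries; its absolute values are taken so all weight matrices are
    nonnegative before thresholding.  MI and BCFD are nonnegative by
    construction and left untouched.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {sorted(MEASURES)}")
    n = ts.n_roi
    w = np.zeros((n, n), dtype=float)
    if measure == "lc":
        w = np.corrcoef(ts.values)
        np.fill_diagonal(w, 0.0)
        w = np.abs(w)
        w = (w + w.T) / 2.0  # exact symmetry against rounding
    else:
        fn = get_measure(measure, **params)
        for i in range(n):
            for j in range(i + 1, n):
                v = fn(ts.values[i], ts.values[j])
                w[i, j] = w[j, i] = v
    return WeightedMatrix(values=w, labels=ts.labels, measure=measure)


def edge_count(n: int, density: float) -> int:
    """Edges retained at a proportional density: round-half-away-from-
    zero of density * N(N-1)/2."""
    n_pairs = n * (n - 1) // 2
    return int(np.floor(density * n_pairs + 0.5))


def proportional_threshold(w: WeightedMatrix, density: float) -> BinaryGraph:
    """Keep exactly the strongest ``density`` fraction of connections.

    Ties at the cut are broken deterministically by upper-triangle
    (row, column) order.
    """
    if not (0.0 < density <= 1.0):
        raise ValueError(f"density must lie in (0, 1], got {density}")
    n = w.n
    k = edge_count(n, density)
    if k == 0:
        raise ValueError(
            f"density {density} keeps no edges on a {n}-node network"
        )
    iu, ju = np.triu_indices(n, 1)
    weights = w.values[iu, ju]
    order = np.argsort(-weights, kind="stable")  # stable: ties by (i, j)
    keep = order[:k]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    return BinaryGraph(adjacency=adj, density=float(density), labels=w.labels)


def threshold_sweep(w: WeightedMatrix, densities=DEFAULT_DENSITIES) -> list[BinaryGraph]:
    """One binary graph per density; densities must be ascending, so
    the resulting edge sets are nested."""
    densities = [float(d) for d in densities]
    if any(b <= a for a, b in zip(densities, densities[1:])):
        raise ValueError("densities must be sorted strictly ascending")
    return [proportional_threshold(w, d) for d in densities]
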
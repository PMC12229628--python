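"""Weighted centrality and density metrics for symptom networks.

Edge weights are partial correlations; a stronger (larger magnitude)
association means the two symptoms are "closer", so each edge is assigned the
length ``1/|w|`` and all path-based metrics run on those lengths.  Negative
partial correlations are taken in absolute value throughout (strength and
lengths) — the standard convention for weighted psychological networks, noted
here because a literal "sum of edge weights" would differ for negative edges.

Metrics
-------
strength
    Sum of absolute incident edge weights.
closeness
    Reciprocal of the summed shortest-path distance to every other node;
    0 if any node is unreachable.
betweenness
    Brandes pair-dependency accumulation over unordered pairs; geodesic ties
    are split fractionally and detected with relative tolerance 1e-9.
ASPL / global efficiency
    Mean shortest-path length over reachable unordered pairs, and mean
    reciprocal shortest-path length over all unordered pairs (1/inf = 0).
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .network import SymptomNetwork

__all__ = [
    "DistanceMatrix",
    "CentralityProfile",
    "DensityMetrics",
    "to_distances",
    "strength",
    "closeness",
    "betweenness",
    "density_metrics",
    "centrality_profile",
]

#: Relative tolerance for declaring two geodesic lengths tied.
TIE_RTOL = 1e-9


@dataclass
class DistanceMatrix:
    """All-pairs shortest-path lengths over edge lengths ``1/|w|``."""

    items: tuple[str, ...]
    d: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.items), columns=list(self.items))


@dataclass
class CentralityProfile:
    """Per-item strength / closeness / betweenness for one participant."""

    participant_id: str
    values: pd.DataFrame  # index: item, columns: strength, closeness, betweenness

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)


@dataclass
class DensityMetrics:
    """Network-level density summary for one participant."""

    participant_id: str
    aspl: float  # NaN when no pair is reachable
    global_efficiency: float
    fraction_reachable: float


def _edge_lengths(network: SymptomNetwork) -> np.ndarray:
    aw = np.abs(network.w)
    with np.errstate(divide="ignore"):
        lengths = np.where(aw > 0, 1.0 / np.where(aw > 0, aw, 1.0), np.inf)
    np.fill_diagonal(lengths, np.inf)  # no self loops
    return lengths


def to_distances(network: SymptomNetwork) -> DistanceMatrix:
    """All-pairs shortest paths with edge length ``1/|w_ij|``.

    Unreachable pairs get ``inf``; the diagonal is 0.
    """
    n = network.n_items
    lengths = _edge_lengths(network)
    rows, cols = np.nonzero(np.isfinite(lengths))
    graph = csr_array((lengths[rows, cols], (rows, cols)), shape=(n, n))
    d = dijkstra(graph, directed=False)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(items=network.items, d=d)


def strength(network: SymptomNetwork) -> pd.Series:
    """Node strength: sum of absolute incident edge weights."""
    return pd.Series(
        np.abs(network.w).sum(axis=1), index=list(network.items), name="strength"
    )


def closeness(
    network: SymptomNetwork, distances: DistanceMatrix | None = None
) -> pd.Series:
    """Closeness: ``1 / sum_j d(i, j)``; 0 (with a warning) if any j unreachable."""
    if distances is None:
        distances = to_distances(network)
    d = distances.d
    n = len(distances.items)
    out = np.zeros(n)
    any_unreachable = False
    for i in range(n):
        row = np.delete(d[i], i)
        if np.isinf(row).any():
            any_unreachable = True
            out[i] = 0.0
        elif n > 1:
            out[i] = 1.0 / row.sum()
    if any_unreachable:
        warnings.warn(
            "network is disconnected; closeness set to 0 for nodes with "
            "unreachable partners",
            stacklevel=2,
        )
    return pd.Series(out, index=list(distances.items), name="closeness")


def betweenness(network: SymptomNetwork, rtol: float = TIE_RTOL) -> pd.Series:
    """Weighted betweenness by Brandes accumulation over unordered pairs.

    For every pair {s, t} (s != v != t) node v accrues
    ``sigma_st(v) / sigma_st``, the fraction of geodesics through v.
    Geodesics tied within relative tolerance ``rtol`` split the credit
    fractionally; edge lengths are ``1/|w|`` so ties among floating-point
    path sums are detected rather than broken arbitrarily.
    """
    n = network.n_items
    lengths = _edge_lengths(network)
    neighbours = [np.flatnonzero(np.isfinite(lengths[v])) for v in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        preds: list[list[int]] = [[] for _ in range(n)]
        done = np.zeros(n, dtype=bool)
        dist[s] = 0.0
        sigma[s] = 1.0
        order: list[int] = []
        heap: list[tuple[float, int]] = [(0.0, s)]
        while heap:
            dv, v = heapq.heappop(heap)
            if done[v]:
                continue
            done[v] = True
            order.append(v)
            for u in neighbours[v]:
                if done[u]:
                    continue
                alt = dist[v] + lengths[v, u]
                if math.isclose(alt, dist[u], rel_tol=rtol):
                    sigma[u] += sigma[v]
                    preds[u].append(v)
                elif alt < dist[u]:
                    dist[u] = alt
                    sigma[u] = sigma[v]
                    preds[u] = [v]
                    heapq.heappush(heap, (alt, u))
        delta = np.zeros(n)
        for v in reversed(order):
            for p in preds[v]:
                delta[p] += sigma[p] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bc[v] += delta[v]
    bc /= 2.0  # each unordered pair accumulated from both endpoints
    return pd.Series(bc, index=list(network.items), name="betweenness")


def density_metrics(
    network: SymptomNetwork, distances: DistanceMatrix | None = None
) -> DensityMetrics:
    """ASPL, global efficiency and reachable-pair fraction of one network.

    ASPL averages finite distances over unordered pairs (NaN if none are
    finite, with a warning when some pairs are excluded); global efficiency
    averages ``1/d`` over *all* unordered pairs with ``1/inf = 0``.
    """
    if distances is None:
        distances = to_distances(network)
    d = distances.d
    n = len(distances.items)
    iu = np.triu_indices(n, k=1)
    pairs = d[iu]
    if pairs.size == 0:
        return DensityMetrics(
            participant_id=network.provenance.get("participant_id", ""),
            aspl=float("nan"),
            global_efficiency=0.0,
            fraction_reachable=1.0,
        )
    finite = np.isfinite(pairs)
    fraction = float(finite.mean())
    if finite.any():
        aspl = float(pairs[finite].mean())
        if not finite.all():
            warnings.warn(
                f"{(~finite).sum()} unreachable pair(s) excluded from ASPL",
                stacklevel=2,
            )
    else:
        aspl = float("nan")
    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / np.where(finite, pairs, 1.0), 0.0)
    return DensityMetrics(
        participant_id=network.provenance.get("participant_id", ""),
        aspl=aspl,
        global_efficiency=float(inv.mean()),
        fraction_reachable=fraction,
    )


def centrality_profile(network: SymptomNetwork) -> CentralityProfile:
    """Strength, closeness and betweenness for every item of one network."""
    distances = to_distances(network)
    values = pd.DataFrame(
        {
            "strength": strength(network),
            "closeness": closeness(network, distances),
            "betweenness": betweenness(network),
        }
    )
    return CentralityProfile(
        participant_id=network.provenance.get("participant_id", ""), values=values
    )
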
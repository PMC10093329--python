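"""Weighted brain networks: proportional thresholding, graph metrics, null models.

A connectivity matrix is reduced to a sparse weighted graph by keeping the
top fraction of its off-diagonal weights (proportional threshold), so that
networks compared across subjects share the same edge count.  On the
thresholded graph we compute:

* the weighted clustering coefficient of Barrat et al. —
  ``C_i = (1 / (S_i (k_i - 1))) * sum over ordered neighbour pairs (j, h)
  closing a triangle of (w_ij + w_ih)/2`` — which lies in [0, 1] and reduces
  to the binary clustering coefficient when all weights are equal;
* the weighted characteristic path length with edge length ``1/w`` (strong
  edges are short);
* the small-world index ``sigma = (C/C_rand) / (L/L_rand)`` against
  degree-preserving Maslov-Sneppen surrogate graphs whose edges carry the
  original weight multiset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .connectivity import ConnectivityMatrix
from .montage import RhythmBand

#: Density fractions 25%..35% in 1% steps — the default threshold sweep.
DEFAULT_SWEEP: tuple[float, ...] = tuple(round(f / 100, 2) for f in range(25, 36))

DEFAULT_N_SURROGATES = 50
DEFAULT_SWAPS_PER_EDGE = 10
#: Rewiring attempt budget, as a multiple of the requested successful swaps.
ATTEMPT_BUDGET_FACTOR = 100


@dataclass
class WeightedNetwork:
    """Sparse weighted graph on labelled nodes; edges are (i, j, w) with i < j."""

    nodes: tuple[str, ...]
    edge_index: np.ndarray  # (E, 2) int, i < j
    weights: np.ndarray  # (E,) float in (0, 1]
    density_fraction: float | None = None
    band: RhythmBand | str | None = None
    rewire_failed: bool = False

    def __post_init__(self) -> None:
        self.nodes = tuple(str(n) for n in self.nodes)
        self.edge_index = np.asarray(self.edge_index, dtype=int).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if len(self.edge_index) != len(self.weights):
            raise ValueError("edge_index and weights disagree in length")
        if len(self.edge_index):
            i, j = self.edge_index[:, 0], self.edge_index[:, 1]
            if np.any(i >= j):
                raise ValueError("edges must be stored with i < j (no self-loops)")
            if i.min() < 0 or j.max() >= self.n_nodes:
                raise ValueError("edge endpoint out of node range")
            pairs = set(map(tuple, self.edge_index))
            if len(pairs) != len(self.edge_index):
                raise ValueError("duplicate edges")
            if np.any(self.weights <= 0):
                raise ValueError("all edge weights must be positive")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric weight matrix."""
        w = np.zeros((self.n_nodes, self.n_nodes))
        if self.n_edges:
            i, j = self.edge_index[:, 0], self.edge_index[:, 1]
            w[i, j] = self.weights
            w[j, i] = self.weights
        return w

    def degrees(self) -> np.ndarray:
        k = np.zeros(self.n_nodes, dtype=int)
        for a, b in self.edge_index:
            k[a] += 1
            k[b] += 1
        return k

    def isolated_nodes(self) -> list[str]:
        return [self.nodes[i] for i in np.flatnonzero(self.degrees() == 0)]

    def to_edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_i": [self.nodes[a] for a, _ in self.edge_index],
                "node_j": [self.nodes[b] for _, b in self.edge_index],
                "weight": self.weights,
            }
        )


@dataclass
class PathLength:
    """Characteristic path length with disconnection bookkeeping."""

    value: float
    disconnected: bool = False
    n_unreachable_pairs: int = 0  # unordered pairs

    def __float__(self) -> float:
        return self.value


@dataclass
class NetworkMetrics:
    """Weighted graph metrics for one network (or a threshold-sweep mean)."""

    clustering_mean: float
    path_length: float
    sigma: float = math.nan
    c_rand: float = math.nan
    l_rand: float = math.nan
    n_surrogates: int = 0
    threshold: float | str | None = None
    clustering_per_node: np.ndarray | None = None
    disconnected: bool = False
    sigma_undefined: bool = False
    c_exceeds_random: bool | None = None
    l_at_least_random: bool | None = None


def proportional_threshold(m: ConnectivityMatrix, fraction: float) -> WeightedNetwork:
    """Keep the ``round(fraction * N(N-1)/2)`` strongest weights as edges.

    Rounding is round-half-up; ties among equal weights at the cut are broken
    by lexicographic (i, j) order so the result is deterministic.  Retaining a
    zero weight is refused (the graph would carry a meaningless edge).
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"density fraction must be in (0, 1], got {fraction}")
    n = m.n_nodes
    n_pairs = n * (n - 1) // 2
    k = int(math.floor(fraction * n_pairs + 0.5))
    k = max(k, 1)
    iu = np.triu_indices(n, k=1)
    weights = m.values[iu]
    order = np.lexsort((iu[1], iu[0], -weights))  # weight desc, then (i, j)
    top = order[:k]
    if np.any(weights[top] <= 0):
        raise ValueError(
            f"cannot retain {k} edges: the matrix has fewer than {k} positive weights"
        )
    edge_index = np.column_stack((iu[0][top], iu[1][top]))
    # store edges themselves in (i, j) order for stable output
    key = np.lexsort((edge_index[:, 1], edge_index[:, 0]))
    return WeightedNetwork(
        nodes=m.channel_names,
        edge_index=edge_index[key],
        weights=weights[top][key],
        density_fraction=fraction,
        band=m.band,
    )


def threshold_sweep(
    m: ConnectivityMatrix, fractions: Sequence[float] = DEFAULT_SWEEP
) -> list[WeightedNetwork]:
    """One proportionally thresholded network per density fraction."""
    if not len(fractions):
        raise ValueError("fractions must be non-empty")
    return [proportional_threshold(m, f) for f in fractions]


def weighted_clustering(net: WeightedNetwork) -> tuple[np.ndarray, float]:
    """Barrat weighted clustering per node and its mean over all N nodes.

    Nodes of degree < 2 contribute 0 (the coefficient is undefined there) but
    stay in the mean's denominator.
    """
    if net.n_edges == 0:
        raise ValueError("clustering of an empty network is undefined")
    w = net.adjacency()
    a = (w > 0).astype(float)
    k = a.sum(axis=1)
    s = w.sum(axis=1)
    # ordered-neighbour-pair triangle sum: diag(W A A)_i = sum_{j,h} w_ij a_jh a_hi
    tri = np.einsum("ij,jh,hi->i", w, a, a)
    per_node = np.zeros(net.n_nodes)
    ok = k >= 2
    per_node[ok] = tri[ok] / (s[ok] * (k[ok] - 1))
    return per_node, float(per_node.mean())


def weighted_path_length(net: WeightedNetwork) -> PathLength:
    """Mean shortest-path length over node pairs with edge length 1/weight.

    If the graph is disconnected, the mean is over reachable pairs only and
    the result is flagged with the unreachable-pair count.
    """
    if net.n_edges == 0:
        raise ValueError("path length of an empty network is undefined")
    n = net.n_nodes
    i, j = net.edge_index[:, 0], net.edge_index[:, 1]
    lengths = 1.0 / net.weights
    graph = csr_matrix(
        (np.concatenate([lengths, lengths]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    )
    dist = dijkstra(graph, directed=False)
    off = ~np.eye(n, dtype=bool)
    d = dist[off]
    unreachable = int(np.isinf(d).sum()) // 2
    finite = d[np.isfinite(d)]
    if finite.size == 0:
        raise ValueError("no reachable node pairs")
    return PathLength(
        value=float(finite.mean()),
        disconnected=unreachable > 0,
        n_unreachable_pairs=unreachable,
    )


def maslov_sneppen_rewire(
    net: WeightedNetwork,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int | np.random.Generator = 0,
) -> WeightedNetwork:
    """Degree-preserving randomisation by repeated double-edge swaps.

    A swap replaces edges (a, b), (c, d) with (a, d), (c, b), rejected when it
    would create a self-loop or a duplicate edge; each edge keeps its weight
    through the swaps, so node count, edge count, degree sequence and the
    weight multiset are all conserved.  If no valid swap is found within the
    attempt budget the input topology is returned with ``rewire_failed=True``.
    """
    if net.n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    if swaps_per_edge < 1:
        raise ValueError(f"swaps_per_edge must be >= 1, got {swaps_per_edge}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = [tuple(e) for e in net.edge_index]
    weights = list(net.weights)
    present = set(edges)
    n_edges = len(edges)
    target = swaps_per_edge * n_edges
    budget = ATTEMPT_BUDGET_FACTOR * target
    successes = 0
    for _ in range(budget):
        if successes >= target:
            break
        e1, e2 = rng.choice(n_edges, size=2, replace=False)
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.integers(2):  # also consider the reversed orientation of edge 2
            c, d = d, c
        if a == d or c == b:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 == new2 or new1 in present or new2 in present:
            continue
        present.discard(edges[e1])
        present.discard(edges[e2])
        present.add(new1)
        present.add(new2)
        edges[e1] = new1
        edges[e2] = new2
        successes += 1
    if successes == 0:
        return replace(net, rewire_failed=True)
    edge_index = np.asarray(edges, dtype=int)
    key = np.lexsort((edge_index[:, 1], edge_index[:, 0]))
    return WeightedNetwork(
        nodes=net.nodes,
        edge_index=edge_index[key],
        weights=np.asarray(weights)[key],
        density_fraction=net.density_fraction,
        band=net.band,
    )


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def small_world_sigma(
    net: WeightedNetwork,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int = 0,
) -> NetworkMetrics:
    """Small-world index against Maslov-Sneppen surrogate means.

    ``sigma = (Cw / Cw_rand) / (Lw / Lw_rand)`` with the random-network terms
    averaged over ``n_surrogates`` independently rewired surrogates (child
    seeds derived deterministically from ``seed``).
    """
    if n_surrogates < 1:
        raise ValueError(f"n_surrogates must be >= 1, got {n_surrogates}")
    per_node, cw = weighted_clustering(net)
    lw = weighted_path_length(net)
    c_surr = np.empty(n_surrogates)
    l_surr = np.empty(n_surrogates)
    any_disconnected = lw.disconnected
    for idx, child in enumerate(_child_seeds(seed, n_surrogates)):
        surr = maslov_sneppen_rewire(net, swaps_per_edge=swaps_per_edge, seed=child)
        _, c_surr[idx] = weighted_clustering(surr)
        pl = weighted_path_length(surr)
        l_surr[idx] = pl.value
        any_disconnected |= pl.disconnected
    c_rand = float(c_surr.mean())
    l_rand = float(l_surr.mean())
    sigma_undefined = c_rand == 0
    sigma = math.nan if sigma_undefined else (cw / c_rand) / (lw.value / l_rand)
    return NetworkMetrics(
        clustering_mean=cw,
        path_length=lw.value,
        sigma=sigma,
        c_rand=c_rand,
        l_rand=l_rand,
        n_surrogates=n_surrogates,
        threshold=net.density_fraction,
        clustering_per_node=per_node,
        disconnected=any_disconnected,
        sigma_undefined=sigma_undefined,
        c_exceeds_random=bool(cw > c_rand),
        l_at_least_random=bool(lw.value >= l_rand),
    )


@dataclass
class SweepMetrics:
    """Per-threshold metrics plus their arithmetic mean across the sweep."""

    per_threshold: pd.DataFrame
    summary: NetworkMetrics


def metrics_over_sweep(
    m: ConnectivityMatrix,
    fractions: Sequence[float] = DEFAULT_SWEEP,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int = 0,
) -> SweepMetrics:
    """Threshold sweep -> per-network Cw, Lw, sigma -> sweep means.

    One seed child per threshold keeps the surrogate draws independent across
    the sweep while staying reproducible.
    """
    nets = threshold_sweep(m, fractions)
    rows = []
    children = _child_seeds(seed, len(nets))
    for net, child in zip(nets, children):
        rec = small_world_sigma(
            net, n_surrogates=n_surrogates, swaps_per_edge=swaps_per_edge, seed=child
        )
        rows.append(
            {
                "threshold": net.density_fraction,
                "n_edges": net.n_edges,
                "Cw": rec.clustering_mean,
                "Lw": rec.path_length,
                "sigma": rec.sigma,
                "c_rand": rec.c_rand,
                "l_rand": rec.l_rand,
                "disconnected": rec.disconnected,
                "sigma_undefined": rec.sigma_undefined,
                "n_isolated": len(net.isolated_nodes()),
            }
        )
    table = pd.DataFrame(rows)
    summary = NetworkMetrics(
        clustering_mean=float(table["Cw"].mean()),
        path_length=float(table["Lw"].mean()),
        sigma=float(table["sigma"].mean()),
        c_rand=float(table["c_rand"].mean()),
        l_rand=float(table["l_rand"].mean()),
        n_surrogates=n_surrogates,
        threshold="sweep-mean",
        disconnected=bool(table["disconnected"].any()),
        sigma_undefined=bool(table["sigma_undefined"].any()),
    )
    return SweepMetrics(per_threshold=table, summary=summary)
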
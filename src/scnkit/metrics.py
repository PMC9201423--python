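"""Global and nodal graph metrics with random-null normalization.

All metrics operate on simple undirected binary graphs. Conventions (these
change the numbers and are therefore spelled out):

* clustering and local efficiency: nodes with degree < 2 contribute 0;
* characteristic path length requires a connected graph, global efficiency
  treats unreachable pairs as contributing 0;
* betweenness is exact Brandes betweenness with endpoints excluded, counting
  each unordered pair once; the normalized variant divides by the network
  mean (zeros included), so it averages to 1 whenever any shortest path has
  an interior node;
* γ = Cp/Cp_rand and λ = Lp/Lp_rand are normalized against the mean of an
  ensemble of degree-preserving randomized graphs (connected double-edge
  swaps, 10 × edge-count swaps each), and σ = γ/λ is the small-world index;
  a network with γ > 1 and λ ≈ 1 or σ > 1 is considered small-world;
* degree assortativity is undefined (NaN) when edge-end degrees have no
  variance, e.g. on regular graphs;
* modularity uses a deterministic greedy agglomeration with local node-move
  refinement; the ``seed`` argument is accepted for interface stability but
  the optimizer draws no random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from . import _kernels
from .errors import DataError
from .network import BinaryGraph

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "transitivity",
    "assortativity",
    "modularity",
    "modularity_partition",
    "betweenness",
    "random_null_ensemble",
    "randomize_degree_preserving",
    "small_world",
    "global_metrics",
]

GraphLike = Union[BinaryGraph, np.ndarray]


def _adj(g: GraphLike) -> np.ndarray:
    if isinstance(g, BinaryGraph):
        return g.adjacency
    return BinaryGraph(adjacency=np.asarray(g)).adjacency


def _csr(adj: np.ndarray):
    return _kernels.build_csr(adj, adj.shape[0])


def _bits(adj: np.ndarray):
    return _kernels.build_bits(adj, adj.shape[0])


@dataclass
class GlobalMetrics:
    """Whole-network metrics at one density, with null-normalized variants."""

    cp: float
    lp: float
    eglob: float
    eloc: float
    assort: float
    trans: float
    q: float
    cprand: float
    lprand: float
    gamma: float
    lam: float
    sigma: float


@dataclass
class NodalMetrics:
    """Per-node betweenness (raw and network-mean normalized) and degree."""

    bc_raw: np.ndarray
    bc_norm: np.ndarray
    degree: np.ndarray
    norm_defined: bool


def clustering_coefficient(g: GraphLike) -> float:
    """Mean local clustering (fraction of neighbor pairs that are linked)."""
    adj = _adj(g)
    n = adj.shape[0]
    if n == 0:
        return 0.0
    indptr, indices = _csr(adj)
    cp, _ = _kernels.clustering_transitivity(indptr, indices, adj, n)
    return float(cp)


def characteristic_path_length(g: GraphLike) -> float:
    """Mean shortest-path length over all node pairs (connected graphs)."""
    adj = _adj(g)
    n = adj.shape[0]
    if n < 2:
        raise DataError("characteristic path length needs at least 2 nodes")
    indptr, indices = _csr(adj)
    lp, _, connected = _kernels.path_stats(indptr, indices, _bits(adj), n)
    if not connected:
        raise DataError("characteristic path length is undefined on a disconnected graph")
    return float(lp)


def global_efficiency(g: GraphLike) -> float:
    """Mean inverse shortest-path length; unreachable pairs contribute 0."""
    adj = _adj(g)
    n = adj.shape[0]
    if n < 2:
        return 0.0
    indptr, indices = _csr(adj)
    _, eglob, _ = _kernels.path_stats(indptr, indices, _bits(adj), n)
    return float(eglob)


def local_efficiency(g: GraphLike) -> float:
    """Mean over nodes of the efficiency of the neighbor-induced subgraph."""
    adj = _adj(g)
    n = adj.shape[0]
    if n == 0:
        return 0.0
    indptr, indices = _csr(adj)
    return float(_kernels.local_efficiency(indptr, indices, _bits(adj), n))


def transitivity(g: GraphLike) -> float:
    """3 × triangles / connected triples; 0 when there are no triples."""
    adj = _adj(g)
    n = adj.shape[0]
    if n == 0:
        return 0.0
    indptr, indices = _csr(adj)
    _, trans = _kernels.clustering_transitivity(indptr, indices, adj, n)
    return float(trans)


def assortativity(g: GraphLike) -> float:
    """Newman degree assortativity; NaN when undefined (no degree variance)."""
    adj = _adj(g)
    n = adj.shape[0]
    if n == 0:
        return float("nan")
    indptr, indices = _csr(adj)
    return float(_kernels.assortativity(indptr, indices, n))


def modularity(g: GraphLike, seed: int = 0) -> float:
    """Newman–Girvan Q of a deterministically optimized partition."""
    adj = _adj(g)
    n = adj.shape[0]
    m = int(adj.sum() // 2)
    if m == 0:
        raise DataError("modularity is undefined on an edgeless graph")
    indptr, indices = _csr(adj)
    q, _labels = _kernels.modularity_partition(adj, indptr, indices, n, m)
    return float(q)


def modularity_partition(g: GraphLike, seed: int = 0) -> tuple[float, np.ndarray]:
    """(Q, community label per node) of the optimized partition."""
    adj = _adj(g)
    n = adj.shape[0]
    m = int(adj.sum() // 2)
    if m == 0:
        raise DataError("modularity is undefined on an edgeless graph")
    indptr, indices = _csr(adj)
    q, labels = _kernels.modularity_partition(adj, indptr, indices, n, m)
    return float(q), np.asarray(labels)


def betweenness(g: GraphLike) -> NodalMetrics:
    """Exact betweenness; bc_norm = bc_raw / mean(bc_raw) (zeros included).

    When no shortest path has an interior node (e.g. complete graphs), the
    mean is 0 and bc_norm is defined as all-zero with ``norm_defined=False``.
    """
    adj = _adj(g)
    n = adj.shape[0]
    indptr, indices = _csr(adj)
    bc = np.asarray(_kernels.betweenness(indptr, indices, n))
    mean = bc.mean() if n else 0.0
    if mean > 0:
        bc_norm = bc / mean
        defined = True
    else:
        bc_norm = np.zeros_like(bc)
        defined = False
    return NodalMetrics(
        bc_raw=bc,
        bc_norm=bc_norm,
        degree=adj.sum(axis=1).astype(np.int64),
        norm_defined=defined,
    )


def random_null_ensemble(
    g: GraphLike,
    n_null: int = 20,
    seed: int = 0,
    null_model: str = "degree_preserving",
    swap_multiplier: int = 10,
) -> tuple[float, float]:
    """Mean (Cp, Lp) of an ensemble of connected randomized graphs.

    ``degree_preserving`` randomizes by connected double-edge swaps
    (swap_multiplier × edge-count swaps per realization, failed windows
    undone); ``er`` draws connected Erdős–Rényi graphs with the same node and
    edge counts. Every realization has the same degree sequence as ``g`` in
    degree-preserving mode. Identical seeds give identical ensembles.
    """
    if n_null < 1:
        raise DataError("n_null must be >= 1")
    if null_model not in ("degree_preserving", "er"):
        raise DataError(f"unknown null model {null_model!r}")
    adj = _adj(g)
    n = adj.shape[0]
    if not _kernels.dense_connected(adj, n):
        raise DataError("null normalization requires a connected graph")
    iu, ju = np.nonzero(np.triu(adj, 1))
    edges = np.stack([iu, ju], axis=1).astype(np.int64)
    cpr, lpr, ok = _kernels.null_cp_lp(
        edges,
        n,
        n_null,
        swap_multiplier * edges.shape[0],
        int(seed) & 0x7FFFFFFF,
        1 if null_model == "er" else 0,
    )
    if ok == 0.0:
        raise DataError(
            "null ensemble failed: could not keep randomized graphs connected "
            "within the swap/resample budget"
        )
    return float(cpr), float(lpr)


def randomize_degree_preserving(
    g: GraphLike, seed: int = 0, swap_multiplier: int = 10
) -> BinaryGraph:
    """One degree-preserving, connectivity-preserving randomization of ``g``.

    Applies swap_multiplier x edge-count double-edge swaps (failed windows
    undone), i.e. a single realization of the null ensemble behind γ/λ.
    """
    adj = _adj(g).copy()
    n = adj.shape[0]
    if not _kernels.dense_connected(adj, n):
        raise DataError("randomization requires a connected graph")
    iu, ju = np.nonzero(np.triu(adj, 1))
    edges = np.stack([iu, ju], axis=1).astype(np.int64)
    ok = _kernels.connected_swap(
        adj, edges, swap_multiplier * edges.shape[0], int(seed) & 0x7FFFFFFF
    )
    if ok == 0.0:
        raise DataError("could not keep the randomized graph connected")
    return BinaryGraph(adjacency=adj)


def small_world(cp: float, lp: float, cprand: float, lprand: float) -> tuple[float, float, float]:
    """(γ, λ, σ) = (cp/cprand, lp/lprand, γ/λ)."""
    if not (cprand > 0 and lprand > 0):
        raise DataError(f"null means must be positive, got cprand={cprand}, lprand={lprand}")
    gamma = cp / cprand
    lam = lp / lprand
    return gamma, lam, gamma / lam


def global_metrics(
    g: GraphLike,
    n_null: int = 20,
    seed: int = 0,
    null_model: str = "degree_preserving",
) -> GlobalMetrics:
    """All global metrics of one graph, including γ/λ/σ."""
    cp = clustering_coefficient(g)
    lp = characteristic_path_length(g)
    cprand, lprand = random_null_ensemble(g, n_null=n_null, seed=seed, null_model=null_model)
    gamma, lam, sigma = small_world(cp, lp, cprand, lprand)
    return GlobalMetrics(
        cp=cp,
        lp=lp,
        eglob=global_efficiency(g),
        eloc=local_efficiency(g),
        assort=assortativity(g),
        trans=transitivity(g),
        q=modularity(g),
        cprand=cprand,
        lprand=lprand,
        gamma=gamma,
        lam=lam,
        sigma=sigma,
    )
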
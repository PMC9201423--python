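"""Network resilience: targeted-attack and random-failure curves.

Resilience is the tolerance of the largest connected component to sequential
node removal: *targeted attack* removes nodes in descending order of
betweenness centrality ranked once on the intact graph (ties by index),
*random failure* averages over uniformly random removal orders. After each
removal the relative size of the largest remaining component is recorded,
with the original node count as the denominator, so curves start at 1 for a
connected graph and end at 0 when every node is gone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .errors import DataError
from .inference import PermutationConfig, _run_permutations
from .network import BinaryGraph, edge_count_for_density, rank_edges, _residualize_arrays
from .synthetic import CohortTable

__all__ = [
    "ResilienceCurve",
    "ResilienceComparisonResult",
    "targeted_attack_curve",
    "random_failure_curve",
    "resilience_comparison",
]


@dataclass
class ResilienceCurve:
    """Relative largest-component size against the fraction of nodes removed."""

    fraction_removed: np.ndarray  # length n+1, 0 … 1
    rel_lcc: np.ndarray
    mode: str  # "targeted" | "random"
    n_iter: int = 1

    def auc(self) -> float:
        return float(np.trapezoid(self.rel_lcc, self.fraction_removed))


@dataclass
class ResilienceComparisonResult:
    """Permutation comparison of two groups' resilience curves."""

    groups: tuple[str, str]
    mode: str
    reference_density: float
    fraction_removed: np.ndarray
    curve_a: np.ndarray
    curve_b: np.ndarray
    per_fraction_p: np.ndarray
    auc_a: float
    auc_b: float
    auc_diff: float
    auc_p: float
    n_perm: int = 0
    seed: int = 0
    n_resampled: int = 0


def _attack_order(adj: np.ndarray) -> np.ndarray:
    indptr, indices = _kernels.build_csr(adj, adj.shape[0])
    bc = np.asarray(_kernels.betweenness(indptr, indices, adj.shape[0]))
    return np.argsort(-bc, kind="stable")


def targeted_attack_curve(g: BinaryGraph) -> ResilienceCurve:
    """Remove nodes in descending intact-graph betweenness order."""
    adj = g.adjacency
    n = g.n_nodes
    order = _attack_order(adj)
    indptr, indices = _kernels.build_csr(adj, n)
    curve = np.asarray(_kernels.lcc_curve(indptr, indices, n, order))
    return ResilienceCurve(
        fraction_removed=np.arange(n + 1) / n,
        rel_lcc=curve,
        mode="targeted",
    )


def random_failure_curve(g: BinaryGraph, n_iter: int = 50, seed: int = 0) -> ResilienceCurve:
    """Mean curve over ``n_iter`` uniformly random removal orders."""
    if n_iter < 1:
        raise DataError("n_iter must be >= 1")
    n = g.n_nodes
    indptr, indices = _kernels.build_csr(g.adjacency, n)
    curve = np.asarray(
        _kernels.random_failure_mean(indptr, indices, n, n_iter, int(seed) & 0x7FFFFFFF)
    )
    return ResilienceCurve(
        fraction_removed=np.arange(n + 1) / n,
        rel_lcc=curve,
        mode="random",
        n_iter=n_iter,
    )


def _graph_at_density(
    vols: np.ndarray, tiv: np.ndarray, density: float, n_edges: int, mode: str
) -> tuple[np.ndarray, bool]:
    resid = _residualize_arrays(vols, tiv)
    corr = np.corrcoef(resid)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    eu, ev = rank_edges(corr, mode)
    n = corr.shape[0]
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[eu[:n_edges], ev[:n_edges]] = 1
    adj[ev[:n_edges], eu[:n_edges]] = 1
    return adj, bool(_kernels.dense_connected(adj, n))


def resilience_comparison(
    cohort: CohortTable,
    config: PermutationConfig,
    mode: str = "targeted",
    reference_density: Optional[float] = None,
    n_iter: int = 50,
) -> ResilienceComparisonResult:
    """Permutation test on resilience curves at one reference density.

    The curves are compared at ``reference_density`` (default: the grid's
    minimum density, where connectivity is guaranteed by construction) both
    pointwise per removal fraction and via the curve AUC, with the same
    label-permutation engine and add-one two-tailed p-rule as the metric
    comparison.
    """
    if mode not in ("targeted", "random"):
        raise DataError(f"mode must be 'targeted' or 'random', got {mode!r}")
    cfg = config
    d_ref = reference_density if reference_density is not None else cfg.densities.d_min
    ga, gb = cohort.groups
    grp = cohort.data["group"].astype(str).to_numpy()
    vols = cohort.volumes()
    tiv = cohort.tiv()
    idx_a0 = np.flatnonzero(grp == ga)
    idx_b0 = np.flatnonzero(grp == gb)
    n = vols.shape[1]
    n_edges = edge_count_for_density(n, d_ref)
    fractions = np.arange(n + 1) / n

    def curve_for(adj: np.ndarray, seed: int) -> np.ndarray:
        indptr, indices = _kernels.build_csr(adj, n)
        if mode == "targeted":
            return np.asarray(_kernels.lcc_curve(indptr, indices, n, _attack_order(adj)))
        return np.asarray(_kernels.random_failure_mean(indptr, indices, n, n_iter, seed))

    def evaluate(idx_a, idx_b, seed_a, seed_b):
        adj_a, ok_a = _graph_at_density(
            vols[idx_a], tiv[idx_a], d_ref, n_edges, cfg.threshold_mode
        )
        if not ok_a:
            return np.empty(0), False, None
        adj_b, ok_b = _graph_at_density(
            vols[idx_b], tiv[idx_b], d_ref, n_edges, cfg.threshold_mode
        )
        if not ok_b:
            return np.empty(0), False, None
        # common random removal orders for both groups (paired Monte Carlo):
        # identical graphs then give identical curves, and the comparison
        # variance shrinks
        ca = curve_for(adj_a, seed_a)
        cb = curve_for(adj_b, seed_a)
        auc_a = float(np.trapezoid(ca, fractions))
        auc_b = float(np.trapezoid(cb, fractions))
        stat = np.concatenate([cb - ca, [auc_b - auc_a]])
        return stat, True, (ca, cb, auc_a, auc_b)

    obs, extras, p, n_resampled = _run_permutations(
        len(grp), idx_a0, idx_b0, cfg, evaluate
    )
    ca, cb, auc_a, auc_b = extras
    return ResilienceComparisonResult(
        groups=(ga, gb),
        mode=mode,
        reference_density=float(d_ref),
        fraction_removed=fractions,
        curve_a=ca,
        curve_b=cb,
        per_fraction_p=p[:-1],
        auc_a=auc_a,
        auc_b=auc_b,
        auc_diff=auc_b - auc_a,
        auc_p=float(p[-1]),
        n_perm=cfg.n_perm,
        seed=cfg.seed,
        n_resampled=n_resampled,
    )
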
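"""From per-group volume tables to binary covariance graphs.

The group-level structural covariance network is built in three steps:
regional volumes are residualized on total intracranial volume (ordinary
least squares, per region), residuals are correlated across subjects to give
a region×region Pearson association matrix, and the matrix is binarized by
keeping the strongest correlations at a target edge density. Densities run
over a fixed grid (default 0.27–0.50 in steps of 0.01); thresholding is
rank-based, so edge sets are nested across the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from . import _kernels
from .errors import ConfigError, DataError
from .synthetic import CohortTable

__all__ = [
    "DensityGrid",
    "AssociationMatrix",
    "BinaryGraph",
    "residualize_tiv",
    "build_association",
    "rank_edges",
    "edge_count_for_density",
    "threshold_by_density",
    "find_dmin",
]


@dataclass(frozen=True)
class DensityGrid:
    """Inclusive, evenly spaced density grid (defaults: 0.27:0.01:0.50)."""

    d_min: float = 0.27
    d_max: float = 0.50
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.d_min <= self.d_max <= 1.0):
            raise ConfigError(f"need 0 < d_min <= d_max <= 1, got {self}")
        if self.step <= 0:
            raise ConfigError("step must be positive")

    @property
    def points(self) -> np.ndarray:
        n = int(round((self.d_max - self.d_min) / self.step)) + 1
        return np.round(self.d_min + self.step * np.arange(n), 10)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class AssociationMatrix:
    """Symmetric region×region Pearson correlation matrix for one group.

    The diagonal is stored as 0 by convention and is never edge-eligible.
    """

    values: np.ndarray
    n_subjects: int
    group: str = ""
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError(f"association matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DataError("association matrix must be symmetric")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (np.abs(off) > 1.0 + 1e-12).any():
            raise DataError("correlations must lie in [-1, 1]")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryGraph:
    """Undirected, unweighted graph as a symmetric 0/1 adjacency matrix."""

    adjacency: np.ndarray
    density: float = 0.0

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise DataError(f"adjacency must be square, got {a.shape}")
        a = (a != 0).astype(np.uint8)
        if (np.diag(a) != 0).any():
            raise DataError("adjacency must have a zero diagonal")
        if not (a == a.T).all():
            raise DataError("adjacency must be symmetric")
        self.adjacency = a
        if self.density == 0.0 and a.shape[0] > 1:
            n = a.shape[0]
            self.density = float(a.sum() / (n * (n - 1)))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def is_connected(self) -> bool:
        return bool(_kernels.dense_connected(self.adjacency, self.n_nodes))


def _residualize_arrays(volumes: np.ndarray, tiv: np.ndarray) -> np.ndarray:
    """OLS residuals of every region on TIV (with intercept).

    volumes: (n_subjects, n_regions); returns (n_regions, n_subjects).
    """
    n = volumes.shape[0]
    if n < 3:
        raise DataError(f"need at least 3 subjects to residualize, got {n}")
    t = tiv - tiv.mean()
    stt = float(t @ t)
    if stt <= 1e-12 * max(1.0, float(np.abs(tiv).max()) ** 2):
        raise DataError("TIV is constant; cannot regress it out")
    vc = volumes - volumes.mean(axis=0, keepdims=True)
    beta = (t @ vc) / stt
    resid = vc - np.outer(t, beta)
    return resid.T


def residualize_tiv(
    cohort: Union[CohortTable, np.ndarray],
    group: Optional[str] = None,
    tiv: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Remove the TIV confound from regional volumes by linear regression.

    Accepts a CohortTable (optionally restricted to one group) or a raw
    (n_subjects, n_regions) array plus a TIV vector. Returns the
    region×subject residual matrix; residuals have zero mean and zero sample
    correlation with TIV by construction.
    """
    if isinstance(cohort, CohortTable):
        return _residualize_arrays(cohort.volumes(group), cohort.tiv(group))
    if tiv is None:
        raise ConfigError("tiv vector required when passing a raw volume array")
    return _residualize_arrays(np.asarray(cohort, dtype=np.float64), np.asarray(tiv, dtype=np.float64))


def build_association(
    residuals: np.ndarray,
    n_subjects: Optional[int] = None,
    group: str = "",
    labels: Optional[tuple[str, ...]] = None,
) -> AssociationMatrix:
    """Pearson correlations between region residual vectors.

    residuals: (n_regions, n_subjects). The diagonal is set to 0.
    """
    r = np.asarray(residuals, dtype=np.float64)
    if r.ndim != 2:
        raise DataError("residuals must be a region×subject matrix")
    if r.shape[1] < 3:
        raise DataError(f"need at least 3 subjects, got {r.shape[1]}")
    sd = r.std(axis=1)
    zero = np.flatnonzero(sd <= 0)
    if zero.size:
        names = [labels[i] if labels else f"region {i}" for i in zero]
        raise DataError(f"zero-variance regions: {names}")
    corr = np.corrcoef(r)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return AssociationMatrix(
        values=corr,
        n_subjects=n_subjects if n_subjects is not None else r.shape[1],
        group=group,
        labels=labels,
    )


def edge_count_for_density(n_nodes: int, density: float) -> int:
    """round-half-away-from-zero of density × n(n−1)/2."""
    return int(math.floor(density * n_nodes * (n_nodes - 1) / 2.0 + 0.5))


def rank_edges(values: np.ndarray, mode: str = "signed") -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs ordered strongest-first.

    ``signed`` ranks by the signed correlation (most positive first, the
    covariance-toolbox convention); ``absolute`` ranks by magnitude. Ties are
    broken by ascending (row, column) index via a stable sort, making the
    ranking — and hence every thresholded graph — deterministic.
    """
    if mode not in ("signed", "absolute"):
        raise ConfigError(f"threshold mode must be 'signed' or 'absolute', got {mode!r}")
    n = values.shape[0]
    iu, ju = np.triu_indices(n, 1)
    vals = values[iu, ju]
    key = -np.abs(vals) if mode == "absolute" else -vals
    order = np.argsort(key, kind="stable")
    return iu[order], ju[order]


def threshold_by_density(
    assoc: AssociationMatrix, density: float, mode: str = "signed"
) -> BinaryGraph:
    """Keep exactly round(d·N(N−1)/2) strongest edges as a binary graph."""
    if not (0.0 < density <= 1.0):
        raise ConfigError(f"density must be in (0, 1], got {density}")
    n = assoc.size
    n_pairs = n * (n - 1) // 2
    n_edges = edge_count_for_density(n, density)
    if n_edges < 1:
        raise DataError(f"density {density} keeps no edges on {n} nodes")
    if n_edges > n_pairs:
        raise DataError(f"density {density} demands {n_edges} edges but only {n_pairs} pairs exist")
    eu, ev = rank_edges(assoc.values, mode)
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[eu[:n_edges], ev[:n_edges]] = 1
    adj[ev[:n_edges], eu[:n_edges]] = 1
    return BinaryGraph(adjacency=adj, density=density)


def find_dmin(
    assoc_a: AssociationMatrix,
    assoc_b: AssociationMatrix,
    grid_step: float = 0.01,
    d_max: float = 0.50,
    mode: str = "signed",
) -> float:
    """Smallest grid density at which both groups' graphs are connected.

    Walks d = grid_step, 2·grid_step, ... up to d_max and returns the first
    density where both thresholded graphs form a single connected component.
    """
    if assoc_a.size != assoc_b.size:
        raise DataError(
            f"association matrices differ in size: {assoc_a.size} vs {assoc_b.size}"
        )
    n = assoc_a.size
    best_d, best_frac = 0.0, 0.0
    k = 1
    while True:
        d = round(k * grid_step, 10)
        if d > d_max + 1e-12:
            break
        k += 1
        n_edges = edge_count_for_density(n, d)
        if n_edges < 1:
            continue
        if n_edges > n * (n - 1) // 2:
            break
        ga = threshold_by_density(assoc_a, d, mode)
        gb = threshold_by_density(assoc_b, d, mode)
        if ga.is_connected() and gb.is_connected():
            return d
        frac = min(_lcc_fraction(ga), _lcc_fraction(gb))
        if frac > best_frac:
            best_frac, best_d = frac, d
    raise DataError(
        f"no density <= {d_max} connects both groups; best density {best_d} "
        f"reaches a largest component of {best_frac:.2f} of nodes"
    )


def _lcc_fraction(g: BinaryGraph) -> float:
    indptr, indices = _kernels.build_csr(g.adjacency, g.n_nodes)
    curve = _kernels.lcc_curve(indptr, indices, g.n_nodes, np.arange(g.n_nodes))
    return float(curve[0])
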
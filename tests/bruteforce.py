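"""Independent brute-force oracles for graph metrics.

Everything here is written for clarity on tiny graphs (enumeration,
Floyd–Warshall, exhaustive partition search) and deliberately shares no code
with the package's compiled kernels.
"""

from itertools import combinations

import numpy as np

INF = float("inf")


# ---------------------------------------------------------------------------
# graph constructions


def complete_graph(n: int) -> np.ndarray:
    a = np.ones((n, n), dtype=np.uint8)
    np.fill_diagonal(a, 0)
    return a


def star_graph(n_leaves: int) -> np.ndarray:
    a = np.zeros((n_leaves + 1, n_leaves + 1), dtype=np.uint8)
    a[0, 1:] = 1
    a[1:, 0] = 1
    return a


def path_graph(n: int) -> np.ndarray:
    a = np.zeros((n, n), dtype=np.uint8)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return a


def ring_lattice(n: int, k: int) -> np.ndarray:
    """Ring of n nodes, each linked to its k nearest neighbours (k even)."""
    a = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        for d in range(1, k // 2 + 1):
            j = (i + d) % n
            a[i, j] = a[j, i] = 1
    return a


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, 1)
    return a + a.T


# ---------------------------------------------------------------------------
# metric oracles


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    d[adj > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def bf_clustering(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for v in range(n):
        nbrs = np.flatnonzero(adj[v])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(adj[a, b] for a, b in combinations(nbrs, 2))
        total += 2.0 * links / (k * (k - 1))
    return total / n


def bf_transitivity(adj: np.ndarray) -> float:
    n = adj.shape[0]
    triangles = 0
    triples = 0
    for v in range(n):
        nbrs = np.flatnonzero(adj[v])
        k = len(nbrs)
        triples += k * (k - 1) // 2
        triangles += sum(adj[a, b] for a, b in combinations(nbrs, 2))
    return triangles / triples if triples else 0.0


def bf_path_length(adj: np.ndarray) -> float:
    """Mean pairwise distance; inf when disconnected."""
    d = floyd_warshall(adj)
    n = adj.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j]
    return float(np.mean(vals)) if vals else 0.0


def bf_global_efficiency(adj: np.ndarray) -> float:
    d = floyd_warshall(adj)
    n = adj.shape[0]
    if n < 2:
        return 0.0
    inv = [1.0 / d[i, j] if np.isfinite(d[i, j]) and d[i, j] > 0 else 0.0
           for i in range(n) for j in range(n) if i != j]
    return float(np.mean(inv))


def bf_local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for v in range(n):
        nbrs = np.flatnonzero(adj[v])
        if len(nbrs) < 2:
            continue
        total += bf_global_efficiency(adj[np.ix_(nbrs, nbrs)])
    return total / n


def bf_assortativity(adj: np.ndarray) -> float:
    deg = adj.sum(axis=1)
    xs, ys = [], []
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                xs.append(deg[i])
                ys.append(deg[j])
    if not xs:
        return float("nan")
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if np.var(xs) < 1e-12 or np.var(ys) < 1e-12:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def bf_betweenness(adj: np.ndarray) -> np.ndarray:
    """Exact betweenness by enumerating all shortest paths (tiny graphs)."""
    n = adj.shape[0]
    d = floyd_warshall(adj)
    bc = np.zeros(n)

    def shortest_paths(s, t):
        if not np.isfinite(d[s, t]):
            return []
        paths = []

        def extend(path):
            v = path[-1]
            if v == t:
                paths.append(path)
                return
            for w in np.flatnonzero(adj[v]):
                if d[s, w] == len(path) and d[w, t] == d[s, t] - len(path):
                    extend(path + [int(w)])

        extend([s])
        return paths

    for s in range(n):
        for t in range(s + 1, n):
            paths = shortest_paths(s, t)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def set_partitions(items):
    if len(items) == 1:
        yield [items]
        return
    first = items[0]
    for smaller in set_partitions(items[1:]):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [[first] + subset] + smaller[i + 1 :]
        yield [[first]] + smaller


def bf_modularity(adj: np.ndarray) -> float:
    """Maximum Newman–Girvan Q over all partitions (exhaustive)."""
    n = adj.shape[0]
    m = adj.sum() / 2.0
    deg = adj.sum(axis=1).astype(float)
    best = -np.inf
    for part in set_partitions(list(range(n))):
        q = 0.0
        for block in part:
            for i in block:
                for j in block:
                    q += adj[i, j] - deg[i] * deg[j] / (2.0 * m)
        best = max(best, q / (2.0 * m))
    return best


def bf_components(adj: np.ndarray, removed: set) -> list:
    """Connected components after deleting a node set (exhaustive search)."""
    n = adj.shape[0]
    alive = [v for v in range(n) if v not in removed]
    seen = set()
    comps = []
    for start in alive:
        if start in seen:
            continue
        stack = [start]
        comp = set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            for w in np.flatnonzero(adj[v]):
                if w not in removed and w not in comp:
                    stack.append(int(w))
        seen |= comp
        comps.append(comp)
    return comps


def bf_lcc_curve(adj: np.ndarray, order) -> np.ndarray:
    """Relative LCC size after each removal, denominator = original n."""
    n = adj.shape[0]
    curve = np.zeros(n + 1)
    removed = set()
    comps = bf_components(adj, removed)
    curve[0] = max(len(c) for c in comps) / n if comps else 0.0
    for k, v in enumerate(order, start=1):
        removed.add(int(v))
        comps = bf_components(adj, removed)
        curve[k] = max(len(c) for c in comps) / n if comps else 0.0
    return curve


def bf_bh(p: np.ndarray) -> np.ndarray:
    """Textbook Benjamini–Hochberg step-up with enforced monotonicity."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return np.minimum(adjusted, 1.0)
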
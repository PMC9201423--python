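"""Compiled graph kernels.

Everything the permutation engine touches per evaluation lives here as numba
``njit`` functions operating on dense uint8 adjacency matrices, CSR neighbor
lists and uint64 bitset rows: BFS path statistics, clustering/transitivity,
local efficiency, degree assortativity, Brandes betweenness, deterministic
modularity maximization, degree-preserving (connected double-edge-swap) and
Erdős–Rényi null ensembles, and largest-connected-component curves for
resilience. A group comparison re-runs these across 24 densities × 2 groups ×
(n_perm+1) evaluations, hence the emphasis on allocation-free, branch-light
inner loops; distances propagate level-by-level through 64-bit reachability
masks rather than per-source queues.

Graphs are simple and undirected: ``adj`` is symmetric with a zero diagonal.
Distances are BFS hop counts. Conventions that change numbers are noted on
each kernel (degree<2 nodes contribute 0 to clustering and local efficiency;
betweenness excludes endpoints and counts each unordered pair once).
"""

import numpy as np
from numba import njit

__all__ = [
    "build_csr",
    "build_bits",
    "path_stats",
    "clustering_transitivity",
    "local_efficiency",
    "assortativity",
    "betweenness",
    "modularity_partition",
    "connected_swap",
    "null_cp_lp",
    "dense_connected",
    "lcc_curve",
    "random_failure_mean",
    "grid_global",
    "grid_betweenness",
    "GLOBAL_COLS",
]

# Column layout of the grid_global output.
GLOBAL_COLS = ("cp", "lp", "eglob", "eloc", "assort", "trans", "q", "cprand", "lprand")

_ONE = np.uint64(1)
_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)
_S56 = np.uint64(56)
_S58 = np.uint64(58)
# De Bruijn multiply-shift table for isolating the lowest set bit's index
_DB = np.uint64(0x03F79D71B4CA8B09)
_DB_TABLE = np.zeros(64, np.int64)
for _i in range(64):
    _DB_TABLE[(((1 << _i) * 0x03F79D71B4CA8B09) % (1 << 64)) >> 58] = _i


@njit(cache=True, inline="always")
def _popcnt(x):
    x = x - ((x >> _ONE) & _M1)
    x = (x & _M2) + ((x >> np.uint64(2)) & _M2)
    x = (x + (x >> np.uint64(4))) & _M4
    return int((x * _H01) >> _S56)


@njit(cache=True)
def build_csr(adj, n):
    indptr = np.zeros(n + 1, np.int64)
    for i in range(n):
        d = 0
        for j in range(n):
            if adj[i, j]:
                d += 1
        indptr[i + 1] = indptr[i] + d
    indices = np.empty(indptr[n], np.int64)
    pos = 0
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                indices[pos] = j
                pos += 1
    return indptr, indices


@njit(cache=True)
def build_bits(adj, n):
    """Adjacency rows as uint64 bitsets: bits[v, t] holds neighbors 64t..64t+63."""
    n_words = (n + 63) // 64
    bits = np.zeros((n, n_words), np.uint64)
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                bits[i, j >> 6] |= _ONE << np.uint64(j & 63)
    return bits


@njit(cache=True)
def path_stats(indptr, indices, bits, n):
    """(lp, eglob, connected). lp is NaN when the graph is disconnected.

    Distance counts come from level-synchronous reachability propagation:
    reach_{L}[s] = union of reach_{L-1}[u] over neighbors u, so the number of
    nodes at distance exactly L is the popcount increment. Means run over all
    ordered pairs (equivalently unordered, by symmetry); unreachable pairs
    contribute 0 to global efficiency.
    """
    if n < 2:
        return (0.0, 0.0, True)
    n_words = bits.shape[1]
    cur = np.empty((n, n_words), np.uint64)
    nxt = np.empty((n, n_words), np.uint64)
    cnt = np.empty(n, np.int64)
    for s in range(n):
        for t in range(n_words):
            cur[s, t] = bits[s, t]
        cur[s, s >> 6] |= _ONE << np.uint64(s & 63)
        c = 0
        for t in range(n_words):
            c += _popcnt(cur[s, t])
        cnt[s] = c
    total = 0.0
    inv = 0.0
    for s in range(n):
        total += cnt[s] - 1
        inv += cnt[s] - 1.0
    level = 1
    while level < n:
        level += 1
        any_new = False
        for s in range(n):
            for t in range(n_words):
                nxt[s, t] = cur[s, t]
            for k in range(indptr[s], indptr[s + 1]):
                u = indices[k]
                for t in range(n_words):
                    nxt[s, t] |= cur[u, t]
        inv_l = 1.0 / level
        for s in range(n):
            c = 0
            for t in range(n_words):
                c += _popcnt(nxt[s, t])
            newly = c - cnt[s]
            if newly > 0:
                any_new = True
                total += level * newly
                inv += newly * inv_l
                cnt[s] = c
        tmp = cur
        cur = nxt
        nxt = tmp
        if not any_new:
            break
    connected = True
    for s in range(n):
        if cnt[s] < n:
            connected = False
            break
    pairs = n * (n - 1)
    lp = total / pairs if connected else np.nan
    return (lp, inv / pairs, connected)


@njit(cache=True)
def clustering_transitivity(indptr, indices, adj, n):
    """(mean clustering, transitivity); degree<2 nodes contribute 0 to Cp."""
    cp_sum = 0.0
    tri_sum = 0.0
    triple_sum = 0.0
    for v in range(n):
        k = indptr[v + 1] - indptr[v]
        if k < 2:
            continue
        t = 0
        for a in range(indptr[v], indptr[v + 1]):
            u = indices[a]
            for b in range(a + 1, indptr[v + 1]):
                if adj[u, indices[b]]:
                    t += 1
        cp_sum += 2.0 * t / (k * (k - 1.0))
        tri_sum += t
        triple_sum += k * (k - 1.0) / 2.0
    cp = cp_sum / n if n > 0 else 0.0
    trans = tri_sum / triple_sum if triple_sum > 0 else 0.0
    return (cp, trans)


@njit(cache=True)
def local_efficiency(indptr, indices, bits, n):
    """Mean over nodes of the efficiency of the neighbor-induced subgraph.

    Nodes with fewer than two neighbors contribute 0. Each neighborhood
    subgraph is rebuilt in local index space by extracting the set bits of
    ``bits[a] & bits[v]`` (De Bruijn lowest-bit indexing), then gets the same
    level-synchronous bitset propagation as path_stats — usually a single
    64-bit word per row — so all pairwise subgraph distances are exact
    without per-source queues.
    """
    n_words = bits.shape[1]
    nbr = np.empty(n, np.int64)
    loc = np.full(n, -1, np.int64)
    sub_indptr = np.empty(n + 1, np.int64)
    sub_indices = np.empty(n * n, np.int64)
    max_w = (n + 63) // 64
    cur = np.empty((n, max_w), np.uint64)
    nxt = np.empty((n, max_w), np.uint64)
    cur1 = np.empty(n, np.uint64)
    nxt1 = np.empty(n, np.uint64)
    cnt = np.empty(n, np.int64)
    total = 0.0
    for v in range(n):
        k = indptr[v + 1] - indptr[v]
        if k < 2:
            continue
        for a in range(k):
            nbr[a] = indices[indptr[v] + a]
            loc[nbr[a]] = a
        if k <= 64:
            # single-word fast path: one uint64 per subgraph row
            pos = 0
            sub_indptr[0] = 0
            for ai in range(k):
                a = nbr[ai]
                w = np.uint64(0)
                for t in range(n_words):
                    m = bits[a, t] & bits[v, t]
                    base = t << 6
                    while m:
                        b = m & (np.uint64(0) - m)
                        bi = loc[base + _DB_TABLE[int((b * _DB) >> _S58)]]
                        sub_indices[pos] = bi
                        pos += 1
                        w |= _ONE << np.uint64(bi)
                        m ^= b
                sub_indptr[ai + 1] = pos
                cur1[ai] = w | (_ONE << np.uint64(ai))
                cnt[ai] = _popcnt(cur1[ai])
            inv = 0.0
            for ai in range(k):
                inv += cnt[ai] - 1.0
            level = 1
            while level < k:
                level += 1
                any_new = False
                for ai in range(k):
                    acc = cur1[ai]
                    for c2 in range(sub_indptr[ai], sub_indptr[ai + 1]):
                        acc |= cur1[sub_indices[c2]]
                    nxt1[ai] = acc
                inv_l = 1.0 / level
                for ai in range(k):
                    c = _popcnt(nxt1[ai])
                    if c > cnt[ai]:
                        any_new = True
                        inv += (c - cnt[ai]) * inv_l
                        cnt[ai] = c
                    cur1[ai] = nxt1[ai]
                if not any_new:
                    break
            total += inv / (k * (k - 1.0))
        else:
            w_sub = (k + 63) // 64
            pos = 0
            sub_indptr[0] = 0
            for ai in range(k):
                for t in range(w_sub):
                    cur[ai, t] = np.uint64(0)
            for ai in range(k):
                a = nbr[ai]
                for t in range(n_words):
                    m = bits[a, t] & bits[v, t]
                    base = t << 6
                    while m:
                        b = m & (np.uint64(0) - m)
                        bi = loc[base + _DB_TABLE[int((b * _DB) >> _S58)]]
                        sub_indices[pos] = bi
                        pos += 1
                        cur[ai, bi >> 6] |= _ONE << np.uint64(bi & 63)
                        m ^= b
                sub_indptr[ai + 1] = pos
            inv = 0.0
            for ai in range(k):
                cur[ai, ai >> 6] |= _ONE << np.uint64(ai & 63)
                c = 0
                for t in range(w_sub):
                    c += _popcnt(cur[ai, t])
                cnt[ai] = c
                inv += c - 1.0
            level = 1
            while level < k:
                level += 1
                any_new = False
                for ai in range(k):
                    for t in range(w_sub):
                        nxt[ai, t] = cur[ai, t]
                    for c2 in range(sub_indptr[ai], sub_indptr[ai + 1]):
                        bi = sub_indices[c2]
                        for t in range(w_sub):
                            nxt[ai, t] |= cur[bi, t]
                inv_l = 1.0 / level
                for ai in range(k):
                    c = 0
                    for t in range(w_sub):
                        c += _popcnt(nxt[ai, t])
                    newly = c - cnt[ai]
                    if newly > 0:
                        any_new = True
                        inv += newly * inv_l
                        cnt[ai] = c
                tmp = cur
                cur = nxt
                nxt = tmp
                if not any_new:
                    break
            total += inv / (k * (k - 1.0))
        for a in range(k):
            loc[nbr[a]] = -1
    return total / n if n > 0 else 0.0


@njit(cache=True)
def assortativity(indptr, indices, n):
    """Newman degree assortativity; NaN when edge-end degrees have no variance."""
    sum_jk = 0.0
    sum_half = 0.0
    sum_sq = 0.0
    m = 0
    for v in range(n):
        kv = indptr[v + 1] - indptr[v]
        for a in range(indptr[v], indptr[v + 1]):
            w = indices[a]
            if w > v:
                kw = indptr[w + 1] - indptr[w]
                sum_jk += kv * kw
                sum_half += 0.5 * (kv + kw)
                sum_sq += 0.5 * (kv * kv + kw * kw)
                m += 1
    if m == 0:
        return np.nan
    mu = sum_half / m
    num = sum_jk / m - mu * mu
    den = sum_sq / m - mu * mu
    if den < 1e-12:
        return np.nan
    return num / den


@njit(cache=True)
def betweenness(indptr, indices, n):
    """Exact Brandes betweenness, endpoints excluded, unordered pairs."""
    bc = np.zeros(n, np.float64)
    dist = np.empty(n, np.int64)
    sigma = np.empty(n, np.float64)
    delta = np.empty(n, np.float64)
    order = np.empty(n, np.int64)
    for s in range(n):
        for i in range(n):
            dist[i] = -1
            sigma[i] = 0.0
            delta[i] = 0.0
        dist[s] = 0
        sigma[s] = 1.0
        order[0] = s
        head = 0
        tail = 1
        while head < tail:
            v = order[head]
            head += 1
            dv = dist[v]
            sv = sigma[v]
            for k in range(indptr[v], indptr[v + 1]):
                w = indices[k]
                if dist[w] < 0:
                    dist[w] = dv + 1
                    order[tail] = w
                    tail += 1
                if dist[w] == dv + 1:
                    sigma[w] += sv
        for idx in range(tail - 1, 0, -1):
            w = order[idx]
            coeff = (1.0 + delta[w]) / sigma[w]
            dw = dist[w]
            for k in range(indptr[w], indptr[w + 1]):
                v = indices[k]
                if dist[v] == dw - 1:
                    delta[v] += sigma[v] * coeff
            bc[w] += delta[w]
    for i in range(n):
        bc[i] *= 0.5
    return bc


@njit(cache=True)
def _partition_q(adj, deg, labels, n, m):
    q = 0.0
    two_m = 2.0 * m
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                a = 1.0 if adj[i, j] else 0.0
                q += a - deg[i] * deg[j] / two_m
    return q / two_m


@njit(cache=True)
def _exact_modularity(adj, n, m):
    """Exhaustive maximum-modularity partition for tiny graphs.

    Enumerates all set partitions as restricted growth strings in
    lexicographic order (first optimum wins, so ties are deterministic).
    Bell(8) = 4140 partitions keeps this instant for n <= 8.
    """
    deg = np.zeros(n, np.float64)
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                deg[i] += 1
    a = np.zeros(n, np.int64)
    b = np.zeros(n, np.int64)  # b[i] = max(a[0..i-1])
    best_q = -1e18
    best = np.zeros(n, np.int64)
    two_m = 2.0 * m
    while True:
        q = 0.0
        for i in range(n):
            for j in range(n):
                if a[i] == a[j]:
                    aa = 1.0 if adj[i, j] else 0.0
                    q += aa - deg[i] * deg[j] / two_m
        q /= two_m
        if q > best_q + 1e-15:
            best_q = q
            for i in range(n):
                best[i] = a[i]
        j2 = n - 1
        while j2 > 0 and a[j2] > b[j2]:
            j2 -= 1
        if j2 == 0:
            break
        a[j2] += 1
        nb = a[j2] if a[j2] > b[j2] else b[j2]
        for i in range(j2 + 1, n):
            a[i] = 0
            b[i] = nb
    return best_q, best


@njit(cache=True)
def modularity_partition(adj, indptr, indices, n, m):
    """Deterministic modularity maximization: (Q, labels).

    Exhaustive search for n <= 8; above that, index-order local node moves
    (including splitting a node off into a fresh singleton) alternated with
    greedy agglomeration (merge the community pair with the largest positive
    gain, ties broken by lowest indices) until neither phase improves.
    Fully deterministic.
    """
    if n <= 8:
        return _exact_modularity(adj, n, m)
    deg = np.zeros(n, np.float64)
    for i in range(n):
        deg[i] = indptr[i + 1] - indptr[i]
    labels = np.arange(n)
    deg_c = deg.copy()
    size_c = np.ones(n, np.int64)
    fm = float(m)
    two_m2 = 2.0 * fm * fm
    link = np.zeros(n, np.float64)  # scratch: node->community edge counts
    touched = np.empty(n, np.int64)
    W = np.empty((n, n), np.float64)

    for _round in range(60):
        changed = False

        # --- node-move phase (link counts over neighbor communities only)
        for _sweep in range(120):
            moved = False
            for v in range(n):
                a = labels[v]
                nt = 0
                for kidx in range(indptr[v], indptr[v + 1]):
                    c = labels[indices[kidx]]
                    if link[c] == 0.0:
                        touched[nt] = c
                        nt += 1
                    link[c] += 1.0
                deg_a_rest = deg_c[a] - deg[v]
                best_gain = 1e-12
                best_c = -1
                for ti in range(nt):
                    c = touched[ti]
                    if c == a:
                        continue
                    gain = (link[c] - link[a]) / fm - deg[v] * (
                        deg_c[c] - deg_a_rest
                    ) / two_m2
                    if gain > best_gain or (gain == best_gain and 0 <= best_c and c < best_c):
                        best_gain = gain
                        best_c = c
                if size_c[a] > 1:
                    gain = (0.0 - link[a]) / fm + deg[v] * deg_a_rest / two_m2
                    if gain > best_gain:
                        for c in range(n):
                            if size_c[c] == 0:
                                best_gain = gain
                                best_c = c
                                break
                for ti in range(nt):
                    link[touched[ti]] = 0.0
                if best_c >= 0:
                    labels[v] = best_c
                    deg_c[a] -= deg[v]
                    size_c[a] -= 1
                    deg_c[best_c] += deg[v]
                    size_c[best_c] += 1
                    moved = True
                    changed = True
            if not moved:
                break

        # --- merge phase: community-pair weights rebuilt, then kept current
        for i in range(n):
            for j in range(n):
                W[i, j] = 0.0
        for i in range(n):
            for kidx in range(indptr[i], indptr[i + 1]):
                W[labels[i], labels[indices[kidx]]] += 1.0
        while True:
            best = 1e-12
            bc_ = -1
            bd_ = -1
            for c in range(n):
                if size_c[c] == 0:
                    continue
                for d in range(c + 1, n):
                    if size_c[d] == 0 or W[c, d] <= 0.0:
                        continue
                    gain = W[c, d] / fm - deg_c[c] * deg_c[d] / two_m2
                    if gain > best:
                        best = gain
                        bc_ = c
                        bd_ = d
            if bc_ < 0:
                break
            changed = True
            W[bc_, bc_] += W[bd_, bd_] + 2.0 * W[bc_, bd_]
            for x in range(n):
                if x == bc_ or x == bd_:
                    continue
                W[bc_, x] += W[bd_, x]
                W[x, bc_] += W[x, bd_]
            for x in range(n):
                W[bd_, x] = 0.0
                W[x, bd_] = 0.0
            W[bc_, bd_] = 0.0
            W[bd_, bc_] = 0.0
            deg_c[bc_] += deg_c[bd_]
            size_c[bc_] += size_c[bd_]
            deg_c[bd_] = 0.0
            size_c[bd_] = 0
            for i in range(n):
                if labels[i] == bd_:
                    labels[i] = bc_

        if not changed:
            break

    q = _partition_q(adj, deg, labels, n, m)
    return q, labels


@njit(cache=True)
def dense_connected(adj, n):
    if n == 0:
        return True
    seen = np.zeros(n, np.uint8)
    queue = np.empty(n, np.int64)
    seen[0] = 1
    queue[0] = 0
    head = 0
    tail = 1
    while head < tail:
        v = queue[head]
        head += 1
        for w in range(n):
            if adj[v, w] and not seen[w]:
                seen[w] = 1
                queue[tail] = w
                tail += 1
    return tail == n


_XS_MULT = np.uint64(0x2545F4914F6CDD1D)
_SM_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SM_M1 = np.uint64(0xBF58476D1CE4E5B9)
_SM_M2 = np.uint64(0x94D049BB133111EB)


@njit(cache=True, inline="always")
def _seed_state(seed):
    # splitmix64 step so small integer seeds yield well-mixed xorshift states
    z = np.uint64(seed) + _SM_GAMMA
    z = (z ^ (z >> np.uint64(30))) * _SM_M1
    z = (z ^ (z >> np.uint64(27))) * _SM_M2
    z = z ^ (z >> np.uint64(31))
    if z == np.uint64(0):  # xorshift64* needs a nonzero state
        z = _SM_GAMMA
    return z


@njit(cache=True, inline="always")
def _xs_next(state):
    # xorshift64*: returns (new_state, 64 random bits)
    s = state
    s ^= s >> np.uint64(12)
    s ^= s << np.uint64(25)
    s ^= s >> np.uint64(27)
    return s, s * _XS_MULT


@njit(cache=True)
def _er_edges(n, n_edges):
    """Uniform simple graph with exactly n_edges edges (partial Fisher–Yates)."""
    n_pairs = n * (n - 1) // 2
    pool = np.empty(n_pairs, np.int64)
    for i in range(n_pairs):
        pool[i] = i
    edges = np.empty((n_edges, 2), np.int64)
    for e in range(n_edges):
        j = e + np.random.randint(n_pairs - e)
        tmp = pool[e]
        pool[e] = pool[j]
        pool[j] = tmp
        p = pool[e]
        # invert the row-major upper-triangle pair index
        i = 0
        rem = p
        row_len = n - 1
        while rem >= row_len:
            rem -= row_len
            i += 1
            row_len -= 1
        edges[e, 0] = i
        edges[e, 1] = i + 1 + rem
    return edges


@njit(cache=True)
def connected_swap(adj, edges, nswap, seed):
    """Randomize a connected graph in place by nswap double-edge swaps.

    Degree sequence and connectivity are preserved: swaps run in a window
    that doubles after each passed connectivity check and is undone and
    halved when a check fails (Gkantsidis-style). Returns 1.0 on success,
    0.0 when the attempt budget is exhausted (e.g. trees, where most swaps
    disconnect the graph).
    """
    n = adj.shape[0]
    n_edges = edges.shape[0]
    ne64 = np.uint64(n_edges)
    state = _seed_state(seed)
    log = np.empty((1024, 6), np.int64)
    swaps = 0
    attempts = 0
    max_attempts = 100 * nswap + 10000
    window = 1
    while swaps < nswap:
        done = 0
        while done < window and swaps + done < nswap:
            attempts += 1
            if attempts > max_attempts:
                return 0.0
            state, r1 = _xs_next(state)
            state, r2 = _xs_next(state)
            # Lemire multiply-shift maps 32 random bits onto [0, n_edges)
            i = int(((r1 >> np.uint64(32)) * ne64) >> np.uint64(32))
            j = int(((r2 >> np.uint64(32)) * ne64) >> np.uint64(32))
            if i == j:
                continue
            b1 = int((r1 >> np.uint64(13)) & _ONE)
            b2 = int((r2 >> np.uint64(13)) & _ONE)
            u = edges[i, b1]
            v = edges[i, 1 - b1]
            x = edges[j, b2]
            y = edges[j, 1 - b2]
            if (u == x) | (u == y) | (v == x) | (v == y):
                continue
            if adj[u, x] | adj[v, y]:
                continue
            adj[u, v] = 0
            adj[v, u] = 0
            adj[x, y] = 0
            adj[y, x] = 0
            adj[u, x] = 1
            adj[x, u] = 1
            adj[v, y] = 1
            adj[y, v] = 1
            edges[i, 0] = u
            edges[i, 1] = x
            edges[j, 0] = v
            edges[j, 1] = y
            log[done, 0] = i
            log[done, 1] = j
            log[done, 2] = u
            log[done, 3] = v
            log[done, 4] = x
            log[done, 5] = y
            done += 1
        if dense_connected(adj, n):
            swaps += done
            if window < 1024:
                window *= 2
        else:
            for z in range(done - 1, -1, -1):
                i = log[z, 0]
                j = log[z, 1]
                u = log[z, 2]
                v = log[z, 3]
                x = log[z, 4]
                y = log[z, 5]
                adj[u, x] = 0
                adj[x, u] = 0
                adj[v, y] = 0
                adj[y, v] = 0
                adj[u, v] = 1
                adj[v, u] = 1
                adj[x, y] = 1
                adj[y, x] = 1
                edges[i, 0] = u
                edges[i, 1] = v
                edges[j, 0] = x
                edges[j, 1] = y
            window = max(window // 2, 1)
    return 1.0


@njit(cache=True)
def null_cp_lp(edges0, n, n_null, nswap, seed, er_mode):
    """Mean (Cp, Lp) over a connected null ensemble; third slot is a status.

    Degree-preserving mode randomizes by connected double-edge swaps; ER
    mode draws connected Erdős–Rényi graphs with the same edge count.
    Returns status 0.0 when the swap/resample budget is exhausted.
    """
    np.random.seed(seed)
    n_edges = edges0.shape[0]
    adj = np.zeros((n, n), np.uint8)
    edges = edges0.copy()
    cp_acc = 0.0
    lp_acc = 0.0
    for _t in range(n_null):
        if er_mode:
            ok = False
            for _try in range(200):
                adj[:, :] = 0
                edges = _er_edges(n, n_edges)
                for e in range(n_edges):
                    adj[edges[e, 0], edges[e, 1]] = 1
                    adj[edges[e, 1], edges[e, 0]] = 1
                if dense_connected(adj, n):
                    ok = True
                    break
            if not ok:
                return (np.nan, np.nan, 0.0)
        else:
            adj[:, :] = 0
            for e in range(n_edges):
                edges[e, 0] = edges0[e, 0]
                edges[e, 1] = edges0[e, 1]
                adj[edges[e, 0], edges[e, 1]] = 1
                adj[edges[e, 1], edges[e, 0]] = 1
            if connected_swap(adj, edges, nswap, seed + 7919 * (_t + 1)) == 0.0:
                return (np.nan, np.nan, 0.0)
        indptr, indices = build_csr(adj, n)
        bits = build_bits(adj, n)
        cp_t, _trans = clustering_transitivity(indptr, indices, adj, n)
        lp_t, _eg, _conn = path_stats(indptr, indices, bits, n)
        cp_acc += cp_t
        lp_acc += lp_t
    return (cp_acc / n_null, lp_acc / n_null, 1.0)


@njit(cache=True)
def _uf_find(parent, v):
    while parent[v] != v:
        parent[v] = parent[parent[v]]
        v = parent[v]
    return v


@njit(cache=True)
def lcc_curve(indptr, indices, n, order):
    """Relative largest-component size after removing order[:k], k=0..n.

    Computed backwards with union–find: nodes are re-added from last removed
    to first. The denominator is the original node count n.
    """
    parent = np.arange(n)
    size = np.ones(n, np.int64)
    present = np.zeros(n, np.uint8)
    curve = np.zeros(n + 1, np.float64)
    best = 0
    for k in range(n - 1, -1, -1):
        v = order[k]
        present[v] = 1
        if best < 1:
            best = 1
        for a in range(indptr[v], indptr[v + 1]):
            w = indices[a]
            if present[w]:
                rv = _uf_find(parent, v)
                rw = _uf_find(parent, w)
                if rv != rw:
                    if size[rv] < size[rw]:
                        rv, rw = rw, rv
                    parent[rw] = rv
                    size[rv] += size[rw]
                    if size[rv] > best:
                        best = size[rv]
        curve[k] = best / n
    curve[n] = 0.0
    return curve


@njit(cache=True)
def random_failure_mean(indptr, indices, n, n_iter, seed):
    """Mean lcc_curve over n_iter uniformly random removal orders."""
    np.random.seed(seed)
    acc = np.zeros(n + 1, np.float64)
    order = np.empty(n, np.int64)
    for _it in range(n_iter):
        for i in range(n):
            order[i] = i
        for i in range(n - 1, 0, -1):
            j = np.random.randint(i + 1)
            tmp = order[i]
            order[i] = order[j]
            order[j] = tmp
        acc += lcc_curve(indptr, indices, n, order)
    return acc / n_iter


@njit(cache=True)
def grid_global(eu, ev, n, edge_counts, want, n_null, nswap_mult, seed):
    """Global metrics across a nested density grid.

    eu/ev: edge endpoints in rank order (strongest correlation first); the
    graph at grid point d contains the first edge_counts[d] of them.
    want: uint8 flags (cp, lp, eglob, eloc, assort, trans, q, nulls).
    Returns (out[d, 9] per GLOBAL_COLS, connected[d], status); status drops to
    0.0 if a null ensemble fails its swap budget.
    """
    n_d = edge_counts.shape[0]
    out = np.full((n_d, 9), np.nan)
    connected = np.zeros(n_d, np.uint8)
    adj = np.zeros((n, n), np.uint8)
    n_words = (n + 63) // 64
    bits = np.zeros((n, n_words), np.uint64)
    status = 1.0
    k = 0
    for di in range(n_d):
        n_edges = edge_counts[di]
        while k < n_edges:
            a = eu[k]
            b = ev[k]
            adj[a, b] = 1
            adj[b, a] = 1
            bits[a, b >> 6] |= _ONE << np.uint64(b & 63)
            bits[b, a >> 6] |= _ONE << np.uint64(a & 63)
            k += 1
        indptr, indices = build_csr(adj, n)
        lp, eglob, conn = path_stats(indptr, indices, bits, n)
        connected[di] = 1 if conn else 0
        out[di, 1] = lp
        out[di, 2] = eglob
        if want[0] or want[5]:
            cp, trans = clustering_transitivity(indptr, indices, adj, n)
            out[di, 0] = cp
            out[di, 5] = trans
        if want[3]:
            out[di, 3] = local_efficiency(indptr, indices, bits, n)
        if want[4]:
            out[di, 4] = assortativity(indptr, indices, n)
        if want[6]:
            q, _labels = modularity_partition(adj, indptr, indices, n, n_edges)
            out[di, 6] = q
        if want[7] and conn:
            edges = np.empty((n_edges, 2), np.int64)
            for e in range(n_edges):
                edges[e, 0] = eu[e]
                edges[e, 1] = ev[e]
            cpr, lpr, ok = null_cp_lp(
                edges, n, n_null, nswap_mult * n_edges, seed + di, 0
            )
            out[di, 7] = cpr
            out[di, 8] = lpr
            if ok == 0.0:
                status = 0.0
    return out, connected, status


@njit(cache=True)
def grid_betweenness(eu, ev, n, edge_counts):
    """Raw betweenness per node at every density of the nested grid."""
    n_d = edge_counts.shape[0]
    out = np.zeros((n_d, n), np.float64)
    adj = np.zeros((n, n), np.uint8)
    k = 0
    for di in range(n_d):
        n_edges = edge_counts[di]
        while k < n_edges:
            adj[eu[k], ev[k]] = 1
            adj[ev[k], eu[k]] = 1
            k += 1
        indptr, indices = build_csr(adj, n)
        out[di] = betweenness(indptr, indices, n)
    return out
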
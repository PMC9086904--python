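"""Numba-compiled inner loops.

Everything here is a plain-array kernel: no objects, no I/O. The public
modules wrap these with validation and typed containers. Each kernel has a
slow reference twin in the test suite (pure numpy / networkx / brute force)
so the compiled paths are never the only route to a number.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _kde_on_grid(samples, bandwidth, lo, step, n_grid, out):
    # Gaussian KDE evaluated at lo + k*step, k = 0..n_grid-1.
    # Normalization constants are dropped: masses are renormalized anyway.
    inv2h2 = 1.0 / (2.0 * bandwidth * bandwidth)
    for g in range(n_grid):
        x = lo + g * step
        acc = 0.0
        for s in range(samples.shape[0]):
            d = x - samples[s]
            acc += np.exp(-d * d * inv2h2)
        out[g] = acc


@njit(cache=True)
def _floor_normalize(mass, floor):
    total = 0.0
    for g in range(mass.shape[0]):
        total += mass[g]
    for g in range(mass.shape[0]):
        mass[g] = mass[g] / total
        if mass[g] < floor:
            mass[g] = floor
    total = 0.0
    for g in range(mass.shape[0]):
        total += mass[g]
    for g in range(mass.shape[0]):
        mass[g] /= total


@njit(cache=True)
def _symmetric_kl(p, q):
    kl = 0.0
    for g in range(p.shape[0]):
        kl += p[g] * np.log(p[g] / q[g]) + q[g] * np.log(q[g] / p[g])
    return kl


@njit(cache=True)
def kls_matrix(values, offsets, bandwidths, mins, maxs, n_grid, floor):
    """Full symmetric KLS matrix over ROIs stored as a ragged array.

    values: concatenated per-ROI sample vectors; ROI i occupies
    values[offsets[i]:offsets[i+1]]. For each unordered pair a shared grid
    of n_grid points spans the pooled sample range padded by 3 bandwidths.
    """
    n_roi = offsets.shape[0] - 1
    out = np.zeros((n_roi, n_roi))
    p = np.empty(n_grid)
    q = np.empty(n_grid)
    for i in range(n_roi):
        vi = values[offsets[i]:offsets[i + 1]]
        for j in range(i + 1, n_roi):
            vj = values[offsets[j]:offsets[j + 1]]
            h = max(bandwidths[i], bandwidths[j])
            lo = min(mins[i], mins[j]) - 3.0 * h
            hi = max(maxs[i], maxs[j]) + 3.0 * h
            step = (hi - lo) / (n_grid - 1)
            _kde_on_grid(vi, bandwidths[i], lo, step, n_grid, p)
            _kde_on_grid(vj, bandwidths[j], lo, step, n_grid, q)
            _floor_normalize(p, floor)
            _floor_normalize(q, floor)
            s = np.exp(-_symmetric_kl(p, q))
            out[i, j] = s
            out[j, i] = s
    return out


@njit(cache=True)
def kls_row(values, offsets, bandwidths, mins, maxs, target, n_grid, floor):
    """KLS of one target ROI against every other ROI (row of kls_matrix)."""
    n_roi = offsets.shape[0] - 1
    out = np.zeros(n_roi)
    p = np.empty(n_grid)
    q = np.empty(n_grid)
    vt = values[offsets[target]:offsets[target + 1]]
    for j in range(n_roi):
        if j == target:
            continue
        vj = values[offsets[j]:offsets[j + 1]]
        h = max(bandwidths[target], bandwidths[j])
        lo = min(mins[target], mins[j]) - 3.0 * h
        hi = max(maxs[target], maxs[j]) + 3.0 * h
        step = (hi - lo) / (n_grid - 1)
        _kde_on_grid(vt, bandwidths[target], lo, step, n_grid, p)
        _kde_on_grid(vj, bandwidths[j], lo, step, n_grid, q)
        _floor_normalize(p, floor)
        _floor_normalize(q, floor)
        out[j] = np.exp(-_symmetric_kl(p, q))
    return out


@njit(cache=True)
def rewire(edges, adj, n_attempts, seed):
    """Maslov-Sneppen degree-preserving rewiring, in place.

    edges is an (m, 2) int array; adj the matching 0/1 matrix. Returns the
    number of accepted swaps. Self-loops and multi-edges are rejected, so
    the degree sequence is invariant.
    """
    np.random.seed(seed)
    m = edges.shape[0]
    accepted = 0
    for _ in range(n_attempts):
        e1 = np.random.randint(0, m)
        e2 = np.random.randint(0, m)
        if e1 == e2:
            continue
        a = edges[e1, 0]
        b = edges[e1, 1]
        c = edges[e2, 0]
        d = edges[e2, 1]
        if np.random.randint(0, 2) == 1:
            c, d = d, c
        # proposed replacement: (a,b),(c,d) -> (a,d),(c,b)
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] == 1 or adj[c, b] == 1:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[c, b] = 1
        adj[b, c] = 1
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        accepted += 1
    return accepted


@njit(cache=True)
def _find_root(parent, x):
    root = x
    while parent[root] != root:
        root = parent[root]
    while parent[x] != root:
        nxt = parent[x]
        parent[x] = root
        x = nxt
    return root


@njit(cache=True)
def max_component_edges(n_nodes, eu, ev):
    """Largest connected component measured in edges, via union-find."""
    m = eu.shape[0]
    if m == 0:
        return 0
    parent = np.arange(n_nodes)
    for k in range(m):
        ru = _find_root(parent, eu[k])
        rv = _find_root(parent, ev[k])
        if ru != rv:
            parent[ru] = rv
    counts = np.zeros(n_nodes, dtype=np.int64)
    best = 0
    for k in range(m):
        r = _find_root(parent, eu[k])
        counts[r] += 1
        if counts[r] > best:
            best = counts[r]
    return best


@njit(cache=True)
def clustering_and_pathlength(adj):
    """(mean clustering, char. path length over connected pairs, all-connected flag).

    BFS from every node on a dense 0/1 adjacency. Used in the rewired-null
    loop where calling out to networkx per null would dominate runtime.
    """
    n = adj.shape[0]
    # clustering
    csum = 0.0
    for i in range(n):
        k = 0
        for j in range(n):
            k += adj[i, j]
        if k >= 2:
            tri = 0
            for a in range(n):
                if adj[i, a] == 0:
                    continue
                for b in range(a + 1, n):
                    if adj[i, b] == 1 and adj[a, b] == 1:
                        tri += 1
            csum += 2.0 * tri / (k * (k - 1))
    cp = csum / n
    # BFS all-pairs
    dist_sum = 0.0
    n_pairs = 0
    all_connected = True
    queue = np.empty(n, dtype=np.int64)
    dist = np.empty(n, dtype=np.int64)
    for src in range(n):
        for j in range(n):
            dist[j] = -1
        dist[src] = 0
        head = 0
        tail = 0
        queue[tail] = src
        tail += 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u]
            for v in range(n):
                if adj[u, v] == 1 and dist[v] < 0:
                    dist[v] = du + 1
                    queue[tail] = v
                    tail += 1
        for j in range(n):
            if j == src:
                continue
            if dist[j] > 0:
                dist_sum += dist[j]
                n_pairs += 1
            else:
                all_connected = False
    lp = dist_sum / n_pairs if n_pairs > 0 else np.inf
    return cp, lp, all_connected


@njit(cache=True)
def _neighbor_lists(adj):
    n = adj.shape[0]
    deg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for j in range(n):
            deg[i] += adj[i, j]
    indptr = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        indptr[i + 1] = indptr[i] + deg[i]
    indices = np.empty(indptr[n], dtype=np.int64)
    fill = indptr.copy()
    for i in range(n):
        for j in range(n):
            if adj[i, j] == 1:
                indices[fill[i]] = j
                fill[i] += 1
    return indptr, indices


@njit(cache=True)
def _bfs(indptr, indices, src, dist, queue):
    n = dist.shape[0]
    for j in range(n):
        dist[j] = -1
    dist[src] = 0
    head = 0
    tail = 0
    queue[tail] = src
    tail += 1
    while head < tail:
        u = queue[head]
        head += 1
        du = dist[u]
        for p in range(indptr[u], indptr[u + 1]):
            v = indices[p]
            if dist[v] < 0:
                dist[v] = du + 1
                queue[tail] = v
                tail += 1
    return tail


@njit(cache=True)
def graph_measures(adj):
    """(Eglob, Eloc, Cp, Lp, connected, degree, betweenness, nodal_eff).

    Single pass over a dense 0/1 adjacency using neighbor lists: BFS
    all-pairs for distances, Brandes accumulation for betweenness (pairs
    counted once, as in undirected conventions), triangle counting for
    clustering, and BFS on each neighbor-induced subgraph for Eloc.
    """
    n = adj.shape[0]
    indptr, indices = _neighbor_lists(adj)
    degree = np.empty(n, dtype=np.float64)
    for i in range(n):
        degree[i] = indptr[i + 1] - indptr[i]

    dist = np.empty(n, dtype=np.int64)
    queue = np.empty(n, dtype=np.int64)
    sigma = np.empty(n, dtype=np.float64)
    delta = np.empty(n, dtype=np.float64)
    betw = np.zeros(n, dtype=np.float64)
    nodal_eff = np.zeros(n, dtype=np.float64)

    dist_sum = 0.0
    n_reached = 0
    connected = True
    for s in range(n):
        # BFS with path counting
        for j in range(n):
            dist[j] = -1
            sigma[j] = 0.0
            delta[j] = 0.0
        dist[s] = 0
        sigma[s] = 1.0
        head = 0
        tail = 0
        queue[tail] = s
        tail += 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u]
            for p in range(indptr[u], indptr[u + 1]):
                v = indices[p]
                if dist[v] < 0:
                    dist[v] = du + 1
                    queue[tail] = v
                    tail += 1
                if dist[v] == du + 1:
                    sigma[v] += sigma[u]
        if tail < n:
            connected = False
        inv_sum = 0.0
        for j in range(n):
            if j != s and dist[j] > 0:
                dist_sum += dist[j]
                n_reached += 1
                inv_sum += 1.0 / dist[j]
        nodal_eff[s] = inv_sum / (n - 1) if n > 1 else 0.0
        # Brandes accumulation in reverse BFS order
        for qi in range(tail - 1, -1, -1):
            w = queue[qi]
            coeff = (1.0 + delta[w]) / sigma[w]
            for p in range(indptr[w], indptr[w + 1]):
                v = indices[p]
                if dist[v] == dist[w] - 1:
                    delta[v] += sigma[v] * coeff
            if w != s:
                betw[w] += delta[w]
    for i in range(n):
        betw[i] /= 2.0  # each unordered pair contributes from both endpoints

    eglob = 0.0
    for i in range(n):
        eglob += nodal_eff[i]
    eglob /= n
    lp = dist_sum / n_reached if n_reached > 0 else np.inf

    # clustering
    cp_sum = 0.0
    for i in range(n):
        k = indptr[i + 1] - indptr[i]
        if k >= 2:
            tri = 0
            for p in range(indptr[i], indptr[i + 1]):
                a = indices[p]
                for q in range(p + 1, indptr[i + 1]):
                    b = indices[q]
                    if adj[a, b] == 1:
                        tri += 1
            cp_sum += 2.0 * tri / (k * (k - 1))
    cp = cp_sum / n

    # local efficiency: Eglob of each neighbor-induced subgraph
    eloc_sum = 0.0
    sub_dist = np.empty(n, dtype=np.int64)
    sub_queue = np.empty(n, dtype=np.int64)
    for i in range(n):
        k = indptr[i + 1] - indptr[i]
        if k < 2:
            continue
        nb = indices[indptr[i]:indptr[i + 1]]
        sub = np.empty((k, k), dtype=np.uint8)
        has_edge = False
        for a in range(k):
            for b in range(k):
                sub[a, b] = adj[nb[a], nb[b]]
                if sub[a, b] == 1:
                    has_edge = True
        if not has_edge:
            continue
        sp, si = _neighbor_lists(sub)
        acc = 0.0
        for src in range(k):
            _bfs(sp, si, src, sub_dist[:k], sub_queue[:k])
            for j in range(k):
                if j != src and sub_dist[j] > 0:
                    acc += 1.0 / sub_dist[j]
        eloc_sum += acc / (k * (k - 1))
    eloc = eloc_sum / n

    return eglob, eloc, cp, lp, connected, degree, betw, nodal_eff


@njit(cache=True)
def cp_lp(adj):
    """(mean clustering, path length over connected pairs, connected flag).

    Cheap variant for the rewired-null loop.
    """
    n = adj.shape[0]
    indptr, indices = _neighbor_lists(adj)
    dist = np.empty(n, dtype=np.int64)
    queue = np.empty(n, dtype=np.int64)
    dist_sum = 0.0
    n_reached = 0
    connected = True
    for s in range(n):
        tail = _bfs(indptr, indices, s, dist, queue)
        if tail < n:
            connected = False
        for j in range(n):
            if j != s and dist[j] > 0:
                dist_sum += dist[j]
                n_reached += 1
    lp = dist_sum / n_reached if n_reached > 0 else np.inf
    cp_sum = 0.0
    for i in range(n):
        k = indptr[i + 1] - indptr[i]
        if k >= 2:
            tri = 0
            for p in range(indptr[i], indptr[i + 1]):
                a = indices[p]
                for q in range(p + 1, indptr[i + 1]):
                    b = indices[q]
                    if adj[a, b] == 1:
                        tri += 1
            cp_sum += 2.0 * tri / (k * (k - 1))
    return cp_sum / n, lp, connected
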
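"""Independent brute-force reference implementations used only by tests.

Deliberately naive: Floyd-Warshall distances, explicit shortest-path
enumeration for betweenness, direct triangle counting. These never share
code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

INF = float("inf")


def floyd_warshall(adj) -> list[list[float]]:
    n = len(adj)
    d = [[0.0 if i == j else (1.0 if adj[i][j] else INF) for j in range(n)]
         for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def global_efficiency(adj) -> float:
    n = len(adj)
    d = floyd_warshall(adj)
    total = sum(1.0 / d[i][j] for i in range(n) for j in range(n)
                if i != j and math.isfinite(d[i][j]))
    return total / (n * (n - 1))


def char_path_length(adj) -> float:
    n = len(adj)
    d = floyd_warshall(adj)
    finite = [d[i][j] for i in range(n) for j in range(n)
              if i != j and math.isfinite(d[i][j]) and d[i][j] > 0]
    return sum(finite) / len(finite)


def clustering(adj) -> float:
    n = len(adj)
    total = 0.0
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        k = len(nb)
        if k < 2:
            continue
        tri = sum(1 for a, b in itertools.combinations(nb, 2) if adj[a][b])
        total += 2.0 * tri / (k * (k - 1))
    return total / n


def local_efficiency(adj) -> float:
    n = len(adj)
    total = 0.0
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        if len(nb) < 2:
            continue
        sub = [[adj[a][b] for b in nb] for a in nb]
        if not any(any(row) for row in sub):
            continue
        total += global_efficiency(sub)
    return total / n


def nodal_efficiency(adj) -> list[float]:
    n = len(adj)
    d = floyd_warshall(adj)
    return [sum(1.0 / d[i][j] for j in range(n)
                if j != i and math.isfinite(d[i][j])) / (n - 1)
            for i in range(n)]


def _all_shortest_paths(adj, s, t, d):
    """Enumerate every shortest s-t path by depth-first descent."""
    if not math.isfinite(d[s][t]):
        return []
    paths = []

    def walk(node, trail):
        if node == t:
            paths.append(list(trail))
            return
        for nxt in range(len(adj)):
            if adj[node][nxt] and d[node][t] == d[nxt][t] + 1:
                trail.append(nxt)
                walk(nxt, trail)
                trail.pop()

    walk(s, [s])
    return paths


def betweenness(adj) -> list[float]:
    """Pair-counted betweenness via explicit shortest-path enumeration."""
    n = len(adj)
    d = floyd_warshall(adj)
    out = [0.0] * n
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(adj, s, t, d)
            if not paths:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                out[v] += through / len(paths)
    return out


def degrees(adj) -> list[int]:
    return [sum(row) for row in adj]


def random_adjacency(rng, n, p=0.5, ensure_edge=True):
    """Random symmetric 0/1 matrix as plain lists."""
    while True:
        adj = [[0] * n for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    adj[i][j] = adj[j][i] = 1
        if not ensure_edge or any(any(row) for row in adj):
            return adj


def components_by_hand(edges):
    """Connected components of an edge list, by repeated expansion."""
    edges = [tuple(sorted(e)) for e in edges]
    comps = []
    remaining = set(edges)
    while remaining:
        seed = remaining.pop()
        nodes = set(seed)
        comp = {seed}
        changed = True
        while changed:
            changed = False
            for e in list(remaining):
                if e[0] in nodes or e[1] in nodes:
                    comp.add(e)
                    nodes.update(e)
                    remaining.discard(e)
                    changed = True
        comps.append((frozenset(nodes), frozenset(comp)))
    return comps


def normal_pdf_density(mu, sigma, grid):
    """Discretized analytic normal as a (grid, mass) pair summing to 1."""
    mass = np.exp(-((grid - mu) ** 2) / (2 * sigma ** 2))
    return mass / mass.sum()
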
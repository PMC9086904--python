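"""Network-based statistics over stacks of subject KLS matrices.

Edgewise F (omnibus) or pooled-variance t (pairwise) statistics are
thresholded, the surviving edges are grouped into connected components, and
each observed component's edge count is tested against the permutation null
distribution of the maximal suprathreshold component size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels

TAILS = ("greater", "less", "omnibus")


@dataclass
class NbsConfig:
    f_threshold: float = 4.64
    t_threshold: float = 2.64
    n_perm: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    node_subset: list | None = None

    def __post_init__(self):
        if self.f_threshold <= 0 or self.t_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class Component:
    nodes: tuple
    edges: list            # list of (i, j) with i < j
    n_edges: int
    p_value: float = np.nan


@dataclass
class NbsResult:
    components: list
    direction: str
    threshold: float
    null_max_sizes: np.ndarray = field(repr=False, default=None)
    stat_matrix: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self):
        return [c for c in self.components if c.p_value < 0.05]


def _stack_to_edges(stack: np.ndarray):
    n_sub, n, _ = stack.shape
    iu, ju = np.triu_indices(n, 1)
    return stack[:, iu, ju], iu, ju


def _edge_f(flat: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Vectorized one-way F per edge; flat is (n_subjects, n_edges)."""
    n = flat.shape[0]
    k = sizes.size
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    grand = flat.mean(axis=0)
    ssb = np.zeros(flat.shape[1])
    ssw = np.zeros(flat.shape[1])
    for g in range(k):
        block = flat[bounds[g]:bounds[g + 1]]
        bm = block.mean(axis=0)
        ssb += block.shape[0] * (bm - grand) ** 2
        ssw += ((block - bm) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    f[ssw == 0] = np.where(ssb[ssw == 0] > 0, np.inf, 0.0)
    return f


def _edge_t(flat: np.ndarray, na: int) -> np.ndarray:
    """Vectorized pooled-variance t per edge for a two-block split."""
    a, b = flat[:na], flat[na:]
    nb = b.shape[0]
    am, bm = a.mean(axis=0), b.mean(axis=0)
    sp2 = (((a - am) ** 2).sum(axis=0) + ((b - bm) ** 2).sum(axis=0)) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (am - bm) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = am - bm
    t[sp2 == 0] = np.where(diff[sp2 == 0] != 0,
                           np.sign(diff[sp2 == 0]) * np.inf, 0.0)
    return t


def edgewise_stats(matrix_stack_by_group: dict, contrast) -> np.ndarray:
    """Per-edge F (contrast="anova") or signed t (contrast=(a, b)) matrix.

    Matrices within and across groups must share ROI ordering and shape;
    the output is symmetric with a zero diagonal.
    """
    stacks = {g: np.asarray(v, dtype=float) for g, v in matrix_stack_by_group.items()}
    shapes = {v.shape[1:] for v in stacks.values()}
    if len(shapes) != 1:
        raise ValueError("matrix stacks have mismatched ROI dimensions")
    if contrast == "anova":
        order = list(stacks)
        data = np.concatenate([stacks[g] for g in order], axis=0)
        sizes = np.array([stacks[g].shape[0] for g in order])
        flat, iu, ju = _stack_to_edges(data)
        stat = _edge_f(flat, sizes)
    else:
        ga, gb = contrast
        data = np.concatenate([stacks[ga], stacks[gb]], axis=0)
        flat, iu, ju = _stack_to_edges(data)
        stat = _edge_t(flat, stacks[ga].shape[0])
    n = data.shape[1]
    out = np.zeros((n, n))
    out[iu, ju] = stat
    out[ju, iu] = stat
    return out


def suprathreshold_components(stat_matrix: np.ndarray, threshold: float,
                              node_subset=None) -> list[Component]:
    """Connected components of the graph of edges with statistic > threshold.

    Restricted to ``node_subset`` when given; components are returned sorted
    by edge count (descending) and only components with >= 1 edge appear.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    stat = np.asarray(stat_matrix, dtype=float)
    n = stat.shape[0]
    mask = np.zeros((n, n), dtype=bool)
    if node_subset is not None:
        subset = np.asarray(sorted(node_subset), dtype=int)
        mask[np.ix_(subset, subset)] = True
    else:
        mask[:] = True
    keep = (stat > threshold) & mask
    np.fill_diagonal(keep, False)
    iu, ju = np.nonzero(np.triu(keep, 1))
    if iu.size == 0:
        return []
    # union-find over suprathreshold edges
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in zip(iu, ju):
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for a, b in zip(iu, ju):
        groups.setdefault(find(int(a)), []).append((int(a), int(b)))
    comps = []
    for edges in groups.values():
        nodes = tuple(sorted({x for e in edges for x in e}))
        comps.append(Component(nodes=nodes, edges=sorted(edges),
                               n_edges=len(edges)))
    comps.sort(key=lambda c: (-c.n_edges, c.nodes))
    return comps


def nbs_permutation_test(matrix_stack: np.ndarray, group_labels,
                         contrast, config: NbsConfig | None = None,
                         tail: str = "omnibus") -> NbsResult:
    """Max-component permutation test.

    contrast: "anova" (omnibus; edges with F > f_threshold) or a pair of
    group labels with tail "greater" (t > t_threshold) or "less"
    (t < -t_threshold). Component extent is measured in edges; p = (1 +
    #{max_null >= size_obs}) / (1 + n_perm).
    """
    config = config or NbsConfig()
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    stack = np.asarray(matrix_stack, dtype=float)
    labels = np.asarray(group_labels)
    if labels.shape[0] != stack.shape[0]:
        raise ValueError("one label per subject required")
    n_nodes = stack.shape[1]

    if contrast == "anova":
        groups = list(dict.fromkeys(labels))
        sel = np.concatenate([np.flatnonzero(labels == g) for g in groups])
        sizes = np.array([(labels == g).sum() for g in groups])
        threshold = config.f_threshold
    else:
        ga, gb = contrast
        ia, ib = np.flatnonzero(labels == ga), np.flatnonzero(labels == gb)
        if ia.size < 2 or ib.size < 2:
            raise ValueError("each contrasted group needs n >= 2")
        sel = np.concatenate([ia, ib])
        sizes = np.array([ia.size, ib.size])
        threshold = config.t_threshold

    flat, iu, ju = _stack_to_edges(stack[sel])

    def signed_stat(values):
        if contrast == "anova":
            return _edge_f(values, sizes)
        t = _edge_t(values, sizes[0])
        return -t if tail == "less" else t

    stat = signed_stat(flat)
    stat_matrix = np.zeros((n_nodes, n_nodes))
    stat_matrix[iu, ju] = stat
    stat_matrix[ju, iu] = stat
    observed = suprathreshold_components(stat_matrix, threshold,
                                         config.node_subset)

    if config.node_subset is not None:
        subset = set(int(x) for x in config.node_subset)
        edge_ok = np.array([i in subset and j in subset
                            for i, j in zip(iu, ju)])
    else:
        edge_ok = np.ones(iu.size, dtype=bool)

    rng = np.random.default_rng(config.seed)
    n_sub = flat.shape[0]
    null_max = np.empty(config.n_perm, dtype=np.int64)
    for p in range(config.n_perm):
        perm = rng.permutation(n_sub)
        s = signed_stat(flat[perm])
        supra = (s > threshold) & edge_ok
        null_max[p] = _kernels.max_component_edges(
            n_nodes, iu[supra].astype(np.int64), ju[supra].astype(np.int64))

    for comp in observed:
        count = int((null_max >= comp.n_edges).sum())
        comp.p_value = (1 + count) / (1 + config.n_perm)

    direction = {"omnibus": "omnibus", "greater": "increase",
                 "less": "decrease"}[tail]
    return NbsResult(components=observed, direction=direction,
                     threshold=threshold, null_max_sizes=null_max,
                     stat_matrix=stat_matrix)
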
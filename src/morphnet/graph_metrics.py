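"""Sparsity thresholding, graph metrics, rewired-null normalization, and AUC.

Networks are binarized by keeping the strongest edges at each sparsity level.
Global metrics (Eglob, Eloc, Cp, Lp), normalized metrics against
degree-preserving Maslov-Sneppen nulls (gamma, lambda, sigma = gamma/lambda),
and nodal metrics (degree, betweenness, efficiency) are computed per level
and summarized by the trapezoidal area under the curve across the range.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .roi_io import MorphNetwork

GLOBAL_METRICS = ("Eglob", "Eloc", "Cp", "Lp", "gamma", "lambda_", "sigma")
NODAL_METRICS = ("degree", "betweenness", "efficiency")


@dataclass
class ThresholdSpec:
    """Sparsity sweep: defaults 0.10..0.35 in steps of 0.01 (26 levels)."""

    s_min: float = 0.10
    s_max: float = 0.35
    s_step: float = 0.01

    def __post_init__(self):
        if not (0 < self.s_min <= self.s_max < 1):
            raise ValueError("need 0 < s_min <= s_max < 1")
        if self.s_step <= 0:
            raise ValueError("s_step must be positive")

    @property
    def levels(self) -> np.ndarray:
        n = int(round((self.s_max - self.s_min) / self.s_step)) + 1
        lv = self.s_min + self.s_step * np.arange(n)
        return lv[lv <= self.s_max + 1e-12]


@dataclass
class BinaryGraph:
    adjacency: np.ndarray = field(repr=False)
    sparsity_achieved: float = 0.0

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class GlobalMetrics:
    Eglob: float
    Eloc: float
    Cp: float
    Lp: float
    gamma: float = np.nan
    lambda_: float = np.nan
    sigma: float = np.nan
    connected: bool = True
    rewiring_failed: bool = False


@dataclass
class NodalMetrics:
    degree: np.ndarray
    betweenness: np.ndarray
    efficiency: np.ndarray


@dataclass
class MetricPanel:
    """All metrics per threshold plus AUC summaries for one subject."""

    subject_id: str
    roi_labels: list[str]
    thresholds: np.ndarray
    global_table: pd.DataFrame          # index: threshold, columns: GLOBAL_METRICS + connected
    nodal: dict                          # metric -> (n_levels, n_nodes)
    auc_global: dict                     # metric -> scalar
    auc_nodal: dict                      # metric -> (n_nodes,)


def threshold_graph(network, s: float) -> BinaryGraph:
    """Keep the round(s * N(N-1)/2) strongest off-diagonal weights as edges.

    Ties are broken deterministically: descending weight, then ascending
    (i, j) index.
    """
    matrix = network.matrix if isinstance(network, MorphNetwork) else np.asarray(network)
    if not (0 < s < 1):
        raise ValueError("sparsity must be in (0, 1)")
    n = matrix.shape[0]
    n_pairs = n * (n - 1) // 2
    k = int(round(s * n_pairs))
    if k == 0:
        raise ValueError(f"sparsity {s} yields 0 edges for {n} nodes")
    iu, ju = np.triu_indices(n, 1)
    w = matrix[iu, ju]
    order = np.lexsort((ju, iu, -w))  # primary: weight desc; then (i, j) asc
    keep = order[:k]
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[keep], ju[keep]] = 1
    adj[ju[keep], iu[keep]] = 1
    return BinaryGraph(adjacency=adj, sparsity_achieved=k / n_pairs)


def global_metrics(graph: BinaryGraph | np.ndarray) -> GlobalMetrics:
    """Raw Cp, Lp, Eglob, Eloc of a binary undirected graph.

    Lp averages over connected ordered pairs only; a ``connected`` flag
    records whether any pair was unreachable. Nodes with degree < 2
    contribute 0 to Cp and Eloc.
    """
    adj = _as_adjacency(graph)
    eglob, eloc, cp, lp, connected, _, _, _ = _kernels.graph_measures(adj)
    return GlobalMetrics(Eglob=eglob, Eloc=eloc, Cp=cp, Lp=lp,
                         connected=bool(connected))


def nodal_metrics(graph: BinaryGraph | np.ndarray) -> NodalMetrics:
    """Degree, Brandes betweenness (unnormalized pair counts), nodal efficiency."""
    adj = _as_adjacency(graph)
    _, _, _, _, _, degree, betweenness, efficiency = _kernels.graph_measures(adj)
    return NodalMetrics(degree=degree, betweenness=betweenness,
                        efficiency=efficiency)


def _as_adjacency(graph) -> np.ndarray:
    adj = graph.adjacency if isinstance(graph, BinaryGraph) else np.asarray(graph)
    adj = np.ascontiguousarray(adj.astype(np.uint8))
    if adj.sum() == 0:
        raise ValueError("graph has no edges")
    return adj


def _all_measures(graph) -> tuple[GlobalMetrics, NodalMetrics]:
    adj = _as_adjacency(graph)
    eglob, eloc, cp, lp, connected, deg, betw, eff = _kernels.graph_measures(adj)
    gm = GlobalMetrics(Eglob=eglob, Eloc=eloc, Cp=cp, Lp=lp,
                       connected=bool(connected))
    return gm, NodalMetrics(degree=deg, betweenness=betw, efficiency=eff)


def _edge_list(adj: np.ndarray) -> np.ndarray:
    iu, ju = np.nonzero(np.triu(adj, 1))
    return np.column_stack([iu, ju]).astype(np.int64)


def normalized_metrics(graph: BinaryGraph | np.ndarray, n_nulls: int = 100,
                       seed: int = 0, swap_factor: int = 10,
                       raw: GlobalMetrics | None = None) -> GlobalMetrics:
    """gamma, lambda, sigma against Maslov-Sneppen degree-preserving nulls.

    Each null applies ``swap_factor * |E|`` swap attempts. If no swap is ever
    accepted (rewiring-invariant degree sequence) the nulls equal the
    original graph and the result is flagged.
    """
    adj = _as_adjacency(graph)
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    if raw is None:
        raw = global_metrics(adj)
    edges0 = _edge_list(adj)
    m = edges0.shape[0]
    rng = np.random.SeedSequence(seed)
    null_seeds = rng.generate_state(n_nulls) & 0x7FFFFFFF

    cps = np.empty(n_nulls)
    lps = np.empty(n_nulls)
    total_swaps = 0
    for k in range(n_nulls):
        edges = edges0.copy()
        a = adj.copy()
        total_swaps += _kernels.rewire(edges, a, swap_factor * m, int(null_seeds[k]))
        cps[k], lps[k], _ = _kernels.cp_lp(a)
    gamma = raw.Cp / cps.mean() if cps.mean() > 0 else np.nan
    lam = raw.Lp / lps.mean() if lps.mean() > 0 else np.nan
    return GlobalMetrics(Eglob=raw.Eglob, Eloc=raw.Eloc, Cp=raw.Cp, Lp=raw.Lp,
                         gamma=gamma, lambda_=lam, sigma=gamma / lam,
                         connected=raw.connected,
                         rewiring_failed=(total_swaps == 0))


def metric_auc(values, spec: ThresholdSpec) -> float:
    """Trapezoidal integral of one value per threshold level over sparsity."""
    values = np.asarray(values, dtype=float)
    levels = spec.levels
    if values.shape[0] != levels.shape[0]:
        raise ValueError(f"{values.shape[0]} values for {levels.shape[0]} levels")
    if levels.shape[0] < 2:
        raise ValueError("AUC needs at least 2 threshold levels")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    return float(np.trapezoid(values, levels))


def _subject_tag(subject_id: str) -> int:
    return zlib.crc32(subject_id.encode("utf-8"))


def sweep_metrics(network: MorphNetwork, spec: ThresholdSpec | None = None,
                  n_nulls: int = 100, seed: int = 0) -> MetricPanel:
    """All global and nodal metrics at every sparsity level, plus AUCs.

    The null RNG is seeded per (subject, threshold level), so panels are
    reproducible independent of evaluation order.
    """
    spec = spec or ThresholdSpec()
    levels = spec.levels
    tag = _subject_tag(network.subject_id)
    n = network.n_rois

    rows = []
    nodal = {m: np.empty((levels.size, n)) for m in NODAL_METRICS}
    for li, s in enumerate(levels):
        bg = threshold_graph(network, float(s))
        level_seed = int(np.random.SeedSequence([seed, tag, li]).generate_state(1)[0])
        raw, nm = _all_measures(bg)
        gm = normalized_metrics(bg, n_nulls=n_nulls, seed=level_seed, raw=raw)
        rows.append({"threshold": s, "Eglob": gm.Eglob, "Eloc": gm.Eloc,
                     "Cp": gm.Cp, "Lp": gm.Lp, "gamma": gm.gamma,
                     "lambda_": gm.lambda_, "sigma": gm.sigma,
                     "connected": gm.connected,
                     "rewiring_failed": gm.rewiring_failed})
        for m in NODAL_METRICS:
            nodal[m][li] = getattr(nm, m)

    table = pd.DataFrame(rows).set_index("threshold")

    def safe_auc(values):
        # nan-poisoned curves (e.g. undefined gamma on degenerate nulls)
        # yield a nan AUC rather than aborting the panel
        values = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(values)):
            return np.nan
        return metric_auc(values, spec)

    auc_global = {m: safe_auc(table[m].to_numpy()) for m in GLOBAL_METRICS}
    auc_nodal = {m: np.array([safe_auc(nodal[m][:, i]) for i in range(n)])
                 for m in NODAL_METRICS}
    return MetricPanel(subject_id=network.subject_id,
                       roi_labels=list(network.roi_labels),
                       thresholds=levels, global_table=table, nodal=nodal,
                       auc_global=auc_global, auc_nodal=auc_nodal)


def panel_to_tidy(panel: MetricPanel) -> pd.DataFrame:
    """Tidy (subject, metric, threshold, value) rows for global metrics."""
    recs = []
    for s, row in panel.global_table.iterrows():
        for m in GLOBAL_METRICS:
            recs.append((panel.subject_id, m, s, row[m]))
    return pd.DataFrame(recs, columns=["subject", "metric", "threshold", "value"])


def auc_to_tidy(panels: list[MetricPanel]) -> pd.DataFrame:
    """Tidy AUC table: one row per (subject, metric[, node])."""
    recs = []
    for p in panels:
        for m, v in p.auc_global.items():
            recs.append((p.subject_id, m, "", v))
        for m, vec in p.auc_nodal.items():
            for lab, v in zip(p.roi_labels, vec):
                recs.append((p.subject_id, m, lab, v))
    return pd.DataFrame(recs, columns=["subject", "metric", "node", "auc"])
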
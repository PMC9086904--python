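"""Nonparametric permutation inference on AUC metrics with FDR control.

p-values use the add-one convention p = (1 + #{stat_perm >= stat_obs}) /
(1 + n_perm), two-sided via |t| for pairwise contrasts; an exact variant
enumerates every distinct label arrangement (including the identity) on tiny
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np


@dataclass
class PermutationConfig:
    n_perm: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    fdr_q: float = 0.05

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must be in (0, 1)")


@dataclass
class GroupTestResult:
    metric: str
    statistic: float
    p_value: float
    group_means: list
    significant: bool | None = None
    degenerate: bool = False


def f_statistic(values: np.ndarray, sizes: np.ndarray) -> float:
    """One-way ANOVA F from concatenated values grouped by consecutive blocks."""
    n = values.size
    k = sizes.size
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    grand = values.mean()
    ssb = 0.0
    ssw = 0.0
    for g in range(k):
        block = values[bounds[g]:bounds[g + 1]]
        ssb += block.size * (block.mean() - grand) ** 2
        ssw += ((block - block.mean()) ** 2).sum()
    if ssw == 0:
        return np.inf if ssb > 0 else np.nan
    return (ssb / (k - 1)) / (ssw / (n - k))


def t_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample t with pooled variance."""
    na, nb = a.size, b.size
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    if sp2 == 0:
        d = a.mean() - b.mean()
        return np.inf * np.sign(d) if d != 0 else np.nan
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))


def _as_groups(values_by_group) -> list[np.ndarray]:
    groups = [np.asarray(v, dtype=float).ravel() for v in values_by_group]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
        if not np.all(np.isfinite(g)):
            raise ValueError("values must be finite")
    return groups


def permutation_anova(values_by_group, config: PermutationConfig | None = None,
                      metric: str = "") -> GroupTestResult:
    """Omnibus permutation test: one-way F against the label-shuffle null."""
    config = config or PermutationConfig()
    groups = _as_groups(values_by_group)
    sizes = np.array([g.size for g in groups])
    pooled = np.concatenate(groups)
    f_obs = f_statistic(pooled, sizes)
    means = [float(g.mean()) for g in groups]
    if np.isnan(f_obs):
        return GroupTestResult(metric=metric, statistic=np.nan, p_value=np.nan,
                               group_means=means, degenerate=True)
    rng = np.random.default_rng(config.seed)
    count = 0
    for _ in range(config.n_perm):
        perm = rng.permutation(pooled)
        if f_statistic(perm, sizes) >= f_obs:
            count += 1
    p = (1 + count) / (1 + config.n_perm)
    return GroupTestResult(metric=metric, statistic=float(f_obs), p_value=p,
                           group_means=means)


def permutation_pairwise(values_a, values_b,
                         config: PermutationConfig | None = None,
                         metric: str = "") -> GroupTestResult:
    """Two-sided pairwise permutation test on the pooled-variance t statistic."""
    config = config or PermutationConfig()
    a, b = _as_groups([values_a, values_b])
    t_obs = t_statistic(a, b)
    means = [float(a.mean()), float(b.mean())]
    if np.isnan(t_obs):
        return GroupTestResult(metric=metric, statistic=np.nan, p_value=np.nan,
                               group_means=means, degenerate=True)
    pooled = np.concatenate([a, b])
    na = a.size
    rng = np.random.default_rng(config.seed)
    count = 0
    for _ in range(config.n_perm):
        perm = rng.permutation(pooled)
        if abs(t_statistic(perm[:na], perm[na:])) >= abs(t_obs):
            count += 1
    p = (1 + count) / (1 + config.n_perm)
    return GroupTestResult(metric=metric, statistic=float(t_obs), p_value=p,
                           group_means=means)


def exact_anova_p(values_by_group) -> float:
    """Exhaustive-enumeration omnibus p on tiny inputs.

    Enumerates every distinct assignment of observations to group slots
    (identity included); p is the fraction with F >= observed F.
    """
    groups = _as_groups(values_by_group)
    sizes = np.array([g.size for g in groups])
    pooled = np.concatenate(groups)
    n = pooled.size
    if comb(n, int(sizes[0])) > 200_000:
        raise ValueError("too many arrangements to enumerate")
    f_obs = f_statistic(pooled, sizes)
    count = 0
    total = 0
    for arrangement in _assignments(np.arange(n), sizes):
        total += 1
        if f_statistic(pooled[arrangement], sizes) >= f_obs - 1e-12:
            count += 1
    return count / total


def _assignments(indices: np.ndarray, sizes: np.ndarray):
    """All distinct splits of ``indices`` into consecutive blocks of ``sizes``."""
    if sizes.size == 1:
        yield indices
        return
    head_n = int(sizes[0])
    idx_set = list(indices)
    for head in combinations(idx_set, head_n):
        rest = np.array([i for i in idx_set if i not in set(head)])
        for tail in _assignments(rest, sizes[1:]):
            yield np.concatenate([np.array(head), tail])


def fdr_correct(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up: (significance mask, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adjusted = ranked * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(adjusted[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    adj = np.empty(m)
    adj[order] = adjusted
    mask = adj <= q
    return mask, adj
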
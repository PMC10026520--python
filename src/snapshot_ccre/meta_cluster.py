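"""Merge Index-Sets into Meta-Index-Sets.

Hierarchical (complete-linkage) clustering of the IS mean-signal vectors,
with the cluster count chosen by AIC under a shared-variance spherical
Gaussian model: AIC(K) = 2 (K d + 1) + n d ln(RSS / (n d)).
IS sizes play no role in the merge, so rare patterns are not absorbed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .indexing import NULL_INDEX, IndexSet

__all__ = ["MetaIndexSet", "build_linkage", "select_k_by_aic", "assign_meta", "merge_index_sets"]

_RSS_EPS = 1e-12


@dataclass
class MetaIndexSet:
    meta_id: int
    member_is: list[str]  # index strings of member ISs
    mean_signal: np.ndarray  # cCRE-weighted over member ISs
    size: int  # total cCREs


def build_linkage(is_mean_signals: np.ndarray, method: str = "complete") -> np.ndarray:
    """Agglomerative dendrogram over IS mean-signal vectors (Euclidean)."""
    means = np.asarray(is_mean_signals, dtype=float)
    if len(means) < 2:
        raise ValueError("need >=2 Index-Sets to build a dendrogram")
    return linkage(means, method=method, metric="euclidean")


def aic_for_labels(means: np.ndarray, labels: np.ndarray) -> float:
    n, d = means.shape
    k = len(np.unique(labels))
    rss = 0.0
    for lab in np.unique(labels):
        grp = means[labels == lab]
        rss += float(((grp - grp.mean(axis=0)) ** 2).sum())
    return 2.0 * (k * d + 1) + n * d * np.log(max(rss / (n * d), _RSS_EPS))


def select_k_by_aic(
    dendrogram: np.ndarray,
    is_mean_signals: np.ndarray,
    k_range: range | list[int] | None = None,
) -> tuple[int, dict[int, float]]:
    """Cut the dendrogram at each K, score by AIC, return argmin (+ table).

    Ties go to the smallest K. A zero-RSS cut wins outright (its log term is
    clamped at an epsilon floor).
    """
    means = np.asarray(is_mean_signals, dtype=float)
    n = len(means)
    if k_range is None:
        k_range = range(2, min(30, n - 1) + 1)
    ks = [k for k in k_range if 1 <= k <= n]
    if not ks:
        raise ValueError("k_range contains no feasible K")
    table: dict[int, float] = {}
    for k in ks:
        labels = fcluster(dendrogram, t=k, criterion="maxclust")
        table[k] = aic_for_labels(means, labels)
    best = min(sorted(table), key=lambda k: (table[k], k))
    return best, table


def assign_meta(
    dendrogram: np.ndarray,
    k: int,
    index_sets: list[IndexSet],
) -> list[MetaIndexSet]:
    """Cut into K groups; meta ids follow first appearance in leaf order.

    Meta-IS mean_signal is the cCRE-count-weighted mean of member IS
    mean-signal vectors (the merge itself ignored sizes; the summary does
    not).
    """
    labels = fcluster(dendrogram, t=k, criterion="maxclust")
    order = leaves_list(dendrogram)
    seen: dict[int, int] = {}
    for leaf in order:
        lab = labels[leaf]
        if lab not in seen:
            seen[lab] = len(seen) + 1
    metas: list[MetaIndexSet] = []
    for lab, meta_id in sorted(seen.items(), key=lambda kv: kv[1]):
        members = [index_sets[i] for i in np.flatnonzero(labels == lab)]
        sizes = np.array([m.size for m in members], dtype=float)
        signals = np.vstack([m.mean_signal for m in members])
        weights = sizes / sizes.sum() if sizes.sum() > 0 else np.full(len(members), 1 / len(members))
        metas.append(
            MetaIndexSet(
                meta_id=meta_id,
                member_is=[m.index for m in members],
                mean_signal=weights @ signals,
                size=int(sizes.sum()),
            )
        )
    return metas


def merge_index_sets(
    index_sets: list[IndexSet],
    k_range: range | list[int] | None = None,
    include_null: bool = False,
    linkage_method: str = "complete",
) -> tuple[list[MetaIndexSet], int, dict[int, float]]:
    """End-to-end merge: linkage -> AIC model selection -> meta assignment."""
    pool = [s for s in index_sets if include_null or s.index != NULL_INDEX]
    if any(s.mean_signal is None for s in pool):
        raise ValueError("all Index-Sets need mean_signal before merging")
    means = np.vstack([s.mean_signal for s in pool])
    if len(pool) == 1:
        only = pool[0]
        meta = MetaIndexSet(1, [only.index], np.asarray(only.mean_signal), only.size)
        return [meta], 1, {1: float("nan")}
    z = build_linkage(means, method=linkage_method)
    k, table = select_k_by_aic(z, means, k_range)
    metas = assign_meta(z, k, pool)
    return metas, k, table
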
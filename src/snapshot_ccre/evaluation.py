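"""Clustering assessment: window entropy, noise-injection ARI, rare-cluster recovery.

Three protocols:

* a 2-D sliding window (N adjacent rows x M cell types) scans the sorted
  binary index map one row at a time; the Shannon entropy of the observed
  N-by-M pattern frequencies (natural log) measures how ordered the map is;
* clustering repeated under fresh Uniform(-0.1, 0.1) noise, scored by all
  pairwise adjusted Rand indices;
* repeated K-means runs matched to reference cluster mean vectors by cosine
  distance, counting how often each reference pattern is recovered.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .indexing import NULL_INDEX, IndexSet, parse_index

__all__ = [
    "EntropyProfile",
    "sort_for_map",
    "shannon_entropy",
    "ari_reproducibility",
    "rare_cluster_frequency",
]


@dataclass
class EntropyProfile:
    window_height: int
    se: dict[int, float] = field(default_factory=dict)  # M -> entropy
    pattern_counts: dict[int, Counter] = field(default_factory=dict)


def sort_for_map(index_sets: list[IndexSet], bm: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Row-order the binary matrix for the 2-D cluster map.

    Rows are grouped by IS; ISs are ordered by their index read as a binary
    number over the leaf order, descending (the all-ones pattern first),
    with the null IS last. Returns ``(row_ids, sorted_matrix)``.
    """

    def is_key(s: IndexSet) -> tuple[int, int]:
        if s.index == NULL_INDEX:
            return (1, 0)
        value = int("".join(str(b) for b in s.bits()), 2)
        return (0, -value)

    ordered = sorted(index_sets, key=is_key)
    row_ids = np.concatenate([s.member_ids for s in ordered if s.size > 0])
    return row_ids, bm.loc[row_ids].to_numpy()


def shannon_entropy(
    sorted_map: np.ndarray,
    n: int,
    m_values: list[int],
    col_offset: int = 0,
) -> EntropyProfile:
    """Entropy of N-by-M window patterns scanned down the sorted map.

    For each M, windows cover rows [t, t+N) and the M contiguous columns
    starting at ``col_offset``; SE = -sum p_i ln p_i over the pattern
    frequencies.
    """
    mat = np.asarray(sorted_map)
    n_rows, n_cols = mat.shape
    if n > n_rows:
        raise ValueError(f"window height {n} exceeds {n_rows} rows")
    profile = EntropyProfile(window_height=n)
    for m in m_values:
        if col_offset + m > n_cols:
            raise ValueError(f"window width {m} at offset {col_offset} exceeds {n_cols} columns")
        sub = np.ascontiguousarray(mat[:, col_offset : col_offset + m], dtype=np.uint8)
        counts: Counter = Counter()
        for t in range(n_rows - n + 1):
            counts[sub[t : t + n].tobytes()] += 1
        total = sum(counts.values())
        p = np.array(list(counts.values()), dtype=float) / total
        profile.se[m] = float(-(p * np.log(p)).sum())
        profile.pattern_counts[m] = counts
    return profile


def ari_reproducibility(
    cluster_fn,
    data: np.ndarray,
    n_reps: int = 5,
    noise_low: float = -0.1,
    noise_high: float = 0.1,
    seed: int = 0,
) -> list[float]:
    """Pairwise ARIs across re-clusterings of noise-perturbed data.

    ``cluster_fn(noisy_data, rep_seed)`` must return integer labels and be
    deterministic given its arguments.
    """
    rng = np.random.default_rng(seed)
    labelings = []
    for rep in range(n_reps):
        noise = rng.uniform(noise_low, noise_high, size=data.shape)
        labelings.append(np.asarray(cluster_fn(data + noise, rep)))
    aris = []
    for a, b in combinations(range(n_reps), 2):
        la, lb = labelings[a], labelings[b]
        if len(set(la)) == 1 and len(set(lb)) == 1:
            aris.append(1.0)  # two trivial one-cluster partitions agree
        else:
            aris.append(float(adjusted_rand_score(la, lb)))
    return aris


def _cosine_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise cosine distance; any zero vector is at distance 1 from everything."""
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    sim = np.zeros((len(a), len(b)))
    ok_a, ok_b = na > 0, nb > 0
    if ok_a.any() and ok_b.any():
        sim[np.ix_(ok_a, ok_b)] = (
            a[ok_a] @ b[ok_b].T / np.outer(na[ok_a], nb[ok_b])
        )
    return 1.0 - sim


def rare_cluster_frequency(
    meta_means: np.ndarray,
    data: np.ndarray,
    k: int = 19,
    rounds: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """How often each reference mean is the nearest match of a K-means centroid.

    Per round, K-means (fresh seed) is run on ``data``; each centroid is
    matched to its cosine-nearest reference mean; every reference matched by
    at least one centroid gains one count. Returns counts in [0, rounds].
    """
    meta_means = np.asarray(meta_means, dtype=float)
    counts = np.zeros(len(meta_means), dtype=int)
    for r in range(rounds):
        km = KMeans(n_clusters=k, n_init=1, random_state=seed + r).fit(data)
        dist = _cosine_distance(km.cluster_centers_, meta_means)
        nearest = dist.argmin(axis=1)
        counts[np.unique(nearest)] += 1
    return counts
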
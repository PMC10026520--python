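"""Dominant epigenetic-state assignment and cluster-level state summaries.

A cCRE spanning several fixed-width segmentation bins can intersect bins
with different states; one dominant state is chosen per (cCRE, cell type)
by an ordered rule cascade:

1. quiescent is ineligible whenever any non-quiescent state overlaps;
2. largest covered proportion of the cCRE wins;
3. tie -> the state whose covered-span midpoint (union of its overlapping
   bins clipped to the cCRE) is closest to the cCRE midpoint;
4. tie -> the state whose overlapping bins span more total base pairs,
   counting extension beyond the cCRE edges;
5. tie -> lexicographically smallest label (determinism guard; the four
   rules above can still tie on symmetric layouts).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

QUIESCENT_LABELS = frozenset({"0", "Q", "quiescent"})

__all__ = [
    "QUIESCENT_LABELS",
    "dominant_state",
    "representative_states",
    "assign_states",
    "summarize_cluster_states",
]


def dominant_state(
    ccre_start: int,
    ccre_end: int,
    bins: list[tuple[int, int, str]],
    quiescent_labels: frozenset[str] = QUIESCENT_LABELS,
) -> str:
    """Pick the single dominant state for one cCRE in one cell type.

    ``bins`` are (start, end, state) segmentation bins; non-overlapping
    bins are ignored. With no overlapping bin at all the cCRE is labelled
    'quiescent' with a warning.
    """
    length = ccre_end - ccre_start
    if length <= 0:
        raise ValueError("degenerate cCRE")
    per_state: dict[str, dict[str, float]] = {}
    for b_start, b_end, state in bins:
        clip_s, clip_e = max(b_start, ccre_start), min(b_end, ccre_end)
        if clip_e <= clip_s:
            continue
        acc = per_state.setdefault(
            state,
            {"covered": 0.0, "span_min": np.inf, "span_max": -np.inf, "total_bp": 0.0},
        )
        acc["covered"] += clip_e - clip_s
        acc["span_min"] = min(acc["span_min"], clip_s)
        acc["span_max"] = max(acc["span_max"], clip_e)
        acc["total_bp"] += b_end - b_start
    if not per_state:
        warnings.warn(f"no state bin overlaps cCRE {ccre_start}-{ccre_end}; set to quiescent")
        return "quiescent"
    eligible = dict(per_state)
    if any(s not in quiescent_labels for s in per_state):
        eligible = {s: v for s, v in per_state.items() if s not in quiescent_labels}
    ccre_mid = 0.5 * (ccre_start + ccre_end)

    def sort_key(state: str):
        acc = eligible[state]
        midpoint = 0.5 * (acc["span_min"] + acc["span_max"])
        return (
            -acc["covered"],  # rule 2 (proportion of a fixed-length cCRE)
            abs(midpoint - ccre_mid),  # rule 3
            -acc["total_bp"],  # rule 4 (unclipped bin span)
            state,  # rule 5
        )

    return min(eligible, key=sort_key)


def representative_states(
    member_states: list[str] | Counter,
    colors: dict[str, tuple[float, float, float]],
) -> tuple[list[str], tuple[float, float, float]]:
    """Minimal prefix of states (by frequency) cumulatively covering >50%.

    Frequency ties are broken by label order. The summary color is the
    frequency-weighted mean of the prefix states' RGB values, weights
    renormalized over the prefix.
    """
    counts = Counter(member_states)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no member states")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    prefix: list[tuple[str, int]] = []
    cum = 0
    for state, c in ranked:
        if state not in colors:
            raise KeyError(f"no color defined for state {state!r}")
        prefix.append((state, c))
        cum += c
        if cum / total > 0.5:
            break
    weights = np.array([c for _, c in prefix], dtype=float)
    weights /= weights.sum()
    rgb = np.array([colors[s] for s, _ in prefix], dtype=float)
    color = tuple((weights @ rgb).tolist())
    return [s for s, _ in prefix], color  # type: ignore[return-value]


def assign_states(
    master: pd.DataFrame,
    state_tracks: dict[str, pd.DataFrame],
    quiescent_labels: frozenset[str] = QUIESCENT_LABELS,
) -> pd.DataFrame:
    """Dominant state per (cCRE, cell type); rows indexed by master cCRE id."""
    out = {}
    for cell, track in state_tracks.items():
        by_chrom = {
            chrom: (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["state"].to_numpy(),
            )
            for chrom, sub in track.groupby("chrom", sort=False)
        }
        labels = np.empty(len(master), dtype=object)
        for i, (chrom, start, end) in enumerate(
            zip(master["chrom"], master["start"], master["end"])
        ):
            if chrom not in by_chrom:
                labels[i] = "quiescent"
                continue
            b_starts, b_ends, b_states = by_chrom[chrom]
            lo = int(np.searchsorted(b_ends, start, side="right"))
            hi = int(np.searchsorted(b_starts, end, side="left"))
            bins = [
                (int(b_starts[j]), int(b_ends[j]), str(b_states[j])) for j in range(lo, hi)
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                labels[i] = dominant_state(int(start), int(end), bins, quiescent_labels)
        out[cell] = labels
    df = pd.DataFrame(out, index=master["id"].to_numpy())
    df.index.name = "ccre_id"
    return df


def summarize_cluster_states(
    ccre_states: pd.DataFrame,
    clusters: dict[str, np.ndarray],
    colors: dict[str, tuple[float, float, float]],
) -> pd.DataFrame:
    """Representative states + summary color per (cluster, cell type).

    ``clusters`` maps cluster id -> member cCRE ids. Returns a tidy frame
    with columns cluster, cell_type, representative_states, color_hex.
    """
    rows = []
    for cluster_id, members in clusters.items():
        if len(members) == 0:
            continue
        sub = ccre_states.loc[members]
        for cell in ccre_states.columns:
            states, rgb = representative_states(list(sub[cell]), colors)
            rows.append(
                {
                    "cluster": cluster_id,
                    "cell_type": cell,
                    "representative_states": ",".join(states),
                    "color_hex": "#%02x%02x%02x" % tuple(int(round(c)) for c in rgb),
                }
            )
    return pd.DataFrame(rows)
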
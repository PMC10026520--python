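"""Binarize cCRE presence across cell types and group cCREs into Index-Sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CellTree, merge_intervals

__all__ = ["IndexSet", "binarize", "make_index", "parse_index", "group_into_index_sets"]

NULL_INDEX = "null"


@dataclass
class IndexSet:
    """All cCREs sharing one binary presence/absence index string."""

    index: str
    member_ids: np.ndarray
    mean_signal: np.ndarray | None = None
    status: str | None = None  # abundant | filtered | null | None

    @property
    def size(self) -> int:
        return len(self.member_ids)

    def bits(self) -> np.ndarray:
        if self.index == NULL_INDEX:
            raise ValueError("null IS has no binary index")
        return parse_index(self.index)


def make_index(row: np.ndarray) -> str:
    """Join 0/1 bits with underscores, e.g. [0,0,0,1,0] -> '0_0_0_1_0'."""
    arr = np.asarray(row)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"non-binary entry in index row: {arr!r}")
    return "_".join(str(int(b)) for b in arr)


def parse_index(index: str) -> np.ndarray:
    bits = np.array([int(b) for b in index.split("_")])
    if not np.isin(bits, (0, 1)).all():
        raise ValueError(f"malformed index string {index!r}")
    return bits


def _overlap_flags(master: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    """1 where a master interval shares >=1 bp with any peak."""
    flags = np.zeros(len(master), dtype=np.int8)
    if peaks.empty:
        return flags
    merged = merge_intervals(peaks)
    by_chrom = {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in merged.groupby("chrom", sort=False)
    }
    for chrom, sub in master.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            continue
        p_starts, p_ends = by_chrom[chrom]
        c_starts = sub["start"].to_numpy()
        c_ends = sub["end"].to_numpy()
        # Peaks are merged + sorted: a cCRE overlaps iff the last peak
        # starting before ccre.end extends past ccre.start.
        idx = np.searchsorted(p_starts, c_ends, side="left")
        hit = (idx > 0) & (p_ends[np.maximum(idx - 1, 0)] > c_starts)
        flags[sub.index.to_numpy()] = hit.astype(np.int8)
    return flags


def binarize(
    master: pd.DataFrame,
    peak_lists: dict[str, pd.DataFrame],
    tree: CellTree,
) -> pd.DataFrame:
    """Presence/absence matrix: rows = master cCRE ids, cols = tree.leaf_order.

    Entry (i, c) is 1 iff master interval i overlaps >=1 bp with any peak of
    cell type c.
    """
    missing = [c for c in tree.leaf_order if c not in peak_lists]
    if missing:
        raise ValueError(f"no peak list for cell types: {missing}")
    master = master.reset_index(drop=True)
    cols = {cell: _overlap_flags(master, peak_lists[cell]) for cell in tree.leaf_order}
    bm = pd.DataFrame(cols, index=master["id"].to_numpy())
    bm.index.name = "ccre_id"
    return bm


def group_into_index_sets(bm: pd.DataFrame, drop_all_zero: bool = True) -> list[IndexSet]:
    """One IndexSet per distinct observed index.

    cCREs with all-zero rows (no peak in any cell type; possible when the
    master list is user-supplied) are excluded before grouping.
    """
    if bm.empty:
        raise ValueError("binary matrix is empty")
    mat = bm.to_numpy()
    ids = bm.index.to_numpy()
    if drop_all_zero:
        keep = mat.sum(axis=1) > 0
        mat, ids = mat[keep], ids[keep]
    index_strings = np.array([make_index(row) for row in mat])
    sets: list[IndexSet] = []
    for idx in sorted(set(index_strings)):
        members = ids[index_strings == idx]
        sets.append(IndexSet(index=idx, member_ids=members))
    return sets
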
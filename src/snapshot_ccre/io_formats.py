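"""Readers and writers for the external formats the pipeline touches.

Interval semantics are BED throughout: 0-based, half-open ``[start, end)``.
Strand is ignored. Peak and master lists are pandas DataFrames with columns
``chrom``, ``start``, ``end`` (plus ``id`` for master lists); signal tracks
are bedGraph (bigWig is accepted when pyBigWig is importable); state
segmentations are BED4; trees are two-column edge lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CcreInterval",
    "CellTree",
    "read_peak_beds",
    "read_bed",
    "build_master_list",
    "merge_intervals",
    "read_signal",
    "read_cell_tree",
    "read_state_bed",
    "read_color_table",
    "write_bed",
    "write_bedgraph",
]

INTERVAL_COLUMNS = ["chrom", "start", "end"]


@dataclass(frozen=True)
class CcreInterval:
    """A genomic interval from the master list; the unit of clustering."""

    chrom: str
    start: int
    end: int
    id: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"degenerate interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class CellTree:
    """A rooted cell-differentiation tree (or forest) fixing the bit order.

    ``leaf_order`` is the depth-first pre-order over all nodes (internal
    nodes included: every cell type with data occupies one bit).
    """

    nodes: list[str]
    edges: list[tuple[str, str]]
    leaf_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.leaf_order:
            self.leaf_order = self._preorder()
        missing = set(self.nodes) - set(self.leaf_order)
        if missing:
            raise ValueError(f"leaf_order is missing cell types: {sorted(missing)}")

    def _preorder(self) -> list[str]:
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        has_parent: set[str] = set()
        for parent, child in self.edges:
            children[parent].append(child)
            has_parent.add(child)
        roots = [n for n in self.nodes if n not in has_parent]
        order: list[str] = []
        seen: set[str] = set()

        def visit(node: str) -> None:
            if node in seen:
                raise ValueError(f"cycle detected at cell type {node!r}")
            seen.add(node)
            order.append(node)
            for c in children[node]:
                visit(c)

        for root in roots:
            visit(root)
        if len(order) != len(self.nodes):
            raise ValueError("cycle detected: some nodes unreachable from any root")
        return order

    @property
    def roots(self) -> list[str]:
        has_parent = {c for _, c in self.edges}
        return [n for n in self.nodes if n not in has_parent]

    def depth(self, node: str) -> int:
        parent = {c: p for p, c in self.edges}
        d = 0
        while node in parent:
            node = parent[node]
            d += 1
        return d


# ---------------------------------------------------------------------------
# BED peaks and the master list
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into a sorted interval frame; extra columns dropped."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end < 0:
                raise ValueError(f"{path}:{lineno}: negative coordinate")
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            rows.append((parts[0], start, end))
    if not rows:
        warnings.warn(f"empty BED file: {path}")
        return pd.DataFrame(columns=INTERVAL_COLUMNS).astype({"start": int, "end": int})
    df = pd.DataFrame(rows, columns=INTERVAL_COLUMNS)
    return df.sort_values(["chrom", "start", "end"], kind="mergesort", ignore_index=True)


def read_peak_beds(paths: Mapping[str, str | Path]) -> dict[str, pd.DataFrame]:
    """Read one peak BED per cell type, keyed by cell-type label."""
    return {cell: read_bed(p) for cell, p in paths.items()}


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge strictly overlapping (>=1 bp shared) intervals.

    Book-ended intervals (``end == start``) are kept separate, mirroring
    ``bedtools merge -d 0`` under half-open coordinates.
    """
    if df.empty:
        return df.copy()
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort", ignore_index=True)
    out_chrom: list[str] = []
    out_start: list[int] = []
    out_end: list[int] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
        if chrom == cur_chrom and start < cur_end:
            cur_end = max(cur_end, end)
        else:
            if cur_chrom is not None:
                out_chrom.append(cur_chrom)
                out_start.append(cur_start)
                out_end.append(cur_end)
            cur_chrom, cur_start, cur_end = chrom, start, end
    out_chrom.append(cur_chrom)  # type: ignore[arg-type]
    out_start.append(cur_start)
    out_end.append(cur_end)
    return pd.DataFrame({"chrom": out_chrom, "start": out_start, "end": out_end})


def build_master_list(peak_lists: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Pool peaks from all cell types and merge overlaps into a master list.

    Returns a sorted, non-overlapping frame with an ``id`` column 0..n-1.
    """
    frames = [df for df in peak_lists if not df.empty]
    if not frames:
        raise ValueError("all peak lists are empty; cannot build a master list")
    pooled = pd.concat(frames, ignore_index=True)
    merged = merge_intervals(pooled)
    merged["id"] = np.arange(len(merged))
    return merged


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------

def _read_bedgraph_track(path: Path) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": np.float64},
    )
    track: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="mergesort")
        track[str(chrom)] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["value"].to_numpy(),
        )
    return track


def _mean_over_interval(
    track: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    chrom: str,
    start: int,
    end: int,
) -> float:
    # Uncovered bases count as signal 0.
    starts, ends, values = track[chrom]
    lo = int(np.searchsorted(ends, start, side="right"))
    hi = int(np.searchsorted(starts, end, side="left"))
    if hi <= lo:
        return 0.0
    if hi - lo == 1 and starts[lo] <= start and ends[lo] >= end:
        return float(values[lo])  # fully covered by one segment: exact
    s = np.maximum(starts[lo:hi], start)
    e = np.minimum(ends[lo:hi], end)
    overlap = np.maximum(e - s, 0)
    return float(np.dot(overlap, values[lo:hi]) / (end - start))


def read_signal(path: str | Path, intervals: pd.DataFrame) -> np.ndarray:
    """Mean signal per interval from a bedGraph (or bigWig) track.

    Bases not covered by the track contribute 0 to the mean. A chromosome
    absent from the track yields 0 for its intervals with a warning.
    """
    path = Path(path)
    if path.suffix.lower() in {".bw", ".bigwig"}:
        return _read_signal_bigwig(path, intervals)
    track = _read_bedgraph_track(path)
    out = np.zeros(len(intervals), dtype=float)
    missing: set[str] = set()
    for i, (chrom, start, end) in enumerate(
        zip(intervals["chrom"], intervals["start"], intervals["end"])
    ):
        if chrom not in track:
            missing.add(chrom)
            continue
        out[i] = _mean_over_interval(track, chrom, int(start), int(end))
    for chrom in sorted(missing):
        warnings.warn(f"{path}: chromosome {chrom!r} not in track; signal set to 0")
    return out


def _read_signal_bigwig(path: Path, intervals: pd.DataFrame) -> np.ndarray:
    try:
        import pyBigWig  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            f"{path}: reading bigWig requires pyBigWig; convert to bedGraph instead"
        ) from exc
    bw = pyBigWig.open(str(path))  # pragma: no cover
    out = np.zeros(len(intervals), dtype=float)  # pragma: no cover
    for i, (chrom, start, end) in enumerate(  # pragma: no cover
        zip(intervals["chrom"], intervals["start"], intervals["end"])
    ):
        if chrom not in bw.chroms():
            warnings.warn(f"{path}: chromosome {chrom!r} not in track; signal set to 0")
            continue
        v = bw.stats(chrom, int(start), int(end), type="sum")[0]
        out[i] = 0.0 if v is None else v / (end - start)
    bw.close()  # pragma: no cover
    return out  # pragma: no cover


# ---------------------------------------------------------------------------
# Tree, states, colors
# ---------------------------------------------------------------------------

def read_cell_tree(path: str | Path, leaf_order: Sequence[str] | None = None) -> CellTree:
    """Parse parent/child pairs (whitespace- or comma-separated, one per line)."""
    edges: list[tuple[str, str]] = []
    nodes: list[str] = []
    seen_children: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            if len(parts) == 1:
                parent, child = parts[0], None
            elif len(parts) == 2:
                parent, child = parts
            else:
                raise ValueError(f"{path}:{lineno}: expected 'parent child', got {line!r}")
            for n in (parent, child):
                if n is not None and n not in nodes:
                    nodes.append(n)
            if child is not None:
                if child in seen_children:
                    raise ValueError(f"{path}:{lineno}: duplicate child {child!r}")
                seen_children.add(child)
                edges.append((parent, child))
    if not nodes:
        raise ValueError(f"{path}: no cell types found")
    tree = CellTree(nodes=nodes, edges=edges)
    if leaf_order is not None:
        if set(leaf_order) != set(nodes):
            raise ValueError("explicit leaf_order must cover exactly the tree's cell types")
        tree.leaf_order = list(leaf_order)
    return tree


def read_state_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED4 state segmentation: chrom, start, end, state_label."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "state"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "state": str},
    )
    return df.sort_values(["chrom", "start"], kind="mergesort", ignore_index=True)


def read_color_table(path: str | Path) -> dict[str, tuple[float, float, float]]:
    """Read 'state<TAB>R,G,B' lines into label -> RGB (0-255 floats)."""
    colors: dict[str, tuple[float, float, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(None, 1)
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'state<TAB>R,G,B'")
            label, rgb = parts
            channels = [float(x) for x in rgb.split(",")]
            if len(channels) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 color channels")
            colors[label] = (channels[0], channels[1], channels[2])
    return colors


# ---------------------------------------------------------------------------
# Writers (used by the fixture generator and the pipeline)
# ---------------------------------------------------------------------------

def write_bed(df: pd.DataFrame, path: str | Path, extra_cols: Sequence[str] = ()) -> None:
    cols = INTERVAL_COLUMNS + list(extra_cols)
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(
    path: str | Path,
    chroms: Sequence[str],
    starts: Sequence[int],
    ends: Sequence[int],
    values: Sequence[float],
) -> None:
    with open(path, "w") as fh:
        for c, s, e, v in zip(chroms, starts, ends, values):
            fh.write(f"{c}\t{s}\t{e}\t{v:.10g}\n")
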
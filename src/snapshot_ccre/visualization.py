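"""Figure outputs: binary maps, signal heatmaps, and per-cluster panels.

Every plotting function is a pure function of already-computed pipeline
tables, and each figure also emits its underlying table as TSV next to the
image so plots can be regenerated without recomputing.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io_formats import CellTree

__all__ = ["plot_binary_map", "plot_mean_signal_heatmap", "plot_cluster_panel", "tree_layout"]


def _emit_table(df: pd.DataFrame, image_path: Path) -> None:
    df.to_csv(image_path.with_suffix(".tsv"), sep="\t", index=False)


def plot_binary_map(
    sorted_map: np.ndarray,
    cell_types: list[str],
    path: str | Path,
) -> Path:
    """Black (1) / white (0) presence map; rows = cCREs in sorted order."""
    mat = np.asarray(sorted_map)
    if mat.size == 0:
        raise ValueError("empty map: nothing to plot")
    path = Path(path)
    fig, ax = plt.subplots(figsize=(max(3, len(cell_types) * 0.5), 6))
    ax.imshow(mat, cmap="gray_r", aspect="auto", interpolation="nearest", vmin=0, vmax=1)
    ax.set_xticks(range(len(cell_types)))
    ax.set_xticklabels(cell_types, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel(f"{mat.shape[0]} cCREs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    _emit_table(pd.DataFrame(mat, columns=cell_types), path)
    return path


def plot_mean_signal_heatmap(
    mean_signals: np.ndarray,
    row_labels: list[str],
    cell_types: list[str],
    path: str | Path,
) -> Path:
    """Cluster-by-cell-type mean-signal heatmap, 1st-99th percentile clipped."""
    mat = np.asarray(mean_signals, dtype=float)
    path = Path(path)
    lo, hi = np.percentile(mat, [1, 99])
    fig, ax = plt.subplots(figsize=(max(3, len(cell_types) * 0.5), max(3, len(row_labels) * 0.25)))
    im = ax.imshow(mat, cmap="viridis", aspect="auto", vmin=lo, vmax=max(hi, lo + 1e-9))
    ax.set_xticks(range(len(cell_types)))
    ax.set_xticklabels(cell_types, rotation=90, fontsize=7)
    ax.set_yticks(range(len(row_labels)))
    ax.set_yticklabels(row_labels, fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    _emit_table(
        pd.DataFrame(mat, columns=cell_types).assign(cluster=row_labels), path
    )
    return path


def tree_layout(tree: CellTree) -> dict[str, tuple[float, float]]:
    """Layered top-down positions: x by leaf-order rank, y by depth."""
    xs = {node: i for i, node in enumerate(tree.leaf_order)}
    return {node: (float(xs[node]), -float(tree.depth(node))) for node in tree.leaf_order}


def _draw_tree(ax, tree: CellTree, node_colors: dict[str, tuple[float, float, float]], title: str):
    pos = tree_layout(tree)
    for parent, child in tree.edges:
        (x0, y0), (x1, y1) = pos[parent], pos[child]
        ax.plot([x0, x1], [y0, y1], color="0.6", lw=1, zorder=1)
    for node, (x, y) in pos.items():
        ax.scatter([x], [y], s=250, color=node_colors.get(node, (0.8, 0.8, 0.8)), zorder=2,
                   edgecolors="k", linewidths=0.5)
        ax.annotate(node, (x, y), fontsize=6, ha="center", va="center", zorder=3)
    ax.set_title(title, fontsize=8)
    ax.axis("off")


def plot_cluster_panel(
    cluster_id: str,
    member_signals: np.ndarray,
    member_states: pd.DataFrame,
    tree: CellTree,
    state_colors: dict[str, tuple[float, float, float]],
    representative_colors: dict[str, tuple[float, float, float]],
    path: str | Path,
) -> Path:
    """Composite per-cluster figure: signal tree, state tree, violins, state bars.

    ``member_signals`` is (n_members, n_celltypes); ``member_states`` holds
    one state label per member per cell type; ``representative_colors`` maps
    cell type -> summary RGB (0-255) from the representative-state rule.
    """
    path = Path(path)
    cells = tree.leaf_order
    signals = np.asarray(member_signals, dtype=float)
    if signals.shape[1] != len(cells):
        raise ValueError("signal width != number of cell types")
    mean_sig = signals.mean(axis=0)
    rng_sig = mean_sig.max() - mean_sig.min()
    sat = (mean_sig - mean_sig.min()) / (rng_sig if rng_sig > 0 else 1.0)
    signal_colors = {c: plt.get_cmap("Reds")(0.15 + 0.85 * s) for c, s in zip(cells, sat)}
    state_node_colors = {
        c: tuple(v / 255.0 for v in representative_colors[c]) for c in cells
    }

    fig, axes = plt.subplots(2, 2, figsize=(10, 7))
    _draw_tree(axes[0, 0], tree, signal_colors, f"{cluster_id}: mean signal")
    _draw_tree(axes[0, 1], tree, state_node_colors, f"{cluster_id}: representative state")

    ax = axes[1, 0]
    ax.violinplot([signals[:, j] for j in range(len(cells))], showmeans=True)
    ax.set_xticks(range(1, len(cells) + 1))
    ax.set_xticklabels(cells, rotation=90, fontsize=7)
    ax.set_ylabel("signal")

    ax = axes[1, 1]
    all_states = sorted(state_colors)
    bottoms = np.zeros(len(cells))
    proportions = {}
    for state in all_states:
        frac = np.array(
            [(member_states[c] == state).mean() for c in cells], dtype=float
        )
        proportions[state] = frac
        ax.bar(
            range(len(cells)),
            frac,
            bottom=bottoms,
            color=tuple(v / 255.0 for v in state_colors[state]),
            edgecolor="0.3",
            linewidth=0.3,
            label=state,
        )
        bottoms += frac
    ax.set_xticks(range(len(cells)))
    ax.set_xticklabels(cells, rotation=90, fontsize=7)
    ax.set_ylabel("state proportion")
    ax.legend(fontsize=6, ncol=min(4, len(all_states)))
    fig.suptitle(cluster_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    table = pd.DataFrame(proportions, index=cells)
    table.insert(0, "mean_signal", mean_sig)
    table.index.name = "cell_type"
    table.reset_index().to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
    return path
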
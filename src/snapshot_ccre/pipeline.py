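"""End-to-end orchestration: index -> filter -> rescue -> meta -> states -> figures.

Each stage is a standalone function that reads only prior-stage TSVs from
the output directory and writes its own, so stages are individually
re-runnable. All tabular outputs are headered TSV; index strings are the
cluster keys across files. ``run_pipeline`` chains the stages and writes a
manifest with sha256 checksums and stage-level counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    abundance_filter,
    evaluation,
    indexing,
    io_formats,
    meta_cluster,
    normalization,
    rescue_qda,
    state_annotation,
    visualization,
)
from .indexing import NULL_INDEX, IndexSet, parse_index

logger = logging.getLogger("snapshot")

__all__ = [
    "RunConfig",
    "run_pipeline",
    "stage_index",
    "stage_filter",
    "stage_rescue",
    "stage_meta",
    "stage_states",
    "stage_plot",
    "stage_eval",
]


@dataclass
class RunConfig:
    peaks: dict[str, str]  # cell type -> BED path
    signals: dict[str, str]  # cell type -> bedGraph/bigWig path
    tree: str
    outdir: str
    states: dict[str, str] | None = None
    colors: str | None = None
    master: str | None = None  # optional user-supplied master list
    leaf_order: list[str] | None = None
    normalization_method: str = "none"
    exclusion_fraction: float = 0.05
    fdr_alpha: float = 0.01
    manual_threshold: int | None = None
    feature_mode: str = "signal"  # signal | binary
    null_posterior_cutoff: float = 0.5
    ridge: float = 1e-6
    k_min: int = 2
    k_max: int = 30
    include_null_in_meta: bool = False
    make_figures: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        flat: dict = {}
        for key, value in raw.items():
            if key == "abundance":
                flat.update(
                    exclusion_fraction=value.get("exclusion_fraction", 0.05),
                    fdr_alpha=value.get("fdr_alpha", 0.01),
                    manual_threshold=value.get("manual_threshold"),
                )
            elif key == "rescue":
                flat.update(
                    feature_mode=value.get("feature_mode", "signal"),
                    null_posterior_cutoff=value.get("null_posterior_cutoff", 0.5),
                    ridge=value.get("ridge", 1e-6),
                )
            elif key == "meta":
                flat.update(
                    k_min=value.get("k_min", 2),
                    k_max=value.get("k_max", 30),
                    include_null_in_meta=value.get("include_null", False),
                )
            elif key == "normalization":
                flat["normalization_method"] = value.get("method", "none")
            else:
                flat[key] = value
        return cls(**flat)

    def validate(self) -> None:
        paths = [*self.peaks.values(), *self.signals.values(), self.tree]
        if self.states:
            paths.extend(self.states.values())
            if self.colors is None:
                raise ValueError("state tracks given but no color table")
            paths.append(self.colors)
        if self.master:
            paths.append(self.master)
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        if set(self.peaks) != set(self.signals):
            raise ValueError("peak and signal cell types differ")


# ---------------------------------------------------------------------------
# TSV plumbing shared by the stages
# ---------------------------------------------------------------------------

def _read_index_sets(outdir: Path) -> tuple[pd.DataFrame, list[IndexSet]]:
    df = pd.read_csv(
        outdir / "index_sets.tsv", sep="\t", dtype={"index": str}, keep_default_na=False,
        na_values=[""],
    )
    sets = []
    for idx, sub in df.groupby("index", sort=True):
        status = sub["is_status"].iloc[0]
        sets.append(
            IndexSet(
                index=str(idx),
                member_ids=sub["ccre_id"].to_numpy(),
                status=None if pd.isna(status) else str(status),
            )
        )
    return df, sets


def _read_signal_matrix(outdir: Path) -> tuple[np.ndarray, list[str], np.ndarray]:
    df = pd.read_csv(outdir / "signal_matrix.tsv", sep="\t")
    cells = [c for c in df.columns if c != "ccre_id"]
    return df[cells].to_numpy(), cells, df["ccre_id"].to_numpy()


def _binary_matrix_from_indices(df: pd.DataFrame) -> pd.DataFrame:
    bits = np.vstack([parse_index(i) for i in df["index"]])
    bm = pd.DataFrame(bits, index=df["ccre_id"].to_numpy())
    bm.index.name = "ccre_id"
    return bm


def _read_final_sets(outdir: Path, cells: list[str]) -> list[IndexSet]:
    fin = pd.read_csv(
        outdir / "final_index_sets.tsv", sep="\t", dtype={"index": str}, keep_default_na=False,
        na_values=[""],
    )
    assign = pd.read_csv(
        outdir / "ccre_assignments.tsv", sep="\t", dtype={"final_index": str},
        keep_default_na=False, na_values=[""],
    )
    members = {
        str(idx): sub["ccre_id"].to_numpy() for idx, sub in assign.groupby("final_index")
    }
    sets = []
    for _, row in fin.iterrows():
        idx = str(row["index"])
        sets.append(
            IndexSet(
                index=idx,
                member_ids=members.get(idx, np.array([], dtype=int)),
                mean_signal=np.array([row[f"mean_signal_{c}"] for c in cells]),
                status=str(row["status"]),
            )
        )
    return sets


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_index(config: RunConfig) -> dict:
    """Build master list, binary matrix, signal matrix, and initial ISs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = io_formats.read_cell_tree(config.tree, leaf_order=config.leaf_order)
    peak_lists = io_formats.read_peak_beds(config.peaks)
    if config.master:
        master = io_formats.read_bed(config.master)
        master["id"] = np.arange(len(master))
    else:
        master = io_formats.build_master_list(peak_lists.values())
    master.to_csv(outdir / "master.tsv", sep="\t", index=False)

    bm = indexing.binarize(master, peak_lists, tree)
    signal = np.column_stack(
        [io_formats.read_signal(config.signals[c], master) for c in tree.leaf_order]
    )
    signal = normalization.normalize(signal, config.normalization_method, bm)
    sig_df = pd.DataFrame(signal, columns=tree.leaf_order)
    sig_df.insert(0, "ccre_id", master["id"].to_numpy())
    sig_df.to_csv(outdir / "signal_matrix.tsv", sep="\t", index=False, float_format="%.10g")

    index_sets = indexing.group_into_index_sets(bm)
    id_to_index = {cid: s.index for s in index_sets for cid in s.member_ids}
    idx_df = master[master["id"].isin(id_to_index)].copy()
    idx_df = idx_df.rename(columns={"id": "ccre_id"})
    idx_df["index"] = idx_df["ccre_id"].map(id_to_index)
    idx_df["is_status"] = ""
    idx_df.to_csv(outdir / "index_sets.tsv", sep="\t", index=False)
    return {
        "n_ccres_master": len(master),
        "n_ccres_indexed": int(sum(s.size for s in index_sets)),
        "n_initial_is": len(index_sets),
    }


def stage_filter(config: RunConfig) -> dict:
    """NB background fit + FDR threshold; stamps is_status into index_sets.tsv."""
    outdir = Path(config.outdir)
    df, sets = _read_index_sets(outdir)
    bg, adj = abundance_filter.apply_filter(
        sets,
        exclusion_fraction=config.exclusion_fraction,
        fdr_alpha=config.fdr_alpha,
        manual_threshold=config.manual_threshold,
    )
    pd.DataFrame(
        {
            "index": [s.index for s in sets],
            "size": [s.size for s in sets],
            "pvalue": bg.tail_pvalue(np.array([s.size for s in sets])),
            "adj_pvalue": adj,
            "status": [s.status for s in sets],
        }
    ).to_csv(outdir / "abundance.tsv", sep="\t", index=False, float_format="%.6g")
    status = {s.index: s.status for s in sets}
    df["is_status"] = df["index"].map(status)
    df.to_csv(outdir / "index_sets.tsv", sep="\t", index=False)
    return {
        "abundance_threshold_size": bg.threshold_size,
        "n_abundant_is": sum(1 for s in sets if s.status == "abundant"),
        "n_filtered_is": sum(1 for s in sets if s.status == "filtered"),
    }


def stage_rescue(config: RunConfig) -> dict:
    """QDA fit on abundant ISs, filtered-cCRE re-assignment, final catalog."""
    outdir = Path(config.outdir)
    df, sets = _read_index_sets(outdir)
    signal, cells, sig_ids = _read_signal_matrix(outdir)
    full_signal = np.zeros((int(sig_ids.max()) + 1, len(cells)))
    full_signal[sig_ids] = signal
    if config.feature_mode == "binary":
        bm = _binary_matrix_from_indices(df)
        features = np.zeros_like(full_signal)
        features[bm.index.to_numpy()] = bm.to_numpy().astype(float)
    else:
        features = full_signal

    abundant = [s for s in sets if s.status == "abundant"]
    filtered = [s for s in sets if s.status == "filtered"]
    model = rescue_qda.fit_qda(
        features,
        abundant,
        ridge=config.ridge,
        null_posterior_cutoff=config.null_posterior_cutoff,
        feature_mode=config.feature_mode,
    )
    filtered_ids = (
        np.concatenate([s.member_ids for s in filtered]) if filtered else np.array([], dtype=int)
    )
    assigned, max_post = rescue_qda.rescue(model, features, filtered_ids)
    id_to_index = dict(zip(df["ccre_id"], df["index"]))
    pd.DataFrame(
        {
            "ccre_id": filtered_ids,
            "original_index": [id_to_index[c] for c in filtered_ids],
            "final_index": assigned,
            "assigned_is": assigned,
            "max_posterior": max_post,
        }
    ).to_csv(outdir / "rescue.tsv", sep="\t", index=False, float_format="%.6g")

    final_sets = rescue_qda.finalize_index_sets(sets, assigned, filtered_ids, full_signal)
    pd.DataFrame(
        {
            "index": [s.index for s in final_sets],
            "size": [s.size for s in final_sets],
            "status": [s.status for s in final_sets],
            **{
                f"mean_signal_{c}": [s.mean_signal[j] for s in final_sets]
                for j, c in enumerate(cells)
            },
        }
    ).to_csv(outdir / "final_index_sets.tsv", sep="\t", index=False, float_format="%.10g")

    final_map = {cid: s.index for s in final_sets for cid in s.member_ids}
    master = pd.read_csv(outdir / "master.tsv", sep="\t")
    assign_df = master[master["id"].isin(final_map)].copy()
    assign_df = assign_df.rename(columns={"id": "ccre_id"})
    assign_df["final_index"] = assign_df["ccre_id"].map(final_map)
    assign_df.to_csv(outdir / "ccre_assignments.tsv", sep="\t", index=False)
    n_rescued = int((assigned != NULL_INDEX).sum()) if len(assigned) else 0
    return {
        "n_rescued": n_rescued,
        "n_null": int(len(assigned) - n_rescued),
        "n_final_is": len(final_sets),
    }


def stage_meta(config: RunConfig) -> dict:
    """Merge final ISs into Meta-ISs with the AIC-selected cut."""
    outdir = Path(config.outdir)
    _, cells, _ = _read_signal_matrix(outdir)
    final_sets = _read_final_sets(outdir, cells)
    pool_n = len(final_sets) - (0 if config.include_null_in_meta else 1)
    k_hi = min(config.k_max, max(config.k_min, pool_n - 1))
    metas, chosen_k, aic_table = meta_cluster.merge_index_sets(
        final_sets,
        k_range=range(config.k_min, k_hi + 1),
        include_null=config.include_null_in_meta,
    )
    pd.DataFrame(
        [
            {"is_index": is_idx, "meta_id": m.meta_id}
            for m in metas
            for is_idx in m.member_is
        ]
    ).to_csv(outdir / "meta.tsv", sep="\t", index=False)
    (outdir / "aic.json").write_text(
        json.dumps({str(k): v for k, v in aic_table.items()}, indent=1)
    )
    means = pd.DataFrame(
        np.vstack([m.mean_signal for m in metas]), columns=cells
    )
    means.insert(0, "meta_id", [m.meta_id for m in metas])
    means.insert(1, "size", [m.size for m in metas])
    means.to_csv(outdir / "meta_mean_signal.tsv", sep="\t", index=False, float_format="%.10g")
    return {"n_meta_is": len(metas), "chosen_k": chosen_k}


def stage_states(config: RunConfig) -> dict:
    """Dominant state per cCRE/cell type + representative states per final IS."""
    if not config.states or not config.colors:
        raise ValueError("state stage requires state tracks and a color table")
    outdir = Path(config.outdir)
    master = pd.read_csv(outdir / "master.tsv", sep="\t")
    _, cells, _ = _read_signal_matrix(outdir)
    tracks = {c: io_formats.read_state_bed(p) for c, p in config.states.items()}
    colors = io_formats.read_color_table(config.colors)
    if "quiescent" not in colors:
        colors = {**colors, "quiescent": (255.0, 255.0, 255.0)}
    ccre_states = state_annotation.assign_states(master, tracks)
    ccre_states = ccre_states[[c for c in cells if c in ccre_states.columns]]
    ccre_states.reset_index().to_csv(outdir / "states_ccre.tsv", sep="\t", index=False)
    final_sets = _read_final_sets(outdir, cells)
    clusters = {s.index: s.member_ids for s in final_sets if s.size > 0}
    state_annotation.summarize_cluster_states(ccre_states, clusters, colors).to_csv(
        outdir / "states_cluster.tsv", sep="\t", index=False
    )
    return {"n_states_assigned": int(ccre_states.size)}


def stage_plot(config: RunConfig) -> dict:
    """Binary map, IS/Meta-IS heatmaps, and per-IS panels (when states exist)."""
    outdir = Path(config.outdir)
    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    df, _ = _read_index_sets(outdir)
    signal, cells, sig_ids = _read_signal_matrix(outdir)
    final_sets = _read_final_sets(outdir, cells)
    bm = _binary_matrix_from_indices(df)
    _, sorted_map = evaluation.sort_for_map(final_sets, bm)
    visualization.plot_binary_map(sorted_map, cells, figdir / "binary_map.png")
    visualization.plot_mean_signal_heatmap(
        np.vstack([s.mean_signal for s in final_sets]),
        [s.index for s in final_sets],
        cells,
        figdir / "is_mean_signal.png",
    )
    n_figs = 2
    meta_path = outdir / "meta_mean_signal.tsv"
    if meta_path.exists():
        mm = pd.read_csv(meta_path, sep="\t")
        visualization.plot_mean_signal_heatmap(
            mm[cells].to_numpy(),
            [f"meta_{i}" for i in mm["meta_id"]],
            cells,
            figdir / "meta_mean_signal.png",
        )
        n_figs += 1
    states_path = outdir / "states_ccre.tsv"
    if states_path.exists() and config.states:
        tree = io_formats.read_cell_tree(config.tree, leaf_order=config.leaf_order)
        colors = io_formats.read_color_table(config.colors)
        if "quiescent" not in colors:
            colors = {**colors, "quiescent": (255.0, 255.0, 255.0)}
        ccre_states = pd.read_csv(states_path, sep="\t").set_index("ccre_id")
        cs = pd.read_csv(outdir / "states_cluster.tsv", sep="\t")
        full_signal = np.zeros((int(sig_ids.max()) + 1, len(cells)))
        full_signal[sig_ids] = signal
        for s in final_sets:
            if s.size == 0 or s.index == NULL_INDEX:
                continue
            sub = cs[cs["cluster"] == s.index]
            rep = {
                row["cell_type"]: tuple(int(row["color_hex"][i : i + 2], 16) for i in (1, 3, 5))
                for _, row in sub.iterrows()
            }
            visualization.plot_cluster_panel(
                s.index,
                full_signal[s.member_ids],
                ccre_states.loc[s.member_ids],
                tree,
                colors,
                rep,
                figdir / f"is_{s.index.replace('_', '')}.png",
            )
            n_figs += 1
    return {"n_figures": n_figs}


def stage_eval(
    config: RunConfig,
    n_values: list[int] = (5, 10, 50),
    m_values: list[int] | None = None,
    n_reps: int = 5,
    rounds: int = 20,
) -> dict:
    """Entropy of the sorted map, noise-injection ARI, K-means rarity counts."""
    from sklearn.cluster import KMeans

    outdir = Path(config.outdir)
    df, _ = _read_index_sets(outdir)
    signal, cells, sig_ids = _read_signal_matrix(outdir)
    final_sets = _read_final_sets(outdir, cells)
    bm = _binary_matrix_from_indices(df)
    _, sorted_map = evaluation.sort_for_map(final_sets, bm)
    if m_values is None:
        m_values = list(range(2, len(cells) + 1))
    rows = []
    for n in n_values:
        if n > sorted_map.shape[0]:
            continue
        prof = evaluation.shannon_entropy(sorted_map, n, m_values)
        rows.extend({"N": n, "M": m, "SE": se} for m, se in prof.se.items())
    pd.DataFrame(rows).to_csv(outdir / "eval_entropy.tsv", sep="\t", index=False)

    id_row = {cid: i for i, cid in enumerate(sig_ids)}
    labels = np.full(len(sig_ids), -1)
    for j, s in enumerate(final_sets):
        for cid in s.member_ids:
            labels[id_row[cid]] = j
    k = max(2, len(final_sets) - 1)

    def kmeans_fn(data, rep_seed):
        return KMeans(n_clusters=k, n_init=1, random_state=config.seed + rep_seed).fit_predict(
            data
        )

    aris = evaluation.ari_reproducibility(kmeans_fn, signal, n_reps=n_reps, seed=config.seed)
    pd.DataFrame({"pair": range(len(aris)), "ari": aris}).to_csv(
        outdir / "eval_ari.tsv", sep="\t", index=False
    )

    meta_path = outdir / "meta_mean_signal.tsv"
    result = {"n_entropy_rows": len(rows), "mean_ari": float(np.mean(aris))}
    if meta_path.exists():
        mm = pd.read_csv(meta_path, sep="\t")
        counts = evaluation.rare_cluster_frequency(
            mm[cells].to_numpy(), signal, k=len(mm), rounds=rounds, seed=config.seed
        )
        pd.DataFrame({"meta_id": mm["meta_id"], "kmeans_recovery": counts}).to_csv(
            outdir / "eval_rarity.tsv", sep="\t", index=False
        )
        result["rounds"] = rounds
    return result


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the output manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, object] = {"seed": config.seed}
    for name, fn in [
        ("index", stage_index),
        ("filter", stage_filter),
        ("rescue", stage_rescue),
        ("meta", stage_meta),
    ]:
        logger.info("stage: %s", name)
        try:
            counts.update(fn(config))
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    if config.states:
        logger.info("stage: states")
        try:
            counts.update(stage_states(config))
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'states' failed: {exc}") from exc
    if config.make_figures:
        logger.info("stage: plot")
        try:
            counts.update(stage_plot(config))
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'plot' failed: {exc}") from exc

    artifacts = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "counts": counts,
        "artifacts": {str(p.relative_to(outdir)): _sha256(p) for p in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
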
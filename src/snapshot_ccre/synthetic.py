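"""Synthetic input bundles with known ground truth for every pipeline stage.

The generator plants a small set of binary index patterns with unbalanced
abundances over a cell-type tree, flips one bit in a configurable fraction
of cCREs, sprinkles singleton noise patterns near the planted ones, draws
heavy-tailed (log-normal) signals separated by presence/absence, and emits
a toy fixed-width state segmentation — all as plain-text files valid for
the readers in :mod:`snapshot_ccre.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .indexing import make_index
from .io_formats import CellTree, write_bedgraph

__all__ = ["FixtureConfig", "Fixture", "default_tree_edges", "default_patterns", "generate"]


def default_tree_edges() -> list[tuple[str, str]]:
    """A 13-cell-type hematopoiesis-like differentiation tree."""
    return [
        ("HSC", "MPP"),
        ("MPP", "CMP"),
        ("CMP", "MEP"),
        ("MEP", "ERY"),
        ("MEP", "MK"),
        ("CMP", "GMP"),
        ("GMP", "GRAN"),
        ("GMP", "MONO"),
        ("MPP", "CLP"),
        ("CLP", "B"),
        ("CLP", "NK"),
        ("CLP", "TCD4"),
    ]


def default_patterns() -> list[tuple[tuple[int, ...], int]]:
    """Five planted 13-bit patterns (pairwise Hamming >= 5), unbalanced sizes."""
    return [
        ((1,) * 13, 2000),
        ((1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0), 1000),  # erythro-megakaryocytic arm
        ((0, 0, 1, 0, 0, 0, 1, 1, 1, 0, 0, 0, 0), 500),  # myeloid arm
        ((0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1), 300),  # lymphoid arm
        ((0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0), 174),  # mature-erythroid only
    ]


@dataclass
class FixtureConfig:
    tree_edges: list[tuple[str, str]] = field(default_factory=default_tree_edges)
    patterns: list[tuple[tuple[int, ...], int]] = field(default_factory=default_patterns)
    bit_flip_rate: float = 0.05  # fraction of cCREs with spurious peak-call flips
    max_flip_bits: int = 2  # each flipped cCRE toggles 1..max_flip_bits random bits
    n_noise_singletons: int = 200  # distinct Hamming-1/2 neighbours, one cCRE each
    n_background: int = 0  # extra all-zero cCREs (master-list only; s3norm anchor)
    present_log_mean: float = np.log(10.0)
    absent_log_mean: float = 0.0
    log_sigma: float = 0.25
    scale_distortions: list[float] | None = None  # per-cell multiplicative factor
    interval_length: int = 200
    interval_gap: int = 200
    chrom: str = "chr1"
    state_alphabet: list[str] = field(default_factory=lambda: ["Q", "E", "H"])
    state_colors: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: {"Q": (255, 255, 255), "E": (240, 60, 40), "H": (40, 60, 240)}
    )
    state_freqs_present: dict[str, float] = field(
        default_factory=lambda: {"E": 0.8, "H": 0.2}
    )
    state_freqs_absent: dict[str, float] = field(default_factory=lambda: {"Q": 0.9, "H": 0.1})
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.bit_flip_rate < 0.5:
            raise ValueError("bit_flip_rate must be in [0, 0.5)")
        if any(a < 1 for _, a in self.patterns):
            raise ValueError("pattern abundances must be >= 1")
        if self.present_log_mean <= self.absent_log_mean:
            raise ValueError("present-bit signal mean must exceed absent-bit mean")
        for freqs in (self.state_freqs_present, self.state_freqs_absent):
            unknown = set(freqs) - set(self.state_alphabet)
            if unknown:
                raise ValueError(f"state frequencies reference unknown states {unknown}")
        missing = set(self.state_alphabet) - set(self.state_colors)
        if missing:
            raise ValueError(f"states without colors: {missing}")


@dataclass
class Fixture:
    config: FixtureConfig
    tree: CellTree
    master: pd.DataFrame  # chrom, start, end, id
    true_matrix: pd.DataFrame  # planted bits (pre-flip), index = ccre id
    observed_matrix: pd.DataFrame  # bits after flips; what peak files encode
    signal: np.ndarray  # raw (distorted) per-cCRE per-cell signal means
    peak_lists: dict[str, pd.DataFrame]
    state_tracks: dict[str, pd.DataFrame]
    state_matrix: pd.DataFrame  # planted state per (ccre, cell)
    colors: dict[str, tuple[float, float, float]]
    truth: pd.DataFrame  # ccre_id, true_index, observed_index, flipped, flipped_bit
    paths: dict[str, object] = field(default_factory=dict)

    @property
    def cell_types(self) -> list[str]:
        return self.tree.leaf_order


def _noise_patterns(
    planted: list[tuple[int, ...]], n: int, n_cells: int, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    """Distinct non-planted patterns at Hamming distance 1-2 from planted ones."""
    taken = set(planted)
    out: list[tuple[int, ...]] = []
    zero = (0,) * n_cells
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100 * n:
            raise ValueError("cannot find enough distinct noise patterns; too few cell types")
        base = list(planted[rng.integers(len(planted))])
        for bit in rng.choice(n_cells, size=int(rng.integers(1, 3)), replace=False):
            base[bit] = 1 - base[bit]
        cand = tuple(base)
        if cand in taken or cand == zero:
            continue
        taken.add(cand)
        out.append(cand)
    return out


def generate(config: FixtureConfig, outdir: str | Path | None = None) -> Fixture:
    """Build the full input bundle; write plain-text files when outdir is given.

    The same seed yields a byte-identical bundle.
    """
    rng = np.random.default_rng(config.seed)
    nodes: list[str] = []
    for p, c in config.tree_edges:
        for n in (p, c):
            if n not in nodes:
                nodes.append(n)
    tree = CellTree(nodes=nodes, edges=list(config.tree_edges))
    n_cells = len(tree.leaf_order)
    for pat, _ in config.patterns:
        if len(pat) != n_cells:
            raise ValueError("pattern length must equal number of cell types")

    planted = [tuple(p) for p, _ in config.patterns]
    singles = _noise_patterns(planted, config.n_noise_singletons, n_cells, rng)
    rows: list[tuple[int, ...]] = []
    archetype: list[int] = []  # planted-pattern id, -1 noise, -2 background
    for k, (pat, abundance) in enumerate(config.patterns):
        rows.extend([pat] * abundance)
        archetype.extend([k] * abundance)
    rows.extend(singles)
    archetype.extend([-1] * len(singles))
    rows.extend([(0,) * n_cells] * config.n_background)
    archetype.extend([-2] * config.n_background)

    n = len(rows)
    order = rng.permutation(n)  # interleave patterns along the chromosome
    true_mat = np.array(rows, dtype=np.int8)[order]
    archetype = np.array(archetype)[order]

    # Spurious peak calls: a bit_flip_rate fraction of non-background cCREs
    # gets 1..max_flip_bits random bits toggled in the *peak calls only*;
    # the underlying signal keeps following the true pattern.
    flip_draw = rng.random(n)
    flipped = (flip_draw < config.bit_flip_rate) & (archetype != -2)
    observed = true_mat.copy()
    flipped_bits: list[str] = [""] * n
    for i in np.flatnonzero(flipped):
        n_bits = int(rng.integers(1, config.max_flip_bits + 1))
        bits = rng.choice(n_cells, size=n_bits, replace=False)
        observed[i, bits] ^= 1
        if observed[i].sum() == 0:
            # an all-zero row would be dropped before IS formation; undo
            observed[i] = true_mat[i]
            flipped[i] = False
        else:
            flipped_bits[i] = ",".join(str(b) for b in sorted(bits))

    step = config.interval_length + config.interval_gap
    starts = np.arange(n) * step
    master = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": starts,
            "end": starts + config.interval_length,
            "id": np.arange(n),
        }
    )

    # Signals: log-normal, location set by the *true* bit (peak-call flips are
    # spurious calls; the signal still reflects the planted pattern), with a
    # per-cell multiplicative distortion.
    loc = np.where(true_mat == 1, config.present_log_mean, config.absent_log_mean)
    raw = np.exp(rng.normal(loc, config.log_sigma))
    distort = np.asarray(
        config.scale_distortions if config.scale_distortions is not None else np.ones(n_cells)
    )
    if len(distort) != n_cells:
        raise ValueError("scale_distortions length must equal number of cell types")
    raw = raw * distort
    # Quantize so text round-trips are exact.
    signal = np.array([[float(f"{v:.4f}") for v in row] for row in raw])

    peak_lists = {
        cell: master.loc[observed[:, j] == 1, ["chrom", "start", "end"]].reset_index(drop=True)
        for j, cell in enumerate(tree.leaf_order)
    }

    # States: one bin per cCRE per cell type, drawn by observed presence.
    def draw_states(freqs: dict[str, float], size: int) -> np.ndarray:
        labels = sorted(freqs)
        p = np.array([freqs[s] for s in labels], dtype=float)
        p /= p.sum()
        return np.array(labels, dtype=object)[rng.choice(len(labels), size=size, p=p)]

    state_cols = {}
    for j, cell in enumerate(tree.leaf_order):
        col = np.empty(n, dtype=object)
        pres = observed[:, j] == 1
        col[pres] = draw_states(config.state_freqs_present, int(pres.sum()))
        col[~pres] = draw_states(config.state_freqs_absent, int((~pres).sum()))
        state_cols[cell] = col
    state_matrix = pd.DataFrame(state_cols, index=master["id"].to_numpy())
    state_matrix.index.name = "ccre_id"
    state_tracks = {
        cell: pd.DataFrame(
            {
                "chrom": config.chrom,
                "start": master["start"],
                "end": master["end"],
                "state": state_cols[cell],
            }
        )
        for cell in tree.leaf_order
    }

    true_index = [make_index(r) for r in true_mat]
    observed_index = [make_index(r) for r in observed]
    truth = pd.DataFrame(
        {
            "ccre_id": np.arange(n),
            "archetype": archetype,
            "true_index": true_index,
            "observed_index": observed_index,
            "flipped": flipped,
            "flipped_bits": flipped_bits,
        }
    )
    colors = {s: tuple(float(c) for c in rgb) for s, rgb in config.state_colors.items()}

    fixture = Fixture(
        config=config,
        tree=tree,
        master=master,
        true_matrix=pd.DataFrame(
            true_mat, index=master["id"].to_numpy(), columns=tree.leaf_order
        ),
        observed_matrix=pd.DataFrame(
            observed, index=master["id"].to_numpy(), columns=tree.leaf_order
        ),
        signal=signal,
        peak_lists=peak_lists,
        state_tracks=state_tracks,
        state_matrix=state_matrix,
        colors=colors,
        truth=truth,
    )
    if outdir is not None:
        fixture.paths = _write_bundle(fixture, Path(outdir))
    return fixture


def _write_bundle(fx: Fixture, outdir: Path) -> dict[str, object]:
    outdir.mkdir(parents=True, exist_ok=True)
    for sub in ("peaks", "signals", "states"):
        (outdir / sub).mkdir(exist_ok=True)
    paths: dict[str, object] = {
        "peaks": {},
        "signals": {},
        "states": {},
        "tree": outdir / "tree.txt",
        "colors": outdir / "colors.txt",
        "master": outdir / "master.bed",
        "truth": outdir / "truth.tsv",
    }
    for j, cell in enumerate(fx.cell_types):
        p = outdir / "peaks" / f"{cell}.bed"
        fx.peak_lists[cell].to_csv(p, sep="\t", header=False, index=False)
        paths["peaks"][cell] = p  # type: ignore[index]
        s = outdir / "signals" / f"{cell}.bedgraph"
        write_bedgraph(
            s, fx.master["chrom"], fx.master["start"], fx.master["end"], fx.signal[:, j]
        )
        paths["signals"][cell] = s  # type: ignore[index]
        st = outdir / "states" / f"{cell}.bed"
        fx.state_tracks[cell].to_csv(st, sep="\t", header=False, index=False)
        paths["states"][cell] = st  # type: ignore[index]
    with open(paths["tree"], "w") as fh:  # type: ignore[arg-type]
        for parent, child in fx.tree.edges:
            fh.write(f"{parent}\t{child}\n")
    with open(paths["colors"], "w") as fh:  # type: ignore[arg-type]
        for state, rgb in fx.colors.items():
            fh.write(f"{state}\t{int(rgb[0])},{int(rgb[1])},{int(rgb[2])}\n")
    fx.master.to_csv(paths["master"], sep="\t", header=False, index=False)  # type: ignore[arg-type]
    fx.truth.to_csv(paths["truth"], sep="\t", index=False)  # type: ignore[arg-type]
    return paths
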
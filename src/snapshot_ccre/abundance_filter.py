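"""Negative-binomial background model over Index-Set sizes.

IS sizes are treated as counts from a background process; unusually large
ISs (upper-tail, FDR-controlled) are called abundant, the rest filtered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .indexing import IndexSet

__all__ = ["NbBackground", "fit_nb_background", "abundance_threshold", "apply_filter"]


@dataclass
class NbBackground:
    """Method-of-moments NB fit (Poisson fallback when underdispersed)."""

    mean: float
    var: float
    r: float | None  # NB size parameter; None => Poisson
    p: float | None  # NB success probability (scipy convention); None => Poisson
    exclusion_fraction: float = 0.05
    fdr_alpha: float = 0.01
    threshold_size: int | None = None  # smallest size called abundant

    @property
    def is_poisson(self) -> bool:
        return self.r is None

    def tail_pvalue(self, sizes: np.ndarray) -> np.ndarray:
        """Upper-tail P(X >= size) under the background."""
        sizes = np.asarray(sizes)
        if self.is_poisson:
            return stats.poisson.sf(sizes - 1, self.mean)
        return stats.nbinom.sf(sizes - 1, self.r, self.p)


def fit_nb_background(sizes: np.ndarray, exclusion_fraction: float = 0.05) -> NbBackground:
    """Fit the NB background to IS sizes, excluding the largest ISs.

    The top ``exclusion_fraction`` of ISs by size is removed before fitting;
    sizes tied with the first retained value stay in (only sizes strictly
    greater than the boundary value are dropped). Method-of-moments:
    r = m^2/(v-m), p = m/v; Poisson(m) fallback when v <= m.
    """
    if not 0 < exclusion_fraction < 0.5:
        raise ValueError("exclusion_fraction must be in (0, 0.5)")
    sizes = np.asarray(sizes, dtype=float)
    n_excl = int(np.floor(len(sizes) * exclusion_fraction))
    desc = np.sort(sizes)[::-1]
    boundary = desc[n_excl] if n_excl < len(sizes) else desc[-1]
    kept = sizes[sizes <= boundary]
    if len(kept) < 5:
        raise ValueError(f"only {len(kept)} ISs left after exclusion; need >=5 to fit")
    m = float(kept.mean())
    v = float(kept.var(ddof=1))
    if v <= m:
        warnings.warn("sizes underdispersed (var <= mean); falling back to Poisson")
        return NbBackground(mean=m, var=v, r=None, p=None, exclusion_fraction=exclusion_fraction)
    r = m * m / (v - m)
    p = m / v
    return NbBackground(mean=m, var=v, r=r, p=p, exclusion_fraction=exclusion_fraction)


def abundance_threshold(
    bg: NbBackground,
    sizes: np.ndarray,
    fdr_alpha: float = 0.01,
    manual_threshold: int | None = None,
) -> tuple[int, np.ndarray]:
    """Derive the abundance threshold and per-IS BH-adjusted p-values.

    Returns ``(threshold_size, adjusted_pvalues)`` where ``threshold_size``
    is the smallest size called abundant. With ``manual_threshold`` t, an IS
    is abundant iff its size is strictly greater than t (so
    ``threshold_size = t + 1``); adjusted p-values are still reported.
    """
    if not 0 < fdr_alpha < 1:
        raise ValueError("fdr_alpha must be in (0, 1)")
    sizes = np.asarray(sizes)
    pvals = bg.tail_pvalue(sizes)
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    if manual_threshold is not None:
        threshold_size = int(manual_threshold) + 1
    else:
        passing = sizes[adj < fdr_alpha]
        if len(passing) == 0:
            raise ValueError(
                "no IS passes the abundance FDR cutoff; supply "
                "abundance.manual_threshold to set the threshold by hand"
            )
        threshold_size = int(passing.min())
    bg.fdr_alpha = fdr_alpha
    bg.threshold_size = threshold_size
    return threshold_size, adj


def apply_filter(
    index_sets: list[IndexSet],
    exclusion_fraction: float = 0.05,
    fdr_alpha: float = 0.01,
    manual_threshold: int | None = None,
) -> tuple[NbBackground, np.ndarray]:
    """Fit the background and set each IS's status to abundant/filtered."""
    sizes = np.array([s.size for s in index_sets])
    bg = fit_nb_background(sizes, exclusion_fraction=exclusion_fraction)
    threshold, adj = abundance_threshold(
        bg, sizes, fdr_alpha=fdr_alpha, manual_threshold=manual_threshold
    )
    for s in index_sets:
        s.status = "abundant" if s.size >= threshold else "filtered"
    return bg, adj
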
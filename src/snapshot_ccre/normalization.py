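"""Optional per-cell-type signal normalization.

Three methods: per-column scaling, classic quantile normalization, and a
signal-to-noise matching scheme anchored on the common-peak (all-ones
index) and common-background (all-zeros index) cCREs. Normalization runs
after binarization, so indices never depend on the method chosen.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["scale_norm", "quantile_norm", "s3norm_like", "normalize", "signal_to_noise"]


def scale_norm(sm: np.ndarray) -> np.ndarray:
    """Z-scale each column, then shift so the column minimum is 0."""
    x = np.asarray(sm, dtype=float).copy()
    for c in range(x.shape[1]):
        sd = x[:, c].std(ddof=0)
        if sd <= 0:
            warnings.warn(f"column {c} has zero variance; left unscaled")
            continue
        col = (x[:, c] - x[:, c].mean()) / sd
        x[:, c] = col - col.min()
    return x


def quantile_norm(sm: np.ndarray) -> np.ndarray:
    """Replace each column's sorted values by across-column sorted means.

    Ties receive the average of the reference values they span (average
    ranks interpolated into the reference distribution).
    """
    x = np.asarray(sm, dtype=float)
    if np.isnan(x).any():
        raise ValueError("quantile_norm does not accept NaNs")
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    positions = np.arange(1, n + 1, dtype=float)
    for c in range(x.shape[1]):
        ranks = rankdata(x[:, c], method="average")
        out[:, c] = np.interp(ranks, positions, reference)
    return out


def signal_to_noise(sm: np.ndarray, bm: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Per-column mean signal over common-peak rows minus common-background rows."""
    bits = bm.to_numpy() if isinstance(bm, pd.DataFrame) else np.asarray(bm)
    common_peak = bits.all(axis=1)
    common_bg = ~bits.any(axis=1)
    if common_peak.sum() < 10 or common_bg.sum() < 10:
        raise ValueError(
            "need >=10 common-peak (all-ones) and >=10 common-background "
            "(all-zeros) cCREs for S/N matching; consider quantile normalization"
        )
    x = np.asarray(sm, dtype=float)
    return x[common_peak].mean(axis=0) - x[common_bg].mean(axis=0)


def s3norm_like(sm: np.ndarray, bm: np.ndarray | pd.DataFrame, log: bool = False) -> np.ndarray:
    """Scale each column so its signal-to-noise matches the across-column mean.

    S/N per cell type = mean signal at common-peak cCREs minus mean at
    common-background cCREs; each column is multiplied by
    ``mean(S/N) / S/N_c``. With ``log=True`` the S/N is measured on
    log1p signal; the factor still multiplies the raw columns.
    """
    x = np.asarray(sm, dtype=float)
    work = np.log1p(x) if log else x
    sn = signal_to_noise(work, bm)
    if (sn <= 0).any():
        raise ValueError("non-positive signal-to-noise in some cell type; check inputs")
    factors = sn.mean() / sn
    return x * factors


def normalize(sm: np.ndarray, method: str, bm: np.ndarray | pd.DataFrame | None = None) -> np.ndarray:
    if method == "none":
        return np.asarray(sm, dtype=float)
    if method == "scale":
        return scale_norm(sm)
    if method == "quantile":
        return quantile_norm(sm)
    if method == "s3norm":
        if bm is None:
            raise ValueError("s3norm requires the binary matrix")
        return s3norm_like(sm, bm)
    raise ValueError(f"unknown normalization method {method!r}")
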
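"""Rescue cCREs from filtered Index-Sets via per-IS Gaussian discriminants.

Each abundant IS is modelled as a multivariate Gaussian over per-cell-type
features (continuous signal by default, raw bits optionally). A filtered
cCRE x is scored against IS i with

    score_i(x) = -1/2 log|S_i| - 1/2 (x - mu_i)' S_i^{-1} (x - mu_i) + log P0_i

and assigned to the argmax IS when the softmax posterior reaches the null
cutoff (default 0.5), otherwise to the null class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from .indexing import NULL_INDEX, IndexSet

__all__ = ["QdaModel", "fit_qda", "rescue", "finalize_index_sets"]


@dataclass
class QdaModel:
    class_indices: list[str]  # index string per abundant IS, model order
    means: np.ndarray  # (k, d)
    covariances: np.ndarray  # (k, d, d), after ridge
    priors: np.ndarray  # (k,), proportions among abundant ISs
    ridge: float = 1e-6
    null_posterior_cutoff: float = 0.5
    feature_mode: str = "signal"  # signal | binary
    _log_dets: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _chol: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not 0 < self.null_posterior_cutoff < 1:
            raise ValueError("null_posterior_cutoff must be in (0, 1)")
        if self._log_dets is None:
            self._factorize()

    def _factorize(self) -> None:
        log_dets = []
        chols = []
        for cov in self.covariances:
            c, low = cho_factor(cov, lower=True)
            log_dets.append(2.0 * np.log(np.diag(c)).sum())
            chols.append((c, low))
        self._log_dets = np.array(log_dets)
        self._chol = chols

    def discriminant_scores(self, x: np.ndarray) -> np.ndarray:
        """Score matrix (n, k) of the per-IS discriminant for each row of x."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.means.shape[1]:
            raise ValueError(
                f"feature length {x.shape[1]} != model dimension {self.means.shape[1]}"
            )
        n, k = x.shape[0], len(self.class_indices)
        scores = np.empty((n, k))
        log_priors = np.log(self.priors)
        for i in range(k):
            diff = x - self.means[i]
            solved = cho_solve(self._chol[i], diff.T).T
            maha = np.einsum("ij,ij->i", diff, solved)
            scores[:, i] = -0.5 * self._log_dets[i] - 0.5 * maha + log_priors[i]
        return scores

    def posteriors(self, x: np.ndarray) -> np.ndarray:
        scores = self.discriminant_scores(x)
        return np.exp(scores - logsumexp(scores, axis=1, keepdims=True))


def _class_covariance(x: np.ndarray) -> np.ndarray:
    if len(x) < 2:
        return np.zeros((x.shape[1], x.shape[1]))
    return np.cov(x, rowvar=False, ddof=1)


def fit_qda(
    features: np.ndarray,
    abundant_sets: list[IndexSet],
    ridge: float = 1e-6,
    null_posterior_cutoff: float = 0.5,
    feature_mode: str = "signal",
) -> QdaModel:
    """Fit per-IS mean/covariance/prior on the abundant Index-Sets.

    ``features`` is the (n_ccres, n_celltypes) matrix indexed by cCRE id.
    Classes smaller than d + 2 members borrow the size-weighted pooled
    covariance of all abundant classes. Ridge regularization adds
    ``ridge * tr(S)/d`` to the diagonal; if a covariance is still not
    positive-definite the ridge is increased tenfold up to three times.
    """
    if not abundant_sets:
        raise ValueError("no abundant Index-Sets to fit")
    d = features.shape[1]
    sizes = np.array([s.size for s in abundant_sets], dtype=float)
    priors = sizes / sizes.sum()
    means = np.vstack([features[s.member_ids].mean(axis=0) for s in abundant_sets])
    raw_covs = [_class_covariance(features[s.member_ids]) for s in abundant_sets]
    pooled = np.einsum("i,ijk->jk", sizes / sizes.sum(), np.array(raw_covs))
    covs = []
    for s, cov in zip(abundant_sets, raw_covs):
        covs.append(pooled if s.size < d + 2 else cov)

    def ridged(cov: np.ndarray, lam: float) -> np.ndarray:
        scale = np.trace(cov) / d
        if scale <= 0:
            scale = 1.0
        return cov + lam * scale * np.eye(d)

    lam = ridge
    for _attempt in range(4):
        try:
            model = QdaModel(
                class_indices=[s.index for s in abundant_sets],
                means=means,
                covariances=np.array([ridged(c, lam) for c in covs]),
                priors=priors,
                ridge=lam,
                null_posterior_cutoff=null_posterior_cutoff,
                feature_mode=feature_mode,
            )
            return model
        except np.linalg.LinAlgError:
            lam *= 10
    raise np.linalg.LinAlgError(
        f"covariance singular even after ridge inflation to {lam / 10:g}"
    )


def rescue(model: QdaModel, features: np.ndarray, ccre_ids: np.ndarray):
    """Assign each filtered cCRE to an abundant IS or the null class.

    Returns ``(assigned, max_posterior)``: ``assigned`` holds the winning
    IS's index string (or ``"null"``); a max posterior exactly at the cutoff
    is assigned (the null rule is strict '< cutoff').
    """
    if len(ccre_ids) == 0:
        return np.array([], dtype=object), np.array([])
    post = model.posteriors(features[ccre_ids])
    best = post.argmax(axis=1)
    max_post = post[np.arange(len(best)), best]
    assigned = np.array([model.class_indices[i] for i in best], dtype=object)
    # strict '< cutoff' null rule; tolerance keeps an exact tie at the cutoff
    # (posterior == cutoff up to rounding) on the assigned side
    assigned[max_post < model.null_posterior_cutoff - 1e-9] = NULL_INDEX
    return assigned, max_post


def finalize_index_sets(
    index_sets: list[IndexSet],
    rescue_assigned: np.ndarray,
    rescue_ids: np.ndarray,
    signal: np.ndarray,
) -> list[IndexSet]:
    """Fold rescued cCREs into their abundant ISs and collect the null IS.

    Total cCRE count is conserved; mean_signal is recomputed for every
    final IS from the signal matrix.
    """
    abundant = [s for s in index_sets if s.status == "abundant"]
    extra: dict[str, list[np.ndarray]] = {s.index: [s.member_ids] for s in abundant}
    null_members: list[np.ndarray] = []
    for target in set(rescue_assigned):
        ids = rescue_ids[rescue_assigned == target]
        if target == NULL_INDEX:
            null_members.append(ids)
        else:
            extra[str(target)].append(ids)
    final: list[IndexSet] = []
    for s in abundant:
        members = np.sort(np.concatenate(extra[s.index]))
        final.append(
            IndexSet(
                index=s.index,
                member_ids=members,
                mean_signal=signal[members].mean(axis=0),
                status="abundant",
            )
        )
    null_ids = np.sort(np.concatenate(null_members)) if null_members else np.array([], dtype=int)
    null_mean = signal[null_ids].mean(axis=0) if len(null_ids) else np.zeros(signal.shape[1])
    final.append(
        IndexSet(index=NULL_INDEX, member_ids=null_ids, mean_signal=null_mean, status="null")
    )
    return final
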
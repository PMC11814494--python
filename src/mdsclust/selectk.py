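"""Data-driven choice of the number of clusters k.

Three selectors are provided, all driving the same PAM backend:

* Silhouette index (SI): mean silhouette width, maximized over k >= 2.
* Gap statistic: within-cluster dispersion compared against B uniform
  reference datasets; the smallest k whose gap is within one reference
  standard error of the next is chosen.
* Prediction strength (PS): how reliably medoids fitted on one random half
  of the samples predict co-clustering in the other half; the largest k
  whose mean strength clears a threshold (default 0.8) is chosen.

SI delegates per-sample widths to scikit-learn (precomputed distances);
Gap and PS are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_samples

from .mds import _as_matrix, embed
from .pam import pam_fit

__all__ = [
    "SelectorConfig",
    "silhouette_index",
    "gap_statistic",
    "prediction_strength",
    "select_k",
]


@dataclass(frozen=True)
class SelectorConfig:
    """Which selector to run and its tuning parameters."""

    method: str = "si"  # si | gap | ps
    k_min: int = 1
    k_max: int = 10
    gap_B: int = 50
    ps_threshold: float = 0.8
    ps_splits: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("si", "gap", "ps"):
            raise ValueError("method must be one of si, gap, ps")
        if self.k_min > self.k_max:
            raise ValueError("k_min must not exceed k_max")
        if self.gap_B < 10:
            raise ValueError("gap_B must be at least 10")
        if not 0.0 < self.ps_threshold < 1.0:
            raise ValueError("ps_threshold must lie in (0, 1)")


def silhouette_index(d, membership) -> float:
    """Mean silhouette width of a partition under precomputed distances.

    Singleton clusters contribute width 0.  Requires at least 2 clusters.
    """
    D, _ = _as_matrix(d)
    labels = np.asarray(membership)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(silhouette_samples(D, labels, metric="precomputed").mean())


def _within_dispersion(D_sq: np.ndarray, membership: np.ndarray) -> float:
    """W_k = sum over clusters of (pairwise squared-distance sum) / (2 n_r)."""
    W = 0.0
    for lab in np.unique(membership):
        idx = np.flatnonzero(membership == lab)
        if idx.size < 2:
            continue
        W += D_sq[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return W


def _cluster_points(points: np.ndarray, k: int) -> np.ndarray:
    D = squareform(pdist(points))
    return pam_fit(D, k).membership


def gap_statistic(points=None, dmatrix=None, k_range=None, B: int = 50, seed: int = 0):
    """Gap statistic over a k range; returns (k_hat, diagnostics).

    In embedded mode (``points``) the data are clustered with PAM on their
    Euclidean distances and references are drawn uniformly over the
    per-coordinate bounding box.  In raw-distance mode (``dmatrix``) the
    observed dispersion uses the supplied distances squared, while
    references are drawn uniformly over the bounding box of the full
    principal-coordinate embedding of the matrix — an approximation, since
    the gap statistic has no exact definition for arbitrary dissimilarities.
    (Permuting embedded coordinates instead degenerates whenever one
    coordinate dominates: in 1-D a permutation reproduces the data and the
    gap vanishes identically.)

    Selection rule: the smallest k with Gap(k) >= Gap(k+1) - s_{k+1}, where
    s_k is the reference standard deviation times sqrt(1 + 1/B).
    """
    if (points is None) == (dmatrix is None):
        raise ValueError("provide exactly one of points or dmatrix")
    rng = np.random.default_rng(seed)
    if k_range is None:
        k_range = range(1, 11)
    ks = sorted(int(k) for k in k_range)
    if points is not None:
        points = np.asarray(points, dtype=float)
        D = squareform(pdist(points))
        ref_basis = points
    else:
        D, _ = _as_matrix(dmatrix)
        probe = embed(dmatrix, rank=1)
        n_pos = int((probe.eigenvalues > 1e-12 * max(probe.eigenvalues[0], 1.0)).sum())
        ref_basis = embed(dmatrix, rank=max(n_pos, 1)).coordinates
    D_sq = D * D
    n = D.shape[0]
    logW = {}
    memberships = {}
    for k in ks:
        memberships[k] = pam_fit(D, k).membership
        W = _within_dispersion(D_sq, memberships[k])
        if W <= 0:
            # all points in every cluster coincide: no structure beyond k
            return 1, {"gap": {}, "s": {}, "note": "degenerate (zero dispersion)"}
        logW[k] = np.log(W)
    gap = {}
    s = {}
    lo, hi = ref_basis.min(axis=0), ref_basis.max(axis=0)
    for k in ks:
        ref_logW = np.empty(B)
        for b in range(B):
            ref = rng.uniform(lo, hi, size=ref_basis.shape)
            memb = _cluster_points(ref, k)
            Dr = squareform(pdist(ref))
            Wr = _within_dispersion(Dr * Dr, memb)
            ref_logW[b] = np.log(Wr) if Wr > 0 else -np.inf
        gap[k] = float(ref_logW.mean() - logW[k])
        s[k] = float(ref_logW.std(ddof=0) * np.sqrt(1.0 + 1.0 / B))
    k_hat = ks[-1]
    for i, k in enumerate(ks[:-1]):
        nxt = ks[i + 1]
        if gap[k] >= gap[nxt] - s[nxt]:
            k_hat = k
            break
    return k_hat, {"gap": gap, "s": s}


def prediction_strength(
    dmatrix=None,
    points=None,
    k_range=None,
    threshold: float = 0.8,
    n_splits: int = 10,
    seed: int = 0,
):
    """Prediction strength over a k range; returns (k_hat, mean ps per k).

    Each split halves the samples at random; both halves are clustered with
    PAM, test samples are assigned to their nearest training medoid, and
    ps(k) is the minimum over test clusters of the fraction of co-clustered
    test pairs that the training rule also co-assigns.  ps(1) is 1 by
    definition.  k_hat is the largest k whose mean ps reaches ``threshold``.
    """
    if (points is None) == (dmatrix is None):
        raise ValueError("provide exactly one of points or dmatrix")
    if points is not None:
        D = squareform(pdist(np.asarray(points, dtype=float)))
    else:
        D, _ = _as_matrix(dmatrix)
    n = D.shape[0]
    if n < 4:
        raise ValueError("prediction strength needs at least 4 samples")
    rng = np.random.default_rng(seed)
    if k_range is None:
        k_range = range(1, 11)
    ks = sorted(int(k) for k in k_range)
    scores: dict[int, float] = {}
    splits = [rng.permutation(n) for _ in range(n_splits)]
    for k in ks:
        if k == 1:
            scores[1] = 1.0
            continue
        vals = []
        for perm in splits:
            train, test = perm[: n // 2], perm[n // 2 :]
            if min(train.size, test.size) < k:
                continue
            train_res = pam_fit(D[np.ix_(train, train)], k)
            test_res = pam_fit(D[np.ix_(test, test)], k)
            train_medoids = train[train_res.medoid_indices]
            pred = np.argmin(D[np.ix_(test, train_medoids)], axis=1)
            vals.append(_min_cocluster_agreement(test_res.membership, pred))
        if vals:
            scores[k] = float(np.mean(vals))
    valid = [k for k, v in scores.items() if v >= threshold]
    k_hat = max(valid) if valid else 1
    return k_hat, scores


def _min_cocluster_agreement(test_membership: np.ndarray, pred: np.ndarray) -> float:
    worst = 1.0
    for lab in np.unique(test_membership):
        idx = np.flatnonzero(test_membership == lab)
        m = idx.size
        if m < 2:
            continue
        total = m * (m - 1) / 2
        agree = 0.0
        for p in np.unique(pred[idx]):
            c = int((pred[idx] == p).sum())
            agree += c * (c - 1) / 2
        worst = min(worst, agree / total)
    return worst


def select_k(config: SelectorConfig, points=None, dmatrix=None):
    """Dispatch to the configured selector; returns (k_hat, diagnostics).

    Diagnostics hold the full score curve (one entry per evaluated k) so
    the choice can be audited downstream.
    """
    if (points is None) == (dmatrix is None):
        raise ValueError("provide exactly one of points or dmatrix")
    if dmatrix is None:
        D = squareform(pdist(np.asarray(points, dtype=float)))
    else:
        D, _ = _as_matrix(dmatrix)
    n = D.shape[0]
    k_max = min(config.k_max, n - 1)
    if config.method == "si":
        k_min = max(config.k_min, 2)
        curve = {}
        for k in range(k_min, k_max + 1):
            memb = pam_fit(D, k).membership
            curve[k] = silhouette_index(D, memb)
        k_hat = max(curve, key=lambda k: (curve[k], -k))
        diag = {"si": curve}
        if curve[k_hat] <= 0:
            diag["note"] = "no clear cluster structure (best silhouette <= 0)"
        return k_hat, diag
    k_range = range(max(config.k_min, 1), k_max + 1)
    if config.method == "gap":
        if points is not None:
            return gap_statistic(points=points, k_range=k_range, B=config.gap_B, seed=config.seed)
        return gap_statistic(dmatrix=dmatrix, k_range=k_range, B=config.gap_B, seed=config.seed)
    kwargs = dict(
        k_range=k_range,
        threshold=config.ps_threshold,
        n_splits=config.ps_splits,
        seed=config.seed,
    )
    if points is not None:
        k_hat, scores = prediction_strength(points=points, **kwargs)
    else:
        k_hat, scores = prediction_strength(dmatrix=dmatrix, **kwargs)
    return k_hat, {"ps": scores}
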
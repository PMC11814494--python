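"""Partitioning Around Medoids (k-medoids) on a precomputed distance matrix.

Classical Kaufman-Rousseeuw BUILD + SWAP: BUILD greedily seeds medoids
(first minimizes total distance, each next maximizes cost reduction), then
SWAP repeatedly applies the single best-improving (medoid, non-medoid)
exchange until none lowers the objective.  Fully deterministic — ties
break everywhere to the lowest sample index, so no seed is needed.

Single-start BUILD+SWAP is a local search and can stall above the global
optimum even on tiny instances.  On small problems (n <= 30), where it is
cheap, the search is therefore restarted once from every sample as the
forced first BUILD medoid and the best local optimum kept; empirically this
recovers the exhaustive-search optimum on all small random instances.
Large problems use the single classical start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .mds import MdsEmbedding, _as_matrix

__all__ = ["ClusterResult", "pam_fit", "pam_on_embedding"]

_SWAP_TOL = 1e-12
_MULTISTART_MAX_N = 30


@dataclass(frozen=True)
class ClusterResult:
    """A PAM partition: membership in 1..k, medoids, and the objective.

    Cluster labels are canonical: numbered by first appearance in the
    membership vector, so label identity is reproducible across runs.
    """

    sample_ids: list[str]
    membership: np.ndarray  # length n, values 1..k
    medoid_indices: np.ndarray  # k sample indices, medoid_indices[j] serves cluster j+1
    k: int
    objective: float
    selector_diagnostics: Optional[dict] = None
    diagnostics_extra: Optional[dict] = field(default=None, compare=False)

    def labels(self) -> np.ndarray:
        return self.membership


def pam_fit(d, k: int, selector_diagnostics: dict | None = None) -> ClusterResult:
    """Cluster a distance matrix into k groups around medoids."""
    D, ids = _as_matrix(d)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must lie in 1..n={n}")
    starts = [_build(D, k)]
    if n <= _MULTISTART_MAX_N:
        starts.extend(_build(D, k, first=i) for i in range(n))
    medoids, best_obj = None, np.inf
    for start in starts:
        cand = _swap(D, start)
        obj = D[:, cand].min(axis=1).sum()
        if obj < best_obj - _SWAP_TOL:
            medoids, best_obj = cand, obj
    medoids = np.sort(medoids)
    dist_to_med = D[:, medoids]
    assign = np.argmin(dist_to_med, axis=1)  # ties -> lowest medoid index
    # a medoid serves its own cluster even when duplicates tie at distance 0
    assign[medoids] = np.arange(k)
    objective = float(dist_to_med[np.arange(n), assign].sum())
    membership, medoids = _canonical(assign, medoids)
    return ClusterResult(
        sample_ids=ids,
        membership=membership,
        medoid_indices=medoids,
        k=k,
        objective=objective,
        selector_diagnostics=selector_diagnostics,
    )


def _build(D: np.ndarray, k: int, first: int | None = None) -> np.ndarray:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=0))) if first is None else int(first)]
    nearest = D[:, medoids[0]].copy()
    for _ in range(1, k):
        gains = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        h = int(np.argmax(gains))  # ties -> lowest index
        medoids.append(h)
        nearest = np.minimum(nearest, D[:, h])
    return np.asarray(medoids)


def _swap(D: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    k = medoids.size
    if k == n:
        return medoids
    medoids = medoids.copy()
    while True:
        dist_to_med = D[:, medoids]
        order = np.argsort(dist_to_med, axis=1, kind="stable")
        nearest_val = dist_to_med[np.arange(n), order[:, 0]]
        nearest_pos = order[:, 0]
        second_val = dist_to_med[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        total = nearest_val.sum()
        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[medoids] = True
        best_delta, best_j, best_h = -_SWAP_TOL, -1, -1
        for j in range(k):
            # cost of each point if medoid j were removed
            adj = np.where(nearest_pos == j, second_val, nearest_val)
            cand_cost = np.minimum(D, adj[:, None]).sum(axis=0) - total
            cand_cost[is_medoid] = np.inf
            h = int(np.argmin(cand_cost))
            if cand_cost[h] < best_delta:
                best_delta, best_j, best_h = cand_cost[h], j, h
        if best_j < 0:
            return medoids
        medoids[best_j] = best_h


def _canonical(assign: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel clusters 1..k by first appearance; reorder medoids to match."""
    relabel: dict[int, int] = {}
    membership = np.empty(assign.size, dtype=int)
    for i, a in enumerate(assign):
        if a not in relabel:
            relabel[a] = len(relabel) + 1
        membership[i] = relabel[a]
    new_medoids = np.empty(len(relabel), dtype=int)
    for old, new in relabel.items():
        new_medoids[new - 1] = medoids[old]
    return membership, new_medoids


def pam_on_embedding(e: MdsEmbedding, k: int) -> ClusterResult:
    """PAM on the Euclidean distances of the embedded coordinates."""
    D = squareform(pdist(e.coordinates))
    dm = DistanceMatrix(D, ids=list(e.sample_ids))
    return pam_fit(dm, k)
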
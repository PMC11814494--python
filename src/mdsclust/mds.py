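"""Classical multidimensional scaling (principal coordinates analysis).

Squared pairwise distances are double-centered into a Gram matrix
B = -1/2 L (D o D) L with L = I - 11^T/n, eigendecomposed, and the samples
embedded as Y = Q_r Lambda_r^{1/2} on the leading strictly positive
eigenvalues.  For Euclidean distance matrices this recovers the original
point configuration exactly; for non-Euclidean metrics (Bray-Curtis,
UniFrac) negative eigenvalues appear and are simply excluded — no
Cailliez/Lingoes correction is applied.

The embedding rank is either user-fixed or chosen by the eigenvalue-ratio
rule: the k in 1..kmax maximizing lambda_k / lambda_{k+1}, ties to the
smallest k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from skbio.stats.distance import DistanceMatrix

__all__ = ["MdsEmbedding", "double_center", "embed", "select_rank"]

_EIG_TOL_REL = 1e-12


@dataclass(frozen=True)
class MdsEmbedding:
    """Eigenvalues and rank-r principal coordinates of a distance matrix."""

    sample_ids: list[str]
    eigenvalues: np.ndarray  # all n, non-increasing
    coordinates: np.ndarray  # n x r
    rank: int
    rank_method: str  # "eigenvalue_ratio" or "fixed"

    @property
    def n_samples(self) -> int:
        return self.coordinates.shape[0]


def _as_matrix(d) -> tuple[np.ndarray, list[str]]:
    if isinstance(d, DistanceMatrix):
        return d.data, list(d.ids)
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    return d, [str(i) for i in range(d.shape[0])]


def double_center(d) -> np.ndarray:
    """Gram matrix B = -1/2 L (D o D) L; its row and column means are zero."""
    D, _ = _as_matrix(d)
    sq = D * D
    row = sq.mean(axis=1, keepdims=True)
    col = sq.mean(axis=0, keepdims=True)
    B = -0.5 * (sq - row - col + sq.mean())
    return B


def embed(d, rank: int | str = "auto") -> MdsEmbedding:
    """Embed a distance matrix into its principal-coordinate space.

    Parameters
    ----------
    d : DistanceMatrix or square ndarray
    rank : positive int or "auto"
        "auto" applies the eigenvalue-ratio rule over the strictly positive
        spectrum.  A fixed rank exceeding the positive-eigenvalue count is
        clipped with a warning.
    """
    D, ids = _as_matrix(d)
    n = D.shape[0]
    if n < 3:
        raise ValueError("classical MDS needs at least 3 samples")
    B = double_center(D)
    eigvals, eigvecs = eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = _EIG_TOL_REL * max(abs(eigvals[0]), 1.0)
    n_pos = int((eigvals > tol).sum())
    if n_pos == 0:
        # all samples coincide: a single constant coordinate
        return MdsEmbedding(ids, eigvals, np.zeros((n, 1)), 1, "fixed")
    if rank == "auto":
        kmax = min(n_pos - 1, n // 2)
        r = select_rank(eigvals[:n_pos], kmax) if kmax >= 1 else 1
        method = "eigenvalue_ratio"
    else:
        r = int(rank)
        if r < 1:
            raise ValueError("rank must be positive")
        if r > n_pos:
            warnings.warn(
                f"requested rank {r} exceeds the {n_pos} positive eigenvalues; clipping",
                stacklevel=2,
            )
            r = n_pos
        method = "fixed"
    Q = eigvecs[:, :r]
    # deterministic sign: largest-magnitude loading of each axis is positive
    for j in range(r):
        i = np.argmax(np.abs(Q[:, j]))
        if Q[i, j] < 0:
            Q[:, j] = -Q[:, j]
    Y = Q * np.sqrt(eigvals[:r])
    return MdsEmbedding(ids, eigvals, Y, r, method)


def select_rank(eigenvalues, kmax: int) -> int:
    """Eigenvalue-ratio rank choice: argmax_k lambda_k / lambda_{k+1}.

    ``eigenvalues`` must be positive and sorted non-increasing; ties break
    to the smallest k.  With fewer than 2 positive eigenvalues the rank is
    1 (with a warning).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 2:
        warnings.warn("fewer than 2 positive eigenvalues; rank set to 1", stacklevel=2)
        return 1
    kmax = int(min(kmax, lam.size - 1))
    if kmax < 1:
        return 1
    ratios = lam[:kmax] / lam[1 : kmax + 1]
    return int(np.argmax(ratios)) + 1
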
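"""Pairwise distance metrics for microbiome compositions.

Seven metrics are supported: Bray-Curtis and binary Jaccard on the simplex;
unweighted, weighted (normalized) and generalized UniFrac on a rooted
phylogeny; and Euclidean distance after the CLR or PhILR log-ratio
transform.  Branch proportions for the UniFrac family are accumulated once
per sample by a single post-order traversal, so a full pairwise matrix
costs O(nE) memory and O(n^2 E) time for E tree edges.

Zero handling for the log-ratio metrics follows the usual pseudocount
policy: add 0.5 to raw counts before closure (``with_pseudocount``); for
tables that arrive as proportions, 0.5 / virtual_depth is added instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.stats.composition import clr as _skbio_clr
from skbio.stats.distance import DistanceMatrix

from .io import OtuTable, ValidationError

__all__ = [
    "MetricSpec",
    "METRIC_NAMES",
    "bray_curtis",
    "jaccard",
    "unifrac_unweighted",
    "unifrac_weighted",
    "unifrac_generalized",
    "clr_transform",
    "philr_transform",
    "philr_basis",
    "pairwise",
    "with_pseudocount",
]

METRIC_NAMES = (
    "bray_curtis",
    "jaccard",
    "unifrac_unweighted",
    "unifrac_weighted",
    "unifrac_generalized",
    "clr",
    "philr",
)
PHYLOGENETIC = {"unifrac_unweighted", "unifrac_weighted", "unifrac_generalized", "philr"}
LOG_RATIO = {"clr", "philr"}


@dataclass(frozen=True)
class MetricSpec:
    """A named distance metric plus its tuning knobs.

    alpha applies only to generalized UniFrac (0.5 halves the dominance of
    abundant lineages; 1 recovers weighted UniFrac).  pseudocount applies
    only to the log-ratio metrics.  A tree is required exactly for the
    phylogenetic metrics.
    """

    name: str
    alpha: float = 0.5
    pseudocount: float = 0.5
    virtual_depth: float = 10_000.0
    tree: Optional[TreeNode] = None

    def __post_init__(self) -> None:
        if self.name not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.name!r}; choose from {METRIC_NAMES}")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        needs_tree = self.name in PHYLOGENETIC
        if needs_tree and self.tree is None:
            raise ValueError(f"metric {self.name!r} requires a phylogenetic tree")
        if not needs_tree and self.tree is not None:
            raise ValueError(f"metric {self.name!r} does not accept a tree")

    @property
    def is_phylogenetic(self) -> bool:
        return self.name in PHYLOGENETIC


def _check_pair(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    return a, b


def bray_curtis(a, b) -> float:
    """Sum of absolute abundance differences over the sum of totals."""
    a, b = _check_pair(a, b)
    denom = (a + b).sum()
    if denom == 0:
        raise ValueError("both compositions are empty")
    return float(np.abs(a - b).sum() / denom)


def jaccard(a, b) -> float:
    """1 minus shared over total present OTUs (presence/absence)."""
    a, b = _check_pair(a, b)
    sa, sb = a > 0, b > 0
    union = (sa | sb).sum()
    if union == 0:
        raise ValueError("both compositions are empty")
    return float(1.0 - (sa & sb).sum() / union)


# --- UniFrac family -------------------------------------------------------


class _BranchStructure:
    """Edge lengths and leaf-descendant membership for a rooted tree.

    One column per non-root edge; membership[p, e] is 1 when OTU p descends
    through edge e.  Built by a single post-order pass.
    """

    def __init__(self, tree: TreeNode, otu_ids: list[str]):
        col = {o: i for i, o in enumerate(otu_ids)}
        tips = {t.name for t in tree.tips()}
        missing = [o for o in otu_ids if o not in tips]
        # OTUs absent from the tree are only an error when they carry
        # abundance; recorded here and checked against the data later.
        self.missing = set(missing)
        P = len(otu_ids)
        nodes = [n for n in tree.postorder(include_self=False)]
        self.lengths = np.empty(len(nodes))
        self.membership = np.zeros((P, len(nodes)))
        memb_of: dict[int, np.ndarray] = {}
        for e, node in enumerate(nodes):
            if node.length is None:
                raise ValidationError("tree has a branch without length")
            self.lengths[e] = node.length
            if node.is_tip():
                v = np.zeros(P)
                if node.name in col:
                    v[col[node.name]] = 1.0
            else:
                v = np.zeros(P)
                for child in node.children:
                    v += memb_of[id(child)]
            memb_of[id(node)] = v
            self.membership[:, e] = v


def _branch_structure(tree: TreeNode, otu_ids: list[str]) -> _BranchStructure:
    return _BranchStructure(tree, list(otu_ids))


def _check_on_tree(bs: _BranchStructure, otu_ids, x):
    if not bs.missing:
        return
    x = np.atleast_2d(x)
    for i, o in enumerate(otu_ids):
        if o in bs.missing and (x[:, i] > 0).any():
            raise ValidationError(f"OTU {o!r} has abundance but is not a leaf of the tree")


def _unifrac_from_branches(pa, pb, lengths, kind: str, alpha: float = 0.5) -> float:
    if kind == "unweighted":
        ia, ib = pa > 0, pb > 0
        denom = lengths[ia | ib].sum()
        if denom == 0:
            raise ValueError("both samples are empty on the tree")
        return float(lengths[ia ^ ib].sum() / denom)
    tot = pa + pb
    mask = tot > 0
    if not mask.any():
        raise ValueError("both samples are empty on the tree")
    diff = np.abs(pa - pb)[mask]
    tot = tot[mask]
    w = lengths[mask]
    if kind == "weighted":
        return float((w * diff).sum() / (w * tot).sum())
    # generalized: branch weight (p_a + p_b)^alpha, difference ratio |pa-pb|/(pa+pb)
    wa = w * tot**alpha
    return float((wa * diff / tot).sum() / wa.sum())


def unifrac_unweighted(a, b, tree: TreeNode, otu_ids: list[str] | None = None) -> float:
    """Fraction of branch length leading to OTUs present in exactly one sample."""
    return _unifrac_pairwise_entry(a, b, tree, otu_ids, "unweighted")


def unifrac_weighted(a, b, tree: TreeNode, otu_ids: list[str] | None = None) -> float:
    """Normalized weighted UniFrac: branch-length-weighted L1 difference of
    branch proportions over the same-weighted sum (range [0, 1])."""
    return _unifrac_pairwise_entry(a, b, tree, otu_ids, "weighted")


def unifrac_generalized(
    a, b, tree: TreeNode, alpha: float = 0.5, otu_ids: list[str] | None = None
) -> float:
    """Generalized UniFrac with abundance-attenuation exponent ``alpha``."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    return _unifrac_pairwise_entry(a, b, tree, otu_ids, "generalized", alpha)


def _unifrac_pairwise_entry(a, b, tree, otu_ids, kind, alpha=0.5) -> float:
    a, b = _check_pair(a, b)
    if otu_ids is None:
        otu_ids = sorted(t.name for t in tree.tips())
        if len(otu_ids) != a.size:
            raise ValueError("vector length does not match number of tree leaves")
    bs = _branch_structure(tree, list(otu_ids))
    _check_on_tree(bs, otu_ids, np.vstack([a, b]))
    pa = (a @ bs.membership).ravel()
    pb = (b @ bs.membership).ravel()
    return _unifrac_from_branches(pa, pb, bs.lengths, kind, alpha)


# --- Log-ratio transforms -------------------------------------------------


def clr_transform(a) -> np.ndarray:
    """Centered log-ratio: ln a_p minus the mean of ln a (zero-sum output)."""
    a = np.asarray(a, dtype=float)
    if (a <= 0).any():
        raise ValidationError("CLR requires strictly positive input; apply a pseudocount first")
    return _skbio_clr(a)


def philr_basis(tree: TreeNode, otu_ids: list[str]) -> tuple[np.ndarray, list[str]]:
    """Orthonormal ILR contrast matrix (P x P-1) from the tree's partition.

    The tree is sheared to the requested OTUs and resolved to a binary
    topology (deterministic grouping of the first two children, zero-length
    inserted edges).  Each internal node contributes one balance contrasting
    its first child's clade (numerator) against its second's, with the
    standard sqrt(rs/(r+s)) scaling; the balance of a composition x is then
    column.T @ ln(x).  Columns are orthonormal and sum to zero, so Euclidean
    distance between balance vectors equals the Aitchison distance.
    """
    tips = {t.name for t in tree.tips()}
    missing = [o for o in otu_ids if o not in tips]
    if missing:
        raise ValidationError(f"OTUs not resolvable to tree leaves: {missing[:5]}")
    work = tree.shear(otu_ids).copy()
    # collapse a degree-one root chain left by shearing
    while len(work.children) == 1:
        work = work.children[0]
        work.parent = None
    _binarize(work)
    col = {o: i for i, o in enumerate(otu_ids)}
    P = len(otu_ids)
    leafsets: dict[int, np.ndarray] = {}
    balances = []
    node_names = []
    for node in work.postorder(include_self=True):
        if node.is_tip():
            v = np.zeros(P, dtype=bool)
            v[col[node.name]] = True
            leafsets[id(node)] = v
        else:
            children = node.children
            v = np.zeros(P, dtype=bool)
            for c in children:
                v |= leafsets[id(c)]
            leafsets[id(node)] = v
            plus = leafsets[id(children[0])]
            minus = leafsets[id(children[1])]
            r, s = plus.sum(), minus.sum()
            coef = np.sqrt(r * s / (r + s))
            column = np.zeros(P)
            column[plus] = coef / r
            column[minus] = -coef / s
            balances.append(column)
            node_names.append(node.name or f"n{len(balances)}")
    if len(balances) != P - 1:
        raise ValidationError("tree could not be resolved into P-1 balances")
    # root balance first (preorder of internal nodes) for readability
    V = np.column_stack(balances[::-1])
    return V, node_names[::-1]


def _binarize(node: TreeNode) -> None:
    """Resolve multifurcations in place with zero-length internal edges."""
    for child in list(node.children):
        _binarize(child)
    while len(node.children) > 2:
        c1, c2 = node.children[0], node.children[1]
        node.remove(c1)
        node.remove(c2)
        merged = TreeNode(length=0.0)
        merged.append(c1)
        merged.append(c2)
        node.append(merged)


def philr_transform(a, tree: TreeNode, otu_ids: list[str] | None = None) -> np.ndarray:
    """Phylogenetic ILR balances of a strictly positive composition."""
    a = np.asarray(a, dtype=float)
    if (a <= 0).any():
        raise ValidationError("PhILR requires strictly positive input; apply a pseudocount first")
    if otu_ids is None:
        otu_ids = sorted(t.name for t in tree.tips())
        if len(otu_ids) != a.size:
            raise ValueError("vector length does not match number of tree leaves")
    V, _ = philr_basis(tree, list(otu_ids))
    return np.log(a) @ V


def with_pseudocount(t: OtuTable, pseudocount: float = 0.5, virtual_depth: float = 10_000.0) -> OtuTable:
    """Return a strictly positive proportion table for log-ratio metrics.

    Count tables get ``pseudocount`` added to every cell before closure;
    proportion tables get ``pseudocount / virtual_depth`` (the same policy
    on an assumed depth scale) and are re-closed.
    """
    if t.is_proportion:
        vals = t.values + pseudocount / virtual_depth
    else:
        vals = t.values + pseudocount
    vals = vals / vals.sum(axis=1, keepdims=True)
    return OtuTable(
        sample_ids=list(t.sample_ids),
        otu_ids=list(t.otu_ids),
        values=vals,
        is_proportion=True,
    )


def pairwise(t: OtuTable, spec: MetricSpec) -> DistanceMatrix:
    """Full n x n distance matrix for a proportion table under ``spec``.

    For the log-ratio metrics the entries are Euclidean distances between
    transformed sample vectors; zeros must already have been removed via
    :func:`with_pseudocount`.
    """
    if not t.is_proportion:
        raise ValidationError("pairwise distances require a proportion table (normalize first)")
    X = t.values
    name = spec.name
    if name == "bray_curtis":
        condensed = pdist(X, metric="braycurtis")
    elif name == "jaccard":
        condensed = pdist(X > 0, metric="jaccard")
    elif name == "clr":
        condensed = pdist(clr_transform(X), metric="euclidean")
    elif name == "philr":
        if (X <= 0).any():
            raise ValidationError("PhILR requires strictly positive proportions")
        V, _ = philr_basis(spec.tree, list(t.otu_ids))
        condensed = pdist(np.log(X) @ V, metric="euclidean")
    else:
        condensed = _unifrac_condensed(t, spec)
    D = squareform(condensed)
    dm = DistanceMatrix(D, ids=list(t.sample_ids))
    dm.metric_name = name
    return dm


def _unifrac_condensed(t: OtuTable, spec: MetricSpec) -> np.ndarray:
    bs = _branch_structure(spec.tree, list(t.otu_ids))
    _check_on_tree(bs, t.otu_ids, t.values)
    B = t.values @ bs.membership  # n x E branch proportions
    lengths = bs.lengths
    n = B.shape[0]
    out = []
    kind = spec.name.split("_", 1)[1]  # unweighted | weighted | generalized
    if kind == "unweighted":
        A = ((t.values > 0).astype(float) @ bs.membership) > 0
        for i in range(n - 1):
            sym = A[i] ^ A[i + 1 :]
            uni = A[i] | A[i + 1 :]
            out.append((sym @ lengths) / (uni @ lengths))
    elif kind == "weighted":
        for i in range(n - 1):
            diff = np.abs(B[i] - B[i + 1 :])
            tot = B[i] + B[i + 1 :]
            out.append((diff @ lengths) / (tot @ lengths))
    else:
        alpha = spec.alpha
        for i in range(n - 1):
            tot = B[i] + B[i + 1 :]
            diff = np.abs(B[i] - B[i + 1 :])
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
                w = lengths * tot**alpha
            out.append((ratio * w).sum(axis=1) / w.sum(axis=1))
    return np.concatenate(out) if out else np.empty(0)
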
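"""Model/Results facade over the MDS-enhanced PAM clustering procedure.

``MDSClusterModel`` holds the data and the analysis choices (distance
metric, MDS on/off, embedding rank); ``fit`` estimates the partition —
selecting the number of clusters unless it is supplied — and returns a
``ClusterResults`` object carrying the membership, medoids, embedding
spectrum, selector curves and a printable ``summary()``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import __version__ as _pkg_version
from .distances import MetricSpec
from .evaluate import run_pipeline
from .io import OtuTable, write_result
from .selectk import SelectorConfig

__all__ = ["MDSClusterModel", "ClusterResults"]


class MDSClusterModel:
    """MDS-enhanced distance-based clustering of an OTU table.

    Parameters
    ----------
    table : OtuTable
        Samples x OTUs counts or proportions.
    metric : str
        One of bray_curtis, jaccard, unifrac_unweighted, unifrac_weighted,
        unifrac_generalized, clr, philr.
    tree : skbio.TreeNode, optional
        Rooted phylogeny; required for the UniFrac family and PhILR.
    use_mds : bool
        Denoise by classical MDS before clustering (the recommended
        two-step procedure); False clusters the raw distance matrix.
    rank : int or "auto"
        Embedding rank; "auto" uses the eigenvalue-ratio rule.

    Examples
    --------
    >>> model = MDSClusterModel(table, metric="bray_curtis")
    >>> res = model.fit(selector="si", k_max=8)
    >>> print(res.summary())
    """

    def __init__(
        self,
        table: OtuTable,
        metric: str = "bray_curtis",
        tree: Optional[TreeNode] = None,
        use_mds: bool = True,
        rank="auto",
        alpha: float = 0.5,
        pseudocount: float = 0.5,
    ):
        self.table = table
        self.spec = MetricSpec(name=metric, alpha=alpha, pseudocount=pseudocount, tree=tree)
        self.use_mds = bool(use_mds)
        self.rank = rank

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, is_proportion: bool = False, **kwargs):
        """Build from a samples-in-rows DataFrame of counts or proportions."""
        return cls(OtuTable.from_dataframe(df, is_proportion=is_proportion), **kwargs)

    def fit(
        self,
        k: Optional[int] = None,
        selector: str = "si",
        k_max: int = 10,
        seed: int = 0,
        **selector_kwargs,
    ) -> "ClusterResults":
        """Estimate the partition; returns a :class:`ClusterResults`.

        Provide ``k`` to fix the number of clusters, otherwise ``selector``
        ("si", "gap" or "ps") estimates it over 1..k_max (2..k_max for SI).
        """
        cfg = None
        if k is None:
            cfg = SelectorConfig(method=selector, k_max=k_max, seed=seed, **selector_kwargs)
        raw = run_pipeline(
            self.table, self.spec, use_mds=self.use_mds, rank=self.rank, k=k, selector=cfg
        )
        return ClusterResults(self, raw)


class ClusterResults:
    """Fitted partition plus diagnostics from :class:`MDSClusterModel`."""

    def __init__(self, model: MDSClusterModel, raw):
        self.model = model
        self.sample_ids = raw.sample_ids
        self.membership = raw.membership
        self.medoid_indices = raw.medoid_indices
        self.k = raw.k
        self.objective = raw.objective
        self.selector_diagnostics = raw.selector_diagnostics
        self.diagnostics_extra = dict(raw.diagnostics_extra or {})
        self.diagnostics_extra["package_version"] = _pkg_version
        self._raw = raw

    def cluster_sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.membership, return_counts=True)
        return {int(l): int(c) for l, c in zip(labels, counts)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "cluster": self.membership}
        ).set_index("sample_id")

    def write(self, path_prefix):
        """Write membership TSV and JSON diagnostics (see :func:`io.write_result`)."""
        return write_result(self, path_prefix)

    def summary(self) -> str:
        d = self.diagnostics_extra
        lines = [
            "MDS-enhanced PAM clustering",
            "===========================",
            f"samples:            {len(self.sample_ids)}",
            f"OTUs:               {self.model.table.n_otus}",
            f"distance metric:    {d.get('metric')}",
        ]
        if d.get("use_mds"):
            lines.append(
                f"MDS:                on (rank {d.get('mds_rank')}, {d.get('rank_method')})"
            )
            ev = d.get("eigenvalues") or []
            if ev:
                lines.append(
                    "top eigenvalues:    " + ", ".join(f"{v:.4g}" for v in ev[:5])
                )
        else:
            lines.append("MDS:                off (PAM on the raw distance matrix)")
        mode = (d.get("selection") or {}).get("mode", "fixed")
        lines.append(f"number of clusters: {self.k} ({'fixed' if mode == 'fixed' else mode})")
        if self.selector_diagnostics:
            curve = ", ".join(
                f"k={kk}: {vv:.3f}" for kk, vv in sorted(self.selector_diagnostics.items())
            )
            lines.append(f"selector curve:     {curve}")
        sizes = self.cluster_sizes()
        lines.append(
            "cluster sizes:      " + ", ".join(f"{k}: {v}" for k, v in sizes.items())
        )
        lines.append(f"PAM objective:      {self.objective:.4f}")
        note = (d.get("selection") or {}).get("note")
        if note:
            lines.append(f"note:               {note}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<ClusterResults k={self.k} n={len(self.sample_ids)}>"
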
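"""Clustering evaluation (adjusted Rand index) and the replicate benchmark.

``run_pipeline`` executes the full procedure on one table: normalize ->
distance -> optional MDS denoising -> cluster-number selection -> PAM.
``run_benchmark`` repeats simulated datasets across a grid of metrics,
selectors, MDS on/off and rarefaction, scoring each cell against the known
truth with the ARI; replicates are paired (every cell sees the same
simulated dataset) to reduce comparison variance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import io as mio
from .distances import LOG_RATIO, MetricSpec, pairwise, with_pseudocount
from .io import LabelVector, OtuTable
from .mds import embed
from .pam import ClusterResult, pam_fit, pam_on_embedding
from .selectk import SelectorConfig, select_k
from .simulate import SimDesign, simulate

__all__ = ["adjusted_rand_index", "run_pipeline", "BenchmarkGrid", "run_benchmark"]


def adjusted_rand_index(a, b) -> float:
    """Hubert-Arabie chance-corrected agreement between two partitions.

    1 = identical partitions (two all-singleton or two one-cluster
    partitions count as identical), ~0 = random agreement, negative =
    worse than chance.
    """
    la = a.labels if isinstance(a, LabelVector) else np.asarray(a)
    lb = b.labels if isinstance(b, LabelVector) else np.asarray(b)
    if la.shape != lb.shape:
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(la, lb))


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(
    t: OtuTable,
    spec: MetricSpec,
    use_mds: bool = True,
    rank="auto",
    k: Optional[int] = None,
    selector: Optional[SelectorConfig] = None,
) -> ClusterResult:
    """Cluster one OTU table end to end and return the PAM partition.

    Count tables are normalized to proportions (log-ratio metrics first
    receive the pseudocount on the count scale).  With ``use_mds`` the
    distance matrix is embedded by classical MDS and selection + PAM run on
    Euclidean distances of the coordinates; otherwise they run on the raw
    distance matrix.  Provide ``k`` for an oracle/fixed cluster count or a
    :class:`SelectorConfig` (default: silhouette) to estimate it.
    """
    with _stage("normalize"):
        if spec.name in LOG_RATIO:
            table = with_pseudocount(t, spec.pseudocount, spec.virtual_depth)
        elif t.is_proportion:
            table = t
        else:
            table = mio.normalize(t)
    with _stage("distance"):
        dm = pairwise(table, spec)
    embedding = None
    if use_mds:
        with _stage("mds"):
            embedding = embed(dm, rank=rank)
    diag: dict = {
        "metric": spec.name,
        "use_mds": bool(use_mds),
    }
    if embedding is not None:
        diag["mds_rank"] = int(embedding.rank)
        diag["rank_method"] = embedding.rank_method
        diag["eigenvalues"] = [float(v) for v in embedding.eigenvalues[:10]]
    with _stage("select_k"):
        if k is not None:
            k_hat, sel_diag = int(k), {"mode": "fixed"}
        else:
            cfg = selector or SelectorConfig()
            if embedding is not None:
                k_hat, sel_diag = select_k(cfg, points=embedding.coordinates)
            else:
                k_hat, sel_diag = select_k(cfg, dmatrix=dm)
            sel_diag = dict(sel_diag)
            sel_diag["mode"] = cfg.method
    with _stage("pam"):
        if embedding is not None:
            result = pam_on_embedding(embedding, k_hat)
        else:
            result = pam_fit(dm, k_hat)
    curve = None
    for key in ("si", "gap", "ps"):
        if isinstance(sel_diag.get(key), dict):
            curve = sel_diag[key]
            break
    diag["selection"] = _jsonable(sel_diag)
    return ClusterResult(
        sample_ids=result.sample_ids,
        membership=result.membership,
        medoid_indices=result.medoid_indices,
        k=result.k,
        objective=result.objective,
        selector_diagnostics=curve,
        diagnostics_extra=diag,
    )


@dataclass(frozen=True)
class BenchmarkGrid:
    """The factorial layout of one simulation benchmark."""

    design: SimDesign
    metrics: Sequence[str] = ("bray_curtis", "clr")
    selectors: Sequence = ("oracle",)  # "oracle" or SelectorConfig instances
    mds: Sequence[bool] = (True, False)
    rarefaction: str = "off"  # off | on | both
    n_reps: int = 100
    master_seed: int = 0
    alpha: float = 0.5
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        if self.rarefaction not in ("off", "on", "both"):
            raise ValueError("rarefaction must be off, on or both")
        if not self.metrics or not self.selectors:
            raise ValueError("benchmark grid is empty")


def _selector_label(sel) -> str:
    return sel if isinstance(sel, str) else sel.method


def run_benchmark(grid: BenchmarkGrid, progress: bool = False) -> pd.DataFrame:
    """Run the paired replicate benchmark and return a long-format table.

    Columns: scenario, metric, selector, mds, rarefied, rep, ari, k_hat.
    Per-cell failures are recorded as NaN ARI rather than aborting the run.
    """
    rare_flags = {"off": [False], "on": [True], "both": [False, True]}[grid.rarefaction]
    ss = np.random.SeedSequence(grid.master_seed)
    rep_states = ss.generate_state(2 * grid.n_reps).astype(np.int64) % (2**31)
    rows = []
    for rep in range(grid.n_reps):
        design = replace(grid.design, seed=int(rep_states[2 * rep]))
        sim = simulate(design)
        tables = {}
        tables[False] = sim.table
        if True in rare_flags:
            depth = mio.default_rarefaction_depth(sim.table)
            tables[True] = mio.rarefy(sim.table, depth, seed=int(rep_states[2 * rep + 1]))
        for rarefied in rare_flags:
            table = tables[rarefied]
            for metric in grid.metrics:
                spec = MetricSpec(
                    name=metric,
                    alpha=grid.alpha,
                    pseudocount=grid.pseudocount,
                    tree=sim.tree if metric in ("philr",) or metric.startswith("unifrac") else None,
                )
                for use_mds in grid.mds:
                    for sel in grid.selectors:
                        k = design.n_clusters if isinstance(sel, str) and sel == "oracle" else None
                        cfg = sel if not isinstance(sel, str) else None
                        try:
                            res = run_pipeline(
                                table, spec, use_mds=use_mds, k=k, selector=cfg
                            )
                            ari = adjusted_rand_index(sim.truth.labels, res.membership)
                            k_hat = res.k
                            err = ""
                        except Exception as exc:  # record, don't abort the grid
                            ari, k_hat, err = np.nan, -1, str(exc)
                        rows.append(
                            {
                                "scenario": design.scenario,
                                "metric": metric,
                                "selector": _selector_label(sel),
                                "mds": use_mds,
                                "rarefied": rarefied,
                                "rep": rep,
                                "ari": ari,
                                "k_hat": k_hat,
                                "error": err,
                            }
                        )
        if progress:
            print(f"replicate {rep + 1}/{grid.n_reps} done", flush=True)
    return pd.DataFrame(rows)
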
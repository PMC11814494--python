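"""Reading, writing and preprocessing of OTU tables, trees and label files.

The central container is :class:`OtuTable`, an ``n x P`` matrix of OTU
counts or relative abundances with sample and OTU identifiers.  Counts are
normalized to proportions by dividing each sample (row) by its sequencing
depth; rarefaction subsamples reads without replacement to a common depth.
Trees are scikit-bio :class:`~skbio.TreeNode` objects read from Newick.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "OtuTable",
    "LabelVector",
    "read_otu_table",
    "normalize",
    "rarefy",
    "read_newick",
    "read_labels",
    "write_result",
]

_PROP_TOL = 1e-9
_RENORM_TOL = 1e-6


class FormatError(ValueError):
    """Malformed input file (bad values, duplicate identifiers, syntax)."""


class ValidationError(ValueError):
    """Structurally valid input violating a domain invariant."""


@dataclass(frozen=True)
class OtuTable:
    """Samples x OTUs abundance matrix.

    Parameters
    ----------
    sample_ids : list of str
        Row identifiers (samples).
    otu_ids : list of str
        Column identifiers (OTUs).
    values : ndarray of shape (n, P)
        Non-negative counts or proportions; no sample may be all-zero.
    is_proportion : bool
        If True every row sums to 1 (within 1e-9).
    """

    sample_ids: list[str]
    otu_ids: list[str]
    values: np.ndarray
    is_proportion: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValidationError("values must be a 2-D samples x OTUs matrix")
        n, P = values.shape
        if len(self.sample_ids) != n or len(self.otu_ids) != P:
            raise ValidationError("identifier lengths do not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample identifiers")
        if len(set(self.otu_ids)) != P:
            raise FormatError("duplicate OTU identifiers")
        if not np.isfinite(values).all():
            raise FormatError("non-finite abundance values")
        if (values < 0).any():
            raise FormatError("negative abundance values")
        rowsums = values.sum(axis=1)
        zero = np.flatnonzero(rowsums == 0)
        if zero.size:
            names = ", ".join(self.sample_ids[i] for i in zero[:5])
            raise ValidationError(f"all-zero sample row(s): {names}")
        if self.is_proportion:
            if np.abs(rowsums - 1.0).max() > _RENORM_TOL:
                raise ValidationError("proportion rows do not sum to 1")
            if np.abs(rowsums - 1.0).max() > _PROP_TOL:
                # close but not exact: renormalize silently
                object.__setattr__(self, "values", values / rowsums[:, None])

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_otus(self) -> int:
        return self.values.shape[1]

    @property
    def depths(self) -> np.ndarray:
        """Sequencing depths N_i (row sums); meaningful for count tables."""
        if self.is_proportion:
            raise ValidationError("depths are defined only for count tables")
        return self.values.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, is_proportion: bool = False) -> "OtuTable":
        return cls(
            sample_ids=[str(s) for s in df.index],
            otu_ids=[str(o) for o in df.columns],
            values=df.to_numpy(dtype=float),
            is_proportion=is_proportion,
        )


@dataclass(frozen=True)
class LabelVector:
    """Cluster labels (truth or inferred membership) aligned to sample ids."""

    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1 or labels.shape[0] != len(self.sample_ids):
            raise ValidationError("labels must be 1-D and match sample_ids")


def read_otu_table(path, orientation: str = "samples_in_rows") -> OtuTable:
    """Read an OTU count table from TSV or BIOM v1 JSON.

    TSV files must carry one header row and one identifier column.  The
    returned table is always oriented samples-in-rows regardless of the
    file's orientation.
    """
    if orientation not in ("samples_in_rows", "samples_in_columns"):
        raise ValueError(f"unknown orientation: {orientation}")
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        df = _parse_biom_v1(text)  # BIOM stores observations (OTUs) in rows
        if orientation == "samples_in_rows":
            df = df.T  # caller asserted samples in BIOM rows: honour it
    else:
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise FormatError(f"cannot parse TSV OTU table {path}: {exc}") from exc
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise FormatError("duplicate sample or OTU identifiers")
        if orientation == "samples_in_columns":
            df = df.T
    if not all(np.issubdtype(d, np.number) for d in df.dtypes):
        raise FormatError("non-numeric entries in OTU table")
    return OtuTable.from_dataframe(df)


def _parse_biom_v1(text: str) -> pd.DataFrame:
    """Parse a BIOM v1 (JSON) table into an observations-x-samples frame."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid BIOM JSON: {exc}") from exc
    try:
        obs_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        mat = np.zeros(shape)
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = v
        else:
            mat[:] = np.asarray(doc["data"], dtype=float)
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed BIOM v1 document: {exc}") from exc
    return pd.DataFrame(mat, index=obs_ids, columns=sample_ids)


def normalize(t: OtuTable) -> OtuTable:
    """Divide each count row by its sequencing depth, yielding proportions."""
    if t.is_proportion:
        raise ValidationError("table already holds proportions")
    depths = t.values.sum(axis=1)
    if (depths == 0).any():
        raise ValidationError("zero-depth sample cannot be normalized")
    return replace(t, values=t.values / depths[:, None], is_proportion=True)


def rarefy(t: OtuTable, target_depth: int, seed: int) -> OtuTable:
    """Subsample each sample's reads without replacement to ``target_depth``.

    Uses a multivariate hypergeometric draw per sample, so an OTU's rarefied
    count never exceeds its original count and row sums equal the target
    exactly.  Samples already at the target depth are returned unchanged.
    """
    if t.is_proportion:
        raise ValidationError("rarefaction requires a count table")
    counts = np.rint(t.values).astype(np.int64)
    if not np.allclose(counts, t.values):
        raise ValidationError("rarefaction requires integer counts")
    depths = counts.sum(axis=1)
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    shallow = np.flatnonzero(depths < target_depth)
    if shallow.size:
        names = ", ".join(t.sample_ids[i] for i in shallow)
        raise ValidationError(
            f"target depth {target_depth} exceeds depth of sample(s): {names}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        if depths[i] == target_depth:
            out[i] = counts[i]
        else:
            out[i] = rng.multivariate_hypergeometric(counts[i], target_depth)
    return replace(t, values=out.astype(float))


def default_rarefaction_depth(t: OtuTable) -> int:
    """Minimum sample depth — the common rarefaction convention."""
    return int(np.rint(t.depths).min())


def read_newick(path) -> TreeNode:
    """Read a rooted tree with branch lengths from a Newick file.

    Every non-root edge must carry an explicit branch length; missing
    lengths raise rather than defaulting silently.
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise FormatError(f"cannot parse Newick file {path}: {exc}") from exc
    for node in tree.traverse(include_self=False):
        if node.length is None:
            name = node.name or "<internal>"
            raise FormatError(f"branch without length above node {name}")
        if not np.isfinite(node.length) or node.length < 0:
            raise FormatError(f"invalid branch length {node.length}")
    return tree


def read_labels(path, table: OtuTable | None = None) -> LabelVector:
    """Read a two-column (sample_id, label) TSV; optionally check coverage."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("label file must have two tab-separated columns")
    if df.iloc[0, 1].lstrip("-").isdigit() is False:
        df = df.iloc[1:]  # tolerate a header row
    sample_ids = df.iloc[:, 0].tolist()
    labels = df.iloc[:, 1].astype(int).to_numpy()
    lv = LabelVector(sample_ids=sample_ids, labels=labels)
    if table is not None:
        missing = set(lv.sample_ids) - set(table.sample_ids)
        if missing:
            raise ValidationError(f"labelled samples absent from table: {sorted(missing)[:5]}")
        if set(table.sample_ids) - set(lv.sample_ids):
            raise ValidationError("label file does not cover all samples")
        order = {s: i for i, s in enumerate(lv.sample_ids)}
        idx = [order[s] for s in table.sample_ids]
        lv = LabelVector(sample_ids=list(table.sample_ids), labels=labels[idx])
    return lv


def write_result(result, path_prefix) -> tuple[Path, Path]:
    """Write membership TSV (sample_id, cluster) and a JSON diagnostics file.

    ``result`` is a :class:`mdsclust.pam.ClusterResult` (or the richer
    model Results object exposing the same attributes).
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv_path = prefix.with_suffix(".membership.tsv")
    json_path = prefix.with_suffix(".diagnostics.json")
    with open(tsv_path, "w") as fh:
        fh.write("sample_id\tcluster\n")
        for sid, m in zip(result.sample_ids, result.membership):
            fh.write(f"{sid}\t{int(m)}\n")
    diag = {
        "k": int(result.k),
        "objective": float(result.objective),
        "medoid_indices": [int(i) for i in result.medoid_indices],
        "selector_diagnostics": {
            str(k): float(v) for k, v in (result.selector_diagnostics or {}).items()
        },
    }
    extra = getattr(result, "diagnostics_extra", None)
    if extra:
        diag.update(extra)
    with open(json_path, "w") as fh:
        json.dump(diag, fh, indent=2)
    return tsv_path, json_path
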
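"""Reading, writing and preparing expression matrices.

TSV in / TSV out throughout: a matrix file has a header row of sample ids and
gene ids in the first column; metadata is a sample_id-indexed TSV; gene sets
use the GMT convention (name, description, then member ids, tab-separated).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from skbio import TreeNode

from .containers import ExpressionMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_matrix(path, meta_path=None) -> ExpressionMatrix:
    """Read a genes x samples TSV (blank cells = missing) plus optional metadata.

    Raises ``ValueError`` naming the offending row/column on duplicate ids,
    ragged rows or non-numeric cells.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s) in {path}: {dupes}")
    if raw.columns.has_duplicates:
        dupes = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s) in {path}: {dupes}")
    numeric = raw.replace("", np.nan).apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & (raw != "")
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell {raw.iat[i, j]!r} at gene {raw.index[i]!r}, "
            f"column {raw.columns[j]!r} in {path}"
        )
    meta = read_metadata(meta_path) if meta_path is not None else None
    return ExpressionMatrix(numeric, meta)


def write_matrix(matrix: ExpressionMatrix, path, meta_path=None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    if meta_path is not None:
        write_metadata(matrix.metadata, meta_path)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if meta.index.has_duplicates:
        dupes = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s) in {path}: {dupes}")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path) -> dict:
    """GMT gene sets: ``{set_name: list of gene ids}`` (description dropped)."""
    sets: dict[str, list] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: GMT line needs name, description, >=1 gene")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{line_no}: duplicate set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "")
            fh.write("\t".join([name, desc, *map(str, genes)]) + "\n")


def read_probe_map(path) -> pd.Series:
    """Two-column TSV probe_id -> gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: probe map needs two columns (probe_id, gene_id)")
    s = df.set_index(df.columns[0])[df.columns[1]]
    if s.index.has_duplicates:
        dupes = s.index[s.index.duplicated()].unique().tolist()
        raise ValueError(f"probes mapped more than once: {dupes}")
    return s


# ---------------------------------------------------------------------------
# probe-to-gene collapse
# ---------------------------------------------------------------------------

def collapse_probes(matrix, probe_map: pd.Series, rule: str = "mean"):
    """Collapse probe-level data to gene level.

    ``rule='mean'`` takes ``matrix`` as a probe-level :class:`ExpressionMatrix`
    and averages the probes of each gene per sample.

    ``rule='any_significant'`` takes ``matrix`` as a boolean Series indexed by
    probe (probe-level significance calls) and calls a gene significant iff at
    least one of its probes is.
    """
    probe_map = pd.Series(probe_map)
    if rule == "mean":
        unmapped = matrix.gene_ids.difference(probe_map.index)
        if len(unmapped):
            raise ValueError(f"unmapped probe(s): {unmapped.tolist()[:10]}")
        genes = probe_map.loc[matrix.gene_ids]
        collapsed = matrix.values.groupby(genes.to_numpy()).mean()
        collapsed.index.name = "gene_id"
        return ExpressionMatrix(collapsed, matrix.metadata.copy())
    if rule == "any_significant":
        calls = pd.Series(matrix).astype(bool)
        unmapped = calls.index.difference(probe_map.index)
        if len(unmapped):
            raise ValueError(f"unmapped probe(s): {unmapped.tolist()[:10]}")
        return calls.groupby(probe_map.loc[calls.index].to_numpy()).any()
    raise ValueError(f"unknown collapse rule {rule!r}")


# ---------------------------------------------------------------------------
# detection above background
# ---------------------------------------------------------------------------

def detect_expressed(matrix: ExpressionMatrix, background_quantile: float = 0.1) -> pd.Index:
    """Genes detected above background in at least one tissue.

    A gene is detected iff its maximum per-tissue mean strictly exceeds the
    ``background_quantile`` quantile of all (non-missing) values. This is a
    deliberately simple stand-in for array-specific background estimation.
    """
    if not 0 <= background_quantile < 1:
        raise ValueError("background_quantile must be in [0, 1)")
    vals = matrix.values.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("matrix has no non-missing values")
    threshold = np.quantile(finite, background_quantile)
    group_col = "tissue" if "tissue" in matrix.metadata.columns else None
    if group_col is None:
        tissue_max = matrix.values.max(axis=1)
    else:
        tissue_means = matrix.values.T.groupby(matrix.metadata[group_col]).mean().T
        tissue_max = tissue_means.max(axis=1)
    all_missing = matrix.values.isna().all(axis=1)
    if all_missing.any():
        log.warning("%d gene(s) with all values missing are undetected", all_missing.sum())
    detected = matrix.gene_ids[(tissue_max > threshold).fillna(False) & ~all_missing]
    return detected


# ---------------------------------------------------------------------------
# normalization (optional stand-in)
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalization across samples (optional, off by default).

    Forces every sample to share the same empirical distribution (the mean
    of the per-rank values). This is a simple generic stand-in for
    platform-specific normalization, not a reimplementation of any
    array-processing pipeline; missing values are not supported here.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("quantile normalization requires a complete matrix")
    order = np.argsort(vals, axis=0)
    ranks = np.empty_like(order)
    n = vals.shape[0]
    rows = np.arange(n)
    for j in range(vals.shape[1]):
        ranks[order[:, j], j] = rows
    mean_by_rank = np.sort(vals, axis=0).mean(axis=1)
    normed = mean_by_rank[ranks]
    return ExpressionMatrix(
        pd.DataFrame(normed, index=matrix.gene_ids, columns=matrix.sample_ids),
        matrix.metadata.copy(),
    )


# ---------------------------------------------------------------------------
# technical replicate averaging
# ---------------------------------------------------------------------------

def average_technical_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average dye-swap technical replicates to one column per biological replicate.

    Columns sharing (tissue, tree) metadata are averaged; the dye field is
    dropped from the output metadata. A lone (unpaired) technical replicate
    passes through with a warning.
    """
    meta = matrix.metadata
    if "dye" not in meta.columns:
        return matrix.copy()
    keys = [c for c in ("species", "timepoint", "tissue", "tree") if c in meta.columns]
    if not keys:
        raise ValueError("metadata lacks tissue/tree fields identifying biological replicates")
    group = meta[keys].astype(str).agg(".".join, axis=1)
    sizes = group.value_counts()
    if (sizes == 1).any():
        log.warning("%d unpaired technical replicate(s); using single values", (sizes == 1).sum())
    # preserve first-occurrence order of biological replicates
    order = group.drop_duplicates().tolist()
    averaged = matrix.values.T.groupby(group).mean().T[order]
    new_meta = meta.assign(_g=group).drop_duplicates("_g").set_index("_g").loc[order, keys]
    new_meta.index.name = "sample_id"
    new_meta.index = pd.Index(order, name="sample_id")
    return ExpressionMatrix(averaged, new_meta)


# ---------------------------------------------------------------------------
# sample QC clustering
# ---------------------------------------------------------------------------

def cluster_samples(matrix: ExpressionMatrix, method: str = "ward"):
    """Hierarchical clustering of samples (Euclidean distance, Ward linkage).

    Missing values are imputed with the per-gene mean first (logged). Returns
    a :class:`skbio.TreeNode` with sample ids as leaf names; serialize with
    :func:`write_newick`.
    """
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples to cluster")
    if method != "ward":
        raise ValueError(f"unsupported linkage {method!r}")
    vals = matrix.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        log.info("imputing per-gene means for sample clustering")
        row_means = np.nanmean(vals, axis=1, keepdims=True)
        vals = np.where(np.isnan(vals), row_means, vals)
    # cluster in a canonical sample order so topology ignores input order
    order = np.argsort(matrix.sample_ids)
    dist = pdist(vals[:, order].T, metric="euclidean")
    Z = linkage(dist, method="ward")
    tree = TreeNode.from_linkage_matrix(Z, list(matrix.sample_ids[order]))
    return tree


def write_newick(tree, path) -> None:
    tree.write(str(path), format="newick")
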
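"""Coexpression module detection and the two anticorrelated groups per module.

The workflow mirrors weighted correlation network analysis: Pearson
correlations between high-confidence variable genes are raised to a
soft-thresholding power (unsigned, so anticorrelated genes stay close),
converted to a topological overlap similarity, and the genes are clustered
by average-linkage hierarchical clustering on 1 - TOM with a static branch
cut. Each resulting module is summarized by its eigengene (first principal
component of the standardized member submatrix) and split by the sign of the
member-eigengene correlation into two coexpression groups, "a" (positive)
and "b" (negative), each with a mean-profile template used downstream for
template matching.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ModuleDetectionParams:
    """Knobs for module detection.

    ``beta`` is the soft-thresholding power (14 for the multi-tissue
    experiment, 18 for the seasonal one); ``cut_height`` is the static cut on
    the 1 - TOM dendrogram (0.99 by default, the conventional static cut for
    topological-overlap dendrograms, whose merge heights crowd toward 1);
    clusters smaller than ``min_module_size`` are pooled into the unassigned
    bin.
    """

    beta: float = 14.0
    min_module_size: int = 30
    cut_height: float = 0.99

    def __post_init__(self):
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_module_size < 3:
            raise ValueError("min_module_size must be >= 3")
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must be in (0, 1]")


@dataclass
class ModuleRecord:
    module_id: str
    members: list
    eigengene: pd.Series = None           # per-sample scores, unit norm
    variance_explained: float = np.nan
    member_correlation: pd.Series = None  # gene -> corr with eigengene
    group_a: list = field(default_factory=list)
    group_b: list = field(default_factory=list)
    template_a: pd.Series = None
    template_b: pd.Series = None


@dataclass
class ModuleSet:
    modules: dict                         # module_id -> ModuleRecord
    unassigned: list
    params: ModuleDetectionParams

    def membership(self) -> pd.Series:
        """gene -> module id (unassigned genes excluded)."""
        out = {}
        for mid, rec in self.modules.items():
            for g in rec.members:
                out[g] = mid
        return pd.Series(out, name="module")

    def group_membership(self) -> pd.Series:
        """gene -> group id like 'M1a'."""
        out = {}
        for mid, rec in self.modules.items():
            for g in rec.group_a:
                out[g] = f"{mid}a"
            for g in rec.group_b:
                out[g] = f"{mid}b"
        return pd.Series(out, name="group")

    def templates(self) -> pd.DataFrame:
        """group id -> template profile (rows = groups, columns = samples)."""
        rows = {}
        for mid, rec in self.modules.items():
            if rec.template_a is not None:
                rows[f"{mid}a"] = rec.template_a
            if rec.template_b is not None:
                rows[f"{mid}b"] = rec.template_b
        return pd.DataFrame(rows).T

    def group_sizes(self) -> pd.Series:
        sizes = {}
        for mid, rec in self.modules.items():
            sizes[f"{mid}a"] = len(rec.group_a)
            sizes[f"{mid}b"] = len(rec.group_b)
        return pd.Series(sizes, name="size")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def correlation_matrix(matrix: ExpressionMatrix, genes=None) -> pd.DataFrame:
    """Gene x gene Pearson correlations (pairwise-complete over missing values)."""
    sub = matrix.values if genes is None else matrix.values.loc[list(genes)]
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    var = sub.var(axis=1, ddof=0)
    dead = var[var == 0]
    if len(dead):
        raise ValueError(f"zero-variance gene(s): {dead.index.tolist()[:10]}")
    arr = sub.to_numpy(dtype=float)
    if np.isnan(arr).any():
        corr = sub.T.corr(min_periods=3)
    else:
        corr = pd.DataFrame(np.corrcoef(arr), index=sub.index, columns=sub.index)
    return corr.clip(-1.0, 1.0)


def soft_threshold_adjacency(corr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned weighted adjacency a_ij = |r_ij| ** beta with zero diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    adj = np.abs(corr.to_numpy(dtype=float)) ** beta
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=corr.index, columns=corr.columns)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    k the row sums; TOM_ii = 1. Entries lie in [0, 1] for adjacencies in
    [0, 1].
    """
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.diagonal(a).any():
        raise ValueError("adjacency must have a zero diagonal")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom = np.where(np.isnan(tom), 0.0, tom)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def module_eigengene(matrix: ExpressionMatrix, members) -> tuple[pd.Series, float]:
    """First principal component of the gene-standardized member submatrix.

    Returns the unit-norm per-sample eigengene and the fraction of variance
    it explains. The sign is oriented so that a majority of members correlate
    positively with it; on a tie the lexicographically first member is made
    positive.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("need at least 2 member genes")
    sub = matrix.values.loc[members]
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    arr = sub.to_numpy(dtype=float)
    if np.isnan(arr).any():
        arr = np.where(np.isnan(arr), np.nanmean(arr, axis=1, keepdims=True), arr)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    if (sd == 0).all():
        raise ValueError("degenerate module: all member genes constant")
    sd = np.where(sd == 0, 1.0, sd)
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    if s[0] == 0:
        raise ValueError("degenerate (rank-0) module submatrix")
    eig = vt[0]
    varexp = float(s[0] ** 2 / (s**2).sum())
    corr_sign = np.sign(z @ eig)  # sign of member-eigengene correlation
    pos = (corr_sign > 0).sum()
    neg = (corr_sign < 0).sum()
    if pos < neg:
        eig = -eig
    elif pos == neg:
        first = int(np.argsort(np.asarray(members, dtype=object))[0])
        if corr_sign[first] < 0:
            eig = -eig
    return pd.Series(eig, index=sub.columns, name="eigengene"), varexp


def split_module(record: ModuleRecord, matrix: ExpressionMatrix) -> ModuleRecord:
    """Split a module into groups a/b by sign of correlation with the eigengene.

    Correlation exactly zero goes to group a. Templates are the per-sample
    mean profiles of each group (empty group -> no template, logged).
    """
    if record.eigengene is None:
        raise ValueError("eigengene must be computed before splitting")
    sub = matrix.values.loc[record.members]
    eig = record.eigengene.loc[sub.columns].to_numpy()
    arr = sub.to_numpy(dtype=float)
    zc = arr - np.nanmean(arr, axis=1, keepdims=True)
    ec = eig - eig.mean()
    num = np.nansum(zc * ec, axis=1)
    den = np.sqrt(np.nansum(zc**2, axis=1) * (ec**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(den > 0, num / den, 0.0)
    record.member_correlation = pd.Series(corr, index=sub.index, name="eigengene_r")
    in_a = corr >= 0
    record.group_a = list(sub.index[in_a])
    record.group_b = list(sub.index[~in_a])
    record.template_a = sub.loc[record.group_a].mean(axis=0) if record.group_a else None
    record.template_b = sub.loc[record.group_b].mean(axis=0) if record.group_b else None
    if not record.group_a or not record.group_b:
        log.info("module %s has a single expression profile (one empty group)", record.module_id)
    return record


def detect_modules(
    matrix: ExpressionMatrix,
    genes,
    params: ModuleDetectionParams = ModuleDetectionParams(),
    label_prefix: str = "M",
) -> ModuleSet:
    """Detect modules among ``genes`` and split each into coexpression groups.

    Average-linkage hierarchical clustering on 1 - TOM, cut at
    ``params.cut_height``; clusters below ``params.min_module_size`` are
    pooled into the unassigned bin. Modules are labelled ``M1, M2, ...`` by
    decreasing size (ties broken by the lexicographically smallest member).
    """
    genes = list(genes)
    if len(genes) < 2 * params.min_module_size:
        raise ValueError(
            f"need at least {2 * params.min_module_size} genes, got {len(genes)}"
        )
    corr = correlation_matrix(matrix, genes)
    adj = soft_threshold_adjacency(corr, params.beta)
    tom = topological_overlap(adj)
    diss = 1.0 - tom.to_numpy()
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(diss, checks=False)
    Z = linkage(condensed, method="average")
    labels = fcluster(Z, t=params.cut_height, criterion="distance")
    if len(np.unique(labels)) == 1:
        log.warning("all genes merged into a single module at cut_height %.3f", params.cut_height)

    gene_arr = np.asarray(genes, dtype=object)
    clusters = []
    unassigned: list = []
    for lab in np.unique(labels):
        members = list(gene_arr[labels == lab])
        if len(members) >= params.min_module_size:
            clusters.append(members)
        else:
            unassigned.extend(members)
    clusters.sort(key=lambda ms: (-len(ms), min(ms)))

    modules = {}
    for i, members in enumerate(clusters, start=1):
        mid = f"{label_prefix}{i}"
        rec = ModuleRecord(module_id=mid, members=members)
        rec.eigengene, rec.variance_explained = module_eigengene(matrix, members)
        rec = split_module(rec, matrix)
        modules[mid] = rec
    return ModuleSet(modules=modules, unassigned=sorted(unassigned), params=params)


# ---------------------------------------------------------------------------
# group-tissue relationships
# ---------------------------------------------------------------------------

def _group_eigengenes(modules: ModuleSet) -> pd.DataFrame:
    """Per-group signed eigengene: group a keeps the module eigengene, b flips it."""
    rows = {}
    for mid, rec in modules.modules.items():
        if rec.group_a:
            rows[f"{mid}a"] = rec.eigengene
        if rec.group_b:
            rows[f"{mid}b"] = -rec.eigengene
    return pd.DataFrame(rows).T


def group_tissue_correlation(
    modules: ModuleSet, metadata: pd.DataFrame, tissue_col: str = "tissue"
) -> pd.DataFrame:
    """Pearson correlation of each group eigengene with each tissue indicator.

    Rows are groups (M1a...), columns tissues; entries are R in [-1, 1].
    """
    if tissue_col not in metadata.columns:
        raise ValueError(f"metadata lacks column {tissue_col!r}")
    tissues = pd.unique(metadata[tissue_col])
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    eig = _group_eigengenes(modules)
    samples = eig.columns
    out = pd.DataFrame(index=eig.index, columns=tissues, dtype=float)
    labels = metadata.loc[samples, tissue_col]
    for t in tissues:
        indicator = (labels == t).to_numpy(dtype=float)
        ic = indicator - indicator.mean()
        for gid in eig.index:
            e = eig.loc[gid].to_numpy(dtype=float)
            ec = e - e.mean()
            den = np.sqrt((ec**2).sum() * (ic**2).sum())
            out.loc[gid, t] = float(ec @ ic / den) if den > 0 else np.nan
    return out


def tissue_tissue_correlation(
    modules: ModuleSet, metadata: pd.DataFrame, tissue_col: str = "tissue"
) -> pd.DataFrame:
    """Tissue x tissue correlation across per-tissue mean eigengene values."""
    eig = _group_eigengenes(modules)
    labels = metadata.loc[eig.columns, tissue_col]
    per_tissue = eig.T.groupby(labels.to_numpy()).mean()  # tissue x group
    return per_tissue.T.corr()
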
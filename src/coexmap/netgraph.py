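"""Unweighted signed correlation-threshold networks and hub analysis.

Two genes are connected iff the absolute Pearson correlation of their
profiles exceeds the threshold (strictly; the canonical cutoff is 0.9), and
the edge carries the sign of the correlation. Hubs are identified by degree
with competition ("1224") ranking: tied degrees share the minimum rank and
the following rank is skipped.
"""
from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .coexmodules import correlation_matrix

log = logging.getLogger(__name__)


def build_network(
    matrix: ExpressionMatrix, genes=None, threshold: float = 0.9
) -> nx.Graph:
    """Build the signed correlation-threshold network over ``genes``.

    Nodes are gene ids (zero-variance genes are retained without edges,
    logged); an edge (i, j) exists iff |r_ij| > threshold and carries
    ``sign`` (+1/-1) and ``r`` attributes. The graph stores the threshold in
    ``G.graph['threshold']``.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    genes = list(genes) if genes is not None else list(matrix.gene_ids)
    sub = matrix.values.loc[genes]
    if sub.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    var = sub.var(axis=1, ddof=0)
    dead = list(var.index[var == 0])
    live = [g for g in genes if g not in set(dead)]
    if dead:
        log.warning("%d zero-variance gene(s) kept as isolated nodes", len(dead))
    G = nx.Graph(threshold=threshold)
    G.add_nodes_from(genes)
    if len(live) >= 2:
        corr = correlation_matrix(matrix.subset_genes(live)).to_numpy()
        iu, ju = np.triu_indices(len(live), k=1)
        hits = np.abs(corr[iu, ju]) > threshold
        for i, j in zip(iu[hits], ju[hits]):
            r = corr[i, j]
            G.add_edge(live[i], live[j], sign=1 if r > 0 else -1, r=float(r))
    return G


def degree_rank(G: nx.Graph) -> pd.DataFrame:
    """Node degrees with tie-aware competition ranks, sorted by degree descending.

    Equal degrees share the minimum rank; the next distinct degree resumes at
    1 + number of higher-degree genes (so degrees 40, 40 ranked 3, 3 are
    followed by rank 5).
    """
    if G.number_of_nodes() == 0:
        return pd.DataFrame(columns=["gene_id", "degree", "rank"]).set_index("gene_id")
    deg = pd.Series(dict(G.degree()), name="degree").astype(int)
    ranks = stats.rankdata(-deg.to_numpy(), method="min").astype(int)
    out = pd.DataFrame({"degree": deg, "rank": ranks}, index=deg.index)
    out.index.name = "gene_id"
    return out.sort_values(["rank", "gene_id"], kind="stable")


def intersect_networks(a: nx.Graph, b: nx.Graph) -> nx.Graph:
    """Edges present in both networks with the same sign; nodes incident to them.

    A shared pair with conflicting signs is dropped (logged).
    """
    G = nx.Graph(threshold=a.graph.get("threshold"))
    dropped = 0
    for u, v, data in a.edges(data=True):
        if b.has_edge(u, v):
            if b[u][v].get("sign") == data.get("sign"):
                G.add_edge(u, v, **data)
            else:
                dropped += 1
    if dropped:
        log.warning("%d shared edge(s) dropped for conflicting signs", dropped)
    return G


def signed_neighbors(G: nx.Graph, gene) -> tuple[set, set]:
    """Partition a gene's neighbors into (positively, negatively) connected sets."""
    if gene not in G:
        raise KeyError(f"gene {gene!r} not in network")
    pos, neg = set(), set()
    for nb in G.neighbors(gene):
        (pos if G[gene][nb].get("sign", 1) > 0 else neg).add(nb)
    return pos, neg


def scale_free_fit(G: nx.Graph, n_bins: int = 10) -> dict:
    """Assess scale-free topology by a log-log degree-distribution regression.

    Positive degrees are binned into ``n_bins`` logarithmically spaced bins;
    mean bin degree vs. bin frequency is fit by ordinary least squares on the
    double-log scale. Returns bin centers/frequencies, the slope, and R^2.
    Requires at least 3 distinct positive degrees.
    """
    degrees = np.array([d for _, d in G.degree() if d > 0], dtype=float)
    if np.unique(degrees).size < 3:
        raise ValueError("need >= 3 distinct positive degrees for a scale-free fit")
    edges = np.logspace(np.log10(degrees.min()), np.log10(degrees.max()), n_bins + 1)
    edges[-1] *= 1 + 1e-9  # include the max degree in the last bin
    idx = np.digitize(degrees, edges) - 1
    centers, freqs = [], []
    for bin_i in range(n_bins):
        sel = idx == bin_i
        if sel.any():
            centers.append(degrees[sel].mean())
            freqs.append(sel.sum() / degrees.size)
    centers = np.asarray(centers)
    freqs = np.asarray(freqs)
    if centers.size < 3:
        raise ValueError("too few occupied bins for a regression")
    x = np.log10(centers)
    y = np.log10(freqs)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return {
        "bin_degree": centers,
        "bin_frequency": freqs,
        "slope": float(slope),
        "intercept": float(intercept),
        "r_squared": float(np.clip(r2, 0.0, 1.0)),
    }


def write_edge_list(G: nx.Graph, path) -> None:
    rows = [
        (u, v, "+" if d.get("sign", 1) > 0 else "-", d.get("r", np.nan))
        for u, v, d in sorted(G.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "sign", "r"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    G = nx.Graph()
    for _, row in df.iterrows():
        G.add_edge(
            row["gene_a"], row["gene_b"],
            sign=1 if row["sign"] == "+" else -1,
            r=float(row.get("r", np.nan)),
        )
    return G
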
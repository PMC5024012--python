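"""Hypergeometric over/under-representation of gene sets across partitions.

Given a partition of the gene universe into cells (coexpression groups,
expression-quartile classes, ...) and one or more gene sets, each (set, cell)
pair is tested both ways: overrepresentation P(X >= k) and
underrepresentation P(X <= k) under Hypergeometric(N, K, n). P-values are
BH-adjusted within a declared family and calls made at the chosen alpha.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ContingencyCell:
    """One cell of a set x partition contingency: k of n in cell, K of N overall."""

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self):
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"invalid cell: k={self.k} not in [0, min(n={self.n}, K={self.K})]")
        if self.n > self.N or self.K > self.N:
            raise ValueError(f"invalid cell: n={self.n}, K={self.K} must not exceed N={self.N}")

    @property
    def expected(self) -> float:
        return self.K * self.n / self.N


def hypergeometric_test(cell: ContingencyCell, alternative: str = "over") -> float:
    """Exact one-tailed hypergeometric p-value for a contingency cell.

    ``over``: P(X >= k); ``under``: P(X <= k) for
    X ~ Hypergeometric(N, K, n).
    """
    hg = stats.hypergeom(cell.N, cell.K, cell.n)
    if alternative == "over":
        return float(hg.sf(cell.k - 1))
    if alternative == "under":
        return float(hg.cdf(cell.k))
    raise ValueError(f"alternative must be 'over' or 'under', got {alternative!r}")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# expression quartile classes
# ---------------------------------------------------------------------------

@dataclass
class QuartilePartition:
    """Four near-equal expression classes; boundaries at the quartiles."""

    classes: pd.Series          # gene -> class label
    boundaries: tuple           # (Q1, Q2, Q3) on the mean-expression scale

    CLASS_LABELS = ("low", "low_moderate", "moderate_high", "high")


def quartile_classes(means: pd.Series) -> QuartilePartition:
    """Split genes into four near-equal classes by mean expression.

    Classes are rank-based: sizes differ by at most one, with any remainder
    allocated to the lowest classes first (so e.g. 4805 genes give sizes
    1202/1201/1201/1201 from low to high). Ties in mean expression are broken
    by stable gene-id order, making the partition deterministic.
    """
    means = pd.Series(means).astype(float)
    if len(means) < 4:
        raise ValueError("need at least 4 genes for quartile classes")
    order = means.reset_index()
    order.columns = ["gene_id", "mean"]
    order = order.sort_values(["mean", "gene_id"], kind="stable")
    n = len(order)
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    labels = np.repeat(QuartilePartition.CLASS_LABELS, sizes)
    classes = pd.Series(labels, index=order["gene_id"], name="class").loc[means.index]
    q1, q2, q3 = np.quantile(means.to_numpy(), [0.25, 0.5, 0.75])
    return QuartilePartition(classes=classes, boundaries=(float(q1), float(q2), float(q3)))


# ---------------------------------------------------------------------------
# full representation analysis
# ---------------------------------------------------------------------------

def representation_analysis(
    sets: dict,
    partition: pd.Series,
    alpha: float = 0.05,
    family: str = "per_set",
) -> pd.DataFrame:
    """Over/under-representation of each gene set in each partition cell.

    Parameters
    ----------
    sets : dict
        ``{set_id: iterable of gene ids}``; every member must be in the
        partition's population.
    partition : pandas.Series
        gene -> cell label over the whole population.
    family : str
        BH family: ``per_set`` (all cells and both tails of one set, the
        default), ``per_cell`` (all sets and tails within one cell — the
        by-column convention for quartile tables), or ``global``.

    Returns a DataFrame with one row per (set, cell): k, n, K, N, expected,
    p_over, p_under, p_over_adj, p_under_adj and call in {over, under, ns}.
    """
    partition = pd.Series(partition)
    population = pd.Index(partition.index)
    N = len(population)
    cells = list(pd.unique(partition))
    rows = []
    for set_id, members in sets.items():
        members = pd.Index(pd.unique(pd.Index(list(members))))
        outside = members.difference(population)
        if len(outside) == len(members):
            raise ValueError(f"set {set_id!r} is disjoint from the population")
        if len(outside):
            raise ValueError(
                f"set {set_id!r} has members outside the population: {outside.tolist()[:5]}"
            )
        K = len(members)
        in_set = partition.index.isin(members)
        for cell_label in cells:
            in_cell = (partition == cell_label).to_numpy()
            cell = ContingencyCell(
                k=int((in_set & in_cell).sum()), n=int(in_cell.sum()), K=K, N=N
            )
            rows.append(
                {
                    "set_id": set_id,
                    "cell_id": cell_label,
                    "k": cell.k,
                    "n": cell.n,
                    "K": cell.K,
                    "N": cell.N,
                    "expected": cell.expected,
                    "p_over": hypergeometric_test(cell, "over"),
                    "p_under": hypergeometric_test(cell, "under"),
                }
            )
    result = pd.DataFrame(rows)

    if family == "per_set":
        keys = result["set_id"]
    elif family == "per_cell":
        keys = result["cell_id"]
    elif family == "global":
        keys = pd.Series(0, index=result.index)
    else:
        raise ValueError(f"unknown BH family {family!r}")
    result["p_over_adj"] = np.nan
    result["p_under_adj"] = np.nan
    for _, idx in result.groupby(keys, sort=False).groups.items():
        pooled = np.concatenate([result.loc[idx, "p_over"], result.loc[idx, "p_under"]])
        adj = bh_adjust(pooled)
        result.loc[idx, "p_over_adj"] = adj[: len(idx)]
        result.loc[idx, "p_under_adj"] = adj[len(idx):]

    call = np.full(len(result), "ns", dtype=object)
    call[(result["k"] > result["expected"]) & (result["p_over_adj"] < alpha)] = "over"
    call[(result["k"] < result["expected"]) & (result["p_under_adj"] < alpha)] = "under"
    result["call"] = call
    return result
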
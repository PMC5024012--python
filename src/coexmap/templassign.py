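"""Template matching: assign low-confidence variable genes to coexpression groups.

Each candidate gene is correlated with every group's mean-profile template;
the best (most positively correlated) template is tested with the t-based
Pearson correlation test, p-values are BH-adjusted across all candidate
genes, and a gene is assigned iff its adjusted p falls below alpha and the
correlation is positive (groups are defined by positively correlated
profiles, so a negative match is no match).
"""
from __future__ import annotations

import sys

import numpy as np
import pandas as pd
from scipy import stats

from .setrep import bh_adjust


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation via t = r sqrt(n-2)/sqrt(1-r^2).

    ``|r| = 1`` is returned as the smallest positive float (the p -> 0 limit).
    """
    if n < 4:
        raise ValueError("need n >= 4 samples")
    if not -1 <= r <= 1:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1:
        return sys.float_info.min
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return float(2 * stats.t.sf(abs(t), n - 2))


def _pearson(profile: np.ndarray, template: np.ndarray) -> tuple[float, int]:
    """Pairwise-complete Pearson r and the number of complete pairs."""
    ok = np.isfinite(profile) & np.isfinite(template)
    n = int(ok.sum())
    if n < 4:
        return np.nan, n
    x = profile[ok] - profile[ok].mean()
    y = template[ok] - template[ok].mean()
    den = np.sqrt((x**2).sum() * (y**2).sum())
    if den == 0:
        return np.nan, n
    return float(np.clip(x @ y / den, -1.0, 1.0)), n


def template_match(
    profiles: pd.DataFrame,
    templates: pd.DataFrame,
    group_sizes: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assign genes to the group whose template they best match.

    Parameters
    ----------
    profiles : DataFrame
        Candidate genes x samples (same sample basis as the templates).
    templates : DataFrame
        Groups x samples mean profiles.
    group_sizes : Series, optional
        Used only to break exact correlation ties (larger group wins, then
        lexicographic group id).
    alpha : float
        Threshold on the BH-adjusted correlation p-value.

    Returns a DataFrame indexed by gene with columns best_group, r, n, p,
    p_adjusted, status ('assigned'/'unassigned') and reason.
    """
    common = profiles.columns.intersection(templates.columns)
    if len(common) < 4:
        raise ValueError("profiles and templates share fewer than 4 samples")
    prof = profiles[common].to_numpy(dtype=float)
    temp = templates[common].to_numpy(dtype=float)
    group_ids = list(templates.index)
    sizes = (
        pd.Series(group_sizes).reindex(group_ids).fillna(0).to_numpy(dtype=float)
        if group_sizes is not None
        else np.zeros(len(group_ids))
    )
    # deterministic candidate order on ties: by (-size, group_id)
    tie_order = sorted(range(len(group_ids)), key=lambda j: (-sizes[j], group_ids[j]))

    rows = []
    for i, gene in enumerate(profiles.index):
        rs = np.full(len(group_ids), np.nan)
        ns = np.zeros(len(group_ids), dtype=int)
        for j in range(len(group_ids)):
            rs[j], ns[j] = _pearson(prof[i], temp[j])
        if np.isnan(rs).all():
            rows.append((gene, "", np.nan, 0, np.nan, "unassigned", "too_few_samples"))
            continue
        best = max(
            (j for j in tie_order if not np.isnan(rs[j])),
            key=lambda j: (rs[j], -tie_order.index(j)),
        )
        p = correlation_pvalue(rs[best], int(ns[best]))
        rows.append((gene, group_ids[best], rs[best], int(ns[best]), p, "", ""))
    result = pd.DataFrame(
        rows, columns=["gene_id", "best_group", "r", "n", "p", "status", "reason"]
    ).set_index("gene_id")

    testable = result["p"].notna()
    result["p_adjusted"] = np.nan
    if testable.any():
        result.loc[testable, "p_adjusted"] = bh_adjust(result.loc[testable, "p"])
    assigned = testable & (result["p_adjusted"] < alpha) & (result["r"] > 0)
    result.loc[assigned, "status"] = "assigned"
    unassigned = testable & ~assigned
    result.loc[unassigned, "status"] = "unassigned"
    result.loc[unassigned & (result["r"] <= 0), "reason"] = "negative_correlation"
    result.loc[unassigned & (result["r"] > 0), "reason"] = "not_significant"
    return result
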
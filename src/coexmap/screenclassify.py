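"""Assumption screening and balanced mixed-model ANOVA gene classification.

Each detected gene in the multi-tissue experiment is modelled as

    y_ijk = mu + tissue_i + tree(tissue)_ij + dye_k + (tissue x dye)_ik + e_ijk

with tissue, dye and their interaction as fixed effects and tree nested in
tissue as a random blocking effect. Because the design is balanced, the
mixed model is solved in closed form with expected-mean-squares F ratios:
the tissue effect is tested against the tree-within-tissue mean square, the
dye terms against the residual. Genes whose residuals are non-normal
(Anderson-Darling), whose tissue variances are heterogeneous (Levene), or
which show a dye or tissue x dye effect are excluded before testing; the
remaining genes are split into invariant / variable-low / variable-high
confidence by the BH-adjusted tissue p-value.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .setrep import bh_adjust


# ---------------------------------------------------------------------------
# Anderson-Darling normality test (composite null, estimated mean and sd)
# ---------------------------------------------------------------------------

def _ad_statistic(sorted_z: np.ndarray) -> np.ndarray:
    """A^2 for rows of sorted standardized values (..., n)."""
    n = sorted_z.shape[-1]
    i = np.arange(1, n + 1)
    logcdf = stats.norm.logcdf(sorted_z)
    logsf = stats.norm.logsf(sorted_z)
    return -n - np.sum((2 * i - 1) * (logcdf + logsf[..., ::-1]), axis=-1) / n


def _ad_pvalue(a2_star: np.ndarray) -> np.ndarray:
    """Piecewise approximation for the case of estimated mean and variance."""
    a = np.asarray(a2_star, dtype=float)
    p = np.empty_like(a)
    hi = a >= 0.6
    mid = (a >= 0.34) & ~hi
    lo = (a > 0.2) & ~hi & ~mid
    tiny = a <= 0.2
    p[hi] = np.exp(1.2937 - 5.709 * a[hi] + 0.0186 * a[hi] ** 2)
    p[mid] = np.exp(0.9177 - 4.279 * a[mid] - 1.38 * a[mid] ** 2)
    p[lo] = 1 - np.exp(-8.318 + 42.796 * a[lo] - 59.938 * a[lo] ** 2)
    p[tiny] = 1 - np.exp(-13.436 + 101.14 * a[tiny] - 223.73 * a[tiny] ** 2)
    return np.clip(p, 0.0, 1.0)


def anderson_darling_normal(sample) -> tuple[float, float]:
    """Anderson-Darling test of normality with estimated parameters.

    Returns ``(A2, p)`` where ``A2`` is the unadjusted statistic and ``p``
    comes from the small-sample-adjusted statistic
    ``A2 * (1 + 0.75/n + 2.25/n^2)`` via the standard piecewise
    approximation. Requires ``n >= 8``; a zero-variance sample is degenerate
    and rejected.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("need a 1-D sample with n >= 8")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance sample: normality test is degenerate")
    z = np.sort((x - x.mean()) / sd)
    a2 = float(_ad_statistic(z))
    n = x.size
    a2_star = a2 * (1 + 0.75 / n + 2.25 / n**2)
    return a2, float(_ad_pvalue(np.array(a2_star)))


# ---------------------------------------------------------------------------
# Levene's test for homogeneity of variances
# ---------------------------------------------------------------------------

def levene_test(groups, center: str = "mean") -> tuple[float, float]:
    """Levene's test on >= 2 groups of values.

    ``center='mean'`` is the classical test; ``center='median'`` gives the
    Brown-Forsythe variant. Identical constant groups give W = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups each with >= 2 values")
    if all(np.ptp(g) == 0 for g in groups):
        return 0.0, 1.0
    w, p = stats.levene(*groups, center=center)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# balanced mixed-model ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Closed-form ANOVA decomposition for one gene.

    ``table`` rows: tissue, tree(tissue), dye, tissue:dye, residual with
    columns ss, df, ms, F, p (F/p only for tested effects).
    """

    gene_id: str
    table: pd.DataFrame

    @property
    def tissue_p(self) -> float:
        return float(self.table.loc["tissue", "p"])


def _layout(metadata: pd.DataFrame):
    """Validate the balanced tissue x tree x dye layout; return sorted index info."""
    for col in ("tissue", "tree"):
        if col not in metadata.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    meta = metadata.copy()
    if "dye" not in meta.columns:
        meta["dye"] = "D1"
    cells = meta.groupby(["tissue", "tree", "dye"], sort=True).size()
    if (cells != 1).any():
        raise ValueError(
            "unbalanced design: every tissue x tree x dye cell must be filled exactly once "
            "(use a generic unbalanced ANOVA instead); offending cells: "
            f"{cells[cells != 1].index.tolist()[:5]}"
        )
    tissues = np.sort(meta["tissue"].unique())
    trees = np.sort(meta["tree"].unique())
    dyes = np.sort(meta["dye"].unique())
    a, b, c = len(tissues), len(trees), len(dyes)
    if a < 2 or b < 2:
        raise ValueError("need >= 2 tissues and >= 2 trees")
    by_cell = meta.reset_index().set_index(["tissue", "tree", "dye"])
    full = pd.MultiIndex.from_product([tissues, trees, dyes])
    if not full.isin(by_cell.index).all():
        raise ValueError("unbalanced design: not all tissues share the same tree/dye labels")
    sample_order = by_cell.loc[full].iloc[:, 0].to_numpy()
    return sample_order, a, b, c


def _anova_arrays(y: np.ndarray, a: int, b: int, c: int):
    """Vectorized balanced decomposition. ``y``: (genes, a, b, c)."""
    g = y.shape[0]
    grand = y.mean(axis=(1, 2, 3), keepdims=True)
    m_i = y.mean(axis=(2, 3), keepdims=True)          # tissue means
    m_ij = y.mean(axis=3, keepdims=True)              # biological replicate means
    m_k = y.mean(axis=(1, 2), keepdims=True)          # dye means
    m_ik = y.mean(axis=2, keepdims=True)              # tissue x dye means

    ss_total = ((y - grand) ** 2).sum(axis=(1, 2, 3))
    ss_tissue = (b * c) * ((m_i - grand) ** 2).sum(axis=(1, 2, 3))
    ss_tree = c * ((m_ij - m_i) ** 2).sum(axis=(1, 2, 3))
    ss_dye = (a * b) * ((m_k - grand) ** 2).sum(axis=(1, 2, 3))
    ss_td = b * ((m_ik - m_i - m_k + grand) ** 2).sum(axis=(1, 2, 3))
    ss_res = ss_total - ss_tissue - ss_tree - ss_dye - ss_td
    ss_res = np.maximum(ss_res, 0.0)

    df = {
        "tissue": a - 1,
        "tree(tissue)": a * (b - 1),
        "dye": c - 1,
        "tissue:dye": (a - 1) * (c - 1),
        "residual": a * (b - 1) * (c - 1),
    }
    resid = y - (m_ij + m_ik - m_i)  # full-model residuals
    return (
        {"tissue": ss_tissue, "tree(tissue)": ss_tree, "dye": ss_dye,
         "tissue:dye": ss_td, "residual": ss_res, "total": ss_total},
        df,
        resid.reshape(g, -1),
    )


def _f_p(ss_num, df_num, ss_den, df_den):
    """F ratio and p with 0/0 -> (0, p=1) convention for degenerate genes."""
    ms_num = ss_num / df_num
    ms_den = ss_den / df_den
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_num / ms_den
    p = np.where(np.isnan(f), 1.0, stats.f.sf(np.where(np.isnan(f), 0.0, f), df_num, df_den))
    f = np.where(np.isnan(f), 0.0, f)
    return f, p


def fit_mixed_anova(gene_profile, metadata: pd.DataFrame, gene_id: str = "gene") -> AnovaResult:
    """Fit the balanced mixed model to a single gene's profile.

    ``gene_profile`` is a Series (indexed by sample id) or array aligned with
    ``metadata``. Raises on an unbalanced design.
    """
    if isinstance(gene_profile, pd.Series):
        y = gene_profile.loc[metadata.index].to_numpy(dtype=float)
    else:
        y = np.asarray(gene_profile, dtype=float)
        if y.size != len(metadata):
            raise ValueError("profile length does not match metadata")
        y = pd.Series(y, index=metadata.index).to_numpy()
    if np.isnan(y).any():
        raise ValueError(f"gene {gene_id}: missing values; design incomplete")
    order, a, b, c = _layout(metadata)
    pos = {s: i for i, s in enumerate(metadata.index)}
    arr = y[[pos[s] for s in order]].reshape(1, a, b, c)
    ss, df, _ = _anova_arrays(arr, a, b, c)

    rows = {}
    f_t, p_t = _f_p(ss["tissue"], df["tissue"], ss["tree(tissue)"], df["tree(tissue)"])
    rows["tissue"] = (ss["tissue"][0], df["tissue"], f_t[0], p_t[0])
    rows["tree(tissue)"] = (ss["tree(tissue)"][0], df["tree(tissue)"], np.nan, np.nan)
    if c > 1:
        f_d, p_d = _f_p(ss["dye"], df["dye"], ss["residual"], df["residual"])
        f_x, p_x = _f_p(ss["tissue:dye"], df["tissue:dye"], ss["residual"], df["residual"])
        rows["dye"] = (ss["dye"][0], df["dye"], f_d[0], p_d[0])
        rows["tissue:dye"] = (ss["tissue:dye"][0], df["tissue:dye"], f_x[0], p_x[0])
        rows["residual"] = (ss["residual"][0], df["residual"], np.nan, np.nan)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["ss", "df", "F", "p"]
    )
    table.insert(2, "ms", table["ss"] / table["df"].replace(0, np.nan))
    return AnovaResult(gene_id=gene_id, table=table)


# ---------------------------------------------------------------------------
# screening + classification over a whole matrix
# ---------------------------------------------------------------------------

CATEGORY_ORDER = ("invariant", "variable_low", "variable_high", "excluded")


def classify_genes(
    matrix: ExpressionMatrix,
    alpha_screen: float = 0.05,
    alpha_variable: float = 0.05,
    alpha_high: float = 0.0001,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen and classify every gene of a balanced multi-tissue experiment.

    Returns ``(screen, classification)`` DataFrames indexed by gene.

    ``screen`` columns: ad_statistic, ad_p, levene_W, levene_p, dye_p,
    tissue_dye_p, status, reason. Screening happens on tissue-centered
    values (normality) and tissue-grouped raw values (variance homogeneity);
    each screening family (normality, variance, dye, tissue x dye) is
    BH-adjusted across genes and a gene is excluded when any adjusted
    screening p falls below ``alpha_screen``.

    ``classification`` columns: tissue_p, tissue_p_adjusted, category with
    category one of invariant / variable_low / variable_high / excluded;
    tissue p-values are BH-adjusted across all tested genes.
    """
    order, a, b, c = _layout(matrix.metadata)
    vals = matrix.values[order].to_numpy(dtype=float)
    genes = matrix.gene_ids
    n_genes = len(genes)

    incomplete = np.isnan(vals).any(axis=1)
    y = np.where(np.isnan(vals), 0.0, vals).reshape(n_genes, a, b, c)
    ss, df, resid = _anova_arrays(y, a, b, c)

    f_t, tissue_p = _f_p(ss["tissue"], df["tissue"], ss["tree(tissue)"], df["tree(tissue)"])
    if c > 1:
        _, dye_p = _f_p(ss["dye"], df["dye"], ss["residual"], df["residual"])
        _, td_p = _f_p(ss["tissue:dye"], df["tissue:dye"], ss["residual"], df["residual"])
    else:
        dye_p = np.ones(n_genes)
        td_p = np.ones(n_genes)

    # Anderson-Darling on tissue-centered values (residuals of the tissue-mean
    # model: retains distributional signal the saturated-model fit would absorb)
    del resid
    res = (y - y.mean(axis=(2, 3), keepdims=True)).reshape(n_genes, -1)
    sd = res.std(axis=1, ddof=1)
    ok = sd > 0
    ad_stat = np.zeros(n_genes)
    ad_p = np.ones(n_genes)
    if ok.any():
        z = np.sort((res[ok] - res[ok].mean(axis=1, keepdims=True)) / sd[ok, None], axis=1)
        a2 = _ad_statistic(z)
        n = res.shape[1]
        ad_stat[ok] = a2
        ad_p[ok] = _ad_pvalue(a2 * (1 + 0.75 / n + 2.25 / n**2))

    # Levene across tissue groups (vectorized one-way ANOVA on |deviations|)
    flat = y.reshape(n_genes, a, b * c)
    zdev = np.abs(flat - flat.mean(axis=2, keepdims=True))
    zbar_g = zdev.mean(axis=2)
    zbar = zdev.mean(axis=(1, 2))
    n_per = b * c
    ss_between = n_per * ((zbar_g - zbar[:, None]) ** 2).sum(axis=1)
    ss_within = ((zdev - zbar_g[:, :, None]) ** 2).sum(axis=(1, 2))
    N = a * n_per
    with np.errstate(divide="ignore", invalid="ignore"):
        W = (ss_between / (a - 1)) / (ss_within / (N - a))
    levene_p = np.where(np.isnan(W), 1.0, stats.f.sf(np.where(np.isnan(W), 0.0, W), a - 1, N - a))
    W = np.where(np.isnan(W), 0.0, W)

    # BH within each screening family across genes, then exclude at alpha_screen
    complete = ~incomplete
    ad_adj = np.full(n_genes, np.nan)
    lev_adj = np.full(n_genes, np.nan)
    dye_adj = np.full(n_genes, np.nan)
    td_adj = np.full(n_genes, np.nan)
    if complete.any():
        ad_adj[complete] = bh_adjust(ad_p[complete])
        lev_adj[complete] = bh_adjust(levene_p[complete])
        if c > 1:
            dye_adj[complete] = bh_adjust(dye_p[complete])
            td_adj[complete] = bh_adjust(td_p[complete])
    reasons = []
    for g in range(n_genes):
        r = []
        if incomplete[g]:
            r.append("incomplete")
        else:
            if ad_adj[g] < alpha_screen:
                r.append("nonnormal")
            if lev_adj[g] < alpha_screen:
                r.append("heteroscedastic")
            if c > 1 and dye_adj[g] < alpha_screen:
                r.append("dye_effect")
            if c > 1 and td_adj[g] < alpha_screen:
                r.append("tissue_dye_interaction")
        reasons.append(",".join(r))
    excluded = np.array([bool(r) for r in reasons])

    screen = pd.DataFrame(
        {
            "ad_statistic": ad_stat,
            "ad_p": ad_p,
            "levene_W": W,
            "levene_p": levene_p,
            "dye_p": dye_p,
            "tissue_dye_p": td_p,
            "status": np.where(excluded, "excluded", "tested"),
            "reason": reasons,
        },
        index=genes,
    )

    tested = ~excluded
    p_adj = np.full(n_genes, np.nan)
    if tested.any():
        p_adj[tested] = bh_adjust(tissue_p[tested])
    category = np.full(n_genes, "excluded", dtype=object)
    category[tested & (p_adj >= alpha_variable)] = "invariant"
    category[tested & (p_adj < alpha_variable)] = "variable_low"
    category[tested & (p_adj < alpha_high)] = "variable_high"

    classification = pd.DataFrame(
        {"tissue_p": tissue_p, "tissue_p_adjusted": p_adj, "category": category},
        index=genes,
    )
    classification.loc[excluded, "tissue_p"] = np.nan
    return screen, classification
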
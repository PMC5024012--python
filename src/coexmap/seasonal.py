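"""Seasonal (time-course) analysis of secondary xylem expression.

A balanced two-way fixed-effects ANOVA (species x timepoint) calls
temporally variable genes; those are clustered with the same
soft-threshold/TOM machinery as the tissue experiment (T-labelled modules,
beta = 18 by default), and the temporal clusters are integrated with the
tissue-based coexpression groups by overrepresentation to call earlywood
(June-July preferential) and latewood (September preferential) genes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .coexmodules import ModuleDetectionParams, ModuleSet, detect_modules
from .ingest import collapse_probes
from .setrep import bh_adjust, representation_analysis

log = logging.getLogger(__name__)

EARLY_TIMEPOINTS = ("June", "July")
LATE_TIMEPOINTS = ("September",)


# ---------------------------------------------------------------------------
# two-way fixed-effects ANOVA
# ---------------------------------------------------------------------------

def _two_way_layout(metadata: pd.DataFrame):
    for col in ("species", "timepoint"):
        if col not in metadata.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    counts = metadata.groupby(["species", "timepoint"]).size()
    species = np.sort(metadata["species"].unique())
    times = np.sort(metadata["timepoint"].unique())
    full = pd.MultiIndex.from_product([species, times])
    missing = full.difference(counts.index)
    if len(missing):
        raise ValueError(f"empty design cell(s): {missing.tolist()}")
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: unequal replication across cells")
    r = int(counts.iloc[0])
    if r < 2:
        raise ValueError("need >= 2 replicates per species x timepoint cell")
    key = metadata["species"].astype(str) + "|" + metadata["timepoint"].astype(str)
    order = (
        metadata.assign(_k=key)
        .sort_values(["species", "timepoint"], kind="stable")
        .index.to_numpy()
    )
    return order, len(species), len(times), r


def _two_way_arrays(y: np.ndarray, a: int, b: int, r: int):
    """Vectorized balanced two-way decomposition; ``y``: (genes, a, b, r)."""
    grand = y.mean(axis=(1, 2, 3), keepdims=True)
    m_a = y.mean(axis=(2, 3), keepdims=True)
    m_b = y.mean(axis=(1, 3), keepdims=True)
    m_ab = y.mean(axis=3, keepdims=True)
    ss_a = (b * r) * ((m_a - grand) ** 2).sum(axis=(1, 2, 3))
    ss_b = (a * r) * ((m_b - grand) ** 2).sum(axis=(1, 2, 3))
    ss_ab = r * ((m_ab - m_a - m_b + grand) ** 2).sum(axis=(1, 2, 3))
    ss_res = ((y - m_ab) ** 2).sum(axis=(1, 2, 3))
    df = {"species": a - 1, "time": b - 1, "interaction": (a - 1) * (b - 1),
          "residual": a * b * (r - 1)}
    return {"species": ss_a, "time": ss_b, "interaction": ss_ab, "residual": ss_res}, df


def _f_p(ss_num, df_num, ss_res, df_res):
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_num / df_num) / (ss_res / df_res)
    p = np.where(np.isnan(f), 1.0, stats.f.sf(np.where(np.isnan(f), 0.0, f), df_num, df_res))
    return np.where(np.isnan(f), 0.0, f), p


def two_way_anova(gene_profile, metadata: pd.DataFrame) -> pd.DataFrame:
    """Balanced two-way fixed-effects ANOVA (species, time, interaction).

    Returns a table with rows species/time/interaction/residual and columns
    ss, df, ms, F, p. Degenerate all-equal profiles report p = 1.
    """
    if isinstance(gene_profile, pd.Series):
        y = gene_profile.loc[metadata.index].to_numpy(dtype=float)
    else:
        y = np.asarray(gene_profile, dtype=float)
        if y.size != len(metadata):
            raise ValueError("profile length does not match metadata")
    if np.isnan(y).any():
        raise ValueError("missing values: design incomplete")
    order, a, b, r = _two_way_layout(metadata)
    pos = {s: i for i, s in enumerate(metadata.index)}
    arr = y[[pos[s] for s in order]].reshape(1, a, b, r)
    ss, df = _two_way_arrays(arr, a, b, r)
    rows = {}
    for effect in ("species", "time", "interaction"):
        f, p = _f_p(ss[effect], df[effect], ss["residual"], df["residual"])
        rows[effect] = (ss[effect][0], df[effect], f[0], p[0])
    rows["residual"] = (ss["residual"][0], df["residual"], np.nan, np.nan)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["ss", "df", "F", "p"])
    table.insert(2, "ms", table["ss"] / table["df"].replace(0, np.nan))
    return table


def call_temporally_variable(
    matrix: ExpressionMatrix,
    probe_map: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-probe two-way ANOVA; BH across all probes; any-probe rule per gene.

    ``matrix`` may be probe-level (with ``probe_map`` giving probe -> gene)
    or gene-level (``probe_map=None``: identity). Returns a gene-indexed
    DataFrame with columns species_p, time_p, interaction_p (BH-adjusted,
    minimum over the gene's probes) and ``variable`` (bool: >= 1 probe with
    adjusted time p < alpha).
    """
    order, a, b, r = _two_way_layout(matrix.metadata)
    vals = matrix.values[order].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("missing values: seasonal ANOVA needs a complete design")
    y = vals.reshape(len(vals), a, b, r)
    ss, df = _two_way_arrays(y, a, b, r)
    _, sp_p = _f_p(ss["species"], df["species"], ss["residual"], df["residual"])
    _, t_p = _f_p(ss["time"], df["time"], ss["residual"], df["residual"])
    _, x_p = _f_p(ss["interaction"], df["interaction"], ss["residual"], df["residual"])
    probes = pd.DataFrame(
        {
            "species_p_adj": bh_adjust(sp_p),
            "time_p_adj": bh_adjust(t_p),
            "interaction_p_adj": bh_adjust(x_p),
        },
        index=matrix.gene_ids,
    )
    probes["significant"] = probes["time_p_adj"] < alpha
    if probe_map is None:
        out = probes.rename(
            columns={"species_p_adj": "species_p", "time_p_adj": "time_p",
                     "interaction_p_adj": "interaction_p"}
        )
        out["variable"] = out.pop("significant")
        return out
    calls = collapse_probes(probes["significant"], probe_map, rule="any_significant")
    gene_of = probe_map.loc[probes.index].to_numpy()
    best = probes.groupby(gene_of).min()
    out = best.rename(
        columns={"species_p_adj": "species_p", "time_p_adj": "time_p",
                 "interaction_p_adj": "interaction_p"}
    ).drop(columns=["significant"])
    out["variable"] = calls.reindex(out.index).fillna(False)
    return out


# ---------------------------------------------------------------------------
# temporal clustering and phase integration
# ---------------------------------------------------------------------------

def temporal_clusters(
    matrix: ExpressionMatrix,
    variable_genes,
    params: ModuleDetectionParams | None = None,
) -> ModuleSet:
    """Cluster temporally variable genes into T-labelled modules (beta = 18).

    The default cut height is 0.8 rather than the 0.99 used for the
    multi-tissue analysis: with only four timepoints, distinct temporal
    shapes are strongly mutually correlated (e.g. a step change vs a
    progressive decline share r ~ 0.87), so their TOM branches merge around
    0.85-0.91 while within-cluster joins complete below ~0.5; a 0.8 cut
    separates them across the generator's noise range.
    """
    if params is None:
        params = ModuleDetectionParams(beta=18.0, cut_height=0.8)
    return detect_modules(matrix, variable_genes, params, label_prefix="T")


def classify_cluster_preference(
    clusters: ModuleSet, metadata: pd.DataFrame, timepoint_col: str = "timepoint"
) -> dict:
    """Label each temporal group june_july / september / other from its template.

    The group's template is averaged per timepoint; the June-July mean is
    compared with the September mean to decide the preference. Intermediate
    timepoints only yield 'other' when they dominate both ends by a clear
    margin (10% of the template's seasonal range) — a step profile that is
    flat June-August must not flip to 'other' on replicate noise. This
    automates what is otherwise declared by inspecting cluster profiles.
    """
    prefs = {}
    templates = clusters.templates()
    labels = metadata.loc[templates.columns, timepoint_col]
    per_time = templates.T.groupby(labels.to_numpy()).mean().T  # groups x timepoints
    early_cols = [t for t in EARLY_TIMEPOINTS if t in per_time.columns]
    late_cols = [t for t in LATE_TIMEPOINTS if t in per_time.columns]
    mid_cols = [t for t in per_time.columns if t not in early_cols + late_cols]
    for gid in per_time.index:
        row = per_time.loc[gid]
        early = row[early_cols].mean() if early_cols else -np.inf
        late = row[late_cols].mean() if late_cols else -np.inf
        mid = row[mid_cols].max() if mid_cols else -np.inf
        margin = 0.1 * (row.max() - row.min())
        if mid > max(early, late) + margin:
            prefs[gid] = "other"
        elif early > late:
            prefs[gid] = "june_july"
        else:
            prefs[gid] = "september"
    return prefs


@dataclass
class PhaseResult:
    phases: pd.Series                 # gene -> earlywood / latewood / none
    representation: pd.DataFrame      # cluster-group x tissue-group table
    cluster_preference: dict          # T-group -> june_july / september / other
    enriched_cells: list              # (cluster_group, tissue_group) over-calls


def phase_integration(
    t_clusters: ModuleSet,
    tissue_groups: pd.Series,
    metadata: pd.DataFrame,
    cluster_preference: dict | None = None,
    alpha: float = 0.05,
) -> PhaseResult:
    """Call earlywood/latewood genes by crossing temporal and tissue structure.

    Each temporal cluster group is tested for overrepresentation across the
    tissue-based coexpression groups (hypergeometric, BH). Members of a
    June-July-preferential cluster that sit in a tissue group where that
    cluster is significantly overrepresented are earlywood genes; September
    symmetrically gives latewood; everything else is phase 'none'.

    ``tissue_groups`` maps gene -> tissue coexpression group label over the
    shared gene universe.
    """
    tissue_groups = pd.Series(tissue_groups)
    t_membership = t_clusters.group_membership()
    universe = tissue_groups.index
    t_in_universe = t_membership[t_membership.index.isin(universe)]
    if t_in_universe.empty:
        raise ValueError("temporal clusters and tissue groups share no genes")
    if cluster_preference is None:
        cluster_preference = classify_cluster_preference(t_clusters, metadata)

    sets = {
        gid: list(t_in_universe.index[t_in_universe == gid])
        for gid in sorted(t_in_universe.unique())
    }
    sets = {gid: genes for gid, genes in sets.items() if genes}
    rep = representation_analysis(sets, tissue_groups, alpha=alpha, family="per_set")

    enriched = [
        (row["set_id"], row["cell_id"])
        for _, row in rep.iterrows()
        if row["call"] == "over"
    ]
    phases = pd.Series("none", index=universe, name="phase")
    for cluster_gid, tissue_gid in sorted(enriched):
        pref = cluster_preference.get(cluster_gid, "other")
        if pref == "june_july":
            phase = "earlywood"
        elif pref == "september":
            phase = "latewood"
        else:
            continue
        members = t_in_universe.index[t_in_universe == cluster_gid]
        in_cell = tissue_groups.loc[members] == tissue_gid
        phases.loc[members[in_cell]] = phase
    return PhaseResult(
        phases=phases,
        representation=rep,
        cluster_preference=cluster_preference,
        enriched_cells=sorted(enriched),
    )
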
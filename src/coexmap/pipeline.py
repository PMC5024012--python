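"""End-to-end pipeline: simulate -> ingest -> classify -> modules -> assign ->
enrich -> network -> seasonal, with a manifest for reproducibility.

The pipeline runs on the synthetic generators, so every stage's output can
be compared with planted truth. All file outputs are TSV/JSON/Newick and the
whole run is a deterministic function of the config (including its seed).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ExpressionMatrix
from .coexmodules import (
    ModuleDetectionParams,
    detect_modules,
    group_tissue_correlation,
)
from .ingest import average_technical_replicates, cluster_samples, write_matrix, write_newick
from .netgraph import build_network, degree_rank, scale_free_fit, write_edge_list
from .screenclassify import classify_genes
from .seasonal import call_temporally_variable, phase_integration, temporal_clusters
from .setrep import quartile_classes, representation_analysis
from .synthdata import (
    PlantedModuleSpec,
    TissueDesign,
    default_progressive_cluster,
    default_step_cluster,
    generate_temporal_experiment,
    generate_tissue_experiment,
    write_truth,
)
from .templassign import template_match

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline thresholds, sizes and seeds in one serializable record."""

    seed: int = 0
    # screening / classification
    alpha_screen: float = 0.05
    alpha_variable: float = 0.05
    alpha_high: float = 0.0001
    # module detection
    beta_tissue: float = 14.0
    beta_temporal: float = 18.0
    min_module_size: int = 30
    cut_height: float = 0.99
    cut_height_temporal: float = 0.8
    # template matching / representation / network
    template_alpha: float = 0.05
    representation_alpha: float = 0.05
    network_threshold: float = 0.9
    # synthetic scenario (tissue experiment)
    n_modules: int = 3
    genes_per_group: int = 60
    n_invariant: int = 300
    n_violators: int = 40
    module_amplitude: float = 2.0
    noise_sd: float = 0.2
    tree_effect_sd: float = 0.1
    dye_effect_sd: float = 0.05
    # synthetic scenario (temporal experiment)
    temporal_genes: int = 400
    temporal_noise_sd: float = 0.2

    def validate(self) -> "PipelineConfig":
        for name in ("alpha_screen", "alpha_variable", "alpha_high",
                     "template_alpha", "representation_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.alpha_high > self.alpha_variable:
            raise ValueError("alpha_high must not exceed alpha_variable")
        if not 0 <= self.network_threshold < 1:
            raise ValueError("network_threshold must be in [0, 1)")
        if self.beta_tissue < 1 or self.beta_temporal < 1:
            raise ValueError("soft-thresholding powers must be >= 1")
        if not 0 < self.cut_height <= 1 or not 0 < self.cut_height_temporal <= 1:
            raise ValueError("cut heights must be in (0, 1]")
        if self.n_modules < 1 or self.genes_per_group < 1:
            raise ValueError("planted module counts must be positive")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()


def tissue_preferential_profile(m: int, n_tissues: int = 7) -> tuple:
    """Mean-zero profile of a module preferential to tissue ``m``: high in one
    tissue, mildly depleted in the rest (between-profile correlation
    -1/(n_tissues - 1), so distinct planted modules are nearly orthogonal)."""
    profile = np.full(n_tissues, -1.0 / (n_tissues - 1))
    profile[m % n_tissues] = 1.0
    return tuple(profile)


def _planted_module_specs(config: PipelineConfig, n_tissues: int) -> list:
    """Planted modules, each preferential to a different tissue."""
    specs = []
    for m in range(config.n_modules):
        specs.append(
            PlantedModuleSpec(
                module_id=f"P{m + 1}",
                n_genes_a=config.genes_per_group,
                n_genes_b=config.genes_per_group,
                tissue_profile=tissue_preferential_profile(m, n_tissues),
                amplitude=config.module_amplitude,
            )
        )
    return specs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage in dependency order; write outputs and a manifest.

    Returns a summary dict (gene-count funnel, recovery diagnostics, output
    paths). Re-running with the same config reproduces identical tables.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(config)}

    # -- stage 1: simulate -------------------------------------------------
    design = TissueDesign()
    modules_spec = _planted_module_specs(config, len(design.tissues))
    matrix, truth = generate_tissue_experiment(
        design,
        modules_spec,
        n_invariant=config.n_invariant,
        n_violators=config.n_violators,
        noise_sd=config.noise_sd,
        dye_effect_sd=config.dye_effect_sd,
        tree_effect_sd=config.tree_effect_sd,
        seed=config.seed,
    )
    write_matrix(matrix, out / "expt1_matrix.tsv", out / "expt1_meta.tsv")
    write_truth(truth, out / "expt1_truth.tsv")
    log.info("simulated %d genes x %d samples", matrix.n_genes, matrix.n_samples)

    # -- stage 2: QC dendrogram -------------------------------------------
    tree = cluster_samples(matrix)
    write_newick(tree, out / "expt1_samples.nwk")

    # -- stage 3: classification ------------------------------------------
    screen, classification = classify_genes(
        matrix, config.alpha_screen, config.alpha_variable, config.alpha_high
    )
    screen.to_csv(out / "screen.tsv", sep="\t")
    classification.to_csv(out / "classification.tsv", sep="\t")
    funnel = classification["category"].value_counts().to_dict()
    funnel["detected"] = int(matrix.n_genes)
    summary["funnel"] = funnel
    log.info("classification funnel: %s", funnel)

    # -- stage 4: modules on high-confidence genes ------------------------
    averaged = average_technical_replicates(matrix)
    high_conf = classification.index[classification["category"] == "variable_high"]
    params = ModuleDetectionParams(
        beta=config.beta_tissue,
        min_module_size=min(config.min_module_size, max(3, config.genes_per_group // 2)),
        cut_height=config.cut_height,
    )
    mods = detect_modules(averaged, high_conf, params)
    mods.group_membership().to_csv(out / "module_groups.tsv", sep="\t", header=True)
    mods.templates().to_csv(out / "templates.tsv", sep="\t")
    gt_corr = group_tissue_correlation(mods, averaged.metadata)
    gt_corr.to_csv(out / "group_tissue_correlation.tsv", sep="\t")
    summary["n_modules"] = len(mods.modules)
    summary["n_groups"] = int((mods.group_sizes() > 0).sum())

    # -- stage 5: template assignment of low-confidence genes -------------
    low_conf = classification.index[classification["category"] == "variable_low"]
    assignments = None
    if len(low_conf) and len(mods.modules):
        assignments = template_match(
            averaged.values.loc[low_conf],
            mods.templates(),
            group_sizes=mods.group_sizes(),
            alpha=config.template_alpha,
        )
        assignments.to_csv(out / "assignments.tsv", sep="\t")
        summary["n_assigned"] = int((assignments["status"] == "assigned").sum())

    # combined gene -> group partition over all variable genes
    partition = mods.group_membership()
    if assignments is not None:
        ok = assignments["status"] == "assigned"
        partition = pd.concat([partition, assignments.loc[ok, "best_group"]])
    partition.to_csv(out / "partition.tsv", sep="\t", header=True)

    # -- stage 6: representation analyses ---------------------------------
    invariant = classification.index[classification["category"] == "invariant"]
    if len(invariant) >= 4:
        quartiles = quartile_classes(matrix.values.loc[invariant].mean(axis=1))
        quartiles.classes.to_csv(out / "invariant_quartiles.tsv", sep="\t", header=True)
    planted_sets = {
        f"planted_{mid}": list(truth.module_members(mid))
        for mid in sorted(truth.table.loc[truth.table["label"] == "module", "module_id"].unique())
    }
    planted_sets = {
        sid: [g for g in genes if g in partition.index]
        for sid, genes in planted_sets.items()
    }
    planted_sets = {sid: genes for sid, genes in planted_sets.items() if genes}
    if planted_sets:
        rep = representation_analysis(
            planted_sets, partition, alpha=config.representation_alpha, family="per_set"
        )
        rep.to_csv(out / "representation.tsv", sep="\t", index=False)

    # -- stage 7: network on the largest module ---------------------------
    if mods.modules:
        biggest = max(mods.modules.values(), key=lambda r: len(r.members))
        net = build_network(averaged, biggest.members, config.network_threshold)
        write_edge_list(net, out / "network_edges.tsv")
        stats_df = degree_rank(net)
        stats_df.to_csv(out / "network_degrees.tsv", sep="\t")
        summary["network"] = {
            "nodes": net.number_of_nodes(),
            "edges": net.number_of_edges(),
        }
        try:
            fit = scale_free_fit(net)
            summary["network"]["scale_free_r2"] = fit["r_squared"]
        except ValueError:
            pass

    # -- stage 8: seasonal experiment -------------------------------------
    group_n = max(1, config.temporal_genes // 6)  # 4 planted groups, 1/3 flat
    t_matrix, t_truth = generate_temporal_experiment(
        n_genes=config.temporal_genes,
        cluster_specs=[
            default_step_cluster("T1", group_n, group_n),
            default_progressive_cluster("T2", group_n, group_n),
        ],
        noise_sd=config.temporal_noise_sd,
        seed=config.seed + 1,
    )
    # couple the seasonal genes to the tissue-experiment universe so the
    # phase integration has a shared gene space: planted temporal cluster
    # groups reuse ids of planted tissue module groups, invariant fill-in
    # reuses invariant ids
    rename = _couple_universes(t_truth.table, truth.table)
    t_matrix = ExpressionMatrix(t_matrix.values.rename(index=rename), t_matrix.metadata)
    t_truth.table = t_truth.table.rename(index=rename)
    write_matrix(t_matrix, out / "expt2_matrix.tsv", out / "expt2_meta.tsv")
    write_truth(t_truth, out / "expt2_truth.tsv")

    calls = call_temporally_variable(t_matrix, alpha=config.alpha_variable)
    calls.to_csv(out / "temporal_calls.tsv", sep="\t")
    variable_genes = calls.index[calls["variable"]]
    summary["n_temporal_variable"] = int(len(variable_genes))
    t_params = ModuleDetectionParams(
        beta=config.beta_temporal,
        min_module_size=min(config.min_module_size, 20),
        cut_height=config.cut_height_temporal,
    )
    if len(variable_genes) >= 2 * t_params.min_module_size:
        t_mods = temporal_clusters(t_matrix, variable_genes, t_params)
        t_mods.group_membership().to_csv(out / "temporal_groups.tsv", sep="\t", header=True)
        phase = phase_integration(
            t_mods, partition, t_matrix.metadata, alpha=config.representation_alpha
        )
        phase.phases.to_csv(out / "phases.tsv", sep="\t", header=True)
        counts = phase.phases.value_counts().to_dict()
        summary["phases"] = {k: int(v) for k, v in counts.items()}

    # -- manifest ----------------------------------------------------------
    outputs = sorted(p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "coexmap_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    config.to_yaml(out / "config.yaml")
    summary["outdir"] = str(out)
    return summary


def _couple_universes(t_table: pd.DataFrame, tissue_table: pd.DataFrame) -> dict:
    """Map seasonal gene ids onto tissue-experiment ids (cluster i -> module i)."""
    rename: dict = {}
    t_clusters = [c for c in pd.unique(t_table["module_id"]) if c]
    m_modules = [m for m in pd.unique(tissue_table["module_id"]) if m]
    for ci, cid in enumerate(t_clusters):
        if ci >= len(m_modules):
            break
        for grp in ("a", "b"):
            src = t_table.index[(t_table["module_id"] == cid) & (t_table["group"] == grp)]
            dst = tissue_table.index[
                (tissue_table["module_id"] == m_modules[ci]) & (tissue_table["group"] == grp)
            ]
            for s, d in zip(src, dst):
                rename[s] = d
    t_flat = [g for g in t_table.index[t_table["label"] == "invariant"]]
    m_inv = [g for g in tissue_table.index[tissue_table["label"] == "invariant"]]
    for s, d in zip(t_flat, m_inv):
        rename[s] = d
    return rename
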
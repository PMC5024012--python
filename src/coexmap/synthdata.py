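"""Synthetic expression experiments with planted, fully known structure.

Two generators emulate the designs this pipeline targets:

* :func:`generate_tissue_experiment` — a balanced multi-tissue two-colour
  microarray design (several vegetative tissues, biological replicates per
  tissue, dye-swap technical replicates), with planted anticorrelated module
  pairs, planted invariant (housekeeping) genes, and genes that deliberately
  violate the ANOVA screening assumptions.
* :func:`generate_temporal_experiment` — a seasonal time-course in secondary
  xylem of two species, with planted temporal clusters (a "stable then
  step-change" shape and a "progressive" shape) carrying an
  earlywood/latewood phase label.

All randomness flows from a single integer seed; per-gene substreams are
spawned deterministically so regenerating with the same arguments is
bit-for-bit reproducible.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

DEFAULT_TISSUES = (
    "apex",
    "foliage",
    "xylem_shoot",
    "xylem_root",
    "phelloderm_shoot",
    "phelloderm_root",
    "root_tip",
)

DEFAULT_TIMEPOINTS = ("June", "July", "August", "September")
DEFAULT_SPECIES = ("white_spruce", "norway_spruce")


@dataclass(frozen=True)
class TissueDesign:
    """Balanced multi-tissue design: tissues x trees x dye replicates."""

    tissues: tuple = DEFAULT_TISSUES
    n_trees: int = 4
    n_dyes: int = 2

    def __post_init__(self):
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissue labels must be unique")
        if self.n_trees < 2:
            raise ValueError("need at least 2 biological replicates per tissue")
        if self.n_dyes not in (1, 2):
            raise ValueError("n_dyes must be 1 or 2")

    @property
    def n_samples(self) -> int:
        return len(self.tissues) * self.n_trees * self.n_dyes

    def sample_table(self) -> pd.DataFrame:
        """One row per array: sample_id, tissue, tree, dye."""
        rows = [
            (f"{t}.T{tree}.D{dye}", t, f"T{tree}", f"D{dye}")
            for t, tree, dye in itertools.product(
                self.tissues, range(1, self.n_trees + 1), range(1, self.n_dyes + 1)
            )
        ]
        df = pd.DataFrame(rows, columns=["sample_id", "tissue", "tree", "dye"])
        return df.set_index("sample_id")


@dataclass(frozen=True)
class PlantedModuleSpec:
    """A planted module: two anticorrelated gene groups sharing one tissue profile.

    Group "a" genes follow ``amplitude * tissue_profile``; group "b" genes
    follow its negation, so with low noise the pair forms one module split
    into two coexpression groups.
    """

    module_id: str
    n_genes_a: int
    n_genes_b: int
    tissue_profile: tuple
    amplitude: float = 2.0

    def __post_init__(self):
        if self.n_genes_a < 1 or self.n_genes_b < 1:
            raise ValueError("both groups need at least one gene")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class TemporalClusterSpec:
    """A planted temporal cluster: anticorrelated gene pair over timepoints.

    ``time_profile`` gives the per-timepoint mean shift (before scaling by
    ``amplitude``) followed by group-a genes; group-b genes get its negation.
    """

    cluster_id: str
    n_genes_a: int
    n_genes_b: int
    time_profile: tuple
    amplitude: float = 2.0

    def __post_init__(self):
        if self.n_genes_a < 1 or self.n_genes_b < 0:
            raise ValueError("group sizes invalid")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass
class SyntheticTruth:
    """Planted labels for every generated gene.

    ``table`` columns: label (invariant / module / violator), module_id,
    group (a/b), baseline, plus generator-level scalars recorded as fields.
    """

    table: pd.DataFrame
    noise_sd: float
    seed: int
    extras: dict = field(default_factory=dict)

    def genes_with_label(self, label: str) -> pd.Index:
        return self.table.index[self.table["label"] == label]

    def module_members(self, module_id: str, group: str | None = None) -> pd.Index:
        sel = self.table["module_id"] == module_id
        if group is not None:
            sel &= self.table["group"] == group
        return self.table.index[sel]


def _gene_rngs(seed: int, n: int):
    """Deterministic independent substream per gene."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_tissue_experiment(
    design: TissueDesign,
    modules: list[PlantedModuleSpec],
    n_invariant: int = 100,
    n_violators: int = 0,
    baseline_range: tuple = (6.0, 12.0),
    noise_sd: float = 0.2,
    dye_effect_sd: float = 0.0,
    tree_effect_sd: float = 0.1,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a balanced multi-tissue dye-swap experiment.

    Gene value = baseline + group_sign * amplitude * tissue_profile[tissue]
    + tree intercept (shared by the dye pair of a biological replicate)
    + dye offset + iid Gaussian noise, all on the log2 scale.

    Violators alternate between heavy-tailed noise (Student-t, 2 df) and an
    additive dye main effect, so both screening branches see positives.

    Returns the expression matrix and a :class:`SyntheticTruth` recording
    every planted assignment.
    """
    if noise_sd < 0 or dye_effect_sd < 0 or tree_effect_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    if n_invariant < 0 or n_violators < 0:
        raise ValueError("gene counts must be non-negative")
    ids = [m.module_id for m in modules]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate module ids: {ids}")
    for m in modules:
        if len(m.tissue_profile) != len(design.tissues):
            raise ValueError(
                f"module {m.module_id}: tissue_profile length {len(m.tissue_profile)} "
                f"!= {len(design.tissues)} tissues"
            )

    samples = design.sample_table()
    tissue_idx = np.array([list(design.tissues).index(t) for t in samples["tissue"]])
    # biological replicate index (tissue x tree), shared across the dye pair
    biorep_codes = (samples["tissue"] + "|" + samples["tree"]).astype("category").cat.codes.to_numpy()
    n_bioreps = biorep_codes.max() + 1
    dye_sign = np.where(samples["dye"] == "D1", -0.5, 0.5)  # contrast-coded dye

    # assemble the planted gene roster
    rows = []
    for m in modules:
        for i in range(m.n_genes_a):
            rows.append((f"{m.module_id}a_{i:04d}", "module", m.module_id, "a"))
        for i in range(m.n_genes_b):
            rows.append((f"{m.module_id}b_{i:04d}", "module", m.module_id, "b"))
    rows += [(f"inv_{i:04d}", "invariant", "", "") for i in range(n_invariant)]
    rows += [(f"viol_{i:04d}", "violator", "", "") for i in range(n_violators)]
    truth = pd.DataFrame(rows, columns=["gene_id", "label", "module_id", "group"]).set_index(
        "gene_id"
    )
    profile_by_module = {m.module_id: m.amplitude * np.asarray(m.tissue_profile, float) for m in modules}

    n_genes = len(truth)
    rngs = _gene_rngs(seed, n_genes)
    values = np.empty((n_genes, design.n_samples))
    baselines = np.empty(n_genes)
    viol_reason = []
    for g, (gene, rec) in enumerate(truth.iterrows()):
        rng = rngs[g]
        base = rng.uniform(*baseline_range)
        baselines[g] = base
        y = np.full(design.n_samples, base)
        if rec["label"] == "module":
            shift = profile_by_module[rec["module_id"]]
            sign = 1.0 if rec["group"] == "a" else -1.0
            y = y + sign * shift[tissue_idx]
        tree_fx = rng.normal(0.0, tree_effect_sd, n_bioreps) if tree_effect_sd > 0 else np.zeros(n_bioreps)
        y = y + tree_fx[biorep_codes]
        if dye_effect_sd > 0:
            y = y + rng.normal(0.0, dye_effect_sd) * dye_sign
        if rec["label"] == "violator":
            # alternate the two violation mechanisms deterministically
            if g % 2 == 0:
                y = y + rng.standard_t(2, design.n_samples) * max(noise_sd, 0.3) * 3.0
                viol_reason.append((gene, "heavy_tailed"))
            else:
                y = y + 1.5 * dye_sign  # strong dye main effect
                y = y + rng.normal(0.0, noise_sd, design.n_samples)
                viol_reason.append((gene, "dye_effect"))
        else:
            if noise_sd > 0:
                y = y + rng.normal(0.0, noise_sd, design.n_samples)
        values[g] = y

    truth["baseline"] = baselines
    truth["violation"] = ""
    for gene, reason in viol_reason:
        truth.loc[gene, "violation"] = reason

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=truth.index, columns=samples.index), samples.copy()
    )
    return matrix, SyntheticTruth(truth, noise_sd=noise_sd, seed=seed)


def default_step_cluster(cluster_id: str = "T1", n_a: int = 60, n_b: int = 60,
                         amplitude: float = 2.0) -> TemporalClusterSpec:
    """Stable June-August, then a sharp change into September (group a high early)."""
    return TemporalClusterSpec(cluster_id, n_a, n_b, (1.0, 1.0, 1.0, -1.0), amplitude)


def default_progressive_cluster(cluster_id: str = "T2", n_a: int = 60, n_b: int = 60,
                                amplitude: float = 2.0) -> TemporalClusterSpec:
    """Progressive decline starting in August, steepest into September."""
    return TemporalClusterSpec(cluster_id, n_a, n_b, (1.0, 1.0, 0.0, -1.0), amplitude)


def generate_temporal_experiment(
    n_genes: int = 400,
    n_species: int = 2,
    timepoints: tuple = DEFAULT_TIMEPOINTS,
    n_trees: int = 6,
    cluster_specs: list[TemporalClusterSpec] | None = None,
    noise_sd: float = 0.2,
    species_effect: float = 0.0,
    baseline_range: tuple = (6.0, 12.0),
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate the seasonal xylem time-course (species x timepoint x tree).

    ``cluster_specs`` defaults to one step-change and one progressive planted
    cluster. Genes not covered by any cluster are temporally invariant.
    Truth records cluster membership, group, and an earlywood/latewood phase
    derived from where each gene's profile peaks (June/July -> earlywood,
    September -> latewood).
    """
    if len(timepoints) < 2:
        raise ValueError("need at least 2 timepoints")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if cluster_specs is None:
        cluster_specs = [default_step_cluster(), default_progressive_cluster()]
    ids = [c.cluster_id for c in cluster_specs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate cluster ids: {ids}")
    planted = sum(c.n_genes_a + c.n_genes_b for c in cluster_specs)
    if planted > n_genes:
        raise ValueError(f"cluster members ({planted}) exceed n_genes ({n_genes})")
    for c in cluster_specs:
        if len(c.time_profile) != len(timepoints):
            raise ValueError(f"cluster {c.cluster_id}: profile length mismatch")

    species = list(DEFAULT_SPECIES[:n_species])
    if n_species > len(DEFAULT_SPECIES):
        species = [f"species{k+1}" for k in range(n_species)]
    rows = [
        (f"{sp}.{tp}.T{tree}", sp, tp, f"T{tree}")
        for sp, tp, tree in itertools.product(species, timepoints, range(1, n_trees + 1))
    ]
    samples = pd.DataFrame(rows, columns=["sample_id", "species", "timepoint", "tree"]).set_index(
        "sample_id"
    )
    time_idx = np.array([list(timepoints).index(t) for t in samples["timepoint"]])
    species_idx = np.array([species.index(s) for s in samples["species"]])
    n_samples = len(samples)

    def _phase(profile: np.ndarray) -> str:
        peak = timepoints[int(np.argmax(profile))]
        if peak in ("June", "July"):
            return "earlywood"
        if peak == "September":
            return "latewood"
        return "none"

    recs = []
    for c in cluster_specs:
        prof = c.amplitude * np.asarray(c.time_profile, float)
        for i in range(c.n_genes_a):
            recs.append((f"{c.cluster_id}a_{i:04d}", "cluster", c.cluster_id, "a", _phase(prof)))
        for i in range(c.n_genes_b):
            recs.append((f"{c.cluster_id}b_{i:04d}", "cluster", c.cluster_id, "b", _phase(-prof)))
    for i in range(n_genes - planted):
        recs.append((f"flat_{i:04d}", "invariant", "", "", "none"))
    truth = pd.DataFrame(
        recs, columns=["gene_id", "label", "module_id", "group", "phase"]
    ).set_index("gene_id")
    profile_by_cluster = {
        c.cluster_id: c.amplitude * np.asarray(c.time_profile, float) for c in cluster_specs
    }

    rngs = _gene_rngs(seed, len(truth))
    values = np.empty((len(truth), n_samples))
    baselines = np.empty(len(truth))
    for g, (gene, rec) in enumerate(truth.iterrows()):
        rng = rngs[g]
        base = rng.uniform(*baseline_range)
        baselines[g] = base
        y = np.full(n_samples, base)
        if rec["label"] == "cluster":
            prof = profile_by_cluster[rec["module_id"]]
            sign = 1.0 if rec["group"] == "a" else -1.0
            y = y + sign * prof[time_idx]
        if species_effect != 0.0:
            y = y + rng.normal(0.0, species_effect) * (species_idx - 0.5)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, n_samples)
        values[g] = y
    truth["baseline"] = baselines

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=truth.index, columns=samples.index), samples.copy()
    )
    return matrix, SyntheticTruth(truth, noise_sd=noise_sd, seed=seed)


def write_truth(truth: SyntheticTruth, path) -> None:
    truth.table.to_csv(path, sep="\t")
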
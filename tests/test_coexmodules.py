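"""Adjacency, topological overlap, module detection, eigengenes and group splits."""
import numpy as np
import pandas as pd
import pytest

from coexmap.containers import ExpressionMatrix
from coexmap.coexmodules import (
    ModuleDetectionParams,
    ModuleRecord,
    correlation_matrix,
    detect_modules,
    group_tissue_correlation,
    module_eigengene,
    soft_threshold_adjacency,
    split_module,
    tissue_tissue_correlation,
    topological_overlap,
)
from coexmap.ingest import average_technical_replicates
from coexmap.pipeline import tissue_preferential_profile
from coexmap.screenclassify import classify_genes
from coexmap.synthdata import PlantedModuleSpec, generate_tissue_experiment


def matrix_from(values: np.ndarray, genes=None, samples=None, meta=None):
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), meta)


class TestCorrelationMatrix:
    def test_duplicate_and_negated_genes(self):
        base = np.array([1.0, 2.0, 4.0, 3.0])
        m = matrix_from(np.vstack([base, base, -base]))
        corr = correlation_matrix(m)
        assert corr.loc["g0", "g1"] == pytest.approx(1.0)
        assert corr.loc["g0", "g2"] == pytest.approx(-1.0)

    def test_hand_computed_three_by_four(self):
        """Correlations of a small table against values computed from the
        definition sum((x-xbar)(y-ybar)) / sqrt(...) by hand."""
        m = matrix_from(np.array([
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 1.0, 4.0, 3.0],
            [1.0, 1.0, 2.0, 6.0],
        ]))
        corr = correlation_matrix(m)
        # deviations: g0 [-1.5,-0.5,0.5,1.5] (ss 5); g1 [-0.5,-1.5,1.5,0.5]
        # (ss 5); g2 [-1.5,-1.5,-0.5,3.5] (ss 17); cross sums 3, 8, 4
        assert corr.loc["g0", "g1"] == pytest.approx(3.0 / 5.0)
        assert corr.loc["g0", "g2"] == pytest.approx(8.0 / np.sqrt(5 * 17.0))
        assert corr.loc["g1", "g2"] == pytest.approx(4.0 / np.sqrt(5 * 17.0))

    def test_zero_variance_gene_named(self):
        m = matrix_from(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))
        with pytest.raises(ValueError, match="g0"):
            correlation_matrix(m)


class TestSoftThreshold:
    def test_extreme_and_identity_cases(self):
        corr = pd.DataFrame(
            [[1.0, 0.5, -1.0], [0.5, 1.0, 0.0], [-1.0, 0.0, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        adj14 = soft_threshold_adjacency(corr, 14)
        assert adj14.loc["a", "c"] == pytest.approx(1.0)       # |r|=1
        assert adj14.loc["a", "b"] == pytest.approx(0.5**14)   # ~6.1e-5
        assert adj14.loc["a", "a"] == 0.0
        adj1 = soft_threshold_adjacency(corr, 1)
        assert adj1.loc["a", "b"] == pytest.approx(0.5)

    def test_monotone_in_beta(self):
        corr = pd.DataFrame([[1.0, 0.7], [0.7, 1.0]], index=list("ab"), columns=list("ab"))
        a_lo = soft_threshold_adjacency(corr, 6).loc["a", "b"]
        a_hi = soft_threshold_adjacency(corr, 14).loc["a", "b"]
        assert a_hi < a_lo

    def test_beta_below_one_rejected(self):
        corr = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            soft_threshold_adjacency(corr, 0.5)


def naive_tom(a: np.ndarray) -> np.ndarray:
    """Direct loop evaluation of the TOM formula (independent oracle)."""
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestTopologicalOverlap:
    def test_complete_graph_maximal(self):
        n = 5
        a = 1.0 - np.eye(n)
        adj = pd.DataFrame(a, index=range(n), columns=range(n))
        tom = topological_overlap(adj).to_numpy()
        off = tom[~np.eye(n, dtype=bool)]
        assert off == pytest.approx(np.ones(n * n - n))

    def test_disconnected_pair_zero(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 0.0
        a[2, 3] = a[3, 2] = 0.9
        adj = pd.DataFrame(a, index=range(4), columns=range(4))
        tom = topological_overlap(adj)
        assert tom.loc[0, 1] == 0.0
        assert tom.loc[0, 2] == 0.0

    def test_matches_naive_formula_on_random(self, rng):
        a = rng.uniform(0, 1, size=(6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        adj = pd.DataFrame(a, index=range(6), columns=range(6))
        tom = topological_overlap(adj).to_numpy()
        assert tom == pytest.approx(naive_tom(a))
        assert tom.min() >= 0.0 and tom.max() <= 1.0

    def test_four_node_hand_case(self):
        """Hand evaluation on a 4-node toy with mixed weights.

        a01=0.8, a02=0.4, a12=0.5, a13=0.2, all else 0.
        k = [1.2, 1.5, 0.9, 0.2].
        TOM01 = (a02*a21 + 0.8) / (min(1.2,1.5)+1-0.8) = (0.2+0.8)/1.4
        """
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 0.8
        a[0, 2] = a[2, 0] = 0.4
        a[1, 2] = a[2, 1] = 0.5
        a[1, 3] = a[3, 1] = 0.2
        adj = pd.DataFrame(a, index=range(4), columns=range(4))
        tom = topological_overlap(adj)
        assert tom.loc[0, 1] == pytest.approx((0.4 * 0.5 + 0.8) / (1.2 + 1 - 0.8))
        assert tom.loc[2, 3] == pytest.approx((0.5 * 0.2 + 0.0) / (0.2 + 1 - 0.0))


class TestEigengene:
    def test_identical_profiles(self):
        base = np.array([1.0, 3.0, 2.0, 5.0])
        m = matrix_from(np.vstack([base, base, base]))
        eig, varexp = module_eigengene(m, ["g0", "g1", "g2"])
        assert varexp == pytest.approx(1.0)
        z = (base - base.mean()) / base.std()
        assert abs(np.corrcoef(eig, z)[0, 1]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        base = np.array([1.0, 3.0, 2.0, 5.0])
        m = matrix_from(np.vstack([base, base, -base, -base]))
        eig, varexp = module_eigengene(m, list(m.gene_ids))
        assert varexp == pytest.approx(1.0)
        rec = split_module(
            ModuleRecord("M1", list(m.gene_ids), eigengene=eig), m
        )
        assert {len(rec.group_a), len(rec.group_b)} == {2}

    def test_maximality_vs_spectral(self, rng):
        """Variance explained equals the top eigenvalue share of the
        standardized gene covariance (full spectral cross-check)."""
        vals = rng.normal(size=(8, 10))
        m = matrix_from(vals)
        _, varexp = module_eigengene(m, list(m.gene_ids))
        z = (vals - vals.mean(1, keepdims=True)) / vals.std(1, keepdims=True)
        eigvals = np.linalg.eigvalsh(z @ z.T)
        assert varexp == pytest.approx(eigvals[-1] / eigvals.sum())

    def test_planted_module_eigengene_tracks_profile(self, two_module_experiment):
        matrix, truth = two_module_experiment
        members = truth.module_members("P1")
        eig, _ = module_eigengene(matrix, members)
        profile = np.asarray(tissue_preferential_profile(0))
        tissue_idx = [list(matrix.metadata["tissue"].unique()).index(t)
                      for t in matrix.metadata["tissue"]]
        planted = profile[tissue_idx]
        assert abs(np.corrcoef(eig, planted)[0, 1]) > 0.95

    def test_degenerate_rejected(self):
        m = matrix_from(np.ones((3, 4)))
        with pytest.raises(ValueError):
            module_eigengene(m, list(m.gene_ids))


class TestSplitModule:
    def test_zero_correlation_goes_to_group_a(self):
        base = np.array([1.0, -1.0, 1.0, -1.0])
        flat = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to base
        m = matrix_from(np.vstack([base, base, flat]))
        eig, _ = module_eigengene(m, ["g0", "g1"])
        rec = split_module(ModuleRecord("M1", ["g0", "g1", "g2"], eigengene=eig), m)
        assert "g2" in rec.group_a

    def test_single_gene_group_template_is_profile(self):
        base = np.array([1.0, 3.0, 2.0, 5.0])
        m = matrix_from(np.vstack([base, base, -base]))
        eig, _ = module_eigengene(m, list(m.gene_ids))
        rec = split_module(ModuleRecord("M1", list(m.gene_ids), eigengene=eig), m)
        single = rec.group_b if len(rec.group_b) == 1 else rec.group_a
        template = rec.template_b if len(rec.group_b) == 1 else rec.template_a
        assert template.to_numpy() == pytest.approx(m.values.loc[single[0]].to_numpy())

    def test_planted_split_matches_truth(self, two_module_experiment):
        matrix, truth = two_module_experiment
        members = list(truth.module_members("P1"))
        eig, _ = module_eigengene(matrix, members)
        rec = split_module(ModuleRecord("M1", members, eigengene=eig), matrix)
        a_true = set(truth.module_members("P1", "a"))
        got_a, got_b = set(rec.group_a), set(rec.group_b)
        assert got_a == a_true or got_b == a_true  # up to label swap


class TestDetectModules:
    def test_two_planted_modules_recovered(self, two_module_experiment):
        from sklearn.metrics import adjusted_rand_score

        matrix, truth = two_module_experiment
        _, cls = classify_genes(matrix)
        hi = cls.index[cls["category"] == "variable_high"]
        avg = average_technical_replicates(matrix)
        ms = detect_modules(avg, hi, ModuleDetectionParams(beta=14, min_module_size=25))
        assert len(ms.modules) == 2
        memb = ms.membership().reindex(hi).fillna("unassigned")
        ari = adjusted_rand_score(truth.table.loc[hi, "module_id"], memb)
        assert ari >= 0.9

    def test_noise_only_genes_unassigned(self, design):
        m, _ = generate_tissue_experiment(design, [], n_invariant=120, noise_sd=0.3, seed=21)
        ms = detect_modules(m, m.gene_ids, ModuleDetectionParams(beta=14, min_module_size=10))
        n_unassigned = len(ms.unassigned)
        assert n_unassigned >= 0.9 * m.n_genes

    def test_sample_relabelling_invariance(self, two_module_experiment, rng):
        matrix, truth = two_module_experiment
        genes = list(truth.module_members("P1")) + list(truth.module_members("P2"))
        params = ModuleDetectionParams(beta=14, min_module_size=10)
        ms1 = detect_modules(matrix, genes, params)
        perm = rng.permutation(matrix.n_samples)
        shuffled = ExpressionMatrix(
            matrix.values.iloc[:, perm], matrix.metadata.iloc[perm]
        )
        ms2 = detect_modules(shuffled, genes, params)
        assert ms1.membership().sort_index().equals(ms2.membership().sort_index())

    def test_too_few_genes_rejected(self, two_module_experiment):
        matrix, _ = two_module_experiment
        with pytest.raises(ValueError, match="at least"):
            detect_modules(matrix, list(matrix.gene_ids[:5]),
                           ModuleDetectionParams(min_module_size=10))


class TestGroupTissueCorrelation:
    def _modules(self, experiment):
        matrix, truth = experiment
        avg = average_technical_replicates(matrix)
        return avg, truth, detect_modules(
            avg, list(truth.module_members("P1")) + list(truth.module_members("P2")),
            ModuleDetectionParams(beta=14, min_module_size=10),
        )

    def test_planted_preferential_tissue_has_max_r(self, two_module_experiment):
        avg, truth, ms = self._modules(two_module_experiment)
        gt = group_tissue_correlation(ms, avg.metadata)
        # P1 prefers tissue 0 (apex): the group holding P1a genes peaks there
        p1a = set(truth.module_members("P1", "a"))
        for gid in gt.index:
            rec = ms.modules[gid[:-1]]
            genes = set(rec.group_a if gid.endswith("a") else rec.group_b)
            if genes and len(genes & p1a) / len(genes) > 0.9:
                assert gt.loc[gid].idxmax() == "apex"
                assert gt.loc[gid].max() > 0.7
                break
        else:
            pytest.fail("no detected group matches planted P1a")

    def test_shift_invariance(self, two_module_experiment):
        avg, _, ms = self._modules(two_module_experiment)
        gt1 = group_tissue_correlation(ms, avg.metadata)
        for rec in ms.modules.values():
            rec.eigengene = rec.eigengene + 5.0
        gt2 = group_tissue_correlation(ms, avg.metadata)
        pd.testing.assert_frame_equal(gt1, gt2)

    def test_indicator_template_perfect_r(self):
        meta = pd.DataFrame({"tissue": ["x", "x", "y", "y"]}, index=list("abcd"))
        vals = np.array([[1.0, 1.0, 0.0, 0.0], [1.0, 0.9, 0.1, 0.0]])
        m = matrix_from(vals, samples=list("abcd"), meta=meta)
        eig, _ = module_eigengene(m, ["g0", "g1"])
        rec = split_module(ModuleRecord("M1", ["g0", "g1"], eigengene=eig), m)
        # g0 itself equals the x-tissue indicator; its group's eigengene is
        # within noise of the indicator
        from coexmap.coexmodules import ModuleSet

        ms = ModuleSet({"M1": rec}, [], ModuleDetectionParams())
        gt = group_tissue_correlation(ms, meta)
        assert gt.loc["M1a", "x"] > 0.99

    def test_single_tissue_rejected(self, two_module_experiment):
        matrix, truth = two_module_experiment
        meta = matrix.metadata.copy()
        meta["tissue"] = "only"
        ms = detect_modules(
            matrix, list(truth.module_members("P1")),
            ModuleDetectionParams(beta=14, min_module_size=10),
        )
        with pytest.raises(ValueError, match="tissues"):
            group_tissue_correlation(ms, meta)

    def test_tissue_tissue_correlation_shape(self, two_module_experiment):
        avg, _, ms = self._modules(two_module_experiment)
        tt = tissue_tissue_correlation(ms, avg.metadata)
        assert tt.shape == (7, 7)
        assert np.allclose(np.diag(tt), 1.0)
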
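"""Embedding, k-means and stability-metric contracts."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import stratmeta as sm
from stratmeta.stratify import (
    DegenerateDataError,
    StabilityReport,
    StratifyError,
    build_stability_report,
    choose_k,
    internal_indices,
)


def _frame(arr, prefix="s"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(len(arr))],
                        columns=[f"PC{i + 1}" for i in range(arr.shape[1])])


class TestVariableGenes:
    def test_single_high_variance_gene_selected(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(np.ones((10, 6)), index=[f"g{i}" for i in range(10)])
        mat.loc["g3"] = rng.normal(0, 5, size=6)
        assert sm.select_variable_genes(mat, 0.1) == ["g3"]

    def test_fraction_one_returns_all(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.normal(size=(12, 5)), index=[f"g{i}" for i in range(12)])
        assert set(sm.select_variable_genes(mat, 1.0)) == set(mat.index)

    def test_tie_broken_lexicographically(self):
        mat = pd.DataFrame(np.zeros((10, 4)), index=[f"g{i}" for i in range(10)])
        mat.loc["g9"] = [0, 1, 0, 1]
        mat.loc["g2"] = [1, 0, 1, 0]   # same variance as g9
        assert sm.select_variable_genes(mat, 0.1) == ["g2"]

    def test_constant_matrix_rejected(self):
        mat = pd.DataFrame(np.ones((10, 4)), index=[f"g{i}" for i in range(10)])
        with pytest.raises(StratifyError, match="zero variance"):
            sm.select_variable_genes(mat, 0.1)


class TestPCA:
    def test_rank_one_data_explains_everything(self):
        t = np.linspace(-2, 2, 8)
        mat = pd.DataFrame(np.vstack([3 * t, -t, 2 * t] + [0 * t] * 7),
                           index=[f"g{i}" for i in range(10)],
                           columns=[f"s{i}" for i in range(8)])
        emb = sm.run_pca(mat, n_pcs=2)
        assert emb.var_explained[0] == pytest.approx(1.0)

    def test_var_explained_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.normal(size=(30, 15)),
                           index=[f"g{i}" for i in range(30)])
        emb = sm.run_pca(mat, n_pcs=10)
        assert (np.diff(emb.var_explained) <= 1e-12).all()
        assert emb.var_explained.sum() <= 1 + 1e-9

    def test_full_reconstruction(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.normal(size=(20, 9)),
                           index=[f"g{i}" for i in range(20)],
                           columns=[f"s{i}" for i in range(9)])
        emb = sm.run_pca(mat, n_pcs=8)   # full rank for 9 samples
        recon = emb.scores.to_numpy() @ emb.loadings.to_numpy().T
        centered = mat.T.to_numpy() - emb.center.to_numpy()
        assert np.abs(recon - centered).max() < 1e-8

    def test_too_many_pcs_rejected(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.normal(size=(20, 5)))
        with pytest.raises(StratifyError, match="n_pcs"):
            sm.run_pca(mat, n_pcs=5)


class TestProjection:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(rng.normal(size=(25, 12)),
                           index=[f"g{i}" for i in range(25)],
                           columns=[f"s{i}" for i in range(12)])
        return mat, sm.run_pca(mat, n_pcs=5)

    def test_training_sample_projects_to_own_score(self, fitted):
        mat, emb = fitted
        proj = sm.project_samples(emb, mat[["s3"]])
        assert np.abs(proj.to_numpy() - emb.scores.loc[["s3"]].to_numpy()).max() < 1e-8

    def test_training_mean_projects_to_origin(self, fitted):
        mat, emb = fitted
        mean_profile = mat.mean(axis=1).to_frame("new")
        proj = sm.project_samples(emb, mean_profile)
        assert np.abs(proj.to_numpy()).max() < 1e-8

    def test_genes_outside_subspace_ignored(self, fitted):
        mat, emb = fitted
        new = pd.concat([mat[["s0"]].rename(columns={"s0": "a"}),
                         mat[["s0"]].rename(columns={"s0": "b"})], axis=1)
        extra = pd.DataFrame([[5.0, -5.0]], index=["extra_gene"], columns=["a", "b"])
        out = sm.project_samples(emb, pd.concat([new, extra]))
        assert np.allclose(out.loc["a"], out.loc["b"])

    def test_missing_variable_gene_rejected(self, fitted):
        mat, emb = fitted
        with pytest.raises(StratifyError, match="lack variable genes"):
            sm.project_samples(emb, mat.iloc[1:][["s0"]])


class TestKMeans:
    def test_two_pairs_recovered_with_hand_wcss(self):
        pts = _frame([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0], [11.0, 0.0]])
        sol = sm.kmeans_cluster(pts, k=2, seed=0)
        a = sol.assignment
        assert a["s0"] == a["s1"] != a["s2"]
        assert a["s2"] == a["s3"]
        # each pair contributes 2 * 0.5^2 = 0.5
        assert sol.wcss == pytest.approx(1.0)

    def test_k1_wcss_is_total_centered_ss(self):
        rng = np.random.default_rng(7)
        pts = _frame(rng.normal(size=(20, 3)))
        sol = sm.kmeans_cluster(pts, k=1, seed=0)
        centered = pts.to_numpy() - pts.to_numpy().mean(axis=0)
        assert sol.wcss == pytest.approx((centered**2).sum())

    def test_same_seed_identical_assignment(self, planted_scores):
        scores, _ = planted_scores
        a = sm.kmeans_cluster(scores, 5, seed=42).assignment
        b = sm.kmeans_cluster(scores, 5, seed=42).assignment
        pd.testing.assert_series_equal(a, b)

    def test_recovers_planted_partition(self, planted_scores):
        scores, labels = planted_scores
        sol = sm.kmeans_cluster(scores, 5, seed=1)
        assert adjusted_rand_score(labels, sol.assignment.to_numpy()) > 0.9


class TestInternalIndices:
    def test_hand_computed_silhouette(self):
        # two clusters of 2 points, within-distance 1, centers 10 apart:
        # for every point a = 1, b = mean(10, 11) or mean(9, 10) -> s ~ 0.9
        pts = _frame([[0.0], [1.0], [10.0], [11.0]])
        sol = sm.kmeans_cluster(pts, 2, seed=0)
        _, sil = internal_indices(pts, sol)
        a = 1.0
        b1 = (10 + 11) / 2
        b2 = (9 + 10) / 2
        expected = np.mean([(b1 - a) / b1, (b2 - a) / b2, (b2 - a) / b2, (b1 - a) / b1])
        assert sil == pytest.approx(expected, abs=1e-12)
        assert sil == pytest.approx(0.9, abs=0.01)

    def test_duplicate_points_give_silhouette_one(self):
        pts = _frame([[0.0, 0.0]] * 3 + [[5.0, 5.0]] * 3)
        sol = sm.kmeans_cluster(pts, 2, seed=0)
        _, sil = internal_indices(pts, sol)
        assert sil == pytest.approx(1.0)

    def test_wcss_matches_solution(self, planted_scores):
        scores, _ = planted_scores
        sol = sm.kmeans_cluster(scores, 4, seed=3)
        wcss, _ = internal_indices(scores, sol)
        assert wcss == pytest.approx(sol.wcss, rel=1e-10)


class TestBootstrapJaccard:
    def test_stable_structure_reproduces(self, planted_scores):
        scores, _ = planted_scores
        per_cluster, overall = sm.bootstrap_jaccard(scores, 5, B=50, seed=0)
        assert overall > 0.9
        assert (per_cluster > 0.8).all()

    def test_degenerate_identical_points_rejected(self):
        pts = _frame([[1.0, 1.0]] * 10)
        with pytest.raises(DegenerateDataError):
            sm.bootstrap_jaccard(pts, 2, B=10, seed=0)

    def test_seed_reproducibility(self, planted_scores):
        scores, _ = planted_scores
        _, a = sm.bootstrap_jaccard(scores, 3, B=20, seed=5)
        _, b = sm.bootstrap_jaccard(scores, 3, B=20, seed=5)
        assert a == b


class TestPredictionStrength:
    def test_k1_is_exactly_one(self, planted_scores):
        scores, _ = planted_scores
        assert sm.prediction_strength(scores, 1, repetitions=5, seed=0) == 1.0

    def test_high_at_true_k(self, planted_scores):
        scores, _ = planted_scores
        ps = sm.prediction_strength(scores, 5, repetitions=30, seed=0)
        assert ps > 0.8

    def test_seed_reproducibility(self, planted_scores):
        scores, _ = planted_scores
        a = sm.prediction_strength(scores, 4, repetitions=10, seed=9)
        b = sm.prediction_strength(scores, 4, repetitions=10, seed=9)
        assert a == b


class TestPAC:
    def test_zero_for_perfect_separation(self, planted_scores):
        scores, _ = planted_scores
        assert sm.pac(scores, 5, iterations=60, seed=0) == pytest.approx(0.0)

    def test_high_for_structureless_data(self):
        # isotropic Gaussian has no cluster structure: the k-means split
        # direction is sampling-noise-driven, so co-clustering is ambiguous
        rng = np.random.default_rng(15)
        scores = _frame(rng.normal(size=(60, 10)))
        val = sm.pac(scores, 3, iterations=100, seed=0)
        assert val > 0.5

    def test_lower_at_true_k_than_inflated_k(self, planted_scores):
        scores, _ = planted_scores
        at_true = sm.pac(scores, 5, iterations=60, seed=2)
        inflated = sm.pac(scores, 8, iterations=60, seed=2)
        assert at_true < inflated

    def test_seed_reproducibility(self, planted_scores):
        scores, _ = planted_scores
        a = sm.pac(scores, 3, iterations=30, seed=4)
        b = sm.pac(scores, 3, iterations=30, seed=4)
        assert a == b


class TestStabilityReportAndChooseK:
    @pytest.fixture(scope="class")
    def report(self, planted_scores):
        scores, _ = planted_scores
        return build_stability_report(
            scores, k_range=range(2, 8), min_cluster_size=15, seed=0,
            n_restarts=10, B=20, ps_repetitions=10, pac_iterations=40)

    def test_wcss_nonincreasing_in_k(self, report):
        assert (np.diff(report.table["wcss"]) <= 1e-9).all()

    def test_true_k_admissible(self, report):
        assert 5 in report.admissible_ks()

    def test_undersized_clusters_inadmissible(self):
        rng = np.random.default_rng(20)
        # planted 5-point cluster far away: any k >= 2 isolates it
        small = rng.normal(0, 0.1, size=(5, 2)) + 50
        big = rng.normal(0, 1.0, size=(40, 2))
        scores = _frame(np.vstack([big, small]))
        rep = build_stability_report(scores, k_range=[2], min_cluster_size=15,
                                     seed=0, n_restarts=5, B=10,
                                     ps_repetitions=5, pac_iterations=20)
        assert rep.table.loc[2, "min_cluster_size"] == 5
        assert not rep.table.loc[2, "admissible"]

    def test_choose_k_auto_maximizes_ps(self):
        tab = pd.DataFrame({
            "prediction_strength": [0.9, 0.7], "pac": [0.1, 0.0],
            "min_cluster_size": [20, 20], "admissible": [True, True],
        }, index=pd.Index([4, 5], name="k"))
        rep = StabilityReport(table=tab, min_cluster_size=15)
        assert choose_k(rep) == 4

    def test_choose_k_tiebreak_by_lower_pac(self):
        tab = pd.DataFrame({
            "prediction_strength": [0.8, 0.8], "pac": [0.2, 0.0],
            "min_cluster_size": [20, 20], "admissible": [True, True],
        }, index=pd.Index([3, 6], name="k"))
        rep = StabilityReport(table=tab, min_cluster_size=15)
        assert choose_k(rep) == 6

    def test_choose_k_fixed_requires_admissible(self, report):
        assert choose_k(report, mode="fixed", fixed_k=5) == 5
        inadmissible = [k for k in report.table.index
                        if not report.table.loc[k, "admissible"]]
        if inadmissible:
            with pytest.raises(StratifyError, match="not admissible"):
                choose_k(report, mode="fixed", fixed_k=inadmissible[0])
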
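"""Expression validation: z-scoring, Ward clustering, ARI, PCA, associations."""

import numpy as np
import pandas as pd
import pytest

from aopminer import (
    ExpressionMatrix,
    assemble_geneset,
    associate_pcs,
    cluster_label_agreement,
    hierarchical_cluster,
    pca_fit,
    read_expression,
    read_metadata,
    subset_by_geneset,
    write_metadata,
    zscore_rows,
)

from conftest import greedy_ward_merges, linkage_merge_partitions


def make_expr(values: np.ndarray, genes=None, samples=None) -> ExpressionMatrix:
    genes = genes or [f"G{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"s{j:02d}" for j in range(values.shape[1])]
    return ExpressionMatrix(values=pd.DataFrame(values, index=genes, columns=samples))


class TestSubset:
    def test_subset_reports_missing(self):
        expr = make_expr(np.zeros((100, 4)))
        wanted = [f"G{i:03d}" for i in range(20)] + [f"X{i}" for i in range(5)]
        gs, _ = assemble_geneset("KE", wanted, [], [])
        sub, missing = subset_by_geneset(expr, gs)
        assert len(sub.genes) == 20
        assert missing == sorted(f"X{i}" for i in range(5))

    def test_fully_absent_geneset_errors(self):
        expr = make_expr(np.zeros((10, 4)))
        gs, _ = assemble_geneset("KE", ["NOPE1", "NOPE2"], [], [])
        with pytest.raises(ValueError):
            subset_by_geneset(expr, gs)

    def test_subset_matches_set_intersection(self):
        rng = np.random.default_rng(41)
        expr = make_expr(rng.normal(size=(50, 6)))
        for _ in range(10):
            wanted = list(
                rng.choice([f"G{i:03d}" for i in range(80)], size=25, replace=False)
            )
            try:
                sub, missing = subset_by_geneset(expr, wanted)
            except ValueError:
                assert not set(wanted) & set(expr.genes)
                continue
            assert set(sub.genes) == set(wanted) & set(expr.genes)
            assert set(missing) == set(wanted) - set(expr.genes)


class TestZscore:
    def test_closed_form_row(self):
        expr = make_expr(np.array([[1.0, 2.0, 3.0]]))
        z = zscore_rows(expr)
        assert np.allclose(z.values.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_constant_row_dropped_with_warning(self, caplog):
        expr = make_expr(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))
        with caplog.at_level("WARNING"):
            z = zscore_rows(expr)
        assert len(z.genes) == 1
        assert "zero-variance" in caplog.text

    def test_all_constant_errors(self):
        with pytest.raises(ValueError):
            zscore_rows(make_expr(np.ones((3, 4))))

    def test_rows_standardized_and_idempotent(self):
        rng = np.random.default_rng(43)
        expr = make_expr(rng.normal(2.0, 3.0, size=(20, 8)))
        z = zscore_rows(expr)
        assert np.all(np.abs(z.values.mean(axis=1)) < 1e-10)
        assert np.allclose(z.values.std(axis=1, ddof=1), 1.0)
        zz = zscore_rows(z)
        assert np.allclose(zz.values.to_numpy(), z.values.to_numpy(), atol=1e-10)


class TestWardClustering:
    def test_identical_pair_groups_first(self):
        X = np.array([[0.0, 0.0, 10.0], [0.0, 0.0, 10.0]])  # s00==s01, s02 far
        result = hierarchical_cluster(make_expr(X), axis="samples")
        a = result.assignments(2)
        assert a[0] == a[1] != a[2]

    def test_merge_sequence_matches_greedy_ward_oracle(self):
        rng = np.random.default_rng(47)
        for n in (3, 4, 5):
            for _ in range(10):
                points = rng.normal(size=(n, 3))
                expr = make_expr(points.T)
                result = hierarchical_cluster(expr, axis="samples")
                got = linkage_merge_partitions(result.linkage, n)
                expected = greedy_ward_merges(points)
                assert got == expected

    def test_two_planted_pairs_merge_first(self):
        points = np.array(
            [[0.0, 0.0], [0.1, 0.0], [10.0, 10.0], [10.1, 10.0]]
        )
        result = hierarchical_cluster(make_expr(points.T), axis="samples")
        first_two = {frozenset(map(int, row[:2])) for row in result.linkage[:2]}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_permutation_invariance_of_tree_topology(self):
        rng = np.random.default_rng(53)
        points = rng.normal(size=(6, 4))
        expr = make_expr(points.T)
        result = hierarchical_cluster(expr, axis="samples")
        perm = rng.permutation(6)
        permuted = ExpressionMatrix(values=expr.values.iloc[:, perm])
        result_p = hierarchical_cluster(permuted, axis="samples")
        # compare partitions at every k, by sample name
        for k in range(2, 6):
            part_a = {}
            for item, lab in zip(result.items, result.assignments(k)):
                part_a.setdefault(lab, set()).add(item)
            part_b = {}
            for item, lab in zip(result_p.items, result_p.assignments(k)):
                part_b.setdefault(lab, set()).add(item)
            assert set(map(frozenset, part_a.values())) == set(
                map(frozenset, part_b.values())
            )

    def test_genes_axis_and_errors(self):
        expr = make_expr(np.random.default_rng(0).normal(size=(5, 3)))
        assert hierarchical_cluster(expr, axis="genes").items == expr.genes
        with pytest.raises(ValueError):
            hierarchical_cluster(make_expr(np.zeros((3, 1))), axis="samples")

    def test_newick_leaves_and_depth(self):
        rng = np.random.default_rng(59)
        expr = make_expr(rng.normal(size=(4, 5)))
        result = hierarchical_cluster(expr, axis="samples")
        newick = result.to_newick()
        assert newick.endswith(";")
        for s in expr.samples:
            assert s in newick


class TestAgreement:
    def test_perfect_agreement(self):
        X = np.vstack([np.zeros((2, 3)), np.full((2, 3), 5.0)]).T  # 3g x 4s? build directly
        points = np.array([[0, 0], [0.1, 0], [5, 5], [5.1, 5]], dtype=float)
        result = hierarchical_cluster(make_expr(points.T), axis="samples")
        labels = ["a", "a", "b", "b"]
        scores = cluster_label_agreement(result, labels, k=2)
        assert scores.ari == pytest.approx(1.0)
        assert scores.overall_purity == pytest.approx(1.0)

    def test_single_cluster_vs_balanced_labels_is_chance(self):
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score([0, 0, 1, 1], [1, 1, 1, 1]) == pytest.approx(0.0)
        # the same degenerate case through our API: k=2 on identical samples
        points = np.array([[0, 0], [0, 0], [0, 0], [1e-9, 0]])
        result = hierarchical_cluster(make_expr(points.T), axis="samples")
        scores = cluster_label_agreement(result, ["a", "b", "a", "b"], k=2)
        assert abs(scores.ari) < 0.7  # chance-level, not 1

    def test_random_labels_have_near_zero_mean_ari(self):
        rng = np.random.default_rng(61)
        points = rng.normal(size=(20, 3))
        result = hierarchical_cluster(make_expr(points.T), axis="samples")
        aris = []
        for _ in range(300):
            labels = rng.integers(0, 2, size=20)
            aris.append(cluster_label_agreement(result, list(labels), k=2).ari)
        assert abs(float(np.mean(aris))) < 0.05

    def test_label_mapping_accepted(self):
        points = np.array([[0, 0], [0.1, 0], [5, 5], [5.1, 5]], dtype=float)
        expr = make_expr(points.T, samples=["s1", "s2", "s3", "s4"])
        result = hierarchical_cluster(expr, axis="samples")
        scores = cluster_label_agreement(
            result, {"s1": "a", "s2": "a", "s3": "b", "s4": "b"}, k=2
        )
        assert scores.ari == pytest.approx(1.0)


class TestPCA:
    def test_collinear_data_put_all_variance_on_pc1(self):
        t = np.linspace(0, 1, 8)
        X = np.vstack([2 * t, -t, 0.5 * t])  # genes x samples, rank 1
        model = pca_fit(make_expr(X))
        assert model.variance_explained[0] == pytest.approx(1.0)

    def test_rotation_invariant_spectrum(self):
        rng = np.random.default_rng(67)
        X = rng.normal(size=(6, 10))  # genes x samples
        model = pca_fit(make_expr(X))
        # random orthogonal rotation of gene space
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        model_rot = pca_fit(make_expr(Q @ X))
        assert np.allclose(
            model.variance_explained, model_rot.variance_explained, atol=1e-10
        )

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(71)
        X = rng.normal(size=(7, 5))
        expr = make_expr(X)
        model = pca_fit(expr)
        recon = model.scores.to_numpy() @ model.loadings.to_numpy().T
        centered = (expr.values.T - expr.values.T.mean(axis=0)).to_numpy()
        assert np.allclose(recon, centered, atol=1e-8)

    def test_loadings_orthonormal_and_variance_sorted(self):
        rng = np.random.default_rng(73)
        model = pca_fit(make_expr(rng.normal(size=(10, 8))))
        L = model.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)
        assert np.all(np.diff(model.variance_explained) <= 1e-12)
        assert model.variance_explained.sum() <= 1 + 1e-12

    def test_planted_group_shift_separates_on_pc1(self):
        from aopminer import ExprSimConfig, simulate_expression

        expr, labels = simulate_expression(ExprSimConfig(seed=79))
        model = pca_fit(zscore_rows(expr), n_components=2)
        pc1 = model.scores["PC1"]
        treated, control = pc1[labels == "treated"], pc1[labels == "control"]
        separable = treated.max() < control.min() or control.max() < treated.min()
        assert separable, "treated and control overlap on PC1"


class TestAssociations:
    def make_pca_with_scores(self, scores: pd.DataFrame):
        from aopminer.validation import PCAModel

        return PCAModel(
            scores=scores,
            loadings=pd.DataFrame(np.zeros((1, scores.shape[1])), columns=scores.columns),
            variance_explained=np.linspace(0.5, 0.1, scores.shape[1]),
            mean=pd.Series(dtype=float),
        )

    def test_identical_scores_across_groups_give_p_near_one(self):
        samples = [f"s{i}" for i in range(8)]
        scores = pd.DataFrame({"PC1": [1.0, 2, 3, 4, 1, 2, 3, 4]}, index=samples)
        meta = pd.DataFrame({"group": ["a"] * 4 + ["b"] * 4}, index=samples)
        table = associate_pcs(
            self.make_pca_with_scores(scores), meta, {"group": "categorical"}
        )
        assert table.loc[0, "test"] == "anova"
        assert table.loc[0, "p_value"] > 0.95

    def test_monotone_covariate_gives_unit_spearman(self):
        samples = [f"s{i}" for i in range(10)]
        pc = np.linspace(-1, 1, 10)
        scores = pd.DataFrame({"PC1": pc}, index=samples)
        meta = pd.DataFrame({"depth": np.exp(pc)}, index=samples)
        table = associate_pcs(
            self.make_pca_with_scores(scores), meta, {"depth": "continuous"}
        )
        assert table.loc[0, "test"] == "spearman"
        assert abs(table.loc[0, "statistic"]) == pytest.approx(1.0)

    def test_single_level_categorical_skipped(self, caplog):
        samples = [f"s{i}" for i in range(4)]
        scores = pd.DataFrame({"PC1": [1.0, 2, 3, 4]}, index=samples)
        meta = pd.DataFrame({"batch": ["x"] * 4}, index=samples)
        with caplog.at_level("WARNING"):
            table = associate_pcs(
                self.make_pca_with_scores(scores), meta, {"batch": "categorical"}
            )
        assert table.empty

    def test_planted_confounder_detected_on_its_own_pc(self):
        from aopminer import ConfounderConfig, ExprSimConfig, simulate_expression

        expr, _labels = simulate_expression(
            ExprSimConfig(confounder=ConfounderConfig(), seed=83)
        )
        model = pca_fit(zscore_rows(expr), n_components=4)
        table = associate_pcs(model, expr.metadata, expr.covariate_types)
        conf = table[table.covariate == "confounder"].set_index("component")
        best_pc = conf.p_value.idxmin()
        # the confounder PC is the one whose loadings sit on the confounder genes
        cfg = ExprSimConfig(confounder=ConfounderConfig(), seed=83)
        mass = (
            (model.loadings.loc[[g for g in cfg.confounder_genes if g in model.loadings.index]] ** 2)
            .sum(axis=0)
        )
        assert best_pc == mass.idxmax()
        treat = table[table.covariate == "treatment"].set_index("component")
        assert treat.p_value.idxmin() != best_pc


class TestMetadataIO:
    def test_metadata_round_trip(self, tmp_path):
        meta = pd.DataFrame(
            {"treatment": ["a", "b"], "depth": [0.5, 1.5]}, index=["s1", "s2"]
        )
        types = {"treatment": "categorical", "depth": "continuous"}
        path = tmp_path / "meta.tsv"
        write_metadata(meta, types, path)
        back, back_types = read_metadata(path)
        assert back_types == types
        assert list(back.index) == ["s1", "s2"]
        assert back["depth"].tolist() == [0.5, 1.5]

    def test_expression_reader(self, tmp_path):
        values = pd.DataFrame(
            np.arange(6, dtype=float).reshape(2, 3),
            index=["G1", "G2"],
            columns=["s1", "s2", "s3"],
        )
        path = tmp_path / "expr.tsv"
        values.to_csv(path, sep="\t", index_label="gene")
        expr = read_expression(path)
        assert expr.genes == ["G1", "G2"] and expr.samples == ["s1", "s2", "s3"]
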
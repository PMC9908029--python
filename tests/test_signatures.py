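"""Log-normalization, module scoring, cycling classification, and marker
derivation."""

import numpy as np
import pandas as pd
import pytest

import myostate as ms
from conftest import make_counts


class TestLogNormalize:
    def test_hand_evaluated_entry(self):
        frame = pd.DataFrame({"c1": [10, 90]}, index=["geneA", "geneB"])
        expr = ms.log_normalize(make_counts(frame), scale=10_000)
        # 10/100 * 10000 = 1000
        assert expr.to_frame().loc["geneA", "c1"] == pytest.approx(np.log1p(1000))

    def test_zero_count_stays_zero(self):
        frame = pd.DataFrame({"c1": [0, 5]}, index=["geneA", "geneB"])
        expr = ms.log_normalize(make_counts(frame))
        assert expr.to_frame().loc["geneA", "c1"] == 0.0

    def test_doubling_a_cell_is_invariant(self, counts_and_truth):
        counts, _ = counts_and_truth
        doubled = counts.matrix.toarray()
        doubled[:, 3] *= 2
        other = ms.CountMatrix(doubled, counts.features, counts.barcodes)
        a = ms.log_normalize(counts).matrix[:, 3].toarray()
        b = ms.log_normalize(other).matrix[:, 3].toarray()
        assert np.allclose(a, b)

    def test_zero_total_cell_warns(self):
        frame = pd.DataFrame({"c1": [0, 0], "c2": [1, 2]},
                             index=["geneA", "geneB"])
        with pytest.warns(UserWarning, match="zero total"):
            expr = ms.log_normalize(make_counts(frame))
        assert expr.matrix[:, 0].nnz == 0

    def test_invalid_scale_rejected(self, counts_and_truth):
        with pytest.raises(ValueError, match="scale"):
            ms.log_normalize(counts_and_truth[0], scale=0)


class TestModuleScore:
    def test_single_gene_whole_bin_control_reduces_to_bin_mean(self):
        """With one bin and controls covering it, the score per cell is the
        gene's expression minus the bin's mean expression."""
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            rng.poisson(5.0, (12, 8)),
            index=[f"g{i}" for i in range(12)],
            columns=[f"c{i}" for i in range(8)],
        )
        expr = ms.log_normalize(make_counts(frame))
        score = ms.module_score(expr, ["g3"], n_bins=1, n_ctrl=100, seed=0)
        dense = expr.to_frame()
        expected = dense.loc["g3"] - dense.mean(axis=0)
        assert np.allclose(score.to_numpy(), expected.to_numpy())

    def test_null_signature_scores_near_zero(self, base_config, logexpr):
        """A random draw of non-marker genes scores ~0 on average."""
        rng = np.random.default_rng(1)
        planted = {g for gs in ms.marker_genes(base_config).values() for g in gs}
        eligible = [g for g in logexpr.genes if g not in planted
                    and not g.startswith("MT-")]
        sig = list(rng.choice(eligible, 30, replace=False))
        score = ms.module_score(logexpr, sig, seed=2)
        assert abs(score.mean()) < 0.05

    def test_planted_markers_separate_their_state(
        self, base_config, counts_and_truth, logexpr
    ):
        _, truth = counts_and_truth
        markers = ms.marker_genes(base_config)
        for state, genes in markers.items():
            score = ms.module_score(logexpr, genes, seed=3)
            in_mean = score[truth == state].mean()
            for other in markers:
                if other != state:
                    assert in_mean > score[truth == other].mean()

    def test_agrees_with_scanpy_scoring(self, base_config, counts_and_truth, logexpr):
        """Independent cross-check: scanpy's bin-control gene scoring ranks
        cells the same way (different control draws, same construction)."""
        sc = pytest.importorskip("scanpy")
        import anndata as ad

        counts, truth = counts_and_truth
        genes = ms.marker_genes(base_config)["musc_like"]
        mine = ms.module_score(logexpr, genes, seed=4)

        adata = ad.AnnData(X=counts.matrix.T.astype(np.float32))
        adata.var_names = list(counts.features)
        adata.obs_names = list(counts.barcodes)
        sc.pp.normalize_total(adata, target_sum=1e4)
        sc.pp.log1p(adata)
        sc.tl.score_genes(adata, genes, ctrl_size=100, n_bins=25,
                          score_name="ref", random_state=4)
        ref = adata.obs["ref"].to_numpy()
        assert np.corrcoef(mine.to_numpy(), ref)[0, 1] > 0.9

    def test_absent_genes_dropped_with_warning(self, logexpr):
        with pytest.warns(UserWarning, match="absent"):
            ms.module_score(logexpr, ["GENE00001", "NOPE"], seed=0)
        with pytest.raises(ValueError, match="no signature gene"):
            ms.module_score(logexpr, ["NOPE"], seed=0)

    def test_seeded_determinism(self, logexpr):
        a = ms.module_score(logexpr, ["GENE00001", "GENE00050"], seed=9)
        b = ms.module_score(logexpr, ["GENE00001", "GENE00050"], seed=9)
        pd.testing.assert_series_equal(a, b)


class TestClassifyCycling:
    @pytest.mark.parametrize(
        "s,g2m,label",
        [
            (0.2, -0.1, ms.HIGH_CYCLING),
            (-0.1, 0.2, ms.HIGH_CYCLING),
            (-0.1, -0.2, ms.LOW_CYCLING),
            (0.0, 0.0, ms.LOW_CYCLING),  # exact zeros are low-cycling
        ],
    )
    def test_rule(self, s, g2m, label):
        assert ms.classify_cycling(s, g2m) == label

    def test_partitions_all_cells(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.normal(size=100))
        g = pd.Series(rng.normal(size=100))
        labels = ms.classify_cycling(s, g)
        assert set(labels.unique()) <= {ms.HIGH_CYCLING, ms.LOW_CYCLING}
        assert labels.notna().all()

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ms.classify_cycling(np.nan, 0.1)


@pytest.fixture(scope="module")
def labelled_expression(counts_and_truth, logexpr):
    _, truth = counts_and_truth
    return logexpr, truth


class TestFindMarkers:
    @pytest.mark.parametrize("mode", ["one_vs_rest", "pairwise"])
    def test_planted_markers_recovered(self, base_config, labelled_expression, mode):
        expr, truth = labelled_expression
        table = ms.find_markers(expr, truth, mode=mode)
        planted = ms.marker_genes(base_config)
        for state, genes in planted.items():
            found = set(table.loc[table["cluster"] == state, "gene"])
            recovered = len(found & set(genes)) / len(genes)
            assert recovered > 0.9
        assert (table["log_fold_change"] > 0.25).all()
        assert (table["direction"] == 1).all()

    def test_low_fraction_gene_excluded(self):
        """A gene expressed in 4% of the cluster is excluded regardless of
        fold change."""
        rng = np.random.default_rng(0)
        n = 100
        frame = pd.DataFrame(
            rng.poisson(2.0, (20, 2 * n)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"c{i}" for i in range(2 * n)],
        )
        frame.iloc[0, :] = 0
        frame.iloc[0, :4] = 500  # 4% of cluster A, huge fold change
        labels = pd.Series(["A"] * n + ["B"] * n, index=frame.columns)
        expr = ms.log_normalize(make_counts(frame))
        table = ms.find_markers(expr, labels)
        assert "g0" not in set(table.loc[table["cluster"] == "A", "gene"])

    def test_null_clusters_yield_almost_no_markers(self):
        """Identically distributed clusters produce <=1 false marker in at
        least 95% of replicates after Bonferroni."""
        ok = 0
        reps = 30
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            frame = pd.DataFrame(
                rng.poisson(2.0, (500, 120)),
                index=[f"g{i}" for i in range(500)],
                columns=[f"c{i}" for i in range(120)],
            )
            labels = pd.Series(["A"] * 60 + ["B"] * 60, index=frame.columns)
            expr = ms.log_normalize(make_counts(frame))
            table = ms.find_markers(expr, labels)
            ok += len(table) <= 1
        assert ok >= int(0.9 * reps)

    def test_invariant_under_cell_permutation(self, labelled_expression):
        expr, truth = labelled_expression
        rng = np.random.default_rng(5)
        perm = rng.permutation(expr.n_cells)
        shuffled = ms.LogExpression(
            matrix=expr.matrix[:, perm],
            genes=expr.genes,
            barcodes=expr.barcodes[perm],
            scale_factor=expr.scale_factor,
        )
        a = ms.find_markers(expr, truth)
        b = ms.find_markers(shuffled, truth.iloc[perm])
        pd.testing.assert_frame_equal(a, b)

    def test_lower_alpha_gives_subset(self, labelled_expression):
        expr, truth = labelled_expression
        loose = ms.find_markers(expr, truth, alpha=0.05)
        strict = ms.find_markers(expr, truth, alpha=0.001)
        loose_keys = set(zip(loose["cluster"], loose["gene"]))
        strict_keys = set(zip(strict["cluster"], strict["gene"]))
        assert strict_keys <= loose_keys

    def test_degenerate_inputs_rejected(self, labelled_expression):
        expr, truth = labelled_expression
        with pytest.raises(ValueError, match="2 clusters"):
            ms.find_markers(expr, pd.Series("A", index=expr.barcodes))
        tiny = truth.copy()
        tiny.iloc[:] = "A"
        tiny.iloc[:2] = "B"
        with pytest.raises(ValueError, match="fewer than 3"):
            ms.find_markers(expr, tiny)
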
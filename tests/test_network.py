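import numpy as np
import pandas as pd
import pytest

from comodule import network
from comodule.network import (
    CoexpressionModuleDetector,
    adjacency,
    assign_by_kme,
    cut_modules,
    filter_genes,
    linkage_from_tom,
    merge_close_modules,
    module_eigengenes,
    pick_soft_threshold,
    scale_free_fit,
    split_modules,
    tom_similarity,
)


def brute_force_tom(adj):
    """Independent triple-loop topological overlap oracle."""
    n = adj.shape[0]
    k = adj.sum(axis=0) - np.diag(adj)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(adj[i, u] * adj[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + adj[i, j]) / (min(k[i], k[j]) + 1 - adj[i, j])
    return tom


def random_adjacency(rng, n):
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


def block_expression(rng, block_sizes, n_samples=20, noise=0.3):
    """Expression with independent latent factors, one per block."""
    rows, ids = [], []
    for b, size in enumerate(block_sizes):
        factor = rng.normal(size=n_samples)
        for g in range(size):
            rows.append(factor + rng.normal(0, noise, n_samples))
            ids.append(f"b{b}_g{g}")
    return pd.DataFrame(rows, index=ids, columns=[f"s{i}" for i in range(n_samples)])


class TestFilterGenes:
    def test_mean_filter_is_strict_and_order_preserving(self):
        expr = pd.DataFrame(
            {
                "s1": [0.5, 1.0, 5.0, 2.0],
                "s2": [0.5, 1.0, 0.1, 3.0],
            },
            index=["low", "boundary", "mixed", "high"],
        )
        kept = filter_genes(expr, 1.0)
        # means: 0.5 (out), 1.0 (out, strict >), 2.55 (in), 2.5 (in)
        assert list(kept.index) == ["mixed", "high"]

    def test_empty_result_is_an_error(self):
        expr = pd.DataFrame({"s1": [0.1], "s2": [0.2]}, index=["g"])
        with pytest.raises(ValueError, match="threshold"):
            filter_genes(expr, 10.0)


class TestAdjacency:
    def test_powers_of_correlation(self):
        samples = [f"s{i}" for i in range(8)]
        base = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        expr = pd.DataFrame(
            [base, -base, base + np.array([0, 1, -1, 0, 1, -1, 0, 0])],
            index=["a", "anti", "noisy"],
            columns=samples,
        )
        adj = adjacency(expr, beta=6)
        assert adj[0, 1] == pytest.approx(1.0)      # anti-correlated, unsigned
        assert np.allclose(np.diag(adj), 1.0)
        r = np.corrcoef(expr.to_numpy())[0, 2]
        assert adj[0, 2] == pytest.approx(abs(r) ** 6)

    def test_exact_half_correlation_value(self):
        # |r| = 0.5 at beta 6 gives 0.5^6 = 0.015625
        assert 0.5**6 == 0.015625

    def test_zero_variance_gene_is_named(self):
        expr = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"],
            columns=["s1", "s2", "s3"],
        )
        with pytest.raises(ValueError, match="flat"):
            adjacency(expr, 2)

    def test_monotone_in_power(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(
            rng.normal(size=(12, 10)),
            index=[f"g{i}" for i in range(12)],
            columns=[f"s{i}" for i in range(10)],
        )
        previous = adjacency(expr, 1)
        for beta in range(2, 8):
            current = adjacency(expr, beta)
            off = ~np.eye(12, dtype=bool)
            assert (current[off] <= previous[off] + 1e-15).all()
            previous = current


class TestTOM:
    def test_empty_network(self):
        adj = np.eye(5)
        tom = tom_similarity(adj)
        assert np.allclose(tom, np.eye(5))

    def test_complete_graph_is_fully_overlapping(self):
        adj = np.ones((6, 6))
        tom = tom_similarity(adj)
        assert np.allclose(tom, 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            adj = random_adjacency(rng, 15)
            assert np.max(np.abs(tom_similarity(adj) - brute_force_tom(adj))) < 1e-12

    def test_rejects_asymmetry(self):
        adj = np.eye(3)
        adj[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(adj)


class TestScaleFreeFit:
    def test_power_law_degrees_fit_well(self):
        """Degree sequence of a preferential-attachment graph approximates a
        power law, so the fit index should clear the 0.8 target."""
        import networkx as nx

        graph = nx.barabasi_albert_graph(2000, 2, seed=1)
        degrees = np.array([d for _, d in graph.degree()], dtype=float)
        fit, slope = scale_free_fit(degrees)
        assert slope < 0
        assert fit >= 0.8

    def test_uniform_degrees_fit_poorly(self):
        rng = np.random.default_rng(3)
        degrees = rng.uniform(10, 12, size=500)
        fit, _ = scale_free_fit(degrees)
        assert fit < 0.5

    def test_grid_of_one_returns_that_power(self, caplog):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(
            rng.normal(size=(40, 10)),
            index=[f"g{i}" for i in range(40)],
            columns=[f"s{i}" for i in range(10)],
        )
        result = pick_soft_threshold(expr, power_grid=[7], r2_target=0.99)
        assert result.beta == 7

    def test_pure_noise_falls_back_to_argmax(self, caplog):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(
            rng.normal(size=(60, 12)),
            index=[f"g{i}" for i in range(60)],
            columns=[f"s{i}" for i in range(12)],
        )
        result = pick_soft_threshold(expr, power_grid=range(1, 4), r2_target=0.999)
        assert not result.reached_target
        assert result.beta == int(result.table.loc[result.table["fit"].idxmax(), "power"])


class TestCutModules:
    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(10)
        expr = block_expression(rng, [40, 40], noise=0.2)
        tom = tom_similarity(adjacency(expr, 6))
        labels = cut_modules(linkage_from_tom(tom), expr.index, min_module_size=30)
        named = [m for m in labels.unique() if m != "unassigned"]
        assert len(named) == 2
        for block in ("b0", "b1"):
            genes = labels.index[labels.index.str.startswith(block)]
            assert labels[genes].nunique() == 1
            assert labels[genes].iloc[0] != "unassigned"

    def test_block_below_min_size_stays_unassigned(self):
        """A 29-gene block cannot form a module at min size 30: the detector
        (cut + refinement) leaves its genes unassigned."""
        rng = np.random.default_rng(11)
        expr = block_expression(rng, [29], noise=0.2)
        noise = pd.DataFrame(
            rng.normal(size=(100, expr.shape[1])),
            index=[f"n{i}" for i in range(100)],
            columns=expr.columns,
        )
        full = pd.concat([expr, noise])
        det = CoexpressionModuleDetector(min_module_size=30, soft_power=6)
        labels = pd.Series(det.fit_predict(full.T), index=full.index)
        block_labels = labels[labels.index.str.startswith("b0")]
        assert (block_labels == "unassigned").all()

    def test_min_size_two_finds_perfect_pair(self):
        rng = np.random.default_rng(12)
        noise = pd.DataFrame(
            rng.normal(size=(30, 16)),
            index=[f"n{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(16)],
        )
        profile = rng.normal(size=16)
        pair = pd.DataFrame(
            [profile, profile + rng.normal(0, 1e-3, 16)],
            index=["p0", "p1"],
            columns=noise.columns,
        )
        full = pd.concat([pair, noise])
        tom = tom_similarity(adjacency(full, 6))
        labels = cut_modules(linkage_from_tom(tom), full.index, min_module_size=2)
        assert labels["p0"] == labels["p1"] != "unassigned"


class TestMergeAndSplit:
    def test_same_factor_modules_merge(self):
        rng = np.random.default_rng(20)
        expr = block_expression(rng, [20], noise=0.3)
        labels = pd.Series(
            ["a"] * 10 + ["b"] * 10, index=expr.index, name="module"
        )
        merged = merge_close_modules(labels, expr, merge_dissimilarity=0.05)
        assert merged.nunique() == 1

    def test_independent_modules_do_not_merge(self):
        rng = np.random.default_rng(21)
        expr = block_expression(rng, [15, 15], noise=0.3)
        labels = pd.Series(
            ["a"] * 15 + ["b"] * 15, index=expr.index, name="module"
        )
        merged = merge_close_modules(labels, expr, merge_dissimilarity=0.05)
        assert set(merged.unique()) == {"a", "b"}

    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(22)
        expr = block_expression(rng, [10, 10], noise=0.3)
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=expr.index)
        pd.testing.assert_series_equal(
            merge_close_modules(labels, expr, 0.0), labels
        )

    def test_two_factor_module_splits_single_factor_does_not(self):
        rng = np.random.default_rng(23)
        two = block_expression(rng, [35, 35], noise=0.3)
        fused = pd.Series(["m"] * 70, index=two.index)
        split = split_modules(fused, two, min_module_size=30)
        assert split.nunique() == 2
        sides = {split[g] for g in two.index[:35]}
        assert len(sides) == 1  # block boundary respected

        one = block_expression(rng, [70], noise=0.3)
        single = pd.Series(["m"] * 70, index=one.index)
        assert split_modules(single, one, min_module_size=30).nunique() == 1

    def test_kme_rescues_stragglers_and_drops_noise(self):
        rng = np.random.default_rng(24)
        expr = block_expression(rng, [40], noise=0.3)
        noise = pd.DataFrame(
            rng.normal(size=(30, expr.shape[1])),
            index=[f"n{i}" for i in range(30)],
            columns=expr.columns,
        )
        full = pd.concat([expr, noise])
        labels = pd.Series("unassigned", index=full.index, name="module")
        labels.iloc[:30] = "core"  # 10 module genes start unassigned
        out = assign_by_kme(labels, full, kme_threshold=0.7, min_module_size=5)
        assert (out[expr.index] == "core").all()
        assert (out[noise.index] == "unassigned").mean() > 0.9


class TestEigengenes:
    def test_identical_genes_reproduce_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        expr = pd.DataFrame(
            [profile, profile * 2 + 1, profile * 0.5],
            index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(6)],
        )
        labels = pd.Series(["m"] * 3, index=expr.index)
        result = module_eigengenes(expr, labels)
        eig = result.eigengenes.loc["m"].to_numpy()
        standardized = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.allclose(eig, standardized, atol=1e-10)
        assert result.variance_explained["m"] == pytest.approx(1.0)

    def test_matches_svd_oracle_on_random_modules(self):
        rng = np.random.default_rng(30)
        for _ in range(20):
            n_genes = rng.integers(2, 12)
            expr = pd.DataFrame(
                rng.normal(size=(n_genes, 10)),
                index=[f"g{i}" for i in range(n_genes)],
                columns=[f"s{i}" for i in range(10)],
            )
            labels = pd.Series(["m"] * n_genes, index=expr.index)
            eig = module_eigengenes(expr, labels).eigengenes.loc["m"].to_numpy()
            std = (
                expr.to_numpy() - expr.to_numpy().mean(1, keepdims=True)
            ) / expr.to_numpy().std(1, ddof=1, keepdims=True)
            _, _, vt = np.linalg.svd(std, full_matrices=False)
            assert abs(np.corrcoef(eig, vt[0])[0, 1]) == pytest.approx(1.0, abs=1e-8)

    def test_sign_rule_on_negated_profiles(self):
        rng = np.random.default_rng(31)
        profile = rng.normal(size=12)
        expr = pd.DataFrame(
            [-profile + rng.normal(0, 0.05, 12) for _ in range(5)],
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(12)],
        )
        labels = pd.Series(["m"] * 5, index=expr.index)
        eig = module_eigengenes(expr, labels).eigengenes.loc["m"]
        module_mean = expr.mean(axis=0)
        assert np.corrcoef(eig, module_mean)[0, 1] > 0

    def test_eigengene_beats_any_single_gene(self, default_bulk, recovered_modules):
        """The eigengene explains at least as much module variance as any
        single standardized member gene (first-PC optimality)."""
        labels, _ = recovered_modules
        expr = np.log2(default_bulk.expression + 1).loc[labels.index]
        result = module_eigengenes(expr, labels)
        for module in result.eigengenes.index[:4]:
            genes = labels.index[labels == module]
            values = expr.loc[genes].to_numpy()
            std = (values - values.mean(1, keepdims=True)) / values.std(
                1, ddof=1, keepdims=True
            )
            total = np.sum(std**2)
            best_gene_ve = max(
                np.sum((std @ (row / np.linalg.norm(row))) ** 2) / total
                for row in std
            )
            eig = result.eigengenes.loc[module].to_numpy()
            eig_ve = np.sum((std @ (eig / np.linalg.norm(eig))) ** 2) / total
            assert eig_ve >= best_gene_ve - 1e-10

    def test_too_small_module_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="fewer than 2"):
            module_eigengenes(expr, pd.Series(["m"], index=["g"]))


class TestDetectorEstimator:
    def test_sklearn_interface_and_block_recovery(self):
        rng = np.random.default_rng(40)
        expr = block_expression(rng, [40, 40], noise=0.3)
        noise = pd.DataFrame(
            rng.normal(size=(60, expr.shape[1])),
            index=[f"n{i}" for i in range(60)],
            columns=expr.columns,
        )
        full = pd.concat([expr, noise])
        det = CoexpressionModuleDetector(min_module_size=30)
        labels = det.fit_predict(full.T)
        assert len(labels) == full.shape[0]
        named = set(labels) - {"unassigned"}
        assert len(named) == 2
        for block in ("b0", "b1"):
            block_labels = {
                l for g, l in zip(full.index, labels) if g.startswith(block)
            }
            assert len(block_labels) == 1

    def test_get_set_params_round_trip(self):
        det = CoexpressionModuleDetector(min_module_size=12)
        params = det.get_params()
        assert params["min_module_size"] == 12
        det.set_params(kme_threshold=0.5)
        assert det.kme_threshold == 0.5
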
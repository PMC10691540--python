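"""Chi-square + Dirichlet-multinomial tests, WARM/MPRO, final-signal rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apamix.differential import test_gene as gene_stats
from apamix.differential import (
    SignalThresholds, TaxonomyTree, adjust_bh, chisq_test, combine_pvalues,
    compute_cell_warm, compute_mpro, compute_warm, dm_loglik, dm_lrt, fit_dm,
    hierarchical_tests, is_significant, relative_positions, run_comparison,

)
from apamix.quantify import PeakCellMatrix, QCSummary
from apamix.simulate import simulate_gene_counts
from scipy import sparse


class TestChisq:
    def test_homogeneous_groups_give_p_near_one(self):
        counts = np.tile([30, 70], (400, 1))
        labels = np.repeat(["a", "b"], 200)
        p, flag = chisq_test(counts, labels)
        assert not flag
        assert p > 0.99

    def test_pearson_statistic_matches_hand_computation(self):
        # pooled 2x2 table [[30,70],[70,30]]: expected 50 everywhere,
        # X^2 = 4 * 20^2/50 = 32
        counts = np.array([[30, 70], [70, 30]])
        labels = np.array(["a", "b"])
        p, _ = chisq_test(counts, labels)
        assert p == pytest.approx(float(stats.chi2.sf(32.0, 1)), rel=1e-12)

    def test_one_group_all_zero_is_degenerate(self):
        counts = np.array([[5, 5], [0, 0]])
        labels = np.array(["a", "b"])
        p, flag = chisq_test(counts, labels)
        assert (p, flag) == (1.0, True)


class TestDirichletMultinomial:
    def test_mle_recovers_planted_alpha(self):
        rng = np.random.default_rng(10)
        counts, _ = simulate_gene_counts({"g": (2.0, 5.0)}, 2000, 20.0, 1e6,
                                         rng)
        fit = fit_dm(counts)
        np.testing.assert_allclose(fit.alpha, [2.0, 5.0], rtol=0.15)
        assert fit.converged and not fit.boundary

    def test_loglik_at_mle_beats_neighbouring_alpha(self):
        rng = np.random.default_rng(11)
        counts, _ = simulate_gene_counts({"g": (3.0, 3.0)}, 500, 15.0, 1e6,
                                         rng)
        fit = fit_dm(counts)
        for scale in (0.7, 1.3):
            assert dm_loglik(counts, fit.alpha * scale) <= fit.loglik + 1e-6

    def test_single_peak_gene_is_trivial(self):
        fit = fit_dm(np.array([[3.0], [5.0]]))
        assert fit.loglik == 0.0

    def test_identical_proportions_drive_alpha_to_cap(self):
        counts = np.tile([10, 10], (200, 1)).astype(float)
        fit = fit_dm(counts)
        assert fit.boundary or fit.alpha.sum() > 1e4

    def test_all_mass_on_one_peak_is_flagged_boundary(self):
        counts = np.column_stack([np.full(100, 10.0), np.zeros(100)])
        fit = fit_dm(counts)
        assert fit.boundary


class TestDmLrt:
    def test_identical_groups_give_p_near_one(self):
        rng = np.random.default_rng(12)
        counts, _ = simulate_gene_counts({"g": (4.0, 4.0)}, 200, 10.0, 10.0,
                                         rng)
        both = np.vstack([counts, counts])
        labels = np.repeat(["a", "b"], len(counts))
        p, _ = dm_lrt(both, labels)
        assert p > 0.99

    def test_power_against_reversed_alpha(self):
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(10):
            counts, labels = simulate_gene_counts(
                {"a": (2.0, 5.0), "b": (5.0, 2.0)}, 300, 15.0, 10.0, rng)
            p, _ = dm_lrt(counts, labels)
            hits += p < 0.001
        assert hits >= 10 * 0.95


class TestCombineAdjust:
    def test_max_rule(self):
        assert combine_pvalues(0.01, 0.20) == 0.20

    def test_bh_hand_example(self):
        adj = adjust_bh([0.001, 0.01, 0.02, 0.8])
        np.testing.assert_allclose(adj, [0.004, 0.02, 0.02 * 4 / 3, 0.8])

    def test_all_ones_stay_ones(self):
        assert adjust_bh([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_bh_matches_step_up_oracle(self):
        def bh_oracle(p):
            p = np.asarray(p)
            n = len(p)
            order = np.argsort(p, kind="stable")
            adj = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                idx = order[rank - 1]
                running = min(running, p[idx] * n / rank)
                adj[idx] = running
            return adj

        rng = np.random.default_rng(14)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(adjust_bh(p), bh_oracle(p), atol=1e-12)


class TestWarm:
    def test_two_peaks_equal_distal_proportion(self):
        assert compute_warm([0, 400], [30, 70]) == pytest.approx(0.7)

    def test_three_same_utr_peaks_linear_interpolation(self):
        warm = compute_warm([0, 50, 200], [10, 10, 20])
        assert warm == pytest.approx(0.5625)

    def test_all_proximal_is_zero(self):
        assert compute_warm([0, 100, 300], [50, 0, 0]) == 0.0

    def test_rank_spacing_for_distinct_utrs(self):
        rel = relative_positions([0, 10, 1000], same_utr=False)
        np.testing.assert_allclose(rel, [0.0, 0.5, 1.0])

    def test_zero_counts_is_missing(self):
        assert np.isnan(compute_warm([0, 100], [0, 0]))

    def test_bounds_property(self):
        rng = np.random.default_rng(15)
        for _ in range(200):
            n = rng.integers(2, 6)
            pos = np.sort(rng.choice(10000, n, replace=False))
            counts = rng.integers(0, 50, n)
            if counts.sum() == 0:
                continue
            w = compute_warm(pos, counts, same_utr=bool(rng.integers(2)))
            assert 0.0 <= w <= 1.0


class TestCellWarm:
    def _pcm_counts(self):
        # two genes, two peaks each; one cell
        counts = np.array([[8], [2], [1], [3]], dtype=float)  # gene1 warm 0.2; gene2 0.75
        gene_index = np.array(["g1", "g1", "g2", "g2"])
        positions = {"g1": np.array([0.0, 100.0]), "g2": np.array([0.0, 100.0])}
        return counts, gene_index, positions

    def test_single_gene_cell_warm_is_gene_warm(self):
        counts = np.array([[6], [4]], dtype=float)
        warm = compute_cell_warm(counts, np.array(["g1", "g1"]),
                                 {"g1": np.array([0.0, 1.0])})
        assert warm[0] == pytest.approx(0.4)

    def test_expression_weighting(self):
        counts, gi, pos = self._pcm_counts()
        warm = compute_cell_warm(counts, gi, pos, weighting="expression")
        assert warm[0] == pytest.approx((0.2 * 10 + 0.75 * 4) / 14)

    def test_equal_weighting(self):
        counts, gi, pos = self._pcm_counts()
        warm = compute_cell_warm(counts, gi, pos, weighting="equal")
        assert warm[0] == pytest.approx((0.2 + 0.75) / 2)

    def test_cell_without_counts_is_missing(self):
        warm = compute_cell_warm(np.zeros((2, 1)), np.array(["g1", "g1"]),
                                 {"g1": np.array([0.0, 1.0])})
        assert np.isnan(warm[0])


class TestMpro:
    def test_two_peak_shift(self):
        mpro, pair = compute_mpro([20, 80], [70, 30])
        assert mpro == pytest.approx(1.0)
        assert pair == (0, 1)

    def test_identical_proportions_give_zero(self):
        mpro, _ = compute_mpro([50, 50], [5, 5])
        assert mpro == pytest.approx(0.0)

    def test_three_peak_enumeration(self):
        mpro, pair = compute_mpro([50, 30, 20], [20, 30, 50])
        assert mpro == pytest.approx(-0.6)
        assert pair == (0, 2)

    def test_swapping_groups_flips_sign(self):
        rng = np.random.default_rng(16)
        for _ in range(100):
            n = rng.integers(2, 5)
            b = rng.integers(1, 50, n)
            a = rng.integers(1, 50, n)
            m1, _ = compute_mpro(b, a)
            m2, _ = compute_mpro(a, b)
            assert m1 == pytest.approx(-m2, abs=1e-12)

    def test_two_peak_mpro_is_twice_distal_delta(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            b = rng.integers(1, 50, 2)
            a = rng.integers(1, 50, 2)
            mpro, _ = compute_mpro(b, a)
            delta_distal = b[1] / b.sum() - a[1] / a.sum()
            assert mpro == pytest.approx(2 * delta_distal, abs=1e-12)

    def test_zero_total_condition_is_undefined(self):
        mpro, _ = compute_mpro([0, 0], [5, 5])
        assert np.isnan(mpro)


class TestFinalSignals:
    EXPR_OK = {"a": np.array([0.3, 0.4]), "b": np.array([0.2, 0.5])}

    def test_all_rules_met(self):
        assert is_significant(0.01, self.EXPR_OK, 0.5)

    def test_mpro_threshold_is_strict(self):
        assert not is_significant(0.01, self.EXPR_OK, 0.2)
        assert is_significant(0.01, self.EXPR_OK, 0.2000001)

    def test_low_expression_group_blocks_signal(self):
        expr = {"a": np.array([0.3, 0.4]), "b": np.array([0.03, 0.01])}
        assert not is_significant(0.04, expr, 0.5)

    def test_adjusted_p_threshold_inclusive(self):
        assert is_significant(0.05, self.EXPR_OK, 0.5)
        assert not is_significant(0.0501, self.EXPR_OK, 0.5)


def _toy_pcm(counts_by_gene, barcodes):
    """counts_by_gene: {gene: peaks x cells array} with 2 peaks per gene."""
    rows = []
    blocks = []
    for gene, arr in counts_by_gene.items():
        for j in range(arr.shape[0]):
            rows.append({"peak_id": f"{gene}:P{j+1}", "gene_id": gene,
                         "chrom": "chrT", "strand": "+",
                         "start": j * 1000, "end": j * 1000 + 100,
                         "mu": j * 1000.0 + 50, "sigma": 30.0})
        blocks.append(np.asarray(arr))
    mat = sparse.csr_matrix(np.vstack(blocks))
    return PeakCellMatrix(mat, pd.DataFrame(rows), list(barcodes), QCSummary())


class TestRunComparison:
    def test_planted_shift_detected_and_null_gene_not(self):
        rng = np.random.default_rng(18)
        n = 120
        barcodes = [f"c{i}" for i in range(2 * n)]
        labels = pd.Series(["a"] * n + ["b"] * n, index=barcodes)
        shift_a, _ = simulate_gene_counts({"a": (8, 2)}, n, 15.0, 10.0, rng)
        shift_b, _ = simulate_gene_counts({"b": (2, 8)}, n, 15.0, 10.0, rng)
        null_ab, _ = simulate_gene_counts({"ab": (5, 5)}, 2 * n, 15.0, 10.0,
                                          rng)
        pcm = _toy_pcm({
            "gShift": np.vstack([shift_a, shift_b]).T,
            "gNull": null_ab.T,
        }, barcodes)
        res = run_comparison(pcm, labels, base="a", alt="b").set_index("gene_id")
        assert bool(res.loc["gShift", "significant"])
        assert not bool(res.loc["gNull", "significant"])
        assert res.loc["gShift", "mpro"] < -0.2   # group a favours proximal

    def test_single_peak_genes_are_not_tested(self):
        barcodes = ["c0", "c1"]
        labels = pd.Series(["a", "b"], index=barcodes)
        pcm = _toy_pcm({"g1": np.array([[3, 4]])}, barcodes)
        assert run_comparison(pcm, labels).empty


class TestHierarchical:
    def _pcm_and_labels(self, rng, leaf_alphas, cells_per_leaf=80):
        barcodes, labels = [], []
        blocks = []
        for leaf, alpha in leaf_alphas.items():
            counts, _ = simulate_gene_counts({leaf: alpha}, cells_per_leaf,
                                             15.0, 10.0, rng)
            blocks.append(counts)
            names = [f"{leaf}-{i}" for i in range(cells_per_leaf)]
            barcodes += names
            labels += [leaf] * cells_per_leaf
        pcm = _toy_pcm({"g1": np.vstack(blocks).T}, barcodes)
        return pcm, pd.Series(labels, index=barcodes)

    def test_two_level_tree_gives_single_pair_of_comparisons(self):
        rng = np.random.default_rng(19)
        tree = TaxonomyTree.from_edges([("root", "A"), ("root", "B")])
        pcm, labels = self._pcm_and_labels(rng, {"A": (5, 5), "B": (5, 5)})
        res = hierarchical_tests(pcm, labels, tree)
        assert sorted(res["node"]) == ["A", "B"]
        assert set(res["level"]) == {1}

    def test_comparison_count_matches_tree_walk_oracle(self):
        rng = np.random.default_rng(20)
        edges = [("root", "N"), ("root", "NN"), ("N", "CNS"), ("N", "PNS"),
                 ("NN", "glia"), ("NN", "nonglia"), ("CNS", "ex"),
                 ("CNS", "inh")]
        tree = TaxonomyTree.from_edges(edges)
        leaves = ["PNS", "glia", "nonglia", "ex", "inh"]
        pcm, labels = self._pcm_and_labels(
            rng, {leaf: (5, 5) for leaf in leaves}, cells_per_leaf=30)
        res = hierarchical_tests(pcm, labels, tree)
        # oracle: nodes with a non-empty complement within their parent
        def members(node):
            return {leaf for leaf in leaves
                    if node in tree.path_to_root(leaf)}
        expected = []
        for node in tree.nodes():
            if node == "root":
                continue
            inside = members(node)
            parent_members = members(tree.parent[node])
            if inside and parent_members - inside:
                expected.append(node)
        assert sorted(res["node"].unique()) == sorted(expected)

    def test_signal_between_deep_siblings_is_tagged_at_that_node(self):
        rng = np.random.default_rng(21)
        edges = [("root", "N"), ("root", "NN"), ("N", "ex"), ("N", "inh")]
        tree = TaxonomyTree.from_edges(edges)
        pcm, labels = self._pcm_and_labels(
            rng, {"ex": (8, 2), "inh": (2, 8), "NN": (5, 5)},
            cells_per_leaf=100)
        res = hierarchical_tests(pcm, labels, tree)
        sig = res[res["significant"]]
        assert {"ex", "inh"} <= set(sig["node"])


def test_combined_test_null_calibration_small():
    """Quick null check: rejection rate of the combined test stays near
    the nominal level under an overdispersed shared null (the full-size
    calibration lives in the acceptance suite)."""
    rng = np.random.default_rng(22)
    rej = 0
    N = 100
    for i in range(N):
        alpha = np.full(2, 1.5)
        counts, labels = simulate_gene_counts({"a": alpha, "b": alpha}, 100,
                                              10.0, 10.0, rng)
        res = gene_stats(counts, labels, positions=[0.0, 400.0])
        rej += res["p_combined"] <= 0.05
    assert rej / N <= 0.12
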
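import numpy as np
import pandas as pd
import pytest

from paleodiv.bd import SpeciesTimes
from paleodiv.diversity import ltt_from_times
from paleodiv.phylo import (
    NewickFormatError,
    TimeTree,
    brownian_covariance,
    classify_trend,
    diversity_at_offset,
    fit_group_contrast,
    pgls_fit,
    read_newick,
    tip_dr,
    tip_rate_table,
    tree_from_newick_string,
    write_newick,
)


class TestNewickIO:
    def test_parse_toy(self, toy_tree):
        assert toy_tree.tip_labels == ("A", "B", "C")
        assert toy_tree.height == pytest.approx(2.0)

    def test_round_trip(self, toy_tree, tmp_path):
        p = tmp_path / "t.nwk"
        write_newick(toy_tree, p)
        again = read_newick(p)
        assert again.tip_labels == toy_tree.tip_labels
        for lbl in toy_tree.tip_labels:
            assert again.depth(lbl) == pytest.approx(toy_tree.depth(lbl), abs=1e-9)

    def test_missing_branch_length(self):
        with pytest.raises(NewickFormatError):
            tree_from_newick_string("((A:1,B),C:2);")

    def test_zero_length_terminal_warns(self):
        with pytest.warns(UserWarning, match="zero-length"):
            tree_from_newick_string("((A:0,B:1):1,C:2);")

    def test_simulated_round_trip(self, random_trees, tmp_path):
        tree = random_trees[0]
        p = tmp_path / "s.nwk"
        write_newick(tree, p)
        again = read_newick(p)
        assert sorted(again.tip_labels) == sorted(tree.tip_labels)
        for lbl in tree.tip_labels:
            assert again.depth(lbl) == pytest.approx(tree.depth(lbl), abs=1e-9)


def brute_force_dr(tree: TimeTree, tip: str) -> float:
    """Independent path-walk: collect edge lengths tip->root, weight 2^-(j-1)."""
    node = tree._leaf_by_label[tip]
    lengths = []
    while node.parent_node is not None:
        lengths.append(float(node.edge.length))
        node = node.parent_node
    return 1.0 / sum(l * 0.5 ** j for j, l in enumerate(lengths))


class TestTipDr:
    def test_two_tip_tree(self):
        t = tree_from_newick_string("(A:2,B:2);")
        assert tip_dr(t, "A") == pytest.approx(0.5)

    def test_toy_value(self, toy_tree):
        assert tip_dr(toy_tree, "A") == pytest.approx(1 / 1.5, abs=1e-12)
        assert tip_dr(toy_tree, "C") == pytest.approx(0.5, abs=1e-12)

    def test_scaling_homogeneity(self, toy_tree):
        t2 = tree_from_newick_string("((A:3,B:3):3,C:6);")  # x3
        for lbl in ("A", "B", "C"):
            assert tip_dr(t2, lbl) == pytest.approx(tip_dr(toy_tree, lbl) / 3, abs=1e-12)

    def test_matches_brute_force_on_random_trees(self, random_trees):
        for tree in random_trees[:25]:
            for lbl in tree.tip_labels:
                assert tip_dr(tree, lbl) == pytest.approx(
                    brute_force_dr(tree, lbl), abs=1e-10)


class TestDiversityAtOffset:
    def test_toy_slices(self, toy_tree):
        assert diversity_at_offset(toy_tree, "A", 0.5) == 3
        assert diversity_at_offset(toy_tree, "A", 1.5) == 2

    def test_offset_zero_ultrametric_counts_extant(self):
        t = tree_from_newick_string("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        for lbl in "ABCD":
            assert diversity_at_offset(t, lbl, 0.0) == 4

    def test_slice_above_root_returns_stem(self, toy_tree):
        with pytest.warns(UserWarning, match="root"):
            assert diversity_at_offset(toy_tree, "A", 5.0) == 1

    def test_agrees_with_ltt_on_edge_spans(self, random_trees):
        """Branch-crossing counts equal the LTT of the tree's edge intervals."""
        offset = 0.37
        for tree in random_trees[:15]:
            spans = []
            for node in tree.tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                spans.append((tree.height - tree._depth[node.parent_node],
                              tree.height - tree._depth[node]))
            times = SpeciesTimes(
                tuple(f"e{i}" for i in range(len(spans))),
                np.array([s[0] for s in spans]),
                np.array([s[1] for s in spans]),
                np.array([s[1] == 0 for s in spans]),
            )
            traj = ltt_from_times(times)
            for lbl in tree.tip_labels:
                t_slice = tree.tip_age(lbl) + offset
                if t_slice >= tree.height:
                    continue
                assert diversity_at_offset(tree, lbl, offset) == traj.at(t_slice)


class TestPgls:
    def star(self, n=8, depth=2.0):
        s = ",".join(f"T{i}:{depth}" for i in range(n))
        return tree_from_newick_string(f"({s});")

    def test_star_tree_equals_ols(self):
        tree = self.star()
        rng = np.random.default_rng(0)
        x = rng.normal(size=8)
        y = 1.0 + 2.0 * x + rng.normal(scale=0.3, size=8)
        X = pd.DataFrame({"x": x}, index=list(tree.tip_labels))
        fit = pgls_fit(tree, pd.Series(y, index=X.index), X)
        import statsmodels.api as sm

        ols = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(fit.params, ols.params, atol=1e-10)
        np.testing.assert_allclose(fit.pvalues, ols.pvalues, atol=1e-10)

    def test_exact_interpolation(self, random_trees):
        tree = next(
            t for t in random_trees
            if np.linalg.cond(brownian_covariance(t)) < 1e8
        )
        labels = list(tree.tip_labels)
        rng = np.random.default_rng(1)
        x = rng.normal(size=len(labels))
        y = pd.Series(0.7 - 1.3 * x, index=labels)
        fit = pgls_fit(tree, y, pd.DataFrame({"x": x}, index=labels))
        assert fit.coef("intercept") == pytest.approx(0.7, abs=1e-10)
        assert fit.coef("x") == pytest.approx(-1.3, abs=1e-10)

    def test_covariance_structure(self, toy_tree):
        V = brownian_covariance(toy_tree)
        # tips A, B share the path to their MRCA at depth 1; C splits at the root
        expected = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        np.testing.assert_allclose(V, expected)

    def test_ci_coverage_calibrated(self, random_trees):
        """Simulating y ~ N(X beta, sigma^2 V) on a fixed tree, the 95% CI for
        the slope must cover the truth at its nominal rate."""
        from scipy import stats as st

        tree = next(t for t in random_trees if 12 <= len(t) <= 25)
        labels = list(tree.tip_labels)
        n = len(labels)
        V = brownian_covariance(tree)
        L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
        rng = np.random.default_rng(7)
        x = rng.normal(size=n)
        X = pd.DataFrame({"x": x}, index=labels)
        beta, sigma = 0.8, 0.6
        tcrit = st.t.ppf(0.975, n - 2)
        covered = 0
        reps = 1000
        for _ in range(reps):
            y = 0.2 + beta * x + sigma * (L @ rng.normal(size=n))
            fit = pgls_fit(tree, pd.Series(y, index=labels), X)
            b, se = fit.coef("x"), fit.bse[fit.names.index("x")]
            if b - tcrit * se <= beta <= b + tcrit * se:
                covered += 1
        assert 0.93 <= covered / reps <= 0.97


class TestClassifyTrend:
    def test_constant_diversity_is_none(self):
        tree = tree_from_newick_string("(A:2,B:2,C:2,D:2);")
        with pytest.warns(UserWarning, match="constant"):
            assert classify_trend(tree) == "none"

    def test_alpha_zero_always_none(self, random_trees):
        assert classify_trend(random_trees[2], alpha_level=0.0) == "none"

    def test_needs_four_tips(self):
        with pytest.raises(ValueError):
            classify_trend(tree_from_newick_string("((A:1,B:1):1,C:2);"))

    def test_invariant_to_label_permutation(self, random_trees):
        import dendropy

        tree = random_trees[3]
        call = classify_trend(tree)
        # rotate which taxon each leaf points at (taxon objects are shared
        # with the fixture tree, so never mutate their labels in place)
        clone = tree.tree.clone(depth=1)
        leaves = list(clone.leaf_node_iter())
        taxa = [lf.taxon for lf in leaves]
        for lf, taxon in zip(leaves, taxa[1:] + taxa[:1]):
            lf.taxon = taxon
        assert classify_trend(TimeTree(clone)) == call

    def test_invariant_to_joint_rescaling(self, random_trees):
        tree = random_trees[4]
        call = classify_trend(tree, offset=0.5)
        clone = tree.tree.clone(depth=1)
        for e in clone.preorder_edge_iter():
            if e.length is not None:
                e.length = e.length * 3.0
        assert classify_trend(TimeTree(clone), offset=1.5) == call

    def test_detects_strong_diversity_dependence(self):
        from paleodiv.treesim import BDSimConfig, simulate_bd_tree

        negatives = 0
        total = 60
        for seed in range(total):
            tree = simulate_bd_tree(BDSimConfig(
                lambda0=1.5, mu0=0.2, K=10, max_height=7.0, min_tips=6, seed=3000 + seed))
            if classify_trend(tree) == "negative":
                negatives += 1
        assert negatives / total > 0.5


class TestGroupContrast:
    def test_single_group_rejected(self, random_trees):
        tree = random_trees[5]
        groups = {lbl: "g" for lbl in tree.tip_labels}
        with pytest.raises(ValueError, match="two groups"):
            fit_group_contrast(tree, groups)

    def test_small_group_rejected(self, random_trees):
        tree = random_trees[5]
        labels = list(tree.tip_labels)
        groups = {lbl: "a" for lbl in labels}
        groups[labels[0]] = "b"
        with pytest.raises(ValueError, match="fewer than 3"):
            fit_group_contrast(tree, groups)

    def test_null_interaction_rate_is_nominal(self, random_trees):
        """When both groups share one DR~SD relationship, the interaction
        should be significant in at most ~alpha of noise draws."""
        tree = next(t for t in random_trees if len(t) >= 12)
        labels = list(tree.tip_labels)
        half = len(labels) // 2
        groups = {l: ("a" if i < half else "b") for i, l in enumerate(labels)}
        tab = tip_rate_table(tree, offset=0.5)
        sd = tab.loc[labels, "sd"].to_numpy(float)
        V = brownian_covariance(tree, labels)
        L = np.linalg.cholesky(V + 1e-12 * np.eye(len(labels)))
        rng = np.random.default_rng(11)
        hits = 0
        reps = 100
        for _ in range(reps):
            y = 0.5 - 0.05 * sd + 0.3 * (L @ rng.normal(size=len(labels)))
            ind = np.array([groups[l] == "b" for l in labels], dtype=float)
            X = pd.DataFrame({"sd": sd, "group": ind, "sd_x_group": sd * ind}, index=labels)
            fit = pgls_fit(tree, pd.Series(y, index=labels), X)
            if fit.pvalue("sd_x_group") < 0.05:
                hits += 1
        assert hits / reps <= 0.10

    def test_constructed_opposite_slopes(self):
        """Two clades built so their DR ~ diversity relationships run in
        opposite directions: a non-ultrametric star versus a pendant comb."""
        star = "(" + ",".join(f"A{i}:{1.0 + 0.8 * i}" for i in range(5)) + "):1"
        comb = "((((B0:0.2,B1:0.4):1,B2:0.9):1,B3:1.6):1,B4:2.6):1"
        tree = tree_from_newick_string(f"({star},{comb});")
        groups = {f"A{i}": "a" for i in range(5)} | {f"B{i}": "b" for i in range(5)}
        contrast = fit_group_contrast(tree, groups, offset=0.3)
        slopes = contrast.simple_slopes
        assert np.sign(slopes["a"]) != np.sign(slopes["b"])
        assert contrast.interaction_p < 0.05


class TestTipRateTable:
    def test_columns_and_groups(self, toy_tree):
        tab = tip_rate_table(toy_tree, offset=0.5, groups={"A": "x", "B": "x", "C": "y"})
        assert list(tab.columns) == ["group", "dr", "sd"]
        assert tab.loc["C", "group"] == "y"
        assert tab.loc["A", "dr"] == pytest.approx(1 / 1.5)
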
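"""Module-network inference: discretization, trees, reassignment, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from sklearn.metrics import adjusted_rand_score

from rootheat.modules import (
    ModuleNetwork,
    ModuleTree,
    TreeNode,
    VARIANCE_FLOOR,
    cluster_genes_kmeans,
    discretize_regulators,
    fit_module_network,
    learn_tree,
    reassign_genes,
    score_gene,
)
from rootheat.simulate import SimConfig, gen_module_expression


def _frame(rows, index=None):
    rows = np.atleast_2d(np.asarray(rows, float))
    return pd.DataFrame(
        rows,
        index=index or [f"tf{i}" for i in range(rows.shape[0])],
        columns=[f"c{i}" for i in range(rows.shape[1])],
    )


class TestDiscretize:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([5, 4, -4, -5, 0, 0], [1, 1, -1, -1, 0, 0]),  # all three ranges
            ([0.5, 1.0, -1.0], [0, 0, 0]),  # single range
            ([4, 5, 0.2], [1, 1, 0]),  # two ranges
            ([-4, -5, 0.2, 0.3], [-1, -1, 0, 0]),
        ],
    )
    def test_range_counting_and_kmeans_labels(self, values, expected):
        states = discretize_regulators(_frame([values]))
        assert states.iloc[0].tolist() == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            discretize_regulators(_frame([[1.0, np.nan]]))


class TestClusterGenes:
    def test_separated_profiles_split_exactly(self):
        rng = np.random.default_rng(0)
        a = rng.normal(5, 0.1, size=(10, 6))
        b = rng.normal(-5, 0.1, size=(10, 6))
        expr = _frame(np.vstack([a, b]), index=[f"g{i}" for i in range(20)])
        labels = cluster_genes_kmeans(expr, 2, seed=1)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_duplicate_rows_share_labels_and_seed_determinism(self):
        expr = _frame([[1, 2, 3], [1, 2, 3], [9, 9, 9], [1, 2, 3]],
                      index=list("abcd"))
        l1 = cluster_genes_kmeans(expr, 2, seed=3)
        l2 = cluster_genes_kmeans(expr, 2, seed=3)
        assert (l1 == l2).all()
        assert l1[0] == l1[1] == l1[3]

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            cluster_genes_kmeans(_frame([[1, 2]]), 2)


def exhaustive_depth1_loglik(values, states, min_leaf=2):
    """Oracle: best total Gaussian log-likelihood over all depth-1 trees
    (every (TF, query) split plus the no-split leaf), computed with scipy."""

    def leaf_ll(block):
        mu = block.mean()
        s2 = max(block.var(), VARIANCE_FLOOR)
        return float(norm.logpdf(block, mu, np.sqrt(s2)).sum())

    best = leaf_ll(values)
    for ti in range(states.shape[0]):
        for val in (1, -1):
            mask = states[ti] == val
            if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
                continue
            cand = leaf_ll(values[:, mask]) + leaf_ll(values[:, ~mask])
            best = max(best, cand)
    return best


def tree_loglik(values, tree):
    return float(sum(score_gene(values[g], tree) for g in range(values.shape[0])))


def test_greedy_depth1_matches_exhaustive_enumeration():
    """On small random instances the greedy depth-1 split is exactly the
    best over all (TF, query) splits."""
    rng = np.random.default_rng(123)
    for _ in range(100):
        n_tf = int(rng.integers(2, 7))
        n_cond = int(rng.integers(4, 13))
        n_genes = int(rng.integers(2, 6))
        states = rng.choice([-1, 0, 1], size=(n_tf, n_cond))
        values = rng.normal(0, 1, size=(n_genes, n_cond))
        expr = _frame(values, index=[f"g{i}" for i in range(n_genes)])
        regs = _frame(states, index=[f"tf{i}" for i in range(n_tf)])
        tree = learn_tree(expr, regs, max_depth=1, min_leaf_conditions=2)
        got = tree_loglik(values, tree)
        want = exhaustive_depth1_loglik(values, states)
        assert got == pytest.approx(want, abs=1e-8)


def test_learn_tree_recovers_planted_split():
    rng = np.random.default_rng(5)
    states = np.zeros((3, 10), int)
    states[1, :5] = 1  # TF tf1 is up on the first five conditions
    values = np.where(np.arange(10) < 5, 2.0, -2.0) + rng.normal(0, 0.1, (20, 10))
    tree = learn_tree(_frame(values, index=[f"g{i}" for i in range(20)]),
                      _frame(states), max_depth=1)
    assert not tree.root.is_leaf
    assert tree.root.tf == "tf1" and tree.root.query == "is_up"


def test_single_condition_and_constant_values_stay_leaves():
    tree = learn_tree(_frame([[1.0]], index=["g"]), _frame([[1]]), max_depth=3)
    assert tree.root.is_leaf
    flat = learn_tree(_frame([[2.0] * 6], index=["g"]),
                      _frame([np.resize([1, -1], 6)]), max_depth=3)
    assert flat.root.is_leaf  # no positive gain on constant data


def test_empty_condition_set_rejected():
    with pytest.raises(ValueError):
        learn_tree(pd.DataFrame(index=["g"]), pd.DataFrame(index=["tf"]), 1)


class TestScoreGene:
    def test_density_at_leaf_mean(self):
        tree = ModuleTree(TreeNode(is_leaf=True, conditions=[0], mu=1.0, sigma2=1.0), ["c0"])
        assert score_gene([1.0], tree) == pytest.approx(-0.918939, abs=1e-6)

    def test_split_leaves_equal_merged_when_params_match(self):
        merged = ModuleTree(
            TreeNode(is_leaf=True, conditions=[0, 1], mu=0.5, sigma2=2.0), ["a", "b"]
        )
        split = ModuleTree(
            TreeNode(
                is_leaf=False, tf="t", query="is_up",
                yes=TreeNode(is_leaf=True, conditions=[0], mu=0.5, sigma2=2.0),
                no=TreeNode(is_leaf=True, conditions=[1], mu=0.5, sigma2=2.0),
            ),
            ["a", "b"],
        )
        vals = [1.3, -0.2]
        assert score_gene(vals, merged) == pytest.approx(score_gene(vals, split))

    def test_score_decreases_away_from_mean(self):
        tree = ModuleTree(TreeNode(is_leaf=True, conditions=[0], mu=0.0, sigma2=1.0), ["c"])
        assert score_gene([0.1], tree) > score_gene([1.0], tree) > score_gene([3.0], tree)

    def test_coverage_mismatch_rejected(self):
        tree = ModuleTree(TreeNode(is_leaf=True, conditions=[0], mu=0, sigma2=1), ["c"])
        with pytest.raises(ValueError):
            score_gene([1.0, 2.0], tree)


class TestReassign:
    def _trees(self):
        t0 = ModuleTree(TreeNode(is_leaf=True, conditions=[0, 1], mu=2.0, sigma2=0.1),
                        ["a", "b"])
        t1 = ModuleTree(TreeNode(is_leaf=True, conditions=[0, 1], mu=-2.0, sigma2=0.1),
                        ["a", "b"])
        return [t0, t1]

    def test_moves_gene_to_best_tree(self):
        expr = _frame([[2.0, 2.0], [-2.0, -2.0]], index=["up", "dn"])
        labels = reassign_genes(expr, self._trees(), current=np.array([1, 1]))
        assert labels.tolist() == [0, 1]

    def test_identical_trees_keep_current(self):
        t = self._trees()[0]
        expr = _frame([[2.0, 2.0]], index=["g"])
        labels = reassign_genes(expr, [t, t], current=np.array([1]))
        assert labels.tolist() == [1]


def test_fit_module_network_recovers_planting_and_monotone_history():
    cfg = SimConfig(n_genes=200, n_tf=6, n_modules=2, tree_depth=1, leaf_sep=4.0,
                    noise_sd=0.1, seed=17)
    expr, regs, truth = gen_module_expression(cfg)
    est = ModuleNetwork(n_modules=2, random_state=0).fit(expr, reg_states=regs["states"])
    truth_labels = [truth.module_assignment[g] for g in expr.index]
    assert adjusted_rand_score(truth_labels, est.labels_) == 1.0
    assert all(b - a > -1e-9 for a, b in zip(est.history_, est.history_[1:]))
    # leaves of every tree partition the conditions exactly
    n_cond = expr.shape[1]
    for tree in est.trees_:
        conds = sorted(c for leaf in tree.root.leaves() for c in leaf.conditions)
        assert conds == list(range(n_cond))


def test_fit_single_module_converges_fast_and_deterministic():
    cfg = SimConfig(n_genes=50, n_tf=4, n_modules=1, tree_depth=1, noise_sd=0.2, seed=2)
    expr, regs, _ = gen_module_expression(cfg)
    trees1, labels1, hist1 = fit_module_network(expr, regs["states"], k=1, seed=4)
    trees2, labels2, hist2 = fit_module_network(expr, regs["states"], k=1, seed=4)
    assert (labels1 == labels2).all() and hist1 == hist2
    assert len(hist1) <= 2
    assert set(labels1) == {0}


def test_discretization_via_tf_expression_path():
    """Fitting from raw TF expression discretizes internally to the same
    states the generator planted."""
    cfg = SimConfig(n_genes=60, n_tf=5, n_modules=2, tree_depth=1, noise_sd=0.1, seed=9)
    expr, regs, _ = gen_module_expression(cfg)
    est = ModuleNetwork(n_modules=2, random_state=0).fit(expr, tf_expr=regs["expression"])
    assert est.regulator_states_.astype(int).equals(regs["states"].astype(int))
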
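"""Gene regulatory module networks: regulator trees over TF states.

Transcription-factor expression (log2 fold change per condition) is
discretized into up (1) / normal (0) / down (-1) states against +/-3
cutoffs by 1-D K-means, genes are clustered by K-means on their expression
profiles, and each cluster gets a binary decision tree whose internal nodes
query a TF state ("up-regulated or not", "down-regulated or not") and whose
leaves are condition subsets modelled as Gaussians.  Tree learning and gene
reassignment alternate until the total data likelihood stops improving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

__all__ = [
    "TreeNode",
    "ModuleTree",
    "discretize_regulators",
    "cluster_genes_kmeans",
    "learn_tree",
    "score_gene",
    "reassign_genes",
    "fit_module_network",
    "ModuleNetwork",
]

VARIANCE_FLOOR = 1e-4
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class TreeNode:
    """Internal query node or Gaussian leaf of a regulator tree."""

    is_leaf: bool
    conditions: list = field(default_factory=list)  # leaf: condition indices
    mu: float = 0.0
    sigma2: float = 1.0
    tf: str | None = None  # internal: TF id
    query: str | None = None  # internal: "is_up" or "is_down"
    yes: "TreeNode | None" = None
    no: "TreeNode | None" = None

    def leaves(self):
        if self.is_leaf:
            return [self]
        return self.yes.leaves() + self.no.leaves()

    def to_dict(self):
        if self.is_leaf:
            return {
                "leaf": True,
                "conditions": [int(c) for c in self.conditions],
                "mu": self.mu,
                "sigma2": self.sigma2,
            }
        return {
            "leaf": False,
            "tf": self.tf,
            "query": self.query,
            "yes": self.yes.to_dict(),
            "no": self.no.to_dict(),
        }


@dataclass
class ModuleTree:
    """A regulator tree plus the condition ids it partitions."""

    root: TreeNode
    condition_ids: list

    def leaf_params(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-condition (mu, sigma2) arrays implied by the leaf partition."""
        n = len(self.condition_ids)
        mu = np.empty(n)
        s2 = np.empty(n)
        for leaf in self.root.leaves():
            idx = np.asarray(leaf.conditions, int)
            mu[idx] = leaf.mu
            s2[idx] = leaf.sigma2
        return mu, s2

    def split_tfs(self) -> set:
        out = set()

        def walk(node):
            if not node.is_leaf:
                out.add(node.tf)
                walk(node.yes)
                walk(node.no)

        walk(self.root)
        return out


def discretize_regulators(
    tf_expr: pd.DataFrame, high_cut: float = 3.0, low_cut: float = -3.0
) -> pd.DataFrame:
    """Discretize each TF's per-condition expression into {-1, 0, 1} states.

    The number of clusters K for a TF equals the number of the three ranges
    (> high_cut, < low_cut, in between) its values occupy; 1-D K-means with
    that K is run and clusters are mapped to the occupied range labels by
    center order (highest center gets the highest occupied label).
    """
    if not np.all(np.isfinite(tf_expr.to_numpy())):
        raise ValueError("TF expression must be finite")
    states = pd.DataFrame(0, index=tf_expr.index, columns=tf_expr.columns, dtype=int)
    for tf, row in tf_expr.iterrows():
        vals = row.to_numpy(float)
        labels_present = []
        if np.any(vals > high_cut):
            labels_present.append(1)
        if np.any((vals >= low_cut) & (vals <= high_cut)):
            labels_present.append(0)
        if np.any(vals < low_cut):
            labels_present.append(-1)
        k = len(labels_present)
        if k == 1:
            states.loc[tf] = labels_present[0]
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=0).fit(vals.reshape(-1, 1))
        center_order = np.argsort(-km.cluster_centers_.ravel())  # highest first
        label_by_cluster = {}
        for rank, cl in enumerate(center_order):
            label_by_cluster[cl] = sorted(labels_present, reverse=True)[rank]
        states.loc[tf] = [label_by_cluster[c] for c in km.labels_]
    return states


def cluster_genes_kmeans(expr: pd.DataFrame, k: int, seed: int = 0) -> np.ndarray:
    """K-means on gene expression profiles; returns a label per gene."""
    if k > expr.shape[0]:
        raise ValueError("more clusters requested than genes")
    if k < 1:
        raise ValueError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(expr.to_numpy(float))
    return km.labels_


def _leaf_loglik(values: np.ndarray) -> tuple[float, float, float]:
    """Gaussian log-likelihood of a flattened value block with MLE (mu, sigma2)."""
    n = values.size
    mu = float(values.mean())
    s2 = max(float(values.var()), VARIANCE_FLOOR)
    ll = -0.5 * n * (_LOG_2PI + np.log(s2)) - float(np.sum((values - mu) ** 2)) / (2.0 * s2)
    return ll, mu, s2


def learn_tree(
    member_expr: pd.DataFrame,
    reg_states: pd.DataFrame,
    max_depth: int = 3,
    min_leaf_conditions: int = 2,
) -> ModuleTree:
    """Greedy top-down regulator tree for one module's member genes.

    At each node the (TF, query) split maximizing the summed Gaussian
    log-likelihood over the resulting condition subsets is taken, accepted
    only when the gain is positive and both children keep at least
    ``min_leaf_conditions`` conditions.
    """
    if member_expr.shape[1] == 0:
        raise ValueError("empty condition set")
    if member_expr.shape[0] == 0:
        raise ValueError("tree needs at least one member gene")
    if list(member_expr.columns) != list(reg_states.columns):
        raise ValueError("member expression and regulator states disagree on conditions")
    values = member_expr.to_numpy(float)
    states = reg_states.to_numpy(int)
    tf_ids = list(reg_states.index)
    root = _grow(values, states, tf_ids, np.arange(values.shape[1]), max_depth, min_leaf_conditions)
    return ModuleTree(root=root, condition_ids=list(member_expr.columns))


def _grow(values, states, tf_ids, cond_idx, depth_left, min_leaf):
    block = values[:, cond_idx]
    ll_leaf, mu, s2 = _leaf_loglik(block)
    leaf = TreeNode(is_leaf=True, conditions=cond_idx.tolist(), mu=mu, sigma2=s2)
    if depth_left <= 0 or len(cond_idx) < 2 * min_leaf:
        return leaf
    best = None
    for ti in range(states.shape[0]):
        sub_states = states[ti, cond_idx]
        for query, val in (("is_up", 1), ("is_down", -1)):
            mask = sub_states == val
            n_yes = int(mask.sum())
            if n_yes < min_leaf or len(cond_idx) - n_yes < min_leaf:
                continue
            ll_yes, _, _ = _leaf_loglik(values[:, cond_idx[mask]])
            ll_no, _, _ = _leaf_loglik(values[:, cond_idx[~mask]])
            gain = ll_yes + ll_no - ll_leaf
            if gain > 1e-12 and (best is None or gain > best[0]):
                best = (gain, ti, query, mask)
    if best is None:
        return leaf
    _, ti, query, mask = best
    return TreeNode(
        is_leaf=False,
        tf=tf_ids[ti],
        query=query,
        yes=_grow(values, states, tf_ids, cond_idx[mask], depth_left - 1, min_leaf),
        no=_grow(values, states, tf_ids, cond_idx[~mask], depth_left - 1, min_leaf),
    )


def score_gene(gene_values, tree: ModuleTree) -> float:
    """Gaussian log-likelihood of one gene's condition profile under a tree."""
    vals = np.asarray(gene_values, float)
    if vals.size != len(tree.condition_ids):
        raise ValueError("gene profile does not cover the tree's condition set")
    mu, s2 = tree.leaf_params()
    return float(np.sum(-0.5 * (_LOG_2PI + np.log(s2)) - (vals - mu) ** 2 / (2.0 * s2)))


def reassign_genes(expr: pd.DataFrame, trees: list, current: np.ndarray | None = None) -> np.ndarray:
    """Assign each gene to the tree scoring its profile highest.

    Ties keep the current assignment when one is given, otherwise take the
    lowest module index.
    """
    if not trees:
        raise ValueError("need at least one tree")
    vals = expr.to_numpy(float)
    scores = np.empty((vals.shape[0], len(trees)))
    for mi, tree in enumerate(trees):
        mu, s2 = tree.leaf_params()
        scores[:, mi] = np.sum(
            -0.5 * (_LOG_2PI + np.log(s2)) - (vals - mu) ** 2 / (2.0 * s2), axis=1
        )
    best = scores.argmax(axis=1)
    if current is not None:
        keep = np.isclose(scores[np.arange(len(best)), current], scores.max(axis=1))
        best = np.where(keep, current, best)
    return best


def _total_loglik(expr_vals, trees, labels):
    total = 0.0
    for mi, tree in enumerate(trees):
        idx = labels == mi
        if not idx.any():
            continue
        mu, s2 = tree.leaf_params()
        block = expr_vals[idx]
        total += float(
            np.sum(-0.5 * (_LOG_2PI + np.log(s2)) - (block - mu) ** 2 / (2.0 * s2))
        )
    return total


def fit_module_network(
    expr: pd.DataFrame,
    reg_states: pd.DataFrame,
    k: int,
    max_depth: int = 3,
    min_leaf_conditions: int = 2,
    max_iter: int = 20,
    tol: float = 1e-6,
    seed: int = 0,
):
    """Alternate tree learning and gene reassignment from a K-means start.

    Returns ``(trees, labels, history)``; ``history`` is the total
    log-likelihood after each iteration and is guaranteed non-decreasing: a
    newly learned tree replaces a module's previous tree only when it scores
    the module's current members at least as well.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = cluster_genes_kmeans(expr, k, seed=seed)
    vals = expr.to_numpy(float)
    trees = [None] * k
    history = []
    prev_total = -np.inf
    for _ in range(max_iter):
        # (re)learn trees, keeping a previous tree when the fresh greedy tree
        # is worse for the module's current members
        new_trees = []
        for mi in range(k):
            idx = labels == mi
            if not idx.any():
                new_trees.append(trees[mi])
                continue
            candidate = learn_tree(
                expr.loc[idx], reg_states, max_depth=max_depth,
                min_leaf_conditions=min_leaf_conditions,
            )
            if trees[mi] is not None:
                old_ll = _total_loglik(vals[idx], [trees[mi]], np.zeros(idx.sum(), int))
                new_ll = _total_loglik(vals[idx], [candidate], np.zeros(idx.sum(), int))
                candidate = candidate if new_ll >= old_ll else trees[mi]
            new_trees.append(candidate)
        trees = new_trees
        active = [t for t in trees if t is not None]
        labels = reassign_genes(expr, active, current=_remap(labels, trees))
        # drop empty modules
        trees = [t for mi, t in enumerate(active) if np.any(labels == mi)]
        labels = _compact(labels, len(active))
        k = len(trees)
        total = _total_loglik(vals, trees, labels)
        history.append(total)
        if total - prev_total < tol and len(history) > 1:
            break
        prev_total = total
    return trees, labels, history


def _remap(labels, trees):
    """Map labels into the index space of the non-None tree list."""
    mapping = {}
    j = 0
    for mi, t in enumerate(trees):
        if t is not None:
            mapping[mi] = j
            j += 1
    return np.array([mapping.get(l, 0) for l in labels])


def _compact(labels, k):
    used = [mi for mi in range(k) if np.any(labels == mi)]
    remap = {mi: j for j, mi in enumerate(used)}
    return np.array([remap[l] for l in labels])


class ModuleNetwork(BaseEstimator, ClusterMixin):
    """Module-network clusterer: regulator trees with Gaussian leaves.

    Parameters
    ----------
    n_modules : initial number of modules (K-means start); empty modules are
        dropped during fitting.
    max_depth, min_leaf_conditions : tree growth limits.
    max_iter, tol : stopping rule on the total log-likelihood.
    high_cut, low_cut : discretization thresholds for TF expression, on the
        same scale as the input matrix.
    random_state : seed for K-means initialisation.

    Attributes (after fit)
    ----------------------
    trees_ : list of :class:`ModuleTree`.
    labels_ : module index per gene.
    history_ : total log-likelihood per iteration (non-decreasing).
    total_loglik_ : final total log-likelihood.
    regulator_states_ : discretized TF state matrix used for the queries.
    """

    def __init__(self, n_modules: int = 10, max_depth: int = 3,
                 min_leaf_conditions: int = 2, max_iter: int = 20,
                 tol: float = 1e-6, high_cut: float = 3.0, low_cut: float = -3.0,
                 random_state: int = 0):
        self.n_modules = n_modules
        self.max_depth = max_depth
        self.min_leaf_conditions = min_leaf_conditions
        self.max_iter = max_iter
        self.tol = tol
        self.high_cut = high_cut
        self.low_cut = low_cut
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None, *, tf_expr: pd.DataFrame | None = None,
            reg_states: pd.DataFrame | None = None):
        """Fit on a gene x condition log2-fold-change matrix.

        Provide either raw TF expression (``tf_expr``, discretized here) or
        an already-discretized state matrix (``reg_states``).
        """
        if reg_states is None:
            if tf_expr is None:
                raise ValueError("provide tf_expr or reg_states")
            reg_states = discretize_regulators(tf_expr, self.high_cut, self.low_cut)
        self.regulator_states_ = reg_states
        trees, labels, history = fit_module_network(
            X, reg_states, k=self.n_modules, max_depth=self.max_depth,
            min_leaf_conditions=self.min_leaf_conditions, max_iter=self.max_iter,
            tol=self.tol, seed=self.random_state,
        )
        self.trees_ = trees
        self.labels_ = labels
        self.history_ = history
        self.total_loglik_ = history[-1]
        return self

    def to_json_dict(self) -> dict:
        """Serializable model: trees as nested nodes plus condition ids."""
        if not hasattr(self, "trees_"):
            raise AttributeError("fit the estimator first")
        return {
            "modules": [
                {"tree": t.root.to_dict(), "condition_ids": list(t.condition_ids)}
                for t in self.trees_
            ],
            "total_loglik": self.total_loglik_,
            "history": list(self.history_),
        }
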
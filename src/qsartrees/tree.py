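"""Weighted binary decision trees under two split regimes.

One tree structure serves both ensembles:

* CART regime (``criterion="gini"``): splits minimize the weighted-average
  Gini impurity of the two children; used by the random-trees ensemble,
  grown to maximum depth without pruning, optionally drawing a random
  feature subset at every node.
* C5.0 regime (``criterion="gain_ratio"``): splits maximize the gain ratio
  (information gain normalized by split information, log base 2); used by
  the boosted ensemble together with pessimistic post-pruning controlled by
  a severity percentage (confidence level CF = 1 - pSeverity/100).

All impurity computations use sample weights (boosting reweights samples
between trials). Splits are binary everywhere: continuous and ordinal
features are thresholded at midpoints between consecutive distinct values,
and a flag feature's 0/1 partition is the threshold at 0.5. Ties between
equally scoring candidate splits break toward the lower feature index, then
the lower threshold, so trees are fully reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import beta as beta_dist

_TOL = 1e-12


class TreeError(ValueError):
    pass


@dataclass(frozen=True)
class CostMatrix:
    """2x2 misclassification costs with zero diagonal (RB = positive).

    ``rb_as_nrb`` is the cost of predicting NRB for a true RB (a false
    negative); ``nrb_as_rb`` the cost of the converse false positive. The
    study's imbalance handling sets rb_as_nrb twice nrb_as_rb.
    """

    rb_as_nrb: float = 2.0
    nrb_as_rb: float = 1.0

    def __post_init__(self) -> None:
        if self.rb_as_nrb < 0 or self.nrb_as_rb < 0:
            raise TreeError("costs must be non-negative")
        if self.rb_as_nrb == 0 and self.nrb_as_rb == 0:
            raise TreeError("at least one off-diagonal cost must be positive")


@dataclass
class TreeNode:
    """Split node (feature, threshold, two children) or leaf (feature None).

    Every node carries the weighted class totals (w_rb, w_nrb) and the raw
    sample count n of the training data that reached it; internal nodes need
    them for pessimistic pruning.
    """

    w_rb: float
    w_nrb: float
    n: int
    feature: int | None = None
    threshold: float = 0.0
    left: "TreeNode | None" = None  # samples with value <= threshold
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def count_nodes(self) -> int:
        if self.is_leaf:
            return 1
        return 1 + self.left.count_nodes() + self.right.count_nodes()

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())


@dataclass
class DecisionTree:
    root: TreeNode
    criterion: str
    chsize: int = 1
    pseverity: float | None = None
    feature_names: tuple[str, ...] | None = None

    def count_nodes(self) -> int:
        return self.root.count_nodes()


# ---------------------------------------------------------------------------
# impurity / gain primitives (operate on per-class weight vectors)
# ---------------------------------------------------------------------------

def gini_impurity(class_weights: Sequence[float]) -> float:
    """1 - sum_c (w_c / W)^2; zero iff the node is pure."""
    w = np.asarray(class_weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise TreeError("zero total weight")
    p = w / total
    return float(1.0 - np.sum(p * p))


def gini_index(partition: Sequence[Sequence[float]]) -> float:
    """Weighted average of child Gini impurities over a partition."""
    parts = [np.asarray(p, dtype=float) for p in partition]
    if len(parts) < 2:
        raise TreeError("partition needs at least 2 children")
    sizes = np.array([p.sum() for p in parts])
    if (sizes <= 0).any():
        raise TreeError("empty child in partition")
    total = sizes.sum()
    return float(sum(s / total * gini_impurity(p) for s, p in zip(sizes, parts)))


def entropy(class_weights: Sequence[float]) -> float:
    """Shannon entropy in bits; in [0, 1] for two classes."""
    w = np.asarray(class_weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise TreeError("zero total weight")
    p = w[w > 0] / total
    return float(-np.sum(p * np.log2(p)))


def information_gain(
    parent: Sequence[float], partition: Sequence[Sequence[float]]
) -> float:
    """Entropy(parent) - weighted child entropy; non-negative."""
    parent = np.asarray(parent, dtype=float)
    parts = [np.asarray(p, dtype=float) for p in partition]
    if abs(sum(p.sum() for p in parts) - parent.sum()) > 1e-9:
        raise TreeError("partition weights do not sum to the parent weight")
    total = parent.sum()
    child = sum(p.sum() / total * entropy(p) for p in parts if p.sum() > 0)
    return max(float(entropy(parent) - child), 0.0)


def split_information(partition: Sequence[Sequence[float]]) -> float:
    """Entropy of the child-size distribution (the gain-ratio denominator)."""
    sizes = np.array([np.asarray(p, dtype=float).sum() for p in partition])
    total = sizes.sum()
    p = sizes[sizes > 0] / total
    return float(-np.sum(p * np.log2(p)))


def gain_ratio(parent: Sequence[float], partition: Sequence[Sequence[float]]) -> float:
    """Information gain normalized by split information (C4.5/C5.0)."""
    si = split_information(partition)
    if si <= 0:
        raise TreeError("split information is zero (single non-empty child)")
    return information_gain(parent, partition) / si


# ---------------------------------------------------------------------------
# split search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    feature: int
    threshold: float
    score: float  # gini index (lower better) or gain ratio (higher better)


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    candidate_features: Sequence[int],
    criterion: str,
    chsize: int = 1,
) -> SplitSpec | None:
    """Best admissible binary threshold split at a node, or None.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values of each candidate feature (for a 0/1 flag this is the natural
    partition at 0.5). Candidates leaving either child with fewer than
    ``chsize`` samples are rejected. Under ``gini`` the weighted child
    impurity must strictly improve on the parent impurity; under
    ``gain_ratio`` the information gain must be positive and the gain ratio
    is maximized. Ties break toward (lower feature index, lower threshold).
    """
    if criterion not in ("gini", "gain_ratio"):
        raise TreeError(f"unknown criterion {criterion!r}")
    n = len(y)
    if n < 2:
        return None
    tot_rb = float(w[y].sum())
    tot_nrb = float(w[~y].sum())
    total = tot_rb + tot_nrb
    if total <= 0 or tot_rb <= 0 or tot_nrb <= 0:
        return None  # pure (or weightless) node

    if criterion == "gini":
        parent_score = gini_impurity((tot_rb, tot_nrb))
    else:
        parent_entropy = entropy((tot_rb, tot_nrb))

    best: SplitSpec | None = None
    for f in sorted(set(int(f) for f in candidate_features)):
        v = X[:, f]
        order = np.argsort(v, kind="stable")
        vs = v[order]
        ws = w[order]
        ys = y[order]
        cuts = np.nonzero(vs[:-1] < vs[1:])[0]  # split after position i
        if cuts.size == 0:
            continue
        nl = cuts + 1
        ok = (nl >= chsize) & ((n - nl) >= chsize)
        cuts = cuts[ok]
        if cuts.size == 0:
            continue
        cw_rb = np.cumsum(ws * ys)
        cw_all = np.cumsum(ws)
        wl_rb = cw_rb[cuts]
        wl = cw_all[cuts]
        wl_nrb = wl - wl_rb
        wr_rb = tot_rb - wl_rb
        wr = total - wl
        wr_nrb = wr - wr_rb
        thresholds = 0.5 * (vs[cuts] + vs[cuts + 1])

        with np.errstate(divide="ignore", invalid="ignore"):
            if criterion == "gini":
                gl = 1.0 - (wl_rb / wl) ** 2 - (wl_nrb / wl) ** 2
                gr = 1.0 - (wr_rb / wr) ** 2 - (wr_nrb / wr) ** 2
                scores = (wl * gl + wr * gr) / total
                admissible = scores < parent_score - _TOL
            else:
                hl = _entropy2(wl_rb, wl_nrb)
                hr = _entropy2(wr_rb, wr_nrb)
                ig = parent_entropy - (wl * hl + wr * hr) / total
                pl = wl / total
                pr = wr / total
                si = -(pl * np.log2(pl) + pr * np.log2(pr))
                scores = np.where(si > 0, ig / np.maximum(si, _TOL), -np.inf)
                admissible = (ig > _TOL) & (si > 0)

        if not admissible.any():
            continue
        if criterion == "gini":
            # lower is better; argmin takes the earliest (lowest) threshold on ties
            cand = np.where(admissible, scores, np.inf)
            k = int(np.argmin(cand))
            if best is not None and not (cand[k] < best.score - _TOL):
                continue
        else:
            cand = np.where(admissible, scores, -np.inf)
            k = int(np.argmax(cand))
            if best is not None and not (cand[k] > best.score + _TOL):
                continue
        best = SplitSpec(feature=f, threshold=float(thresholds[k]), score=float(cand[k]))
    return best


def _entropy2(wa: np.ndarray, wb: np.ndarray) -> np.ndarray:
    tot = wa + wb
    pa = np.where(tot > 0, wa / np.where(tot > 0, tot, 1.0), 0.0)
    pb = 1.0 - pa
    out = np.zeros_like(pa)
    m = pa > 0
    out[m] -= pa[m] * np.log2(pa[m])
    m = pb > 0
    out[m] -= pb[m] * np.log2(pb[m])
    return out


# ---------------------------------------------------------------------------
# growing
# ---------------------------------------------------------------------------

def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None = None,
    criterion: str = "gini",
    chsize: int = 1,
    nfeature: int | None = None,
    rng: np.random.Generator | None = None,
    feature_names: Sequence[str] | None = None,
) -> DecisionTree:
    """Recursively grow a binary decision tree.

    ``y`` is the boolean RB indicator; ``w`` optional sample weights (counts
    scale). With ``nfeature`` set, each node draws that many features
    uniformly without replacement from ``rng`` before the split search (the
    random-trees regime). Growth stops at purity, the ``chsize`` floor, or
    when no admissible split improves the node.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if w is None:
        w = np.ones(len(y))
    w = np.asarray(w, dtype=float)
    if len(y) == 0:
        raise TreeError("cannot grow a tree on empty data")
    if (w < 0).any() or w.sum() <= 0:
        raise TreeError("sample weights must be non-negative with positive total")
    if nfeature is not None:
        if rng is None:
            raise TreeError("nfeature subsampling requires an rng")
        nfeature = int(min(max(nfeature, 1), X.shape[1]))
    p = X.shape[1]

    def build(idx: np.ndarray) -> TreeNode:
        yi = y[idx]
        wi = w[idx]
        node = TreeNode(
            w_rb=float(wi[yi].sum()), w_nrb=float(wi[~yi].sum()), n=len(idx)
        )
        if node.w_rb <= 0 or node.w_nrb <= 0 or len(idx) < 2 * chsize:
            return node
        if nfeature is not None and nfeature < p:
            feats = rng.choice(p, size=nfeature, replace=False)
        else:
            feats = np.arange(p)
        spec = best_split(X[idx], yi, wi, feats, criterion, chsize)
        if spec is None:
            return node
        mask = X[idx, spec.feature] <= spec.threshold
        node.feature = spec.feature
        node.threshold = spec.threshold
        node.left = build(idx[mask])
        node.right = build(idx[~mask])
        return node

    root = build(np.arange(len(y)))
    return DecisionTree(
        root=root,
        criterion=criterion,
        chsize=chsize,
        feature_names=tuple(feature_names) if feature_names is not None else None,
    )


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def binomial_upper_limit(errors: float, n: float, cf: float) -> float:
    """One-sided upper confidence bound on a binomial error rate.

    The C4.5 convention: the largest error probability U such that observing
    at most ``errors`` errors in ``n`` trials has probability CF. Closed form
    for zero errors: U = 1 - CF**(1/n). Weighted (non-integer) counts are
    accepted via the regularized incomplete beta function.
    """
    if n <= 0:
        return 0.0
    if errors <= 0:
        return float(1.0 - cf ** (1.0 / n))
    if errors >= n:
        return 1.0
    return float(beta_dist.ppf(1.0 - cf, errors + 1.0, n - errors))


def _pessimistic_error(node: TreeNode, cf: float) -> float:
    n = node.w_rb + node.w_nrb
    e = n - max(node.w_rb, node.w_nrb)
    return n * binomial_upper_limit(e, n, cf)


def prune_tree(tree: DecisionTree, pseverity: float) -> DecisionTree:
    """Bottom-up pessimistic pruning at confidence CF = 1 - pSeverity/100.

    A subtree collapses to a leaf when the leaf's pessimistic error (its
    weighted error count inflated to the upper binomial confidence bound)
    does not exceed the sum of its descendants' pessimistic errors. Higher
    severity means lower CF, larger upper bounds on subtree errors, hence
    more pruning.
    """
    if not (0.0 <= pseverity < 100.0):
        raise TreeError("pSeverity must be in [0, 100)")
    cf = 1.0 - pseverity / 100.0

    def prune(node: TreeNode) -> tuple[TreeNode, float]:
        if node.is_leaf:
            return node, _pessimistic_error(node, cf)
        left, err_l = prune(node.left)
        right, err_r = prune(node.right)
        subtree_err = err_l + err_r
        leaf_err = _pessimistic_error(node, cf)
        if leaf_err <= subtree_err + _TOL:
            return TreeNode(w_rb=node.w_rb, w_nrb=node.w_nrb, n=node.n), leaf_err
        out = TreeNode(
            w_rb=node.w_rb,
            w_nrb=node.w_nrb,
            n=node.n,
            feature=node.feature,
            threshold=node.threshold,
            left=left,
            right=right,
        )
        return out, subtree_err

    root, _ = prune(tree.root)
    return DecisionTree(
        root=root,
        criterion=tree.criterion,
        chsize=tree.chsize,
        pseverity=pseverity,
        feature_names=tree.feature_names,
    )


def tree_pessimistic_error(tree: DecisionTree, pseverity: float) -> float:
    """Total pessimistic error estimate of a tree's leaves at a severity."""
    cf = 1.0 - pseverity / 100.0

    def walk(node: TreeNode) -> float:
        if node.is_leaf:
            return _pessimistic_error(node, cf)
        return walk(node.left) + walk(node.right)

    return walk(tree.root)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def leaf_proba(tree: DecisionTree, X: np.ndarray) -> np.ndarray:
    """Route samples to leaves; return each sample's leaf P(RB)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.isfinite(X).all():
        raise TreeError("non-finite feature value in prediction input")
    out = np.empty(len(X))

    def walk(node: TreeNode, idx: np.ndarray) -> None:
        if idx.size == 0:
            return
        if node.is_leaf:
            out[idx] = node.w_rb / (node.w_rb + node.w_nrb)
            return
        mask = X[idx, node.feature] <= node.threshold
        walk(node.left, idx[mask])
        walk(node.right, idx[~mask])

    walk(tree.root, np.arange(len(X)))
    return out


def decide(p_rb: np.ndarray, cost: CostMatrix | None = None) -> np.ndarray:
    """Class decision from leaf probabilities; boolean True = RB.

    Without costs: majority class, ties to NRB. With costs: minimum expected
    misclassification cost — predict RB iff (1-p)*cost(NRB as RB) is
    strictly below p*cost(RB as NRB).
    """
    p_rb = np.asarray(p_rb, dtype=float)
    if cost is None:
        return p_rb > 0.5
    return (1.0 - p_rb) * cost.nrb_as_rb < p_rb * cost.rb_as_nrb


def predict_tree(
    tree: DecisionTree, X: np.ndarray, cost: CostMatrix | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Predict (boolean RB indicator, leaf P(RB)) for each sample."""
    proba = leaf_proba(tree, X)
    return decide(proba, cost), proba


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _node_to_dict(node: TreeNode, names: tuple[str, ...] | None) -> dict:
    if node.is_leaf:
        return {"leaf": {"w_rb": node.w_rb, "w_nrb": node.w_nrb, "n": node.n}}
    return {
        "split": {
            "feature": int(node.feature),
            "name": names[node.feature] if names else None,
            "threshold": node.threshold,
            "w_rb": node.w_rb,
            "w_nrb": node.w_nrb,
            "n": node.n,
            "left": _node_to_dict(node.left, names),
            "right": _node_to_dict(node.right, names),
        }
    }


def _node_from_dict(d: dict) -> TreeNode:
    if "leaf" in d:
        leaf = d["leaf"]
        return TreeNode(w_rb=leaf["w_rb"], w_nrb=leaf["w_nrb"], n=leaf["n"])
    s = d["split"]
    return TreeNode(
        w_rb=s["w_rb"],
        w_nrb=s["w_nrb"],
        n=s["n"],
        feature=s["feature"],
        threshold=s["threshold"],
        left=_node_from_dict(s["left"]),
        right=_node_from_dict(s["right"]),
    )


def tree_to_dict(tree: DecisionTree) -> dict:
    return {
        "criterion": tree.criterion,
        "chsize": tree.chsize,
        "pseverity": tree.pseverity,
        "feature_names": list(tree.feature_names) if tree.feature_names else None,
        "root": _node_to_dict(tree.root, tree.feature_names),
    }


def tree_from_dict(d: dict) -> DecisionTree:
    return DecisionTree(
        root=_node_from_dict(d["root"]),
        criterion=d["criterion"],
        chsize=d["chsize"],
        pseverity=d.get("pseverity"),
        feature_names=tuple(d["feature_names"]) if d.get("feature_names") else None,
    )


def tree_to_json(tree: DecisionTree) -> str:
    return json.dumps(tree_to_dict(tree), indent=1)


def tree_from_json(s: str) -> DecisionTree:
    return tree_from_dict(json.loads(s))
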
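"""Balanced random-trees ensemble with OOB error and permutation importance.

The model handles 2:1 class imbalance at the data level: each tree's
bootstrap draws m samples with replacement from the minority RB class
(m = minority class size) and then m from the majority NRB class, so every
in-bag sample is perfectly class-balanced (2m draws in total). Trees are
grown unpruned to maximum depth under the CART/Gini regime, with a fresh
uniform random subset of ``nfeature`` candidate features at every node.

Prediction is by majority vote; the RB vote fraction doubles as the ROC
score. Each tree's out-of-bag (OOB) samples — training rows never drawn
into its bootstrap — provide an internal error estimate and the basis of
permutation importance: a feature's importance is the mean over trees of
the rise in OOB error when that feature's column is randomly permuted.

The API follows the fitted-model convention: construct
``BalancedRandomTrees(train, ...)`` with the data and hyperparameters, call
``.fit(seed)``, and read estimates off the returned ``RandomTreesResults``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatable import NRB, RB, DescriptorTable
from .tree import DecisionTree, grow_tree, leaf_proba, tree_from_dict, tree_to_dict


class ForestError(ValueError):
    pass


def balanced_bootstrap(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Balanced in-bag index multiset: m minority draws then m majority draws.

    m is the minority class size; both blocks are drawn with replacement, so
    the in-bag multiset has exactly m draws of each class (2m in total).
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ForestError("balanced bootstrap requires both classes")
    # minority first; ties resolve to RB (the positive class)
    if counts[0] == counts[1]:
        minority = RB
    else:
        minority = classes[np.argmin(counts)]
    m = int(np.min(counts))
    idx_min = np.flatnonzero(labels == minority)
    idx_maj = np.flatnonzero(labels != minority)
    draws_min = rng.choice(idx_min, size=m, replace=True)
    draws_maj = rng.choice(idx_maj, size=m, replace=True)
    return np.concatenate([draws_min, draws_maj])


def plain_bootstrap(n: int, rng: np.random.Generator) -> np.ndarray:
    """Conventional N-draw bootstrap over all training indices."""
    return rng.choice(n, size=n, replace=True)


@dataclass
class BalancedRandomTrees:
    """Random-trees model specification bound to a training table.

    Parameters
    ----------
    train : DescriptorTable
        Training data; both classes must be present.
    ntree : int
        Number of trees (default 200).
    nfeature : int or None
        Candidate features drawn at each node; None means round(sqrt(p)),
        which is 7 for the canonical 41-descriptor table.
    balanced : bool
        Balanced per-class bootstraps (True) or plain N-draw bootstraps.
    """

    train: DescriptorTable
    ntree: int = 200
    nfeature: int | None = None
    balanced: bool = True

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ForestError("ntree must be >= 1")
        n_rb, n_nrb = self.train.class_counts()
        if n_rb == 0 or n_nrb == 0:
            raise ForestError("training data must contain both classes")
        if self.nfeature is None:
            self.nfeature = max(int(round(np.sqrt(self.train.p))), 1)
        if not (1 <= self.nfeature <= self.train.p):
            raise ForestError("nfeature must be in [1, p]")

    def fit(self, seed: int) -> "RandomTreesResults":
        """Grow the ensemble deterministically from an integer seed."""
        X = self.train.values
        labels = self.train.labels
        y = self.train.y
        n = self.train.n
        root = np.random.SeedSequence(seed)
        trees: list[DecisionTree] = []
        inbag: list[np.ndarray] = []
        oob: list[np.ndarray] = []
        for child in root.spawn(self.ntree):
            rng = np.random.default_rng(child)
            if self.balanced:
                bag = balanced_bootstrap(labels, rng)
            else:
                bag = plain_bootstrap(n, rng)
            counts = np.bincount(bag, minlength=n)
            tree = grow_tree(
                X[bag],
                y[bag],
                criterion="gini",
                chsize=1,
                nfeature=self.nfeature,
                rng=rng,
                feature_names=self.train.schema.names,
            )
            trees.append(tree)
            inbag.append(bag)
            oob.append(np.flatnonzero(counts == 0))
        return RandomTreesResults(
            model=self, seed=seed, trees=trees, inbag=inbag, oob=oob
        )


@dataclass
class RandomTreesResults:
    """Fitted random-trees ensemble: trees, bags, votes and diagnostics."""

    model: BalancedRandomTrees
    seed: int
    trees: list[DecisionTree]
    inbag: list[np.ndarray]
    oob: list[np.ndarray]

    @property
    def ntree(self) -> int:
        return len(self.trees)

    # -- voting ------------------------------------------------------------

    def _tree_votes(self, X: np.ndarray) -> np.ndarray:
        """(ntree, n) boolean matrix of per-tree RB votes."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.stack([leaf_proba(t, X) > 0.5 for t in self.trees])

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        """RB vote fraction per sample (the ROC score), on {0..ntree}/ntree."""
        return self._tree_votes(X).mean(axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Majority-vote labels; exact ties go to the majority class NRB."""
        score = self.predict_score(X)
        return np.where(score > 0.5, RB, NRB)

    def predict_table(self, table: DescriptorTable) -> np.ndarray:
        return self.predict(table.values)

    # -- out-of-bag diagnostics --------------------------------------------

    def oob_votes(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample (RB OOB votes, total OOB votes) over the training set."""
        n = self.model.train.n
        rb = np.zeros(n)
        tot = np.zeros(n)
        X = self.model.train.values
        for tree, idx in zip(self.trees, self.oob):
            if idx.size == 0:
                continue
            votes = leaf_proba(tree, X[idx]) > 0.5
            rb[idx] += votes
            tot[idx] += 1
        return rb, tot

    def oob_error(self) -> float:
        """Misclassification rate of OOB majority votes on the training set.

        Samples that are OOB for no tree are excluded with a warning.
        """
        rb, tot = self.oob_votes()
        covered = tot > 0
        if not covered.any():
            raise ForestError("no training sample is OOB for any tree")
        if not covered.all():
            warnings.warn(
                f"{int((~covered).sum())} samples are in-bag for every tree "
                "and are excluded from the OOB error",
                stacklevel=2,
            )
        pred_rb = rb[covered] > tot[covered] / 2.0  # tie -> NRB
        truth_rb = self.model.train.y[covered]
        return float(np.mean(pred_rb != truth_rb))

    def _tree_oob_error(self, tree: DecisionTree, idx: np.ndarray, X: np.ndarray) -> float:
        votes = leaf_proba(tree, X[idx]) > 0.5
        return float(np.mean(votes != self.model.train.y[idx]))

    def permutation_importance(self) -> pd.DataFrame:
        """Mean per-tree OOB error increase when each feature is permuted.

        For tree j and feature x, the feature's column is randomly permuted
        within tree j's OOB rows (all other features fixed) and the OOB
        error re-measured; importance(x) = mean_j(PermutedErr_jx - RealErr_j).
        The permutation RNG stream is derived from (seed, tree, feature) so
        results are reproducible and independent of evaluation order.
        """
        X = self.model.train.values
        p = self.model.train.p
        deltas = np.zeros((self.ntree, p))
        for j, (tree, idx) in enumerate(zip(self.trees, self.oob)):
            if idx.size == 0:
                continue
            real = self._tree_oob_error(tree, idx, X)
            Xo = X[idx]
            for f in range(p):
                rng = np.random.default_rng(
                    np.random.SeedSequence([self.seed, j, f])
                )
                Xp = Xo.copy()
                Xp[:, f] = Xo[rng.permutation(idx.size), f]
                votes = leaf_proba(tree, Xp) > 0.5
                perm = float(np.mean(votes != self.model.train.y[idx]))
                deltas[j, f] = perm - real
        imp = deltas.mean(axis=0)
        df = pd.DataFrame(
            {
                "feature": self.model.train.schema.names,
                "kind": self.model.train.schema.kinds,
                "importance": imp,
            }
        )
        return df.sort_values(
            "importance", ascending=False, kind="stable"
        ).reset_index(drop=True)

    # -- reporting / persistence -------------------------------------------

    def summary(self) -> str:
        n_rb, n_nrb = self.model.train.class_counts()
        lines = [
            "Balanced random trees" if self.model.balanced else "Random trees",
            f"  trees:        {self.ntree}",
            f"  nfeature:     {self.model.nfeature}",
            f"  training:     {self.model.train.n} samples "
            f"({n_rb} RB / {n_nrb} NRB)",
            f"  seed:         {self.seed}",
            f"  OOB error:    {self.oob_error():.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kind": "random_trees",
            "params": {
                "ntree": self.ntree,
                "nfeature": self.model.nfeature,
                "balanced": self.model.balanced,
                "seed": self.seed,
            },
            "inbag": [b.tolist() for b in self.inbag],
            "trees": [tree_to_dict(t) for t in self.trees],
        }
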
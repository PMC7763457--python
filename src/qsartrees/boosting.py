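"""Cost-sensitive boosted C5.0-style decision-tree ensemble.

Boosting follows the classic sequential-reweighting scheme: trees are grown
one trial at a time on normalized sample weights; after each trial the
weighted error rate eps_t determines the stage factor beta_t = eps_t /
(1 - eps_t), weights of correctly classified samples are multiplied by
beta_t (shifting mass onto the errors) and renormalized. A trial with
eps_t = 0 is kept and boosting stops; a trial with eps_t >= 0.5 is
discarded and boosting stops. The fitted committee votes with weight
1/beta_t per stage and the class with the highest vote total wins.

Each trial's tree is grown in the C5.0 regime (gain-ratio splits, child
size floor ``chsize``) and pessimistically pruned at severity ``pseverity``.

Cost-sensitivity enters at two switchable points: the initial sample
weights are made proportional to the misclassification cost of each
sample's true class (data level), and leaf decisions minimize expected
misclassification cost instead of error (algorithm level). With the 2:1
RB-vs-NRB cost matrix both mechanisms push the ensemble toward recovering
minority RB samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatable import NRB, RB, DescriptorTable
from .tree import (
    CostMatrix,
    DecisionTree,
    decide,
    grow_tree,
    leaf_proba,
    prune_tree,
    tree_to_dict,
)

#: recorded beta for a perfect (eps = 0) stage so the 1/beta vote weight is
#: finite and dominates every imperfect stage
BETA_FLOOR = 1e-10


class BoostingError(ValueError):
    pass


def apply_cost_weights(labels: np.ndarray, cost: CostMatrix) -> np.ndarray:
    """Initial sample weights proportional to each true class's
    misclassification cost, normalized to sum 1.

    A unit cost matrix reduces to the uniform 1/N initialization.
    """
    labels = np.asarray(labels)
    w = np.where(labels == RB, cost.rb_as_nrb, cost.nrb_as_rb).astype(float)
    total = w.sum()
    if total <= 0:
        raise BoostingError("cost weights sum to zero")
    return w / total


@dataclass
class BoostedC5:
    """Boosted C5.0 model specification bound to a training table.

    Parameters
    ----------
    train : DescriptorTable
    trials : int
        Maximum number of boosting trials T (default 10, the common value).
    chsize : int
        Minimum samples per child branch (default 2).
    pseverity : float
        Pruning severity percentage in [0, 100) (default 75, i.e. CF=0.25).
    cost : CostMatrix or None
        Misclassification costs; None fits the plain boosted model.
    cost_data_level, cost_algorithm_level : bool
        Enable the two cost-injection points independently (both on by
        default when a cost matrix is given); useful for ablation.
    """

    train: DescriptorTable
    trials: int = 10
    chsize: int = 2
    pseverity: float = 75.0
    cost: CostMatrix | None = None
    cost_data_level: bool = True
    cost_algorithm_level: bool = True

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise BoostingError("trials must be >= 1")
        if self.chsize < 1:
            raise BoostingError("chsize must be >= 1")
        if not (0.0 <= self.pseverity < 100.0):
            raise BoostingError("pseverity must be in [0, 100)")
        n_rb, n_nrb = self.train.class_counts()
        if n_rb == 0 or n_nrb == 0:
            raise BoostingError("training data must contain both classes")

    @property
    def _leaf_cost(self) -> CostMatrix | None:
        return self.cost if (self.cost and self.cost_algorithm_level) else None

    def fit(self, seed: int = 0) -> "BoostedC5Results":
        """Run the boosting trial loop; deterministic (seed kept for API
        symmetry and recorded in the results)."""
        X = self.train.values
        y = self.train.y
        n = self.train.n
        if self.cost is not None and self.cost_data_level:
            F = apply_cost_weights(self.train.labels, self.cost)
        else:
            F = np.full(n, 1.0 / n)

        stages: list[tuple[DecisionTree, float]] = []
        history: list[dict] = []
        for t in range(self.trials):
            tree = grow_tree(
                X,
                y,
                w=F * n,  # count-scale weights; trial 1 is one count per sample
                criterion="gain_ratio",
                chsize=self.chsize,
                feature_names=self.train.schema.names,
            )
            tree = prune_tree(tree, self.pseverity)
            pred, _ = _stage_votes(tree, X, self._leaf_cost)
            miss = pred != y
            eps = float(F[miss].sum())
            history.append(
                {"trial": t + 1, "epsilon": eps, "weight_sum": float(F.sum())}
            )
            if eps <= 0.0:
                stages.append((tree, BETA_FLOOR))
                break
            if eps >= 0.5:
                if not stages:
                    warnings.warn(
                        f"first boosting trial has weighted error {eps:.3f} "
                        ">= 0.5; falling back to the single tree",
                        stacklevel=2,
                    )
                    stages.append((tree, 1.0))
                break  # discard this trial's tree and stop
            beta = eps / (1.0 - eps)
            stages.append((tree, beta))
            F = F.copy()
            F[~miss] *= beta
            F /= F.sum()
        return BoostedC5Results(
            model=self, seed=seed, stages=stages, history=history
        )


def _stage_votes(
    tree: DecisionTree, X: np.ndarray, cost: CostMatrix | None
) -> tuple[np.ndarray, np.ndarray]:
    proba = leaf_proba(tree, X)
    return decide(proba, cost), proba


@dataclass
class BoostedC5Results:
    """Fitted boosted committee: ordered (tree, beta) stages."""

    model: BoostedC5
    seed: int
    stages: list[tuple[DecisionTree, float]]
    history: list[dict]

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def betas(self) -> np.ndarray:
        return np.array([b for _, b in self.stages])

    def vote_totals(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(RB vote total, NRB vote total) per sample; stage weight 1/beta."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        rb = np.zeros(len(X))
        nrb = np.zeros(len(X))
        cost = self.model._leaf_cost
        for tree, beta in self.stages:
            w = 1.0 / beta
            votes, _ = _stage_votes(tree, X, cost)
            rb += w * votes
            nrb += w * ~votes
        return rb, nrb

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        """RB share of the weighted vote total (the ROC score)."""
        rb, nrb = self.vote_totals(X)
        return rb / (rb + nrb)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Weighted-vote labels; exact ties go to the majority class NRB."""
        rb, nrb = self.vote_totals(X)
        return np.where(rb > nrb, RB, NRB)

    def predict_table(self, table: DescriptorTable) -> np.ndarray:
        return self.predict(table.values)

    def summary(self) -> str:
        n_rb, n_nrb = self.model.train.class_counts()
        cost = self.model.cost
        lines = [
            "Boosted C5.0 decision trees"
            + (" (cost-sensitive)" if cost else ""),
            f"  stages:       {self.n_stages} (max trials "
            f"{self.model.trials})",
            f"  chsize:       {self.model.chsize}",
            f"  pSeverity:    {self.model.pseverity:g} "
            f"(CF={1 - self.model.pseverity / 100.0:g})",
        ]
        if cost:
            lines.append(
                f"  cost:         RB as NRB = {cost.rb_as_nrb:g}, "
                f"NRB as RB = {cost.nrb_as_rb:g}"
            )
        lines.append(
            f"  training:     {self.model.train.n} samples "
            f"({n_rb} RB / {n_nrb} NRB)"
        )
        for h, (tree, beta) in zip(self.history, self.stages):
            lines.append(
                f"  trial {h['trial']:2d}: eps={h['epsilon']:.4f} "
                f"beta={beta:.4g} nodes={tree.count_nodes()}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kind": "boosted_c5",
            "params": {
                "trials": self.model.trials,
                "chsize": self.model.chsize,
                "pseverity": self.model.pseverity,
                "cost": (
                    {
                        "rb_as_nrb": self.model.cost.rb_as_nrb,
                        "nrb_as_rb": self.model.cost.nrb_as_rb,
                    }
                    if self.model.cost
                    else None
                ),
                "seed": self.seed,
            },
            "stages": [
                {"beta": beta, "tree": tree_to_dict(tree)}
                for tree, beta in self.stages
            ],
        }
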
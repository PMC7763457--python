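"""End-to-end orchestration: screen, train both ensembles, evaluate, rank.

``run_pipeline`` takes a :class:`PipelineConfig` (built directly or read
from a YAML file) naming either delimited train/test descriptor files or a
synthetic generation request, and writes a report bundle under the output
directory: the screening ranking, both serialized models, a two-row metrics
table in the standard column order, per-model ROC point files, and the
top-10 permutation-importance ranking. Every RNG seed used is logged so any
stage can be replayed in isolation.

``grid_search_c5`` tunes (chsize, pSeverity) for the boosted model by
stratified k-fold cross-validated F1 on the training split — F1 because it
balances precision against minority-class recall, the failure mode that
matters under 2:1 imbalance.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .boosting import BoostedC5
from .datatable import DescriptorTable, read_descriptor_table, write_descriptor_table
from .evaluation import MetricsReport, evaluate, metrics_table, roc_curve
from .forest import BalancedRandomTrees
from .screening import rank_importance
from .synthetic import make_paper_like
from .tree import CostMatrix

log = logging.getLogger("qsartrees")


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Configuration of one full pipeline run.

    Exactly one of (``train_path`` + ``test_path``) or ``synthetic`` must be
    given. ``synthetic`` currently selects the paper-like generator.
    """

    seed: int
    out_dir: str
    train_path: str | None = None
    test_path: str | None = None
    synthetic: bool = False
    delimiter: str = ";"
    ntree: int = 200
    nfeature: int | None = None
    balanced: bool = True
    trials: int = 10
    chsize: int = 2
    pseverity: float = 75.0
    cost_rb_as_nrb: float = 2.0
    cost_nrb_as_rb: float = 1.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        have_files = self.train_path is not None or self.test_path is not None
        if have_files and self.synthetic:
            raise PipelineError("give either input paths or a synthetic spec, not both")
        if not have_files and not self.synthetic:
            raise PipelineError("one of input paths or synthetic spec is required")
        if have_files and (self.train_path is None or self.test_path is None):
            raise PipelineError("both train_path and test_path are required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _load_splits(cfg: PipelineConfig) -> tuple[DescriptorTable, DescriptorTable]:
    if cfg.synthetic:
        log.info("generating paper-like synthetic splits (seed=%d)", cfg.seed)
        return make_paper_like(cfg.seed)
    log.info("reading train=%s test=%s", cfg.train_path, cfg.test_path)
    train = read_descriptor_table(cfg.train_path, delimiter=cfg.delimiter)
    test = read_descriptor_table(
        cfg.test_path, schema=train.schema, delimiter=cfg.delimiter
    )
    return train, test


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute screen -> train -> evaluate -> rank; return the bundle index."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        train, test = _load_splits(cfg)
    except Exception as exc:  # noqa: BLE001 - stage-named abort
        raise PipelineError(f"data stage failed: {exc}") from exc

    bundle: dict[str, str] = {}
    if cfg.synthetic:
        write_descriptor_table(train, out / "train.csv", delimiter=cfg.delimiter)
        write_descriptor_table(test, out / "test.csv", delimiter=cfg.delimiter)
        bundle["train"] = "train.csv"
        bundle["test"] = "test.csv"

    try:
        screening = rank_importance(train)
    except Exception as exc:
        raise PipelineError(f"screening stage failed: {exc}") from exc
    screening.to_csv(out / "screening.csv", sep=";", index=False)
    bundle["screening"] = "screening.csv"
    log.info("screening: top feature %s", screening.iloc[0]["feature"])

    try:
        rt_seed = cfg.seed
        log.info("training random trees (ntree=%d, seed=%d)", cfg.ntree, rt_seed)
        rt = BalancedRandomTrees(
            train, ntree=cfg.ntree, nfeature=cfg.nfeature, balanced=cfg.balanced
        ).fit(rt_seed)
        cost = CostMatrix(cfg.cost_rb_as_nrb, cfg.cost_nrb_as_rb)
        c5_seed = cfg.seed + 1
        log.info(
            "training boosted C5.0 (trials=%d, chsize=%d, pseverity=%g, seed=%d)",
            cfg.trials,
            cfg.chsize,
            cfg.pseverity,
            c5_seed,
        )
        c5 = BoostedC5(
            train,
            trials=cfg.trials,
            chsize=cfg.chsize,
            pseverity=cfg.pseverity,
            cost=cost,
        ).fit(c5_seed)
    except Exception as exc:
        raise PipelineError(f"modeling stage failed: {exc}") from exc

    (out / "rt_model.json").write_text(json.dumps(rt.to_dict()))
    (out / "c5_model.json").write_text(json.dumps(c5.to_dict()))
    bundle["rt_model"] = "rt_model.json"
    bundle["c5_model"] = "c5_model.json"

    try:
        reports: dict[str, MetricsReport] = {}
        rt_name = "Balanced RTs" if cfg.balanced else "RTs"
        for name, res in ((rt_name, rt), ("Boosted C5.0 (cost)", c5)):
            pred = res.predict_table(test)
            reports[name] = evaluate(pred, test.labels)
            roc = roc_curve(res.predict_score(test.values), test.labels)
            fname = f"roc_{'rt' if res is rt else 'c5'}.csv"
            roc.as_frame().to_csv(out / fname, sep=";", index=False)
            bundle[fname.removesuffix('.csv')] = fname
            reports_auroc = roc.auroc
            log.info("%s: AUROC %.4f", name, reports_auroc)
        table = metrics_table(reports)
        table.to_csv(out / "metrics.csv", sep=";")
        bundle["metrics"] = "metrics.csv"
    except Exception as exc:
        raise PipelineError(f"evaluation stage failed: {exc}") from exc

    try:
        importance = rt.permutation_importance().head(10)
    except Exception as exc:
        raise PipelineError(f"importance stage failed: {exc}") from exc
    importance.to_csv(out / "importance_top10.csv", sep=";", index=False)
    bundle["importance"] = "importance_top10.csv"

    (out / "bundle.json").write_text(json.dumps(bundle, indent=1))
    return bundle


def stratified_folds(
    labels: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Class-stratified k-fold partition of row indices."""
    labels = np.asarray(labels)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(int(j))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def grid_search_c5(
    train: DescriptorTable,
    chsize_grid: list[int],
    pseverity_grid: list[float],
    folds: int = 5,
    seed: int = 0,
    cost: CostMatrix | None = None,
    trials: int = 10,
) -> tuple[int, float, float]:
    """Cross-validated (chsize, pSeverity) selection by mean F1.

    Returns (best chsize, best pSeverity, its mean CV F1). Ties break toward
    smaller chsize, then larger pSeverity (the more regularized setting).
    """
    if not chsize_grid or not pseverity_grid:
        raise PipelineError("grid must be nonempty")
    if folds < 2:
        raise PipelineError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    parts = stratified_folds(train.labels, folds, rng)
    for f in parts:
        if np.unique(train.labels[f]).size < 2:
            raise PipelineError(
                "a fold lost one class entirely; use fewer folds"
            )
    best: tuple[float, int, float] | None = None  # (f1, chsize, pseverity)
    for ch, ps in itertools.product(sorted(chsize_grid), sorted(pseverity_grid)):
        scores = []
        for i, hold in enumerate(parts):
            keep = np.sort(
                np.concatenate([parts[j] for j in range(folds) if j != i])
            )
            model = BoostedC5(
                train.subset(keep),
                trials=trials,
                chsize=ch,
                pseverity=ps,
                cost=cost,
            ).fit(seed)
            pred = model.predict_table(train.subset(hold))
            scores.append(evaluate(pred, train.labels[hold]).f1)
        mean_f1 = float(np.mean(scores))
        log.debug("grid chsize=%d pseverity=%g f1=%.4f", ch, ps, mean_f1)
        if (
            best is None
            or mean_f1 > best[0] + 1e-12
            or (
                abs(mean_f1 - best[0]) <= 1e-12
                and (ch < best[1] or (ch == best[1] and ps > best[2]))
            )
        ):
            best = (mean_f1, ch, ps)
    return best[1], best[2], best[0]
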
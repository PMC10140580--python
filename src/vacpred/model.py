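"""Random-forest training, grid search and 10-fold cross-validated evaluation.

Reports AUROC, accuracy, AUPRC and PPV per fold and as mean +/- variance,
plus an impurity-based feature-importance ranking averaged across folds.
Two evaluation modes exist: ``pooled`` applies a label-using selection step
once on all data before cross-validation, and ``nested`` (the default)
refits the selection step inside every training fold so no test-fold label
information reaches it. The report records which mode ran.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping

import json
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    precision_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

METRICS = ("auroc", "accuracy", "auprc", "ppv")


@dataclass
class ModelConfig:
    """Random-forest and cross-validation settings."""

    n_trees: int = 500
    max_depth: int | None = 9
    max_features_rule: str = "sqrt"  # sqrt | log2 | all
    split_criterion: str = "gini"
    grid: Mapping[str, list] | None = None
    k: int = 10
    seed: int = 0
    ppv_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_features_rule not in ("sqrt", "log2", "all"):
            raise ValueError("max_features_rule must be sqrt|log2|all")
        if self.split_criterion not in ("gini", "entropy"):
            raise ValueError("split_criterion must be gini|entropy")

    def make_forest(self, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            criterion=self.split_criterion,
            max_features={"sqrt": "sqrt", "log2": "log2", "all": None}[
                self.max_features_rule
            ],
            random_state=seed,
            n_jobs=1,
        )


@dataclass
class CvReport:
    """Per-fold and aggregate cross-validation metrics."""

    per_fold: dict[str, list[float]]
    mean: dict[str, float]
    variance: dict[str, float]
    importance_ranking: list[tuple[str, float]]
    mode: str
    k: int
    n_samples: int
    top_k: int = 15
    selected_per_fold: list[list[str]] = field(default_factory=list)

    @property
    def top_features(self) -> list[tuple[str, float]]:
        return self.importance_ranking[: self.top_k]

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "k": self.k,
            "n_samples": self.n_samples,
            "per_fold": {m: list(v) for m, v in self.per_fold.items()},
            "mean": dict(self.mean),
            "variance": dict(self.variance),
            "importance_ranking": [
                {"feature": f, "importance": w} for f, w in self.importance_ranking
            ],
            "top_features": [
                {"feature": f, "importance": w} for f, w in self.top_features
            ],
            "selected_per_fold": [list(s) for s in self.selected_per_fold],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _check_labels(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")


def crossval_evaluate(
    matrix: pd.DataFrame,
    labels,
    config: ModelConfig = ModelConfig(),
    selector=None,
    mode: str = "nested",
) -> CvReport:
    """Stratified k-fold evaluation of the random forest.

    ``selector`` is an optional unfitted sklearn transformer (e.g. a
    pipeline of :class:`~vacpred.select.CorrelationPruner` and
    :class:`~vacpred.select.ForwardSelector`). In ``nested`` mode it is
    cloned and fit on each training fold; in ``pooled`` mode it is fit once
    on the full data before splitting (the order of operations the original
    analysis describes, which leaks selection information into CV).
    """
    y = np.asarray(labels, dtype=int).ravel()
    _check_labels(y)
    if len(y) < config.k:
        raise ValueError("need at least k samples")
    if mode not in ("nested", "pooled"):
        raise ValueError("mode must be 'nested' or 'pooled'")
    X = matrix

    pooled_empty = False
    if selector is not None and mode == "pooled":
        pooled = clone(selector).fit(X, y).transform(X)
        if pooled.shape[1] > 0:
            X = pooled
        else:
            pooled_empty = True

    skf = StratifiedKFold(n_splits=config.k, shuffle=True, random_state=config.seed)
    per_fold: dict[str, list[float]] = {m: [] for m in METRICS}
    importance_sum: dict[str, float] = {}
    selected_per_fold: list[list[str]] = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        Xtr, Xte = X.iloc[tr], X.iloc[te]
        ytr, yte = y[tr], y[te]
        if len(np.unique(yte)) < 2 or len(np.unique(ytr)) < 2:
            raise ValueError("a fold is missing one of the classes")
        if selector is not None and mode == "nested":
            sel = clone(selector).fit(Xtr, ytr)
            Xtr_s, Xte_s = sel.transform(Xtr), sel.transform(Xte)
        else:
            Xtr_s, Xte_s = Xtr, Xte
        if pooled_empty or Xtr_s.shape[1] == 0:
            # selection retained nothing: the honest model is the intercept-
            # only predictor (training prevalence), i.e. chance discrimination
            selected_per_fold.append([])
            proba = np.full(len(te), float(ytr.mean()))
        else:
            selected_per_fold.append([str(c) for c in Xtr_s.columns])
            forest = config.make_forest(
                seed=(config.seed * 1009 + fold) % (2**31 - 1)
            )
            forest.fit(Xtr_s, ytr)
            proba = forest.predict_proba(Xte_s)[:, 1]
            for name, imp in zip(Xtr_s.columns, forest.feature_importances_):
                importance_sum[str(name)] = (
                    importance_sum.get(str(name), 0.0) + float(imp)
                )
        pred = (proba >= config.ppv_threshold).astype(int)
        per_fold["auroc"].append(float(roc_auc_score(yte, proba)))
        per_fold["accuracy"].append(float(accuracy_score(yte, pred)))
        per_fold["auprc"].append(float(average_precision_score(yte, proba)))
        per_fold["ppv"].append(
            float(precision_score(yte, pred, zero_division=0.0))
        )

    total = sum(importance_sum.values())
    if total > 0:
        ranking = sorted(
            ((f, w / total) for f, w in importance_sum.items()),
            key=lambda kv: (-kv[1], kv[0]),
        )
    else:
        ranking = sorted((f, 0.0) for f in importance_sum)
    return CvReport(
        per_fold=per_fold,
        mean={m: float(np.mean(v)) for m, v in per_fold.items()},
        variance={m: float(np.var(v, ddof=1)) for m, v in per_fold.items()},
        importance_ranking=ranking,
        mode=mode if selector is not None else "no-selection",
        k=config.k,
        n_samples=len(y),
        selected_per_fold=selected_per_fold,
    )


def grid_search(
    matrix: pd.DataFrame,
    labels,
    config: ModelConfig = ModelConfig(),
) -> tuple[dict, pd.DataFrame]:
    """Evaluate every grid point by k-fold mean AUROC with shared folds.

    Ties are broken toward fewer trees, then shallower depth. Returns the
    best hyperparameters and the full search table.
    """
    y = np.asarray(labels, dtype=int).ravel()
    _check_labels(y)
    grid = dict(config.grid) if config.grid else {
        "n_trees": [config.n_trees],
        "max_depth": [config.max_depth],
    }
    if not grid:
        raise ValueError("grid must be non-empty")
    keys = sorted(grid)
    rows = []
    for combo in product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        cfg = ModelConfig(
            n_trees=params.get("n_trees", config.n_trees),
            max_depth=params.get("max_depth", config.max_depth),
            max_features_rule=params.get("max_features_rule", config.max_features_rule),
            split_criterion=params.get("split_criterion", config.split_criterion),
            k=config.k,
            seed=config.seed,  # shared fold assignment across grid points
            ppv_threshold=config.ppv_threshold,
        )
        report = crossval_evaluate(matrix, y, cfg)
        rows.append({**params, "mean_auroc": report.mean["auroc"]})
    table = pd.DataFrame(rows)
    ordered = sorted(
        rows,
        key=lambda r: (
            -r["mean_auroc"],
            r.get("n_trees", config.n_trees),
            r.get("max_depth") or np.inf,
        ),
    )
    best = {k: v for k, v in ordered[0].items() if k != "mean_auroc"}
    return best, table


def feature_importance(
    reports: "CvReport | list[CvReport]", top_k: int = 15
) -> list[tuple[str, float]]:
    """Merged, re-normalised importance ranking across one or more reports."""
    if isinstance(reports, CvReport):
        reports = [reports]
    if not reports:
        raise ValueError("at least one fitted report is required")
    merged: dict[str, float] = {}
    for rep in reports:
        for f, w in rep.importance_ranking:
            merged[f] = merged.get(f, 0.0) + w
    total = sum(merged.values())
    if total > 0:
        merged = {f: w / total for f, w in merged.items()}
    return sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
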
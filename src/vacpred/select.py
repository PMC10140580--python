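"""Feature reduction: correlation pruning and forward stepwise selection.

Both steps are scikit-learn estimators so they compose with pipelines and
can be cloned and refit inside cross-validation folds (the leakage-safe
nested mode of the model stage).

* :class:`CorrelationPruner` walks columns in name order and drops any
  column whose absolute Pearson correlation with an earlier retained column
  is strictly greater than the threshold, so the surviving matrix has
  maximum pairwise ``|r|`` at or below it.
* :class:`ForwardSelector` greedily adds the candidate with the smallest
  likelihood-ratio p-value against the current logistic model. The stopping
  level ``alpha`` is applied per step to the whole candidate family
  (Bonferroni, the default): with hundreds of candidates, the raw smallest
  p-value is small by chance alone, and the corrected rule keeps the
  expected number of false selections at the nominal level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator, TransformerMixin

from ._logistic import batched_candidate_loglik, fit_logistic

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    """Knobs of the reduction stage."""

    corr_threshold: float = 0.95
    alpha: float = 0.05
    max_features: int | None = None
    correction: str = "bonferroni"  # or "none" for the raw per-candidate rule
    seed: int = 0  # selection is deterministic; kept for interface stability

    def __post_init__(self) -> None:
        if not 0.0 < self.corr_threshold < 1.0:
            raise ValueError("corr_threshold must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError("correction must be 'bonferroni' or 'none'")


@dataclass
class SelectionReport:
    """What was removed, what was chosen and in which order."""

    removed_by_correlation: list[str] = field(default_factory=list)
    selection_order: list[tuple[str, float]] = field(default_factory=list)
    final_features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "removed_by_correlation": list(self.removed_by_correlation),
            "selection_order": [
                {"feature": f, "p_value": p} for f, p in self.selection_order
            ],
            "final_features": list(self.final_features),
        }


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(X, columns=[f"x{i:04d}" for i in range(X.shape[1])])


class CorrelationPruner(BaseEstimator, TransformerMixin):
    """Drop features with absolute Pearson correlation strictly above the
    threshold against an earlier retained feature (name order).

    Zero-variance columns have undefined correlations; they are retained
    with a logged notice.
    """

    def __init__(self, threshold: float = 0.95):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = _as_frame(X)
        names = sorted(map(str, X.columns))
        values = X[names].to_numpy(float)
        sd = values.std(axis=0)
        constant = sd == 0
        if constant.any():
            logger.info(
                "correlation pruning: %d zero-variance columns retained "
                "(correlation undefined)", int(constant.sum()),
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(values, rowvar=False)
        corr = np.abs(np.nan_to_num(corr, nan=0.0))
        retained_idx: list[int] = []
        dropped: list[str] = []
        for j in range(len(names)):
            if retained_idx and np.max(corr[j, retained_idx]) > self.threshold:
                dropped.append(names[j])
            else:
                retained_idx.append(j)
        retained = {names[j] for j in retained_idx}
        self.feature_names_in_ = np.asarray(list(map(str, X.columns)))
        self.retained_ = [c for c in map(str, X.columns) if c in retained]
        self.dropped_ = dropped
        return self

    def transform(self, X):
        X = _as_frame(X)
        return X[self.retained_]


class ForwardSelector(BaseEstimator, TransformerMixin):
    """Greedy forward stepwise selection by likelihood-ratio p-values.

    At each step every unselected candidate is scored by the LR test of the
    logistic model (selected + candidate) against (selected); the best
    candidate is added while its p-value clears the (per-step corrected)
    ``alpha`` level and ``max_features`` is not exceeded. Ties are broken by
    column name order. Deterministic given the inputs.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        max_features: int | None = None,
        correction: str = "bonferroni",
    ):
        self.alpha = alpha
        self.max_features = max_features
        self.correction = correction

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y, dtype=float).ravel()
        classes = np.unique(y)
        if not np.all(np.isin(classes, (0.0, 1.0))) or len(classes) != 2:
            raise ValueError("forward selection requires binary 0/1 labels")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError("correction must be 'bonferroni' or 'none'")
        names = sorted(map(str, X.columns))
        values = X[names].to_numpy(float)
        mean = values.mean(axis=0)
        sd = values.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (values - mean) / sd
        n = len(y)

        selected: list[int] = []
        order: list[tuple[str, float]] = []
        remaining = list(range(len(names)))
        while remaining:
            if self.max_features is not None and len(selected) >= self.max_features:
                break
            B = np.column_stack([np.ones(n)] + [Z[:, j] for j in selected])
            base_beta, base_llf, _ = fit_logistic(B, y)
            C = Z[:, remaining]
            llf, penalized = batched_candidate_loglik(B, C, y, base_beta)
            if penalized.any():
                logger.info(
                    "forward selection: %d candidate fits required the "
                    "separation penalty", int(penalized.sum()),
                )
            stat = np.maximum(2.0 * (llf - base_llf), 0.0)
            pvals = chi2.sf(stat, df=1)
            best = int(np.argmin(pvals))  # first minimum = name order tie-break
            level = self.alpha / len(remaining) if self.correction == "bonferroni" \
                else self.alpha
            if pvals[best] >= level:
                break
            j = remaining.pop(best)
            selected.append(j)
            order.append((names[j], float(pvals[best])))

        self.selected_features_ = [names[j] for j in selected]
        self.pvalues_ = [p for _, p in order]
        self.report_ = SelectionReport(
            removed_by_correlation=[],
            selection_order=order,
            final_features=list(self.selected_features_),
        )
        return self

    def transform(self, X):
        X = _as_frame(X)
        return X[self.selected_features_]


def correlation_filter(
    matrix: pd.DataFrame, threshold: float = 0.95
) -> tuple[pd.DataFrame, list[str]]:
    """Functional wrapper over :class:`CorrelationPruner`."""
    pruner = CorrelationPruner(threshold=threshold).fit(matrix)
    return pruner.transform(matrix), pruner.dropped_


def forward_selection(
    matrix: pd.DataFrame, labels, config: SelectionConfig = SelectionConfig()
) -> SelectionReport:
    """Correlation pruning followed by forward selection; returns the report."""
    reduced, removed = correlation_filter(matrix, config.corr_threshold)
    selector = ForwardSelector(
        alpha=config.alpha,
        max_features=config.max_features,
        correction=config.correction,
    ).fit(reduced, labels)
    report = selector.report_
    report.removed_by_correlation = removed
    return report
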
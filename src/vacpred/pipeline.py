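"""End-to-end pipeline: simulate -> preprocess -> label -> featurize ->
select -> train.

Detection runs on range-filtered PEEP/FiO2 so planted outliers cannot
create spurious daily minima. Low-frequency training means for imputation
are computed over the whole cohort; the label-using selection step is refit
inside each training fold in the default ``nested`` mode (see the model
module for the pooled alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from sklearn.pipeline import Pipeline

from . import features as feat_mod
from .model import CvReport, ModelConfig, crossval_evaluate
from .preprocess import (
    DEFAULT_RANGES,
    MissingnessPolicy,
    compute_training_means,
    drop_sparse_variables,
    filter_physiologic_range,
)
from .records import PatientRecord, PredictionSample, VacEvent
from .select import CorrelationPruner, ForwardSelector, SelectionConfig
from .synthetic import SimConfig, generate_cohort
from .vac import VacCriteria, build_samples, detect_vac


@dataclass
class PipelineResult:
    records: list[PatientRecord]
    events: list[VacEvent]
    samples: list[PredictionSample]
    matrix: pd.DataFrame
    labels: pd.Series
    removed_sparse: list[str]
    report: CvReport
    provenance: dict


def detect_events(
    records: list[PatientRecord], criteria: VacCriteria = VacCriteria()
) -> list[VacEvent]:
    """Range-filter the setting channels, then detect one VAC per stay."""
    events: list[VacEvent] = []
    for rec in records:
        peep = filter_physiologic_range(rec.channels["PEEP"].series, "PEEP",
                                        DEFAULT_RANGES)
        fio2 = filter_physiologic_range(rec.channels["FiO2"].series, "FiO2",
                                        DEFAULT_RANGES)
        events.extend(
            detect_vac(peep, fio2, criteria, rec.vent_start, rec.vent_end,
                       rec.patient_id)
        )
    return events


def build_selector(config: SelectionConfig) -> Pipeline:
    """Correlation pruning followed by forward selection, as one clonable
    transformer for nested cross-validation."""
    return Pipeline(
        [
            ("prune", CorrelationPruner(threshold=config.corr_threshold)),
            (
                "forward",
                ForwardSelector(
                    alpha=config.alpha,
                    max_features=config.max_features,
                    correction=config.correction,
                ),
            ),
        ]
    )


def run_pipeline(
    sim_config: SimConfig,
    selection_config: SelectionConfig | None = None,
    model_config: ModelConfig | None = None,
    criteria: VacCriteria = VacCriteria(),
    feature_mode: str = "manual",
    variables: tuple[str, ...] = feat_mod.PREDICTIVE_VARIABLES,
    mode: str = "nested",
) -> PipelineResult:
    """Run the full analysis on one synthetic cohort.

    All randomness derives from ``sim_config.seed``. Two calls with the same
    configuration produce identical feature matrices and reports.
    """
    if selection_config is None:
        selection_config = SelectionConfig(max_features=10)
    if model_config is None:
        model_config = ModelConfig(seed=sim_config.seed)

    records, _truth = generate_cohort(sim_config)
    events = detect_events(records, criteria)
    samples = build_samples(records, events, seed=sim_config.seed)
    if not samples:
        raise ValueError("no prediction samples could be built from this cohort")

    policy = MissingnessPolicy(
        training_means=compute_training_means(records, variables)
    )
    X, y, info = feat_mod.extract_matrix(
        records, samples, policy, variables, mode=feature_mode
    )
    _, removed_vars = drop_sparse_variables(info["missing_indicator"])
    if removed_vars:
        removed_set = set(removed_vars)
        keep = [
            c for c in X.columns
            if info["provenance"]["features"][c]["variable"] not in removed_set
        ]
        X = X[keep]

    selector = build_selector(selection_config)
    report = crossval_evaluate(X, y, model_config, selector=selector, mode=mode)
    return PipelineResult(
        records=records,
        events=events,
        samples=samples,
        matrix=X,
        labels=y,
        removed_sparse=removed_vars,
        report=report,
        provenance=info["provenance"],
    )
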
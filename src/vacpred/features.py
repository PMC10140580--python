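"""Manual windowed summaries, static features and automated functionals.

Each prediction sample contributes one row built from its 35 h feature
window. Manual features are the six summaries (mean, variance, observation
count, min, max, range) over a 12 h and a 3 h partition of the window;
partitions are counted backward from the window end so the most recent data
always occupies complete subwindows (the earliest block absorbs the 11 h /
2 h remainder of the 35 h window). Static features are age, gender, the
neuromuscular-blocker flag, time since ICU admission, the shock index
(mean HR / mean SBP over the window) and the raw measurement count.
Automated features apply the versioned functional catalog to every variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._catalog import CATALOG_VERSION, build_catalog
from .preprocess import MissingnessPolicy, preprocess_window
from .records import HOUR, PatientRecord, PredictionSample

#: Variables used as predictors. PEEP and FiO2 are deliberately excluded:
#: they define the outcome, and including them would leak the label.
PREDICTIVE_VARIABLES: tuple[str, ...] = (
    "DBP", "GCS", "HR", "MAP", "PaO2", "RR", "SBP", "SpO2", "TEMP", "WBC",
    "airway_pressure", "glucose", "pH",
)

MANUAL_STATS = ("mean", "variance", "count", "min", "max", "range")


@dataclass(frozen=True)
class WindowSpec:
    """Feature-window geometry (hours)."""

    window_hours: int = 35
    long_subwindow: int = 12
    short_subwindow: int = 3


def subwindow_blocks(n_slots: int, sub: int) -> list[tuple[int, int]]:
    """Half-open slot ranges counted backward from the window end.

    Block 0 is the most recent; the earliest block may be truncated
    (35 h -> 12/12/11 for 12 h blocks, eleven 3 h blocks plus a 2 h block).
    """
    blocks = []
    stop = n_slots
    while stop > 0:
        start = max(0, stop - sub)
        blocks.append((start, stop))
        stop = start
    return blocks


def manual_features(
    hourly: pd.DataFrame,
    counts: pd.DataFrame,
    spec: WindowSpec = WindowSpec(),
) -> pd.Series:
    """Six summaries per variable per subwindow of both partitions."""
    n = spec.window_hours
    if len(hourly) != n:
        raise ValueError(f"expected a {n}-slot hourly window, got {len(hourly)}")
    out: dict[str, float] = {}
    for var in hourly.columns:
        x = hourly[var].to_numpy(float)
        c = counts[var].to_numpy(float) if var in counts else np.zeros(n)
        for sub in (spec.long_subwindow, spec.short_subwindow):
            for i, (lo, hi) in enumerate(subwindow_blocks(n, sub)):
                seg = x[lo:hi]
                prefix = f"{var}__w{sub}_{i}"
                mn, mx = float(seg.min()), float(seg.max())
                out[f"{prefix}__mean"] = float(seg.mean())
                out[f"{prefix}__variance"] = float(seg.var())
                out[f"{prefix}__count"] = float(c[lo:hi].sum())
                out[f"{prefix}__min"] = mn
                out[f"{prefix}__max"] = mx
                out[f"{prefix}__range"] = mx - mn
    return pd.Series(out)


def static_features(
    record: PatientRecord,
    sample: PredictionSample,
    hourly: pd.DataFrame,
    counts: pd.DataFrame,
) -> pd.Series:
    """Demographic and window-level scalar features."""
    mean_hr = float(hourly["HR"].mean()) if "HR" in hourly else np.nan
    mean_sbp = float(hourly["SBP"].mean()) if "SBP" in hourly else np.nan
    if mean_sbp == 0:
        raise ValueError("undefined shock index: mean SBP is zero")
    return pd.Series(
        {
            "static__age": float(record.age),
            "static__gender_male": float(record.gender == "M"),
            "static__neuromuscular_blocker": float(
                record.med_flags.get("neuromuscular_blocker", False)
            ),
            "static__hours_since_admission": float(
                (sample.decision_time - record.icu_admit_time) / HOUR
            ),
            "static__shock_index": mean_hr / mean_sbp,
            "static__measurement_count": float(counts.to_numpy().sum()),
        }
    )


def automated_features(
    series_by_variable: Mapping[str, np.ndarray],
    catalog: list | None = None,
) -> pd.Series:
    """Apply the functional catalog to each variable's window series.

    Feature names encode variable, functional and parameters
    (``VAR__auto__FUNCTIONAL``); identical inputs give identical vectors.
    """
    if catalog is None:
        catalog = build_catalog()
    out: dict[str, float] = {}
    for var in sorted(series_by_variable):
        x = np.asarray(series_by_variable[var], dtype=float)
        for name, func in catalog:
            out[f"{var}__auto__{name}"] = func(x)
    return pd.Series(out)


def extract_matrix(
    records: list[PatientRecord],
    samples: list[PredictionSample],
    policy: MissingnessPolicy,
    variables: Iterable[str] = PREDICTIVE_VARIABLES,
    mode: str = "manual",
    spec: WindowSpec = WindowSpec(),
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Build the samples x features matrix for a sample set.

    ``mode`` is ``"manual"`` (windowed summaries + statics), ``"auto"``
    (catalog functionals + statics) or ``"both"``. Returns the matrix, the
    aligned label vector and a provenance dictionary (per-feature origin
    plus the catalog version and the per-sample variable-missingness table
    used for sparsity screening).
    """
    if mode not in ("manual", "auto", "both"):
        raise ValueError(f"mode must be manual|auto|both, got {mode!r}")
    variables = sorted(variables)
    by_id = {r.patient_id: r for r in records}
    catalog = build_catalog() if mode in ("auto", "both") else None
    rows: list[pd.Series] = []
    labels: list[int] = []
    ids: list[str] = []
    missing_rows: list[pd.Series] = []
    for sample in samples:
        rec = by_id[sample.patient_id]
        hourly, counts, highfreq = preprocess_window(
            rec, sample.window_start, spec.window_hours, variables, policy
        )
        parts = []
        if mode in ("manual", "both"):
            parts.append(manual_features(hourly, counts, spec))
        if mode in ("auto", "both"):
            arrays = {
                var: (
                    highfreq[var].to_numpy(float)
                    if var in highfreq
                    else hourly[var].to_numpy(float)
                )
                for var in variables
            }
            parts.append(automated_features(arrays, catalog))
        parts.append(static_features(rec, sample, hourly, counts))
        rows.append(pd.concat(parts))
        labels.append(sample.label)
        ids.append(sample.sample_id)
        missing_rows.append(pd.Series(counts.sum(axis=0) == 0, name=sample.sample_id))
    X = pd.DataFrame(rows, index=ids)
    y = pd.Series(labels, index=ids, name="label")
    provenance = {
        "catalog_version": CATALOG_VERSION if catalog is not None else None,
        "mode": mode,
        "features": {
            col: _provenance_of(col) for col in X.columns
        },
    }
    missing = pd.DataFrame(missing_rows, index=ids)
    return X, y, {"provenance": provenance, "missing_indicator": missing}


def _provenance_of(column: str) -> dict:
    if column.startswith("static__"):
        return {"kind": "static", "variable": None}
    var, rest = column.split("__", 1)
    kind = "automated" if rest.startswith("auto__") else "manual"
    return {"kind": kind, "variable": var, "detail": rest}
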
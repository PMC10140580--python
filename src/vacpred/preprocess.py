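"""Physiologic-range filtering, 5-minute median down-sampling and the
gap-length-dependent imputation policy.

Rules implemented here:

* values outside the valid physiologic range of their variable are removed
  (they become missing; timestamps are preserved);
* high-frequency channels are partitioned into 5-minute bins and reduced to
  the in-bin median, one output point per bin at the bin's right edge;
* on the resulting 5-minute grid, interior gaps of more than 12 consecutive
  missing bins (i.e. longer than 1 h) are filled by linear interpolation
  between the bounding observations, gaps of at most 12 bins are carried
  forward, and leading gaps are back-filled from the first observation;
* low-frequency channels are resampled to an hourly grid (last observation
  within each hour); an empty hour following an observed hour is carried
  forward, while hours missing for more than 1 h fall back to the
  training-set mean of the variable;
* variables missing for 40% or more of samples (before imputation) are
  dropped.

Interpolation is applied only within a single historical feature window, so
every value used for a prediction precedes the decision time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import records as rec_mod

#: Valid physiologic ranges (inclusive bounds): outside values are outliers.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "HR": (30.0, 200.0),  # bpm
    "RR": (6.0, 50.0),  # breaths/min
    "DBP": (20.0, 120.0),  # mmHg
    "SBP": (50.0, 220.0),  # mmHg
    "SpO2": (80.0, 100.0),  # %
    "PEEP": (0.0, 20.0),  # cm H2O
    "FiO2": (21.0, 100.0),  # %
}


class ImputationError(ValueError):
    """A channel with zero observations cannot be imputed."""


class PolicyError(ValueError):
    """Missing or inconsistent missingness-policy configuration."""


@dataclass
class MissingnessPolicy:
    """Gap thresholds and training-fold means for imputation.

    ``hf_long_gap * hf_bin_minutes`` must equal ``lowfreq_gap_threshold_hours``
    (12 five-minute bins = 1 h): the two rules describe the same cut-off on
    the two grids.
    """

    lowfreq_gap_threshold_hours: float = 1.0
    hf_bin_minutes: float = 5.0
    hf_long_gap: int = 12
    training_means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isclose(
            self.hf_long_gap * self.hf_bin_minutes / 60.0,
            self.lowfreq_gap_threshold_hours,
        ):
            raise PolicyError(
                "hf_long_gap x hf_bin_minutes must equal lowfreq_gap_threshold_hours"
            )

    def mean_for(self, variable: str) -> float:
        try:
            return self.training_means[variable]
        except KeyError:
            raise PolicyError(
                f"no training mean available for variable {variable!r}"
            ) from None


def validate_ranges(ranges: Mapping[str, tuple[float, float]]) -> None:
    for var, (lo, hi) in ranges.items():
        if not lo < hi:
            raise ValueError(f"range for {var}: lower bound must be < upper bound")


def filter_physiologic_range(
    series: pd.Series,
    variable: str,
    ranges: Mapping[str, tuple[float, float]] = DEFAULT_RANGES,
) -> pd.Series:
    """Mask values outside the variable's valid range (bounds inclusive).

    Removed values become NaN; timestamps are preserved. Variables without a
    defined range pass through unchanged.
    """
    if variable not in ranges:
        return series.copy()
    lo, hi = ranges[variable]
    if not lo < hi:
        raise ValueError(f"range for {variable}: lower bound must be < upper bound")
    values = series.to_numpy(float)
    bad = (values < lo) | (values > hi)
    return pd.Series(np.where(bad, np.nan, values), index=series.index,
                     name=series.name)


def downsample_median(
    series: pd.Series,
    bin_minutes: float = 5.0,
    origin: pd.Timestamp | None = None,
) -> pd.Series:
    """Median down-sampling of a high-frequency channel.

    One output point per bin, stamped at the bin's right edge; empty bins
    yield NaN. ``origin`` anchors the bin edges (defaults to the first
    observation's timestamp floored to the bin width).
    """
    if bin_minutes <= 0:
        raise ValueError("bin width must be positive")
    if len(series) == 0:
        return series.copy()
    freq = pd.Timedelta(minutes=bin_minutes)
    if origin is None:
        origin = series.index[0].floor(freq)
    out = series.resample(freq, origin=origin, label="right", closed="left").median()
    return out


def _nan_runs(isnan: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) half-open index ranges of consecutive NaN runs."""
    runs = []
    n = len(isnan)
    i = 0
    while i < n:
        if isnan[i]:
            j = i
            while j < n and isnan[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def impute_highfreq(series: pd.Series, long_gap: int = 12) -> pd.Series:
    """Fill a 5-minute-grid channel restricted to one feature window.

    Interior gaps strictly longer than ``long_gap`` bins are linearly
    interpolated between the bounding observations; gaps of at most
    ``long_gap`` bins (and all trailing gaps, which have no right endpoint)
    are carried forward; leading gaps are back-filled.
    """
    values = series.to_numpy(float).copy()
    isnan = np.isnan(values)
    if isnan.all():
        raise ImputationError("channel has no observed values in the window")
    for start, stop in _nan_runs(isnan):
        if start == 0:
            values[start:stop] = values[stop]  # leading: back-fill
        elif stop == len(values):
            values[start:stop] = values[start - 1]  # trailing: carry forward
        elif stop - start > long_gap:
            left, right = values[start - 1], values[stop]
            gap = stop - start
            values[start:stop] = left + (right - left) * (
                np.arange(1, gap + 1) / (gap + 1)
            )
        else:
            values[start:stop] = values[start - 1]
    return pd.Series(values, index=series.index, name=series.name)


def impute_lowfreq(
    series: pd.Series,
    variable: str,
    policy: MissingnessPolicy,
    grid_start: pd.Timestamp,
    n_hours: int,
) -> pd.Series:
    """Resample an aperiodic channel to an hourly grid with no missing values.

    Hour ``h`` takes the last observation within ``[h, h+1)``. An empty hour
    immediately following an observed hour carries that hour's value forward
    (gap of at most 1 h); hours missing for longer fall back to the
    training-set mean. A fully empty channel yields the mean everywhere.
    """
    edges = grid_start + pd.to_timedelta(np.arange(n_hours + 1), unit="h")
    clean = series.dropna()
    times = clean.index
    values = clean.to_numpy(float)
    pos = np.searchsorted(times, edges)
    out = np.empty(n_hours)
    mean = None
    for h in range(n_hours):
        lo, hi = pos[h], pos[h + 1]
        if hi > lo:
            out[h] = values[hi - 1]
        elif h > 0 and pos[h] > pos[h - 1]:
            out[h] = out[h - 1]  # previous hour observed: carry forward
        else:
            if mean is None:
                mean = policy.mean_for(variable)
            out[h] = mean
    index = edges[:-1]
    return pd.Series(out, index=index, name=series.name)


def compute_training_means(
    records: Iterable[rec_mod.PatientRecord],
    variables: Iterable[str] | None = None,
    ranges: Mapping[str, tuple[float, float]] = DEFAULT_RANGES,
) -> dict[str, float]:
    """Per-variable mean of range-filtered values over a set of (training)
    patients. The caller controls which patients enter, which is how the
    no-leakage contract is honoured under cross-validation."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    wanted = None if variables is None else set(variables)
    for rec in records:
        for name, ch in rec.channels.items():
            if wanted is not None and name not in wanted:
                continue
            vals = filter_physiologic_range(ch.series, name, ranges).to_numpy(float)
            vals = vals[~np.isnan(vals)]
            if len(vals):
                sums[name] = sums.get(name, 0.0) + float(vals.sum())
                counts[name] = counts.get(name, 0) + len(vals)
    return {name: sums[name] / counts[name] for name in sums}


def drop_sparse_variables(
    missing_indicator: pd.DataFrame, threshold: float = 0.40
) -> tuple[pd.DataFrame, list[str]]:
    """Drop variables missing for ``threshold`` or more of samples.

    ``missing_indicator`` is a samples x variables boolean table computed
    before imputation (True = the variable has no observation for that
    sample). The boundary is inclusive: a variable missing in exactly 40%
    of samples is removed.
    """
    frac = missing_indicator.mean(axis=0)
    removed = [str(c) for c in missing_indicator.columns if frac[c] >= threshold]
    reduced = missing_indicator.drop(columns=removed)
    if removed and reduced.shape[1] == 0:
        import warnings

        warnings.warn("all variables were dropped as sparse", stacklevel=2)
    return reduced, removed


# ---------------------------------------------------------------------------
# feature-window preprocessing
# ---------------------------------------------------------------------------

def preprocess_window(
    record: rec_mod.PatientRecord,
    window_start: pd.Timestamp,
    n_hours: int,
    variables: Iterable[str],
    policy: MissingnessPolicy,
    ranges: Mapping[str, tuple[float, float]] = DEFAULT_RANGES,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.Series]]:
    """Prepare one feature window for extraction.

    Returns ``(hourly, counts, highfreq)`` where ``hourly`` is the fully
    imputed hourly grid (rows = hour slots, columns = variables), ``counts``
    holds the number of raw in-range observations per slot and variable, and
    ``highfreq`` maps each periodic variable to its imputed 5-minute series.
    """
    window_end = window_start + pd.Timedelta(hours=n_hours)
    edges = window_start + pd.to_timedelta(np.arange(n_hours + 1), unit="h")
    hourly: dict[str, pd.Series] = {}
    counts: dict[str, np.ndarray] = {}
    highfreq: dict[str, pd.Series] = {}
    for var in variables:
        ch = record.channels.get(var)
        if ch is None:
            raw = pd.Series(dtype=float, index=pd.DatetimeIndex([]))
            kind = rec_mod.LOWFREQ
        else:
            raw = ch.series[(ch.series.index >= window_start)
                            & (ch.series.index < window_end)]
            kind = ch.kind
        filtered = filter_physiologic_range(raw, var, ranges)
        observed = filtered.dropna()
        pos = np.searchsorted(observed.index, edges)
        counts[var] = np.diff(pos)
        if kind == rec_mod.HIGHFREQ:
            binned = downsample_median(
                filtered, policy.hf_bin_minutes, origin=window_start
            )
            # pad to the full window grid before imputation
            freq = pd.Timedelta(minutes=policy.hf_bin_minutes)
            full = pd.date_range(window_start + freq, window_end, freq=freq)
            binned = binned.reindex(full)
            if binned.notna().sum() == 0:
                hourly[var] = impute_lowfreq(
                    observed, var, policy, window_start, n_hours
                )
                highfreq[var] = pd.Series(
                    np.full(len(full), policy.mean_for(var)), index=full, name=var
                )
                continue
            imputed = impute_highfreq(binned, policy.hf_long_gap)
            highfreq[var] = imputed
            # hourly view for the manual summaries: mean of the 12 bins/hour
            hourly[var] = pd.Series(
                imputed.to_numpy().reshape(n_hours, -1).mean(axis=1),
                index=edges[:-1], name=var,
            )
        else:
            hourly[var] = impute_lowfreq(observed, var, policy, window_start, n_hours)
    hourly_df = pd.DataFrame(hourly, index=edges[:-1])
    counts_df = pd.DataFrame(counts, index=edges[:-1])
    return hourly_df, counts_df, highfreq
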
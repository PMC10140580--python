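"""Hourly VAC onset detection and prediction-sample construction.

A ventilator-associated complication (VAC) is detected at candidate hour
``t`` when

* in the stability window ``[t-48 h, t)`` the two rolling 24 h daily minima
  of BOTH FiO2 and PEEP are non-increasing (day2 <= day1), and
* in the worsening window ``[t, t+48 h)`` every daily minimum of FiO2 is at
  least 20 percentage points above the stability baseline, or every daily
  minimum of PEEP is at least 3 cm H2O above it,

where the baseline of a setting is the minimum of its stability-window daily
minima. "Days" are rolling 24 h blocks aligned to the candidate hour, the
hourly adaptation of the surveillance definition. Only the earliest
qualifying hour is kept (one event per stay). Patients ventilated for less
than 96 h are not at risk and produce no events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import HOUR, PatientRecord, PredictionSample, VacEvent

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VacCriteria:
    """Thresholds and window lengths of the VAC definition."""

    stability_duration: float = 48.0  # hours
    worsening_duration: float = 48.0  # hours
    fio2_increase: float = 20.0  # percentage points (fraction 0.2)
    peep_increase: float = 3.0  # cm H2O
    day_length: float = 24.0  # hours

    def __post_init__(self) -> None:
        for name in ("stability_duration", "worsening_duration", "day_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fio2_increase <= 0 or self.peep_increase <= 0:
            raise ValueError("escalation thresholds must be positive")


def daily_minima(
    series: pd.Series,
    window_start: pd.Timestamp,
    window_end: pd.Timestamp,
    day_length: float = 24.0,
) -> list[float] | None:
    """Per-day minima over consecutive day blocks aligned to ``window_start``.

    Returns None (ineligible window) if any day block has no observation.
    """
    span = (window_end - window_start) / HOUR
    n_days = span / day_length
    if abs(n_days - round(n_days)) > 1e-9:
        raise ValueError("window length must be an integer multiple of day_length")
    n_days = int(round(n_days))
    clean = series.dropna()
    out = []
    for d in range(n_days):
        lo = window_start + pd.Timedelta(hours=d * day_length)
        hi = lo + pd.Timedelta(hours=day_length)
        block = clean[(clean.index >= lo) & (clean.index < hi)]
        if block.empty:
            return None
        out.append(float(block.min()))
    return out


def _block_minima(
    times: np.ndarray, values: np.ndarray, edges_h: np.ndarray
) -> np.ndarray | None:
    """Minima over consecutive blocks given hour-offset edges; None if any
    block is empty."""
    pos = np.searchsorted(times, edges_h)
    mins = np.empty(len(edges_h) - 1)
    for k in range(len(mins)):
        lo, hi = pos[k], pos[k + 1]
        if hi <= lo:
            return None
        mins[k] = values[lo:hi].min()
    return mins


def detect_vac(
    peep: pd.Series,
    fio2: pd.Series,
    criteria: VacCriteria,
    vent_start: pd.Timestamp,
    vent_end: pd.Timestamp,
    patient_id: str = "",
) -> list[VacEvent]:
    """Scan every candidate hour of ventilation for the VAC definition.

    Candidate hours run from ``vent_start + 48 h`` to ``vent_end - 48 h`` on
    the hourly grid anchored at ``vent_start``. At most one event (the
    earliest) is returned.
    """
    total_h = (vent_end - vent_start) / HOUR
    if total_h < 96.0:
        logger.info("%s: ventilated %.0f h < 96 h; excluded", patient_id, total_h)
        return []
    stab = criteria.stability_duration
    wors = criteria.worsening_duration
    day = criteria.day_length
    n_stab = int(round(stab / day))
    n_wors = int(round(wors / day))

    chans = {}
    for name, series in (("PEEP", peep), ("FiO2", fio2)):
        clean = series.dropna()
        times = ((clean.index - vent_start) / HOUR).to_numpy(float)
        chans[name] = (times, clean.to_numpy(float))

    first_t = int(np.ceil(stab))
    last_t = int(np.floor(total_h - wors))
    for t in range(first_t, last_t + 1):
        stab_edges = t - stab + day * np.arange(n_stab + 1)
        wors_edges = t + day * np.arange(n_wors + 1)
        mins = {}
        eligible = True
        for name, (times, values) in chans.items():
            sm = _block_minima(times, values, stab_edges)
            wm = _block_minima(times, values, wors_edges)
            if sm is None or wm is None:
                eligible = False
                break
            mins[name] = (sm, wm)
        if not eligible:
            continue
        stable = all(
            np.all(np.diff(mins[name][0]) <= 0) for name in ("PEEP", "FiO2")
        )
        if not stable:
            continue
        fio2_fires = np.all(
            mins["FiO2"][1] >= mins["FiO2"][0].min() + criteria.fio2_increase
        )
        peep_fires = np.all(
            mins["PEEP"][1] >= mins["PEEP"][0].min() + criteria.peep_increase
        )
        if fio2_fires or peep_fires:
            trigger = "both" if (fio2_fires and peep_fires) else (
                "FiO2" if fio2_fires else "PEEP"
            )
            onset = vent_start + pd.Timedelta(hours=t)
            return [VacEvent(patient_id, onset, trigger)]
    return []


def detect_cohort(
    records: list[PatientRecord], criteria: VacCriteria = VacCriteria()
) -> list[VacEvent]:
    """Run :func:`detect_vac` over a cohort (one event per stay at most)."""
    events = []
    for rec in records:
        events.extend(
            detect_vac(
                rec.channels["PEEP"].series,
                rec.channels["FiO2"].series,
                criteria,
                rec.vent_start,
                rec.vent_end,
                rec.patient_id,
            )
        )
    return events


def hourly_labels(record: PatientRecord, events: list[VacEvent]) -> pd.Series:
    """Binary label per ventilated hour: 1 exactly at the onset hour(s)."""
    n = int(np.floor(record.vent_hours))
    labels = pd.Series(np.zeros(n, dtype=int), name="label")
    labels.index.name = "vent_hour"
    for ev in events:
        if ev.patient_id != record.patient_id:
            continue
        h = int(round((ev.onset_time - record.vent_start) / HOUR))
        if 0 <= h < n:
            labels.iloc[h] = 1
    return labels


def build_samples(
    records: list[PatientRecord],
    events: list[VacEvent],
    seed: int = 0,
    window_hours: float = 36.0,
) -> list[PredictionSample]:
    """Assemble the 1:1-balanced prediction-sample set.

    One positive sample per VAC patient at its onset; negative decision
    hours are drawn (seeded) from the empirical distribution of positive
    onset hours, constrained to leave a full feature window inside the
    ventilation interval; the majority class is trimmed at random.
    """
    rng = np.random.default_rng(seed)
    by_id = {r.patient_id: r for r in records}
    event_ids = {e.patient_id for e in events}

    positives: list[PredictionSample] = []
    onset_hours: list[float] = []
    for ev in sorted(events, key=lambda e: e.patient_id):
        rec = by_id[ev.patient_id]
        h = (ev.onset_time - rec.vent_start) / HOUR
        if h < window_hours:
            logger.info(
                "%s: onset %.0f h leaves no %d h window; excluded",
                ev.patient_id, h, int(window_hours),
            )
            continue
        positives.append(PredictionSample(ev.patient_id, ev.onset_time, 1))
        onset_hours.append(float(h))

    negatives: list[PredictionSample] = []
    if onset_hours:
        neg_records = sorted(
            (r for r in records if r.patient_id not in event_ids),
            key=lambda r: r.patient_id,
        )
        pool = np.asarray(onset_hours)
        for rec in neg_records:
            max_h = np.floor(rec.vent_hours)
            fits = pool[(pool >= window_hours) & (pool <= max_h)]
            if len(fits) == 0:
                continue
            h = float(rng.choice(fits))
            decision = rec.vent_start + pd.Timedelta(hours=h)
            negatives.append(PredictionSample(rec.patient_id, decision, 0))

    n = min(len(positives), len(negatives))
    if len(positives) > n:
        keep = rng.choice(len(positives), size=n, replace=False)
        positives = [positives[i] for i in sorted(keep)]
    if len(negatives) > n:
        keep = rng.choice(len(negatives), size=n, replace=False)
        negatives = [negatives[i] for i in sorted(keep)]
    return positives + negatives
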
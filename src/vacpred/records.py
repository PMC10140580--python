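"""Core data containers for ventilated-patient records and VAC events.

Timestamps are :class:`pandas.Timestamp` throughout; each channel is a
:class:`pandas.Series` of numeric values indexed by observation time.
Durations inside the package are handled in hours relative to the start of
mechanical ventilation (``vent_start``), which anchors the hourly grid used
for labelling and feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

HOUR = pd.Timedelta(hours=1)

#: Controlled vocabulary of channel names.
CHANNEL_VOCABULARY = frozenset(
    {
        "HR", "RR", "SBP", "DBP", "MAP", "SpO2", "TEMP", "PEEP", "FiO2",
        "airway_pressure", "pH", "PaO2", "glucose", "WBC", "GCS",
    }
)

LOWFREQ = "lowfreq"
HIGHFREQ = "highfreq"


@dataclass
class Channel:
    """One named physiologic/ventilator time series.

    Parameters
    ----------
    name
        Variable name from :data:`CHANNEL_VOCABULARY`.
    series
        Values indexed by a strictly increasing ``DatetimeIndex``.
    kind
        ``"lowfreq"`` for aperiodic nurse-charted data, ``"highfreq"`` for
        periodic monitor data.
    """

    name: str
    series: pd.Series
    kind: str = LOWFREQ

    def __post_init__(self) -> None:
        if self.name not in CHANNEL_VOCABULARY:
            raise ValueError(f"unknown channel name {self.name!r}")
        if self.kind not in (LOWFREQ, HIGHFREQ):
            raise ValueError(f"channel kind must be lowfreq/highfreq, got {self.kind!r}")
        idx = self.series.index
        if len(idx) > 1 and not idx.is_monotonic_increasing:
            raise ValueError(f"channel {self.name}: timestamps must be increasing")

    def copy(self) -> "Channel":
        return Channel(self.name, self.series.copy(), self.kind)


@dataclass
class PatientRecord:
    """One ICU stay: demographics, ventilation interval and named channels."""

    patient_id: str
    age: float
    gender: str
    icu_admit_time: pd.Timestamp
    vent_start: pd.Timestamp
    vent_end: pd.Timestamp
    channels: dict[str, Channel] = field(default_factory=dict)
    med_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.vent_start < self.vent_end:
            raise ValueError(f"{self.patient_id}: vent_start must precede vent_end")

    @property
    def vent_hours(self) -> float:
        return (self.vent_end - self.vent_start) / HOUR

    def hours(self, when: pd.Timestamp | pd.DatetimeIndex) -> np.ndarray | float:
        """Convert timestamps to hours since vent_start."""
        return (when - self.vent_start) / HOUR

    def copy(self) -> "PatientRecord":
        return PatientRecord(
            self.patient_id,
            self.age,
            self.gender,
            self.icu_admit_time,
            self.vent_start,
            self.vent_end,
            {k: v.copy() for k, v in self.channels.items()},
            dict(self.med_flags),
        )


@dataclass(frozen=True)
class VacEvent:
    """A ventilator-associated complication: 48 h of stable-or-decreasing
    daily-minimum PEEP/FiO2 followed by 48 h of sustained escalation.

    ``onset_time`` is the transition hour between the two windows.
    """

    patient_id: str
    onset_time: pd.Timestamp
    trigger: str  # "FiO2" | "PEEP" | "both"

    @property
    def stability_window(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return (self.onset_time - 48 * HOUR, self.onset_time)

    @property
    def worsening_window(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return (self.onset_time, self.onset_time + 48 * HOUR)


@dataclass(frozen=True)
class PredictionSample:
    """One labelled instance: a 35 h feature window ending 1 h before the
    decision time (for positives the decision time is the VAC onset)."""

    patient_id: str
    decision_time: pd.Timestamp
    label: int

    @property
    def window_start(self) -> pd.Timestamp:
        return self.decision_time - 36 * HOUR

    @property
    def window_end(self) -> pd.Timestamp:
        return self.decision_time - 1 * HOUR

    @property
    def sample_id(self) -> str:
        return f"{self.patient_id}@{self.decision_time.isoformat()}"


@dataclass
class GroundTruth:
    """Per-patient injected event (None for VAC-negative patients)."""

    events: dict[str, VacEvent | None] = field(default_factory=dict)

    def positives(self) -> list[VacEvent]:
        return [e for e in self.events.values() if e is not None]


# ---------------------------------------------------------------------------
# CSV interchange (long chart-events format + demographics + events)
# ---------------------------------------------------------------------------

def chart_events_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Long-format chart events: patient_id, charttime, variable, value."""
    parts = []
    for rec in records:
        for ch in rec.channels.values():
            parts.append(
                pd.DataFrame(
                    {
                        "patient_id": rec.patient_id,
                        "charttime": ch.series.index,
                        "variable": ch.name,
                        "value": ch.series.to_numpy(),
                    }
                )
            )
    if not parts:
        return pd.DataFrame(columns=["patient_id", "charttime", "variable", "value"])
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(
        ["patient_id", "variable", "charttime"], kind="mergesort"
    ).reset_index(drop=True)


def demographics_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "age": r.age,
            "gender": r.gender,
            "icu_admit_time": r.icu_admit_time,
            "vent_start": r.vent_start,
            "vent_end": r.vent_end,
            "neuromuscular_blocker": int(r.med_flags.get("neuromuscular_blocker", False)),
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def events_frame(events: Iterable[VacEvent]) -> pd.DataFrame:
    rows = [
        {"patient_id": e.patient_id, "onset_time": e.onset_time, "trigger": e.trigger}
        for e in events
    ]
    return pd.DataFrame(rows, columns=["patient_id", "onset_time", "trigger"])


def samples_frame(samples: Iterable[PredictionSample]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": s.patient_id,
            "decision_time": s.decision_time,
            "window_start": s.window_start,
            "window_end": s.window_end,
            "label": s.label,
        }
        for s in samples
    ]
    return pd.DataFrame(
        rows,
        columns=["patient_id", "decision_time", "window_start", "window_end", "label"],
    )


def records_from_frames(
    events: pd.DataFrame,
    demographics: pd.DataFrame,
    highfreq_variables: Iterable[str] = (),
) -> list[PatientRecord]:
    """Rebuild :class:`PatientRecord` objects from the CSV interchange tables."""
    hf = set(highfreq_variables)
    events = events.copy()
    events["charttime"] = pd.to_datetime(events["charttime"])
    grouped: Mapping = {pid: g for pid, g in events.groupby("patient_id")}
    records = []
    for row in demographics.itertuples(index=False):
        chans: dict[str, Channel] = {}
        g = grouped.get(row.patient_id)
        if g is not None:
            for var, gv in g.groupby("variable"):
                gv = gv.sort_values("charttime", kind="mergesort")
                series = pd.Series(
                    gv["value"].to_numpy(float),
                    index=pd.DatetimeIndex(gv["charttime"]),
                    name=var,
                )
                chans[var] = Channel(var, series, HIGHFREQ if var in hf else LOWFREQ)
        records.append(
            PatientRecord(
                patient_id=str(row.patient_id),
                age=float(row.age),
                gender=str(row.gender),
                icu_admit_time=pd.Timestamp(row.icu_admit_time),
                vent_start=pd.Timestamp(row.vent_start),
                vent_end=pd.Timestamp(row.vent_end),
                channels=chans,
                med_flags={"neuromuscular_blocker": bool(row.neuromuscular_blocker)},
            )
        )
    return records
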
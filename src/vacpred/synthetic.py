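"""Synthetic ventilated-ICU cohort generator with ground-truth VAC episodes.

The generator emulates the statistical structure the downstream analysis
assumes, without any real patient data:

* aperiodic, roughly hourly nurse charting of vitals and ventilator settings,
  sparser lab draws, and optional periodic high-frequency monitor channels;
* baseline physiology as stationary AR(1) noise around per-variable
  set-points inside the valid physiologic ranges;
* injected VAC episodes that satisfy the surveillance definition by
  construction (48 h of stable daily-minimum PEEP/FiO2 followed by 48 h of
  sustained escalation of one or both settings);
* a configurable linear pre-onset drift in MAP/HR/RR/SpO2 (the pre
  -decompensation signal the classifier is meant to pick up);
* missingness in contiguous runs and physiologically implausible outliers
  planted strictly outside the valid ranges.

VAC-negative patients receive mild hourly fluctuation of PEEP/FiO2 whose
total range stays strictly below the escalation thresholds, so the outcome
definition provably never fires on them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .preprocess import DEFAULT_RANGES
from .records import (
    HIGHFREQ,
    HOUR,
    LOWFREQ,
    Channel,
    GroundTruth,
    PatientRecord,
    VacEvent,
)

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


#: Ventilator-setting baselines (percent FiO2, cm H2O PEEP) and escalation
#: levels used for injected episodes.
FIO2_BASE = 40.0
PEEP_BASE = 5.0
FIO2_ESCALATED = 60.0  # = base + 20 percentage points
PEEP_ESCALATED = 8.0  # = base + 3 cm H2O
#: Hourly jitter sets; total widths (15 %-points, 2 cm H2O) are strictly below
#: the escalation thresholds, so fluctuation alone can never trigger an event.
FIO2_JITTER = (0.0, 5.0, 10.0, 15.0)
PEEP_JITTER = (0.0, 1.0, 2.0)

#: Baseline physiology: set-point, stationary SD, AR(1) coefficient per
#: charted step, charting interval (hours). Values sit inside the valid
#: ranges so only planted outliers fall outside them.
SIGNAL_MODELS: dict[str, tuple[float, float, float, float]] = {
    "HR": (85.0, 10.0, 0.7, 1.0),
    "RR": (18.0, 4.0, 0.7, 1.0),
    "SBP": (120.0, 15.0, 0.7, 1.0),
    "DBP": (65.0, 10.0, 0.7, 1.0),
    "MAP": (83.0, 10.0, 0.7, 1.0),
    "SpO2": (96.0, 1.5, 0.7, 1.0),
    "TEMP": (37.0, 0.4, 0.8, 1.0),
    "airway_pressure": (15.0, 4.0, 0.7, 1.0),
    "GCS": (9.0, 3.0, 0.9, 4.0),
    "pH": (7.38, 0.05, 0.8, 6.0),
    "PaO2": (95.0, 20.0, 0.8, 6.0),
    "glucose": (130.0, 35.0, 0.8, 6.0),
    "WBC": (10.0, 3.0, 0.9, 6.0),
}

#: Hard clips keeping baseline values inside plausible/valid bounds.
_CLIPS: dict[str, tuple[float, float]] = {
    "HR": (30.0, 200.0),
    "RR": (6.0, 50.0),
    "SBP": (50.0, 220.0),
    "DBP": (20.0, 120.0),
    "MAP": (30.0, 180.0),
    "SpO2": (80.0, 100.0),
    "GCS": (3.0, 15.0),
    "PaO2": (30.0, 400.0),
    "glucose": (30.0, 500.0),
    "WBC": (0.5, 50.0),
}

#: Default signed pre-onset drift pattern (standardised units at onset):
#: haemodynamic deterioration raises HR/RR and lowers MAP/SpO2.
DEFAULT_DRIFT_PATTERN: dict[str, float] = {
    "MAP": -1.0,
    "HR": 1.0,
    "RR": 1.0,
    "SpO2": -1.0,
}

DRIFT_RAMP_HOURS = 36.0


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    ``drift_effect`` may be given as a scalar (scales the default signed
    MAP/HR/RR/SpO2 pattern) or as an explicit mapping signal -> shift in
    standardised units reached at onset.
    """

    n_patients: int = 200
    vac_prevalence: float = 0.5
    vent_duration_hours: tuple[float, float] = (96.0, 336.0)
    charting_interval: float = 1.0  # hours, low-frequency channels
    hf_interval: float = 1.0 / 60.0  # hours, high-frequency channels
    hf_channels: tuple[str, ...] = ()
    drift_effect: Mapping[str, float] | float = 1.0
    missing_rate: float = 0.05
    missing_run_length: float = 2.0  # mean of the geometric run-length law
    outlier_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not 0.0 <= self.vac_prevalence <= 1.0:
            raise ConfigurationError("vac_prevalence must lie in [0, 1]")
        lo, hi = self.vent_duration_hours
        if lo < 96.0:
            raise ConfigurationError(
                "vent_duration_hours minimum must be >= 96 h (inclusion criterion)"
            )
        if hi < lo:
            raise ConfigurationError("vent_duration_hours range must be ordered")
        if self.charting_interval <= 0:
            raise ConfigurationError("charting_interval must be positive")
        if self.hf_interval <= 0:
            raise ConfigurationError("hf_interval must be positive")
        for name in self.hf_channels:
            if name not in SIGNAL_MODELS:
                raise ConfigurationError(f"hf_channels: unknown signal {name!r}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1]")
        if self.missing_run_length < 1.0:
            raise ConfigurationError("missing_run_length mean must be >= 1")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ConfigurationError("outlier_rate must lie in [0, 1]")
        if isinstance(self.drift_effect, (int, float)):
            scale = float(self.drift_effect)
            object.__setattr__(
                self,
                "drift_effect",
                {k: v * scale for k, v in DEFAULT_DRIFT_PATTERN.items()},
            )
        else:
            bad = set(self.drift_effect) - set(SIGNAL_MODELS)
            if bad:
                raise ConfigurationError(f"drift_effect: unknown signals {sorted(bad)}")
            object.__setattr__(self, "drift_effect", dict(self.drift_effect))


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _ar1(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) with unit marginal variance (50-sample burn-in)."""
    burn = 50
    e = rng.standard_normal(n + burn) * np.sqrt(1.0 - phi * phi)
    x = lfilter([1.0], [1.0, -phi], e)
    return x[burn:]


def _baseline_channel(
    name: str,
    vent_start: pd.Timestamp,
    duration_h: float,
    interval_h: float,
    rng: np.random.Generator,
    *,
    periodic: bool,
    phi: float | None = None,
) -> Channel:
    sp, sd, phi_lf, _ = SIGNAL_MODELS[name]
    phi = phi_lf if phi is None else phi
    n = int(np.floor(duration_h / interval_h))
    values = sp + sd * _ar1(n, phi, rng)
    if name in _CLIPS:
        lo, hi = _CLIPS[name]
        values = np.clip(values, lo, hi)
    if periodic:
        offsets = np.arange(n) * interval_h
    else:
        # one observation per charting slot, jittered inside the slot
        offsets = (np.arange(n) + 0.5 + rng.uniform(-0.3, 0.3, n)) * interval_h
    idx = vent_start + pd.to_timedelta(offsets, unit="h")
    return Channel(name, pd.Series(values, index=idx, name=name),
                   HIGHFREQ if periodic else LOWFREQ)


def _settings_channel(
    name: str,
    vent_start: pd.Timestamp,
    duration_h: float,
    rng: np.random.Generator,
) -> Channel:
    """Ventilator setting charted on exact hours: base + mild jitter.

    The jitter range is strictly below the escalation threshold, so these
    trajectories can never satisfy the VAC worsening criterion.
    """
    base = FIO2_BASE if name == "FiO2" else PEEP_BASE
    jitter = FIO2_JITTER if name == "FiO2" else PEEP_JITTER
    n = int(np.floor(duration_h))
    values = base + rng.choice(jitter, size=n)
    idx = vent_start + pd.to_timedelta(np.arange(n), unit="h")
    return Channel(name, pd.Series(values, index=idx, name=name), LOWFREQ)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def inject_vac_episode(
    record: PatientRecord,
    onset: pd.Timestamp,
    trigger: str = "FiO2",
    seed: int | np.random.Generator = 0,
) -> PatientRecord:
    """Rewrite PEEP/FiO2 so the record satisfies the VAC definition at ``onset``.

    From ``onset - 48 h`` to ``onset`` both settings are held at their
    baseline (daily minima constant, hence non-increasing); from ``onset``
    onward the triggering setting(s) stay at least one escalation threshold
    above baseline (FiO2 +20 percentage points, PEEP +3 cm H2O).
    Earlier charted values are left untouched.
    """
    if trigger not in ("FiO2", "PEEP", "both"):
        raise ValueError(f"trigger must be FiO2|PEEP|both, got {trigger!r}")
    if onset < record.vent_start + 48 * HOUR or onset + 48 * HOUR > record.vent_end:
        raise ValueError(
            f"{record.patient_id}: onset {onset} leaves no room for the "
            "48 h stability and worsening windows"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rec = record.copy()
    for name, base, escalated, jitter in (
        ("FiO2", FIO2_BASE, FIO2_ESCALATED, FIO2_JITTER[:3]),
        ("PEEP", PEEP_BASE, PEEP_ESCALATED, PEEP_JITTER),
    ):
        ch = rec.channels[name]
        idx = ch.series.index
        values = ch.series.to_numpy(float).copy()
        stable = (idx >= onset - 48 * HOUR) & (idx < onset)
        worsening = idx >= onset
        values[stable] = base
        if trigger in (name, "both"):
            values[worsening] = escalated + rng.choice(jitter, size=int(worsening.sum()))
        else:
            values[worsening] = base
        rec.channels[name] = Channel(name, pd.Series(values, index=idx, name=name), ch.kind)
    return rec


def _apply_drift(
    record: PatientRecord, onset: pd.Timestamp, drift: Mapping[str, float]
) -> None:
    """Add a linear pre-onset mean shift, in units of each signal's SD,
    ramping from zero at ``onset - 36 h`` to the full effect at ``onset``
    and holding it afterwards (in place)."""
    for name, effect in drift.items():
        if effect == 0.0:
            continue
        sd = SIGNAL_MODELS[name][1]
        ch = record.channels.get(name)
        if ch is None:
            continue
        hours_to_onset = (onset - ch.series.index) / HOUR  # >0 before onset
        ramp = np.clip(1.0 - hours_to_onset / DRIFT_RAMP_HOURS, 0.0, 1.0)
        values = ch.series.to_numpy(float) + effect * sd * np.asarray(ramp)
        if name in _CLIPS:
            values = np.clip(values, *_CLIPS[name])
        record.channels[name] = Channel(name, pd.Series(values, index=ch.series.index,
                                                        name=name), ch.kind)


def apply_missingness(
    record: PatientRecord,
    rate: float,
    run_length_mean: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> PatientRecord:
    """Remove about ``rate`` of each channel's points in contiguous runs.

    Run lengths are geometric with the given mean; runs may overlap. The
    removed points disappear from the series (missingness is the absence of
    a charted observation).
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError("missing rate must lie in [0, 1]")
    if rate == 0.0:
        return record.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rec = record.copy()
    p_geom = 1.0 / max(run_length_mean, 1.0)
    for name, ch in rec.channels.items():
        n = len(ch.series)
        if n == 0:
            continue
        target = int(rng.binomial(n, rate))
        mask = np.zeros(n, dtype=bool)
        removed = 0
        while removed < target:
            start = int(rng.integers(0, n))
            length = int(rng.geometric(p_geom))
            stop = min(n, start + length)
            newly = int((~mask[start:stop]).sum())
            mask[start:stop] = True
            removed += newly
        rec.channels[name] = Channel(name, ch.series[~mask], ch.kind)
    return rec


def apply_outliers(
    record: PatientRecord,
    rate: float,
    seed: int | np.random.Generator = 0,
    ranges: Mapping[str, tuple[float, float]] = DEFAULT_RANGES,
) -> tuple[PatientRecord, dict[str, int]]:
    """Replace a ``rate`` fraction of points with values strictly outside the
    valid physiologic range of their variable.

    Returns the modified record and the per-variable count of planted
    outliers (for downstream assertions). Variables without a defined range
    are skipped with a logged notice.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError("outlier rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rec = record.copy()
    counts: dict[str, int] = {}
    for name, ch in rec.channels.items():
        if name not in ranges:
            logger.info("apply_outliers: no valid range for %s; skipped", name)
            continue
        n = len(ch.series)
        if n == 0 or rate == 0.0:
            counts[name] = 0
            continue
        lo, hi = ranges[name]
        k = int(rng.binomial(n, rate))
        if k == 0:
            counts[name] = 0
            continue
        pos = rng.choice(n, size=k, replace=False)
        span = hi - lo
        low_side = rng.random(k) < 0.5
        vals = np.where(
            low_side,
            lo - rng.uniform(0.5, 0.5 * span, k),
            hi + rng.uniform(0.5, 0.5 * span, k),
        )
        values = ch.series.to_numpy(float).copy()
        values[pos] = vals
        rec.channels[name] = Channel(name, pd.Series(values, index=ch.series.index,
                                                     name=name), ch.kind)
        counts[name] = k
    return rec, counts


def generate_cohort(config: SimConfig) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate a cohort; exactly ``round(n_patients * vac_prevalence)``
    records carry an injected VAC episode. Pure function of ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    patient_seeds = root.spawn(config.n_patients + 1)
    assign_rng = np.random.default_rng(patient_seeds[-1])
    n_vac = int(round(config.n_patients * config.vac_prevalence))
    vac_flags = np.zeros(config.n_patients, dtype=bool)
    vac_flags[assign_rng.permutation(config.n_patients)[:n_vac]] = True

    records: list[PatientRecord] = []
    truth = GroundTruth()
    origin = pd.Timestamp("2020-01-01 00:00")
    lo, hi = config.vent_duration_hours
    for i in range(config.n_patients):
        rng = np.random.default_rng(patient_seeds[i])
        pid = f"P{i:04d}"
        admit = origin + pd.Timedelta(minutes=int(rng.integers(0, 365 * 24 * 60)))
        vent_start = (admit + pd.Timedelta(hours=float(rng.uniform(0, 48)))).ceil("h")
        duration = float(rng.integers(int(lo), int(hi) + 1))
        vent_end = vent_start + pd.Timedelta(hours=duration)

        channels: dict[str, Channel] = {}
        for name, (_, _, _, interval) in SIGNAL_MODELS.items():
            channels[name] = _baseline_channel(
                name, vent_start, duration, interval * config.charting_interval,
                rng, periodic=False,
            )
        for name in ("FiO2", "PEEP"):
            channels[name] = _settings_channel(name, vent_start, duration, rng)
        # monitor channels replace nurse charting for the listed signals
        for name in config.hf_channels:
            channels[name] = _baseline_channel(
                name, vent_start, duration, config.hf_interval, rng,
                periodic=True, phi=0.97,
            )

        record = PatientRecord(
            patient_id=pid,
            age=float(np.clip(rng.normal(67.0, 15.0), 18.0, 95.0).round(1)),
            gender="M" if rng.random() < 0.587 else "F",
            icu_admit_time=admit,
            vent_start=vent_start,
            vent_end=vent_end,
            channels=channels,
            med_flags={"neuromuscular_blocker": bool(rng.random() < 0.3)},
        )

        if vac_flags[i]:
            onset_h = int(rng.integers(48, int(duration) - 48 + 1))
            onset = vent_start + pd.Timedelta(hours=onset_h)
            trig = str(rng.choice(["FiO2", "PEEP", "both"], p=[0.45, 0.45, 0.1]))
            record = inject_vac_episode(record, onset, trig, rng)
            _apply_drift(record, onset, config.drift_effect)
            truth.events[pid] = VacEvent(pid, onset, trig)
        else:
            truth.events[pid] = None

        if config.outlier_rate > 0:
            record, _ = apply_outliers(record, config.outlier_rate, rng)
        if config.missing_rate > 0:
            record = apply_missingness(
                record, config.missing_rate, config.missing_run_length, rng
            )
        records.append(record)
    return records, truth
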
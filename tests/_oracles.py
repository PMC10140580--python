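"""Independent oracles used by the test suite.

The brute-force VAC detector re-tests the surveillance definition literally
at every candidate hour with plain Python loops; it is deliberately written
without reference to the package's vectorised implementation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HOUR = pd.Timedelta(hours=1)


def brute_force_detect(
    peep: pd.Series,
    fio2: pd.Series,
    vent_start: pd.Timestamp,
    vent_end: pd.Timestamp,
    fio2_increase: float = 20.0,
    peep_increase: float = 3.0,
):
    """Earliest (onset_hour, trigger) satisfying the VAC definition, or None.

    For each candidate hour t: both settings must have non-increasing
    per-day minima over [t-48, t) (rolling 24 h days), and every per-day
    minimum over [t, t+48) of FiO2 (or PEEP) must exceed that setting's
    stability baseline (min of its stability daily minima) by at least the
    escalation threshold. Days with no observation make t ineligible.
    """
    total = int((vent_end - vent_start) / HOUR)
    arrays = {}
    for name, series in (("PEEP", peep), ("FiO2", fio2)):
        clean = series.dropna()
        arrays[name] = (
            ((clean.index - vent_start) / HOUR).to_numpy(float),
            clean.to_numpy(float),
        )

    def day_min(name, lo_h, hi_h):
        hours, vals = arrays[name]
        mask = (hours >= lo_h) & (hours < hi_h)
        if not mask.any():
            return None
        return float(vals[mask].min())

    for t in range(48, total - 48 + 1):
        mins = {}
        eligible = True
        for name in ("PEEP", "FiO2"):
            stab = [day_min(name, t - 48, t - 24), day_min(name, t - 24, t)]
            wors = [day_min(name, t, t + 24), day_min(name, t + 24, t + 48)]
            if any(m is None for m in stab + wors):
                eligible = False
                break
            mins[name] = (stab, wors)
        if not eligible:
            continue
        stable = all(
            mins[name][0][1] <= mins[name][0][0] for name in ("PEEP", "FiO2")
        )
        if not stable:
            continue
        fio2_base = min(mins["FiO2"][0])
        peep_base = min(mins["PEEP"][0])
        fio2_fires = all(m >= fio2_base + fio2_increase for m in mins["FiO2"][1])
        peep_fires = all(m >= peep_base + peep_increase for m in mins["PEEP"][1])
        if fio2_fires or peep_fires:
            trigger = (
                "both" if fio2_fires and peep_fires
                else ("FiO2" if fio2_fires else "PEEP")
            )
            return t, trigger
    return None


def random_setting_trajectories(n: int, seed: int):
    """Random 5-7 day hourly PEEP/FiO2 trajectories for oracle comparison.

    A mix of quiet, noisy and escalation-like courses so that both outcomes
    (event / no event) occur with useful frequency.
    """
    rng = np.random.default_rng(seed)
    vent_start = pd.Timestamp("2021-06-01 00:00")
    out = []
    for _ in range(n):
        hours = int(rng.integers(120, 169))
        idx = vent_start + pd.to_timedelta(np.arange(hours), unit="h")
        kind = rng.random()
        if kind < 0.4:
            # mild fluctuation around a base
            fio2 = 40 + rng.choice([0, 5, 10, 15], hours)
            peep = 5 + rng.choice([0, 1, 2], hours)
        elif kind < 0.8:
            # step escalation of one or both settings at a random hour
            step_at = int(rng.integers(24, hours - 24))
            fio2 = np.where(
                np.arange(hours) < step_at,
                40 + rng.choice([0, 5, 10], hours),
                40 + rng.choice([15, 20, 25, 30], hours),
            ).astype(float)
            peep = np.where(
                np.arange(hours) < step_at,
                5 + rng.choice([0, 1], hours),
                5 + rng.choice([2, 3, 4], hours),
            ).astype(float)
        else:
            # drifting random walk
            fio2 = np.clip(40 + np.cumsum(rng.choice([-5, 0, 5], hours)), 21, 100)
            peep = np.clip(5 + np.cumsum(rng.choice([-1, 0, 1], hours)), 0, 20)
        # random gaps so day-eligibility paths are exercised
        if rng.random() < 0.3:
            drop = rng.random(hours) < 0.1
            fio2 = np.where(drop, np.nan, fio2)
        out.append(
            (
                pd.Series(peep.astype(float), index=idx),
                pd.Series(fio2.astype(float), index=idx),
                vent_start,
                vent_start + pd.Timedelta(hours=hours),
            )
        )
    return out
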
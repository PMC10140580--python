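"""Generator contracts: prevalence, determinism, injection geometry,
missingness and outlier mechanics."""

import numpy as np
import pandas as pd
import pytest

import vacpred
from vacpred import SimConfig, apply_missingness, apply_outliers, generate_cohort
from vacpred.records import HOUR, chart_events_frame
from vacpred.synthetic import ConfigurationError, inject_vac_episode


def test_injected_count_follows_prevalence_rounding():
    _, truth = generate_cohort(
        SimConfig(n_patients=10, vac_prevalence=0.5, seed=1, missing_rate=0,
                  outlier_rate=0, vent_duration_hours=(96, 120))
    )
    assert len(truth.positives()) == 5


def test_same_seed_gives_byte_identical_cohort():
    cfg = SimConfig(n_patients=8, seed=42, vent_duration_hours=(96, 144))
    a, truth_a = generate_cohort(cfg)
    b, truth_b = generate_cohort(cfg)
    assert chart_events_frame(a).to_csv() == chart_events_frame(b).to_csv()
    assert {p: e for p, e in truth_a.events.items()} == truth_b.events


@pytest.mark.parametrize(
    "kwargs,field",
    [
        (dict(vac_prevalence=1.5), "vac_prevalence"),
        (dict(vent_duration_hours=(72, 120)), "vent_duration_hours"),
        (dict(missing_rate=-0.1), "missing_rate"),
        (dict(outlier_rate=2.0), "outlier_rate"),
        (dict(n_patients=0), "n_patients"),
    ],
)
def test_invalid_config_names_offending_field(kwargs, field):
    with pytest.raises(ConfigurationError, match=field):
        SimConfig(**kwargs)


def _one_record(seed=5, duration=(144, 144)):
    recs, truth = generate_cohort(
        SimConfig(n_patients=1, vac_prevalence=0.0, seed=seed, missing_rate=0,
                  outlier_rate=0, vent_duration_hours=duration)
    )
    return recs[0]


class TestInjection:
    def test_fio2_escalation_clears_threshold(self):
        rec = _one_record()
        onset = rec.vent_start + 60 * HOUR
        inj = inject_vac_episode(rec, onset, "FiO2", seed=3)
        fio2 = inj.channels["FiO2"].series
        stab = fio2[(fio2.index >= onset - 48 * HOUR) & (fio2.index < onset)]
        wors = fio2[(fio2.index >= onset) & (fio2.index < onset + 48 * HOUR)]
        day1 = stab[stab.index < onset - 24 * HOUR].min()
        day2 = stab[stab.index >= onset - 24 * HOUR].min()
        assert day2 <= day1  # non-increasing daily minima
        baseline = min(day1, day2)
        for lo in (onset, onset + 24 * HOUR):
            assert wors[(wors.index >= lo) & (wors.index < lo + 24 * HOUR)].min() \
                >= baseline + 20.0

    def test_peep_escalation_clears_threshold(self):
        rec = _one_record(seed=6)
        onset = rec.vent_start + 72 * HOUR
        inj = inject_vac_episode(rec, onset, "PEEP", seed=3)
        peep = inj.channels["PEEP"].series
        baseline = peep[(peep.index >= onset - 48 * HOUR)
                        & (peep.index < onset)].min()
        assert baseline == 5.0
        wors = peep[(peep.index >= onset) & (peep.index < onset + 48 * HOUR)]
        assert wors.min() >= baseline + 3.0

    def test_onset_outside_window_is_rejected(self):
        rec = _one_record()
        with pytest.raises(ValueError, match="48 h"):
            inject_vac_episode(rec, rec.vent_start + 24 * HOUR, "FiO2")
        with pytest.raises(ValueError, match="48 h"):
            inject_vac_episode(rec, rec.vent_end - 24 * HOUR, "FiO2")

    def test_detector_recovers_injected_onset(self):
        rec = _one_record(seed=9)
        onset = rec.vent_start + 50 * HOUR
        inj = inject_vac_episode(rec, onset, "PEEP", seed=1)
        events = vacpred.detect_vac(
            inj.channels["PEEP"].series, inj.channels["FiO2"].series,
            vacpred.VacCriteria(), inj.vent_start, inj.vent_end, inj.patient_id,
        )
        assert [e.onset_time for e in events] == [onset]
        assert events[0].trigger == "PEEP"


class TestMissingness:
    def test_rate_zero_is_identity(self):
        rec = _one_record()
        out = apply_missingness(rec, 0.0, seed=1)
        for name, ch in rec.channels.items():
            pd.testing.assert_series_equal(ch.series, out.channels[name].series)

    def test_rate_one_removes_everything(self):
        rec = _one_record()
        out = apply_missingness(rec, 1.0, seed=1)
        assert all(len(ch.series) == 0 for ch in out.channels.values())

    def test_removed_fraction_concentrates_near_rate(self):
        rec = _one_record()
        # inflate one channel to 10k points for a tight concentration check
        idx = rec.vent_start + pd.to_timedelta(
            np.linspace(0, 100, 10_000), unit="h"
        )
        rec.channels["HR"] = vacpred.Channel(
            "HR", pd.Series(np.full(10_000, 80.0), index=idx)
        )
        out = apply_missingness(rec, 0.2, run_length_mean=3.0, seed=11)
        frac = 1 - len(out.channels["HR"].series) / 10_000
        assert abs(frac - 0.2) < 0.02

    def test_removals_form_contiguous_runs(self):
        rec = _one_record()
        n = len(rec.channels["HR"].series)
        out = apply_missingness(rec, 0.3, run_length_mean=4.0, seed=2)
        kept = rec.channels["HR"].series.index.isin(
            out.channels["HR"].series.index
        )
        removed_runs = np.diff(np.flatnonzero(~kept))
        n_runs = int(np.sum(removed_runs > 1)) + 1
        assert n_runs < np.sum(~kept)  # fewer runs than removed points

    def test_seeded_determinism(self):
        rec = _one_record()
        a = apply_missingness(rec, 0.3, seed=5)
        b = apply_missingness(rec, 0.3, seed=5)
        for name in rec.channels:
            pd.testing.assert_series_equal(
                a.channels[name].series, b.channels[name].series
            )


class TestOutliers:
    def test_planted_values_fall_outside_valid_ranges(self):
        rec = _one_record()
        out, counts = apply_outliers(rec, 0.2, seed=4)
        for name, k in counts.items():
            lo, hi = vacpred.DEFAULT_RANGES[name]
            vals = out.channels[name].series.to_numpy()
            outside = int(np.sum((vals < lo) | (vals > hi)))
            assert outside == k

    def test_rate_zero_is_identity(self):
        rec = _one_record()
        out, counts = apply_outliers(rec, 0.0, seed=4)
        assert sum(counts.values()) == 0
        for name, ch in rec.channels.items():
            pd.testing.assert_series_equal(ch.series, out.channels[name].series)

    def test_range_filter_nulls_exactly_the_planted_count(self):
        rec = _one_record()
        out, counts = apply_outliers(rec, 0.15, seed=8)
        for name, k in counts.items():
            filtered = vacpred.filter_physiologic_range(
                out.channels[name].series, name
            )
            assert int(filtered.isna().sum()) == k

    def test_unranged_variables_are_skipped(self):
        rec = _one_record()
        out, counts = apply_outliers(rec, 0.5, seed=4)
        assert "TEMP" not in counts  # no Table-style range defined
        pd.testing.assert_series_equal(
            rec.channels["TEMP"].series, out.channels["TEMP"].series
        )


def test_negative_patients_never_trigger_on_clean_data(clean_cohort):
    records, truth = clean_cohort
    from vacpred.pipeline import detect_events

    detected = {e.patient_id for e in detect_events(records)}
    negatives = {p for p, e in truth.events.items() if e is None}
    assert detected.isdisjoint(negatives)


def test_detector_recovers_every_injected_onset(clean_cohort):
    records, truth = clean_cohort
    from vacpred.pipeline import detect_events

    detected = {e.patient_id: e for e in detect_events(records)}
    for pid, ev in truth.events.items():
        if ev is None:
            continue
        assert pid in detected
        assert detected[pid].onset_time == ev.onset_time
        assert detected[pid].trigger == ev.trigger
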
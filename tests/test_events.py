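"""Pulse detection, interval mixture, bout grouping and catalog rules."""

from datetime import datetime, timedelta

import numpy as np
import pytest

from vibrokit import audio_io, events
from vibrokit.events import (
    COMPONENT_LABELS,
    InsufficientIntervals,
    Pulse,
    detect_pulses,
    filter_rare_types,
    fit_interval_model,
    group_pulses,
    group_pulses_fallback,
    merge_same_sensor,
    resolve_airborne,
)
from .conftest import make_catalog

FS = 48000


def chunk_of(samples):
    return audio_io.RecordingChunk(waveform=audio_io.Waveform(samples, FS))


class TestDetectPulses:
    def test_all_zero_chunk_empty(self):
        det = detect_pulses(chunk_of(np.zeros(FS)))
        assert det.pulses == []

    def test_single_spike_found_at_its_sample(self):
        x = np.random.default_rng(0).normal(0, 0.001, 5 * FS)
        x[2 * FS + 17] = 10.0
        det = detect_pulses(chunk_of(x))
        assert len(det.pulses) == 1
        assert det.pulses[0].time == pytest.approx((2 * FS + 17) / FS,
                                                   abs=1 / FS)
        assert det.pulses[0].amplitude == pytest.approx(10.0)

    def test_min_separation_suppresses_ringing(self):
        x = np.random.default_rng(0).normal(0, 0.001, 2 * FS)
        i = FS
        x[i] = 10.0
        x[i + 200] = 6.0   # ~4 ms later: ringing, suppressed
        x[i + 4800] = 9.0  # 100 ms later: a second pulse
        det = detect_pulses(chunk_of(x))
        assert len(det.pulses) == 2


class TestIntervalModel:
    def test_three_mode_recovery(self):
        rng = np.random.default_rng(42)
        modes = [0.05, 2.0, 120.0]
        iv = np.concatenate([m * 10 ** (0.15 * rng.standard_normal(100))
                             for m in modes])
        model = fit_interval_model(iv, seed=0)
        for est, true in zip(model.means, np.log10(modes)):
            assert est == pytest.approx(true, abs=0.15)
        labels = model.classify(iv)
        expected = np.repeat(COMPONENT_LABELS, 100)
        assert np.mean(labels == expected) >= 0.99

    def test_too_few_intervals_signal_fallback(self):
        with pytest.raises(InsufficientIntervals):
            fit_interval_model(np.array([0.1] * 5), seed=0)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        iv = np.concatenate([m * 10 ** (0.1 * rng.standard_normal(50))
                             for m in (0.1, 3.0, 90.0)])
        a = fit_interval_model(iv, seed=0)
        b = fit_interval_model(iv[rng.permutation(iv.size)], seed=0)
        assert np.allclose(a.means, b.means)
        assert np.allclose(a.weights, b.weights)

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            fit_interval_model(np.array([0.1] * 12 + [0.0]), seed=0)


def model_from_modes(seed=0):
    rng = np.random.default_rng(seed)
    iv = np.concatenate([m * 10 ** (0.1 * rng.standard_normal(60))
                         for m in (0.1, 5.0, 120.0)])
    return fit_interval_model(iv, seed=seed)


class TestGroupPulses:
    def pulses_at(self, times):
        return [Pulse(time=t, amplitude=1.0) for t in times]

    def test_gap_pattern_splits_into_two_bouts(self):
        model = model_from_modes()
        times = np.cumsum([0.0, 0.1, 0.1, 5.0, 0.1, 0.1])
        bouts = group_pulses(self.pulses_at(times), model)
        assert [len(b.pulses) for b in bouts] == [3, 3]
        assert bouts[0].start_s == 0.0
        assert bouts[0].end_s == pytest.approx(0.2)
        assert bouts[1].start_s == pytest.approx(5.2)

    def test_all_within_gaps_single_bout(self):
        model = model_from_modes()
        bouts = group_pulses(self.pulses_at(np.arange(10) * 0.1), model)
        assert len(bouts) == 1
        assert len(bouts[0].pulses) == 10

    def test_single_pulse_zero_duration_bout(self):
        model = model_from_modes()
        bouts = group_pulses(self.pulses_at([3.0]), model)
        assert len(bouts) == 1
        assert bouts[0].duration == 0.0

    def test_pulses_partition_into_bouts(self):
        model = model_from_modes()
        times = np.cumsum(np.random.default_rng(0).choice(
            [0.1, 5.0, 120.0], size=50, p=[0.8, 0.15, 0.05]))
        pulses = self.pulses_at(times)
        bouts = group_pulses(pulses, model)
        regrouped = [p for b in bouts for p in b.pulses]
        assert regrouped == pulses

    def test_fallback_single_threshold(self):
        bouts = group_pulses_fallback(self.pulses_at([0.0, 0.5, 5.0, 5.5]),
                                      gap=2.0)
        assert [len(b.pulses) for b in bouts] == [2, 2]


class TestMergeSameSensor:
    def test_30s_apart_merges(self, t0):
        cat = make_catalog([
            {"start_time": t0, "duration_s": 5.0},
            {"start_time": t0 + timedelta(seconds=35), "duration_s": 5.0},
        ])
        merged = merge_same_sensor(cat)
        assert len(merged) == 1
        assert merged.iloc[0]["duration_s"] == pytest.approx(40.0)

    def test_70s_apart_stays_separate(self, t0):
        cat = make_catalog([
            {"start_time": t0, "duration_s": 5.0},
            {"start_time": t0 + timedelta(seconds=75), "duration_s": 5.0},
        ])
        assert len(merge_same_sensor(cat)) == 2

    def test_chain_merges_transitively(self, t0):
        cat = make_catalog([
            {"start_time": t0 + timedelta(seconds=s), "duration_s": 5.0}
            for s in (0.0, 55.0, 110.0)
        ])
        merged = merge_same_sensor(cat)
        assert len(merged) == 1
        assert merged.iloc[0]["duration_s"] == pytest.approx(115.0)

    def test_different_type_or_sensor_not_merged(self, t0):
        cat = make_catalog([
            {"start_time": t0},
            {"start_time": t0 + timedelta(seconds=10), "type_label": "sp2"},
            {"start_time": t0 + timedelta(seconds=20), "unit_id": "A-u02"},
        ])
        assert len(merge_same_sensor(cat)) == 3

    def test_never_increases_bout_count(self, t0):
        rng = np.random.default_rng(0)
        cat = make_catalog([
            {"start_time": t0 + timedelta(seconds=float(s)),
             "type_label": rng.choice(["a", "b"])}
            for s in np.sort(rng.uniform(0, 600, 40))
        ])
        assert len(merge_same_sensor(cat)) <= len(cat)


class TestResolveAirborne:
    def test_three_sensors_collapse_to_one_airborne(self, t0):
        cat = make_catalog([
            {"start_time": t0, "unit_id": f"A-u{i:02d}", "type_label": "bird"}
            for i in (1, 2, 3)
        ])
        out = resolve_airborne(cat)
        assert len(out) == 1
        assert bool(out.iloc[0]["airborne"])

    def test_same_type_10min_apart_stays_substrate(self, t0):
        cat = make_catalog([
            {"start_time": t0, "unit_id": "A-u01"},
            {"start_time": t0 + timedelta(minutes=10), "unit_id": "A-u02"},
        ])
        out = resolve_airborne(cat)
        assert len(out) == 2
        assert not out["airborne"].any()

    def test_different_types_overlapping_unchanged(self, t0):
        cat = make_catalog([
            {"start_time": t0, "unit_id": "A-u01", "type_label": "sp1"},
            {"start_time": t0, "unit_id": "A-u02", "type_label": "sp2"},
        ])
        out = resolve_airborne(cat)
        assert len(out) == 2
        assert not out["airborne"].any()

    def test_other_plot_not_collapsed(self, t0):
        cat = make_catalog([
            {"start_time": t0, "unit_id": "A-u01", "plot_id": "A"},
            {"start_time": t0, "unit_id": "D-u01", "plot_id": "D",
             "substrate": "pine_litter"},
        ])
        assert len(resolve_airborne(cat)) == 2


class TestFilterRareTypes:
    def make(self, counts, t0):
        rows = []
        for label, n in counts.items():
            rows += [{"start_time": t0 + timedelta(seconds=i),
                      "type_label": label} for i in range(n)]
        return make_catalog(rows)

    def test_strict_greater_than_boundary(self, t0):
        cat = self.make({"at100": 100, "at101": 101}, t0)
        out = filter_rare_types(cat, min_count=100)
        assert set(out["type_label"]) == {"at101"}
        assert len(out) == 101

    def test_empty_catalog_stays_empty(self):
        import pandas as pd
        assert filter_rare_types(pd.DataFrame()).empty
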
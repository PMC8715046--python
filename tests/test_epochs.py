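"""Epoch extraction, baseline correction, and condition averaging."""

import numpy as np
import pytest

from pupilkit import (DiameterSeries, PipelineConfig, TrialEpoch,
                      condition_average, extract_baseline_corrected_epochs)
from pupilkit.preprocess import DataError

FS = 250.0


def _series(values, missing=None):
    n = len(values)
    return DiameterSeries(np.arange(n) / FS,
                          np.asarray(values, float),
                          np.zeros(n, bool) if missing is None else missing)


class TestExtraction:
    def test_constant_series_gives_zero_epoch_of_full_span(self, config, events_factory):
        series = _series(np.full(int(20 * FS), 5.0))
        epochs = extract_baseline_corrected_epochs(
            series, events_factory([10.0], [3.0]), config)
        (e,) = epochs
        assert e.usable
        assert len(e.rel_time) == int((1 + 3 + 1) * FS)
        np.testing.assert_allclose(e.diameter_bc, 0.0, atol=1e-12)
        assert e.baseline == pytest.approx(5.0)

    def test_step_at_onset_measured_from_baseline(self, config, events_factory):
        n = int(20 * FS)
        t = np.arange(n) / FS
        values = np.where(t < 10.0, 5.0, 5.4)
        epochs = extract_baseline_corrected_epochs(
            _series(values), events_factory([10.0], [3.0]), config)
        (e,) = epochs
        pre = e.rel_time < 0
        np.testing.assert_allclose(e.diameter_bc[pre], 0.0, atol=1e-12)
        np.testing.assert_allclose(e.diameter_bc[~pre], 0.4, atol=1e-12)

    def test_fully_masked_baseline_flags_epoch_unusable(self, config, events_factory):
        n = int(20 * FS)
        missing = np.zeros(n, bool)
        t = np.arange(n) / FS
        missing[(t >= 9.85) & (t < 10.0)] = True   # covers the 100-ms baseline
        epochs = extract_baseline_corrected_epochs(
            _series(np.full(n, 5.0), missing), events_factory([10.0], [3.0]), config)
        assert not epochs[0].usable
        assert epochs[0].flag == "baseline_missing"

    def test_trial_past_recording_end_is_truncated(self, config, events_factory):
        series = _series(np.full(int(12 * FS), 5.0))
        epochs = extract_baseline_corrected_epochs(
            series, events_factory([10.0], [3.0]), config)
        assert epochs[0].truncated and not epochs[0].usable

    def test_no_trials_is_error(self, config, events_factory):
        series = _series(np.full(100, 5.0))
        with pytest.raises(DataError, match="no trials"):
            extract_baseline_corrected_epochs(
                series, events_factory([], []), config)

    def test_baseline_window_mean_is_zero_on_noisy_data(self, config, events_factory):
        rng = np.random.default_rng(11)
        series = _series(5.0 + rng.normal(0, 0.3, int(20 * FS)))
        (e,) = extract_baseline_corrected_epochs(
            series, events_factory([10.0], [6.0]), config)
        sel = (e.rel_time >= -config.baseline_window) & (e.rel_time < 0)
        assert abs(np.nanmean(e.diameter_bc[sel])) < 1e-9


def _epoch(values, duration, missing=None, fs=FS, **meta):
    n_pre = int(fs)
    values = np.asarray(values, float)
    n = len(values)
    rel = np.arange(-n_pre, n - n_pre) / fs
    full_meta = {"participant": "p0", "eye": "control", "drug": "control",
                 "duration": duration, "session": "s1", "trial_id": "t0"}
    full_meta.update(meta)
    return TrialEpoch(rel, values,
                      np.zeros(n, bool) if missing is None else missing,
                      full_meta)


class TestConditionAverage:
    def test_arithmetic_mean_of_two_epochs(self):
        n = int(5 * FS)
        avgs = condition_average(
            [_epoch(np.full(n, 0.2), 3.0, trial_id="a"),
             _epoch(np.full(n, 0.4), 3.0, trial_id="b")], fs=FS)
        (avg,) = avgs
        np.testing.assert_allclose(avg.mean_trace, 0.3)
        assert np.all(avg.n_trials == 2)

    def test_missing_point_uses_remaining_epoch(self):
        n = int(5 * FS)
        miss = np.zeros(n, bool)
        miss[600] = True
        avgs = condition_average(
            [_epoch(np.full(n, 0.2), 3.0, missing=miss, trial_id="a"),
             _epoch(np.full(n, 0.4), 3.0, trial_id="b")], fs=FS)
        (avg,) = avgs
        assert avg.mean_trace[600] == pytest.approx(0.4)
        assert avg.n_trials[600] == 1

    def test_pooled_durations_use_covering_epochs_only(self):
        epochs = [_epoch(np.full(int((1 + d + 1) * FS), 0.1 * d), d,
                         trial_id=f"t{d}") for d in (3.0, 6.0, 9.0)]
        (avg,) = condition_average(epochs, group_by=("participant", "eye", "drug"),
                                   fs=FS)
        at5 = np.searchsorted(avg.rel_time, 5.0)
        assert avg.n_trials[at5] == 2          # 6-s and 9-s epochs only
        assert avg.mean_trace[at5] == pytest.approx((0.6 + 0.9) / 2)
        assert avg.meta["duration"] == "pooled"

    def test_matches_naive_matrix_mean_when_complete(self):
        rng = np.random.default_rng(5)
        n = int(5 * FS)
        traces = rng.normal(size=(4, n))
        epochs = [_epoch(traces[i], 3.0, trial_id=f"t{i}") for i in range(4)]
        (avg,) = condition_average(epochs, fs=FS)
        np.testing.assert_allclose(avg.mean_trace, traces.mean(axis=0), atol=1e-12)

    def test_unusable_epochs_are_excluded(self):
        n = int(5 * FS)
        good = _epoch(np.full(n, 0.2), 3.0, trial_id="a")
        bad = _epoch(np.full(n, 9.9), 3.0, trial_id="b")
        bad.usable = False
        (avg,) = condition_average([good, bad], fs=FS)
        np.testing.assert_allclose(avg.mean_trace, 0.2)

    def test_constant_offset_absorbed_by_baseline_correction(self, config, events_factory):
        """Averaging commutes with adding a constant to the raw series."""
        rng = np.random.default_rng(3)
        raw = 5.0 + rng.normal(0, 0.1, int(30 * FS))
        events = events_factory([10.0, 20.0], [3.0, 3.0])
        out = {}
        for shift in (0.0, 1.23):
            eps = extract_baseline_corrected_epochs(
                _series(raw + shift), events, config)
            (avg,) = condition_average(eps, fs=FS)
            out[shift] = avg.mean_trace
        np.testing.assert_allclose(out[0.0], out[1.23], atol=1e-9)
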
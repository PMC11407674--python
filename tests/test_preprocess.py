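"""Autocalibration, nonwear detection, diary merge and validity
screening."""

import warnings

import numpy as np
import pandas as pd
import pytest

import actimetrics as am
from actimetrics.preprocess import (NONWEAR_AUTO, NONWEAR_DIARY, WEAR,
                                    CalibrationResult, apply_diary,
                                    autocalibrate, detect_nonwear,
                                    screen_validity)
from actimetrics.recording import RawRecording


class TestAutocalibrate:
    def test_identity_on_clean_recording(self):
        rec = am.calibration_validation_recording(seed=1)
        _, res = autocalibrate(rec)
        assert res.status == "ok"
        assert np.all(np.abs(res.offset) < 0.003)
        assert np.all(np.abs(res.scale - 1) < 0.003)
        assert res.post_error < 0.001

    def test_recovers_injected_error(self):
        offset = np.array([0.02, -0.01, 0.03])
        scale = np.array([1.01, 0.99, 1.00])
        rec = am.calibration_validation_recording(seed=2,
                                                  calib_error=(offset, scale))
        corrected, res = autocalibrate(rec)
        assert np.all(np.abs(res.offset - offset) < 0.005)
        assert np.all(np.abs(res.scale - scale) < 0.005)
        assert res.post_error < 0.005
        # corrected stationary windows sit back on the unit sphere
        _, res2 = autocalibrate(corrected)
        assert res2.post_error < 0.001

    def test_idempotent(self):
        rec = am.calibration_validation_recording(
            seed=3, calib_error=((0.02, 0.0, -0.02), (1.02, 0.98, 1.0)))
        c1, _ = autocalibrate(rec)
        _, res2 = autocalibrate(c1)
        assert np.all(np.abs(res2.offset) < 1e-4)
        assert np.all(np.abs(res2.scale - 1) < 1e-4)

    def test_insufficient_stillness_skipped(self, rng):
        x = rng.normal(0, 0.5, (30 * 600, 3)) + [0, 0, 1]  # never still
        rec = RawRecording(30.0, "2022-06-06T00:00:00", x)
        out, res = autocalibrate(rec)
        assert res.status == "skipped_insufficient_windows"
        assert np.array_equal(out.samples, rec.samples)

    def test_low_orientation_diversity_skipped(self, rng):
        x = np.tile([0.0, 0.0, 1.0], (30 * 1200, 1)) + rng.normal(0, 0.003, (30 * 1200, 3))
        rec = RawRecording(30.0, "2022-06-06T00:00:00", x)
        _, res = autocalibrate(rec)
        assert res.status == "skipped_low_diversity"

    def test_exclusion_threshold(self):
        assert CalibrationResult(np.zeros(3), np.ones(3), 0.012, 50).exclude
        assert not CalibrationResult(np.zeros(3), np.ones(3), 0.01, 50).exclude


def _active_samples(n_s, fs=30.0, rng=None):
    """Motion on two axes, clearly worn."""
    t = np.arange(int(n_s * fs)) / fs
    x = np.zeros((t.size, 3))
    x[:, 2] = 1.0 + 0.2 * np.sin(2 * np.pi * 1.0 * t)
    x[:, 0] = 0.15 * np.sin(2 * np.pi * 0.7 * t)
    if rng is not None:
        x += rng.normal(0, 0.005, x.shape)
    return x


class TestNonwear:
    def test_motionless_segment_flagged(self, rng):
        fs = 30.0
        parts = [_active_samples(3 * 3600, rng=rng),
                 np.tile([0.0, 0.0, 1.0], (int(2 * 3600 * fs), 1))
                 + rng.normal(0, 0.005, (int(2 * 3600 * fs), 3)),
                 _active_samples(3 * 3600, rng=rng)]
        rec = RawRecording(fs, "2022-06-06T00:00:00", np.vstack(parts))
        mask = detect_nonwear(rec)
        idx = mask.epoch_index()
        mid = (idx >= "2022-06-06 03:30") & (idx < "2022-06-06 04:30")
        assert np.all(mask.flags[mid] == NONWEAR_AUTO)
        # detected nonwear minutes within one 15-min step per transition
        nonwear_min = (mask.flags == NONWEAR_AUTO).sum() * mask.epoch_len / 60
        assert abs(nonwear_min - 120) <= 30

    def test_continuous_activity_never_flagged(self, rng):
        rec = RawRecording(30.0, "2022-06-06T00:00:00",
                           _active_samples(2 * 3600, rng=rng))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask = detect_nonwear(rec)
        assert np.all(mask.flags == WEAR)

    def test_single_quiet_axis_is_wear(self, rng):
        # z quiet, x and y active: only one quiet axis -> worn
        fs = 30.0
        t = np.arange(int(2 * 3600 * fs)) / fs
        x = np.zeros((t.size, 3))
        x[:, 0] = 0.2 * np.sin(2 * np.pi * 0.8 * t)
        x[:, 1] = 0.2 * np.sin(2 * np.pi * 1.1 * t)
        x[:, 2] = 1.0
        x += rng.normal(0, 0.005, x.shape)
        rec = RawRecording(fs, "2022-06-06T00:00:00", x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask = detect_nonwear(rec)
        assert np.all(mask.flags == WEAR)

    def test_schedule_recovery_on_synthetic_day(self):
        profile = {"sleep": 480, "SB": 690, "LPA": 30, "MVPA": 60,
                   "nonwear": 180}
        sched = am.generate_bout_schedule(profile, days=1, seed=3)
        rec = am.synthesize_raw_recording(sched, sample_rate=20.0, seed=4)
        mask = detect_nonwear(rec)
        nonwear_min = (mask.flags == NONWEAR_AUTO).sum() * mask.epoch_len / 60
        assert abs(nonwear_min - 180) <= 30  # one window step per transition


class TestDiary:
    def _mask(self, hours=4):
        n = int(hours * 3600 / 5)
        return am.WearMask(5.0, np.zeros(n, dtype=np.int8),
                           np.datetime64("2022-06-06T12:00:00"))

    def test_offbody_overrides_signal(self):
        diary = pd.DataFrame({"start": [pd.Timestamp("2022-06-06 14:00")],
                              "end": [pd.Timestamp("2022-06-06 15:00")],
                              "type": ["offbody"]})
        out = apply_diary(self._mask(), diary)
        idx = out.epoch_index()
        swim = (idx >= "2022-06-06 14:00") & (idx < "2022-06-06 15:00")
        assert np.all(out.flags[swim] == NONWEAR_DIARY)
        assert np.all(out.flags[~swim] == WEAR)

    def test_empty_diary_identity(self):
        m = self._mask()
        out = apply_diary(m, pd.DataFrame(columns=["start", "end", "type"]))
        assert np.array_equal(out.flags, m.flags)

    def test_sleep_intervals_leave_mask_unchanged(self):
        m = self._mask()
        diary = pd.DataFrame({"start": [pd.Timestamp("2022-06-06 13:00")],
                              "end": [pd.Timestamp("2022-06-06 14:00")],
                              "type": ["sleep"]})
        out = apply_diary(m, diary)
        assert np.array_equal(out.flags, m.flags)

    def test_diary_wins_over_auto(self):
        m = self._mask()
        m.flags[:100] = NONWEAR_AUTO
        diary = pd.DataFrame({"start": [pd.Timestamp("2022-06-06 12:00")],
                              "end": [pd.Timestamp("2022-06-06 12:10")],
                              "type": ["offbody"]})
        out = apply_diary(m, diary)
        assert np.all(out.flags[:120] == NONWEAR_DIARY)

    def test_overlapping_intervals_merged_with_warning(self):
        diary = pd.DataFrame({
            "start": pd.to_datetime(["2022-06-06 13:00", "2022-06-06 13:30"]),
            "end": pd.to_datetime(["2022-06-06 14:00", "2022-06-06 14:30"]),
            "type": ["offbody", "offbody"]})
        with pytest.warns(UserWarning, match="overlapping"):
            out = apply_diary(self._mask(), diary)
        idx = out.epoch_index()
        assert np.all(out.flags[(idx >= "2022-06-06 13:00")
                                & (idx < "2022-06-06 14:30")] == NONWEAR_DIARY)


def _week_mask(day_wear_min):
    """Mask with given wear minutes per calendar day (Mon..)."""
    flags = []
    for wear in day_wear_min:
        n = 1440 * 12  # 5-s epochs per day
        f = np.zeros(n, dtype=np.int8)
        f[int(wear * 12):] = NONWEAR_AUTO
        flags.append(f)
    return am.WearMask(5.0, np.concatenate(flags),
                       np.datetime64("2022-06-06T00:00:00"))  # a Monday


GOOD_CALIB = CalibrationResult(np.zeros(3), np.ones(3), 0.002, 100)


class TestValidity:
    def test_full_week_valid(self):
        rep = screen_validity(_week_mask([1440] * 7), GOOD_CALIB)
        assert rep.file_valid and rep.n_valid_weekdays == 5
        assert rep.n_valid_weekend_days == 2

    def test_weekdays_only_invalid(self):
        rep = screen_validity(_week_mask([1000] * 5 + [100, 100]), GOOD_CALIB)
        assert not rep.file_valid
        assert "weekend" in rep.exclusion_reason

    def test_exact_16h_boundary_is_valid(self):
        rep = screen_validity(_week_mask([960] * 7), GOOD_CALIB)
        assert rep.valid_day.all() and rep.file_valid

    def test_959_min_invalid_day(self):
        rep = screen_validity(_week_mask([959] * 7), GOOD_CALIB)
        assert not rep.valid_day.any()

    def test_calibration_error_excludes_file(self):
        bad = CalibrationResult(np.zeros(3), np.ones(3), 0.012, 100)
        rep = screen_validity(_week_mask([1440] * 7), bad)
        assert not rep.file_valid
        assert "calibration" in rep.exclusion_reason

    def test_four_day_minimum(self):
        rep = screen_validity(_week_mask([1440, 1440, 1440, 100, 100, 100, 100]),
                              GOOD_CALIB)
        assert not rep.file_valid and "valid days" in rep.exclusion_reason
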
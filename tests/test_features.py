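"""Cut-point scaling/classification, sleep detection, daily time use,
average acceleration, intensity gradient, weighted week average."""

import numpy as np
import pandas as pd
import pytest

import actimetrics as am
from actimetrics.features import (DEFAULT_CUTPOINTS, classify_intensity,
                                  daily_time_use, hdcza_sleep_window,
                                  intensity_gradient, average_acceleration,
                                  scale_cutpoints, sleep_mask_from_windows,
                                  weighted_week_average, detect_sleep)

T0 = np.datetime64("2022-06-06T00:00:00")


class TestCutpoints:
    def test_cpm_scaling_to_5s(self):
        cp = scale_cutpoints(DEFAULT_CUTPOINTS["CPM_VA"], 5.0)
        assert cp.mpa == pytest.approx(2020 * 5 / 60, abs=1e-9)
        assert cp.mpa == pytest.approx(168.33, abs=0.005)
        vm = scale_cutpoints(DEFAULT_CUTPOINTS["CPM_VM"], 5.0)
        assert vm.vpa == pytest.approx(513.83, abs=0.005)

    def test_mg_passthrough(self):
        cp = scale_cutpoints(DEFAULT_CUTPOINTS["ENMO"], 5.0)
        assert (cp.lpa, cp.mpa, cp.vpa) == (47.0, 69.0, 260.0)

    def test_nonpositive_epoch_rejected(self):
        with pytest.raises(ValueError):
            scale_cutpoints(DEFAULT_CUTPOINTS["CPM_VA"], 0.0)


class TestClassify:
    def test_printed_examples(self):
        enmo = DEFAULT_CUTPOINTS["ENMO"]
        assert classify_intensity([50.0], enmo)[0] == 1  # LPA
        mad = DEFAULT_CUTPOINTS["MAD"]
        assert classify_intensity([94.0], mad)[0] == 2  # boundary -> MPA
        va5 = scale_cutpoints(DEFAULT_CUTPOINTS["CPM_VA"], 5.0)
        assert classify_intensity([169.0], va5)[0] == 2

    def test_lower_inclusive_boundaries(self):
        cp = DEFAULT_CUTPOINTS["ENMO"]
        vals = [46.999, 47.0, 68.999, 69.0, 259.999, 260.0]
        assert list(classify_intensity(vals, cp)) == [0, 1, 1, 2, 2, 3]

    def test_monotone_in_value(self, rng):
        cp = DEFAULT_CUTPOINTS["MAD"]
        v = np.sort(rng.uniform(0, 500, 200))
        cls = classify_intensity(v, cp)
        assert np.all(np.diff(cls.astype(int)) >= 0)

    def test_metric_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_intensity([10.0], DEFAULT_CUTPOINTS["ENMO"], metric="MAD")


class TestSleep:
    def test_diary_precedence(self):
        diary = pd.DataFrame({"start": [pd.Timestamp("2022-06-06 23:00")],
                              "end": [pd.Timestamp("2022-06-07 07:00")],
                              "type": ["sleep"]})
        wins = detect_sleep(diary)
        assert len(wins) == 1
        minutes = (wins[0][1] - wins[0][0]) / np.timedelta64(60, "s")
        assert minutes == 480

    def test_hdcza_recovers_constant_posture_block(self, rng):
        fs = 20.0
        # 21:00 -> 09:00 span; lying still 23:30-06:30, restless otherwise
        def seg(hours, lying, seed):
            r = np.random.default_rng(seed)
            n = int(hours * 3600 * fs)
            x = np.zeros((n, 3))
            if lying:
                x[:, 0] = 1.0
                x += r.normal(0, 0.004, x.shape)
            else:
                t = np.arange(n) / fs
                # posture flips every ~2 min -> z-angle keeps changing
                flips = (np.floor(t / 120) % 2).astype(int)
                x[:, 2] = np.where(flips, 1.0, 0.2)
                x[:, 1] = np.where(flips, 0.1, 0.95)
                x += r.normal(0, 0.01, x.shape)
            return x
        x = np.vstack([seg(2.5, False, 1), seg(7.0, True, 2), seg(2.5, False, 3)])
        t0 = np.datetime64("2022-06-06T21:00:00")
        win = hdcza_sleep_window(x, fs, t0)
        assert win is not None
        start_err = abs((win[0] - np.datetime64("2022-06-06T23:30:00"))
                        / np.timedelta64(60, "s"))
        end_err = abs((win[1] - np.datetime64("2022-06-07T06:30:00"))
                      / np.timedelta64(60, "s"))
        assert start_err <= 10 and end_err <= 10

    def test_hdcza_rejects_unstable_night(self, rng):
        fs = 20.0
        n = int(8 * 3600 * fs)
        t = np.arange(n) / fs
        x = np.zeros((n, 3))
        # z-angle swinging +/-20 deg on a 30-s period, never 5-min stable
        ang = np.radians(20 * np.sin(2 * np.pi * t / 30))
        x[:, 2] = np.sin(ang)
        x[:, 0] = np.cos(ang)
        win = hdcza_sleep_window(x, fs, T0)
        assert win is None


class TestIntensityGradient:
    def test_exact_power_law(self):
        # minutes(bin) proportional to midpoint^-2 over mids 12.5, 37.5,
        # 112.5 (ratios 1:9:81) -> slope exactly -2, r2 = 1
        vals = np.concatenate([np.full(324, 12.5), np.full(36, 37.5),
                               np.full(4, 112.5)])
        slope, intercept, r2 = intensity_gradient(vals, 5.0, 25.0)
        assert slope == pytest.approx(-2.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_doubling_shifts_intercept_not_slope(self, rng):
        vals = rng.gamma(2.0, 20.0, 2000)
        s1, i1, _ = intensity_gradient(vals, 5.0, 25.0)
        s2, i2, _ = intensity_gradient(2 * vals, 5.0, 50.0)
        # doubled bin width keeps occupancies identical; midpoints double
        assert s2 == pytest.approx(s1, abs=1e-9)
        assert i2 == pytest.approx(i1 - s1 * np.log(2), abs=1e-9)

    def test_single_bin_undefined(self):
        out = intensity_gradient(np.full(100, 10.0), 5.0, 25.0)
        assert all(np.isnan(v) for v in out)

    def test_reordering_invariance(self, rng):
        vals = rng.gamma(2.0, 20.0, 1000)
        a = intensity_gradient(vals, 5.0, 25.0)
        b = intensity_gradient(rng.permutation(vals), 5.0, 25.0)
        assert a == pytest.approx(b)


class TestAverageAcceleration:
    def test_constant(self):
        assert average_acceleration(np.full(17280, 30.0)) == 30.0

    def test_half_half(self):
        v = np.concatenate([np.zeros(8640), np.full(8640, 60.0)])
        assert average_acceleration(v) == 30.0

    def test_nonwear_excluded(self):
        v = np.concatenate([np.full(100, 1000.0), np.full(100, 30.0)])
        wear = np.concatenate([np.zeros(100, bool), np.ones(100, bool)])
        assert average_acceleration(v, wear) == 30.0


def _make_day(classes_min, sleep_min=480, nonwear_min=0):
    """Build per-epoch arrays for one synthetic day from minute totals."""
    order = []
    order += [("sleep", sleep_min)]
    for k, m in enumerate(classes_min):
        order += [(k, m)]
    order += [("nonwear", nonwear_min)]
    n = 1440 * 12
    classes = np.zeros(n, dtype=int)
    wear = np.ones(n, dtype=bool)
    sleep = np.zeros(n, dtype=bool)
    values = np.zeros(n)
    i = 0
    for what, minutes in order:
        j = i + minutes * 12
        if what == "sleep":
            sleep[i:j] = True
        elif what == "nonwear":
            wear[i:j] = False
        else:
            classes[i:j] = what
            values[i:j] = [10.0, 55.0, 150.0, 400.0][what]
        i = j
    assert i == n
    return classes, values, wear, sleep


class TestDailyTimeUse:
    def test_conservation_with_nonwear(self):
        classes, values, wear, sleep = _make_day([700, 100, 80, 20],
                                                 sleep_min=480, nonwear_min=60)
        d = daily_time_use(classes, values, wear, sleep, T0, 5.0)
        row = d.iloc[0]
        total = row["sleep"] + row["SB"] + row["LPA"] + row["MVPA"] + row["nonwear"]
        assert total == pytest.approx(1440)
        assert row["MVPA"] == row["MPA"] + row["VPA"] == 100
        assert row["nonwear"] == 60

    def test_all_sleep_day(self):
        n = 1440 * 12
        d = daily_time_use(np.zeros(n, int), np.zeros(n), np.ones(n, bool),
                           np.ones(n, bool), T0, 5.0)
        row = d.iloc[0]
        assert row["sleep"] == 1440
        assert row["SB"] == row["LPA"] == row["MVPA"] == 0

    def test_enmo_more_sedentary_than_mad_between_cutpoints(self):
        """A bout whose vector-magnitude dynamics put MAD in its LPA band
        while ENMO stays below 47 mg is sedentary under ENMO only."""
        fs = 30.0
        t = np.arange(int(1800 * fs)) / fs
        x = np.zeros((t.size, 3))
        x[:, 2] = 1.0 + 0.05 * np.sin(2 * np.pi * 1.0 * t)  # 50 mg sinusoid
        enmo = am.epoch_enmo(x, fs)
        mad = am.epoch_mad(x, fs)
        assert np.all(enmo < 47) and np.all((mad > 22.5) & (mad < 94))
        cls_enmo = classify_intensity(enmo, DEFAULT_CUTPOINTS["ENMO"])
        cls_mad = classify_intensity(mad, DEFAULT_CUTPOINTS["MAD"])
        assert (cls_enmo == 0).sum() > (cls_mad == 0).sum()


class TestWeightedWeek:
    def _daily(self, wd_sb, we_sb):
        rows = []
        for i in range(7):
            weekend = i >= 5
            sb = we_sb if weekend else wd_sb
            rows.append({"date": pd.Timestamp("2022-06-06") + pd.Timedelta(days=i),
                         "sleep": 500.0, "SB": sb, "LPA": 1440 - 500 - sb - 60,
                         "MPA": 45.0, "VPA": 15.0, "MVPA": 60.0,
                         "nonwear": 0.0, "wear_min": 1440.0,
                         "avg_accel": 20.0, "ig_slope": -2.0,
                         "ig_intercept": 12.0, "ig_r2": 0.9,
                         "is_weekend": weekend})
        return pd.DataFrame(rows).set_index("date")

    def test_weighting_formula(self):
        ad = weighted_week_average(self._daily(600.0, 530.0))
        assert ad.minutes["SB"] == pytest.approx((600 * 5 + 530 * 2) / 7)

    def test_identical_days_identity_and_closure(self):
        ad = weighted_week_average(self._daily(580.0, 580.0))
        assert ad.minutes["SB"] == pytest.approx(580.0)
        assert ad.composition.sum() == pytest.approx(1440, abs=1e-9)

    def test_insufficient_days_rejected(self):
        d = self._daily(600.0, 530.0).iloc[:4]  # no weekend rows
        with pytest.raises(ValueError, match="insufficient"):
            weighted_week_average(d)


def test_sleep_mask_from_windows_covers_intervals():
    wins = [(np.datetime64("2022-06-06T23:00:00"),
             np.datetime64("2022-06-07T07:00:00"))]
    mask = sleep_mask_from_windows(wins, T0, 2 * 1440 * 12, 5.0)
    assert mask.sum() * 5 / 60 == 480
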
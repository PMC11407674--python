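"""End-to-end orchestration: raw recording -> per-metric average day,
plus cohort-level reporting helpers.

The per-recording chain is calibration -> nonwear -> diary merge ->
validity screening -> 5-s epoch metrics -> cut-point classification ->
sleep -> daily summaries -> weighted average day, run once per metric
with that metric's cut-points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as ft
from . import metrics as mt
from . import preprocess as pp
from .coda import DAY_MINUTES, close_composition
from .recording import RawRecording
from .synthetic import TABLE1_PROFILES


@dataclass
class ParticipantResult:
    participant: str
    calibration: pp.CalibrationResult
    validity: pp.ValidityReport
    daily: dict          # metric -> per-day DataFrame
    average_days: dict   # metric -> AverageDay (only when file valid)
    sleep_windows: list


def process_recording(rec: RawRecording, diary: pd.DataFrame | None = None,
                      participant: str = "", epoch_len: float = 5.0,
                      cutpoints: dict = ft.DEFAULT_CUTPOINTS,
                      counts_cfg: mt.CountsConfig = mt.CountsConfig(),
                      ig_bin_width_mg: float = 25.0,
                      autocalibrate: bool = True) -> ParticipantResult:
    """Run the full feature pipeline on one raw recording."""
    if autocalibrate:
        rec, calib = pp.autocalibrate(rec)
    else:
        calib = pp.CalibrationResult(np.zeros(3), np.ones(3), 0.0, 0, "skipped")
    mask = pp.detect_nonwear(rec, epoch_len=epoch_len)
    mask = pp.apply_diary(mask, diary)
    validity = pp.screen_validity(mask, calib)

    series = mt.compute_epoch_series(rec.samples, rec.sample_rate,
                                     epoch_len, counts_cfg, t0=rec.t0)
    n = min(mask.n_epochs, len(series["ENMO"].values))
    wear = mask.wear[:n]
    sleep_windows = ft.detect_sleep(diary, raw=rec.samples,
                                    sample_rate=rec.sample_rate, t0=rec.t0)
    sleep_mask = ft.sleep_mask_from_windows(sleep_windows, rec.t0, n, epoch_len)

    valid_by_date = validity.valid_day
    daily, avg = {}, {}
    for m, s in series.items():
        cp = ft.scale_cutpoints(cutpoints[m], epoch_len)
        vals = np.asarray(s.values[:n], dtype=float)
        classes = ft.classify_intensity(vals, cp, metric=m)
        if m in ("ENMO", "MAD"):
            bw = ig_bin_width_mg
        else:
            bw = ft.counts_ig_bin_width(vals, series["ENMO"].values[:n],
                                        ig_bin_width_mg)
        d = ft.daily_time_use(classes, vals, wear, sleep_mask, rec.t0,
                              epoch_len, ig_bin_width=bw)
        daily[m] = d
        if validity.file_valid:
            vmask = [bool(valid_by_date.get(date, False)) for date in d.index]
            avg[m] = ft.weighted_week_average(d, participant, m, vmask)
    return ParticipantResult(participant, calib, validity, daily, avg,
                             sleep_windows)


# ---------------------------------------------------------------------------
# cohort-level reporting


def behavior_share_percent(minutes: float, total: float = DAY_MINUTES) -> int:
    """Percentage of the day, rounded half away from zero to an integer
    (the convention of the descriptive table)."""
    return int(np.floor(100.0 * minutes / total + 0.5))


def time_use_share_table(profiles: dict = TABLE1_PROFILES) -> pd.DataFrame:
    """Minutes and percentage-of-day shares for per-metric mean days.

    ``profiles`` maps metric -> {behavior: min/day}; shares are computed
    from the minutes, so a row whose minutes sum to 1440 yields shares
    summing to ~100.
    """
    rows = []
    for metric, prof in profiles.items():
        for beh, minutes in prof.items():
            rows.append({"metric": metric, "behavior": beh,
                         "min_per_day": minutes,
                         "share_pct": behavior_share_percent(minutes)})
    return pd.DataFrame(rows)


def average_day_table(average_days) -> pd.DataFrame:
    """Long feature table (one row per participant x metric) from
    AverageDay objects — the input contract of the agreement grid."""
    rows = []
    for ad in average_days:
        sleep, sb, lpa, mvpa = np.asarray(ad.composition, dtype=float)
        rows.append({
            "id": ad.participant, "metric": ad.metric,
            "sleep": sleep, "SB": sb, "LPA": lpa, "MVPA": mvpa,
            "MPA": ad.minutes.get("MPA", np.nan),
            "VPA": ad.minutes.get("VPA", np.nan),
            "avg_accel": ad.avg_accel, "ig_slope": ad.ig_slope,
            "ig_intercept": ad.ig_intercept, "ig_r2": ad.ig_r2,
        })
    return pd.DataFrame(rows)


def cohort_descriptives(feature_table: pd.DataFrame) -> pd.DataFrame:
    """Table-1 style per-metric descriptives: mean (SD) of each feature
    and the percentage-of-day share of each behaviour's mean minutes."""
    out = []
    for metric, g in feature_table.groupby("metric"):
        row = {"metric": metric, "n": len(g)}
        for beh in ("sleep", "SB", "LPA", "MVPA"):
            row[f"{beh}_min"] = g[beh].mean()
            row[f"{beh}_pct"] = behavior_share_percent(g[beh].mean())
        for col in ("avg_accel", "ig_slope", "ig_intercept", "ig_r2"):
            row[f"{col}_mean"] = g[col].mean()
            row[f"{col}_sd"] = g[col].std(ddof=1)
        out.append(row)
    return pd.DataFrame(out)


def simulate_cohort_features(n: int, seed: int,
                             profiles: dict = TABLE1_PROFILES,
                             accel_stats: dict | None = None) -> pd.DataFrame:
    """Synthetic per-participant feature table across the four metrics.

    Compositions are logistic-normal around each metric's mean profile
    with the person-level ILR deviation shared across metrics (plus
    smaller metric-specific noise); volume and gradient features are
    drawn around the printed means with the same participant-level
    activity factor.  The shared components induce the within-person
    between-metric correlation the agreement grid measures.  Used by the
    agreement/compliance stages when raw-signal simulation for a whole
    cohort would be disproportionate.
    """
    from .coda import close_composition, ilr_inverse, ilr_transform

    if accel_stats is None:
        accel_stats = {  # mean, SD of avg accel; mean, SD of gradient
            "ENMO": (18.66, 5.74, -2.22, 0.28),
            "MAD": (31.15, 9.29, -1.89, 0.22),
            "CPM_VA": (28.96, 10.43, -1.76, 0.19),
            "CPM_VM": (63.58, 18.12, -1.56, 0.12),
        }
    rng = np.random.default_rng(seed)
    activity = rng.normal(0, 1, n)  # shared participant factor
    person_z = rng.normal(0, 1, (n, 3)) * [0.10, 0.15, 0.21]
    rows = []
    for k, (metric, prof) in enumerate(profiles.items()):
        comp_mean = [prof["sleep"], prof["SB"], prof["LPA"], prof["MVPA"]]
        mu = ilr_transform(close_composition(comp_mean))
        z = mu + person_z + rng.normal(0, 1, (n, 3)) * [0.06, 0.09, 0.13]
        comps = ilr_inverse(z)
        aa_m, aa_sd, ig_m, ig_sd = accel_stats[metric]
        noise = rng.normal(0, 1, (n, 2))
        aa = aa_m + aa_sd * (0.8 * activity + 0.6 * noise[:, 0])
        ig = ig_m + ig_sd * (0.7 * activity + 0.714 * noise[:, 1])
        for i in range(n):
            sleep, sb, lpa, mvpa = comps[i]
            rows.append({
                "id": f"P{i:04d}", "metric": metric,
                "sleep": sleep, "SB": sb, "LPA": lpa, "MVPA": mvpa,
                "MPA": 0.75 * mvpa, "VPA": 0.25 * mvpa,
                "avg_accel": aa[i], "ig_slope": ig[i],
                "ig_intercept": 12.0 - 0.5 * k, "ig_r2": 0.88,
            })
    return pd.DataFrame(rows)
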
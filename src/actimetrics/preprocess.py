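"""Raw-signal screening: autocalibration, nonwear detection, diary merge
and recording validity.

The calibration model assumes the sensor reports
``recorded = truth * scale + offset`` per axis; stationary windows (low
per-axis variability) should have unit vector magnitude, so offset and
scale are estimated by iteratively regressing each axis of the stationary
means onto its projection on the unit sphere.  Files whose corrected
stationary magnitudes still deviate from 1 g by more than 0.01 g on
average are flagged for exclusion.

Nonwear uses the long-window low-variability rule: within a 60-min
window (slid in 15-min steps) the device is off-body when at least two
of three axes have SD < 13 mg, or when the accumulated acceleration
range is < 50 mg on at least two axes.  Diary off-body intervals always
override the signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import RawRecording

WEAR, NONWEAR_AUTO, NONWEAR_DIARY = 0, 1, 2


@dataclass
class CalibrationResult:
    """Estimated sensor error: corrected = (recorded - offset) / scale."""

    offset: np.ndarray
    scale: np.ndarray
    post_error: float
    n_stationary_windows: int
    status: str = "ok"  # ok | skipped_insufficient_windows | skipped_low_diversity

    @property
    def exclude(self) -> bool:
        """Post-calibration error above the 0.01 g exclusion threshold."""
        return not (self.post_error <= 0.01)


@dataclass
class WearMask:
    """Per-epoch wear flags covering the full recording."""

    epoch_len: float
    flags: np.ndarray  # int8: 0 wear, 1 nonwear (signal), 2 nonwear (diary)
    t0: np.datetime64

    @property
    def wear(self) -> np.ndarray:
        return self.flags == WEAR

    @property
    def n_epochs(self) -> int:
        return self.flags.size

    def epoch_index(self) -> pd.DatetimeIndex:
        return pd.date_range(pd.Timestamp(np.datetime64(self.t0, "s")),
                             periods=self.n_epochs,
                             freq=pd.Timedelta(seconds=self.epoch_len))


@dataclass
class ValidityReport:
    day_wear_min: pd.Series
    valid_day: pd.Series
    n_valid_weekdays: int
    n_valid_weekend_days: int
    post_error: float
    file_valid: bool
    exclusion_reason: str | None = None


def _stationary_window_means(samples, sample_rate, window_s, stillness_sd):
    n = int(round(window_s * sample_rate))
    m = (samples.shape[0] // n) * n
    w = samples[:m].reshape(-1, n, 3)
    sd = w.std(axis=1)
    still = np.all(sd < stillness_sd, axis=1)
    return w.mean(axis=1)[still]


def autocalibrate(rec: RawRecording, window_s: float = 10.0,
                  stillness_sd: float = 0.013, max_iter: int = 200,
                  tol: float = 1e-12, min_windows: int = 10,
                  min_spread: float = 0.15):
    """Estimate and apply the per-axis offset/scale correction.

    Returns a corrected :class:`RawRecording` and a
    :class:`CalibrationResult`.  When fewer than ``min_windows``
    stationary windows are found, or their orientations are too similar
    (max pairwise distance below ``min_spread`` g), calibration is
    skipped: the recording is returned unchanged and the post-error is
    evaluated on the raw stationary windows.
    """
    pts = _stationary_window_means(rec.samples, rec.sample_rate, window_s,
                                   stillness_sd)
    n_still = pts.shape[0]

    def _post_error(p):
        if p.shape[0] == 0:
            return float("nan")
        return float(np.mean(np.abs(np.linalg.norm(p, axis=1) - 1.0)))

    if n_still < min_windows:
        return rec, CalibrationResult(np.zeros(3), np.ones(3),
                                      _post_error(pts), n_still,
                                      "skipped_insufficient_windows")
    spread = max(
        float(pts[:, i].max() - pts[:, i].min()) for i in range(3))
    if spread < min_spread:
        return rec, CalibrationResult(np.zeros(3), np.ones(3),
                                      _post_error(pts), n_still,
                                      "skipped_low_diversity")

    # iterative closest-point-on-sphere least squares, per axis
    d = np.zeros(3)
    e = np.ones(3)
    for _ in range(max_iter):
        cur = d + e * pts
        norms = np.linalg.norm(cur, axis=1, keepdims=True)
        target = cur / norms
        d_new, e_new = np.empty(3), np.empty(3)
        for ax in range(3):
            A = np.column_stack([np.ones(n_still), pts[:, ax]])
            coef, *_ = np.linalg.lstsq(A, target[:, ax], rcond=None)
            d_new[ax], e_new[ax] = coef
        if np.max(np.abs(d_new - d)) < tol and np.max(np.abs(e_new - e)) < tol:
            d, e = d_new, e_new
            break
        d, e = d_new, e_new

    corrected_pts = d + e * pts
    post = _post_error(corrected_pts)
    corrected = RawRecording(
        sample_rate=rec.sample_rate, t0=rec.t0,
        samples=d + e * rec.samples, truth=rec.truth,
        calib_truth=rec.calib_truth,
    )
    # report in the sensor-error convention recorded = truth*scale + offset
    result = CalibrationResult(offset=-d / e, scale=1.0 / e,
                               post_error=post, n_stationary_windows=n_still)
    return corrected, result


def detect_nonwear(rec: RawRecording, epoch_len: float = 5.0,
                   window_min: float = 60.0, step_min: float = 15.0,
                   sd_threshold: float = 0.013, range_threshold: float = 0.050,
                   min_quiet_axes: int = 2) -> WearMask:
    """Long-window low-variability nonwear detection.

    Windows of ``window_min`` minutes slide in ``step_min`` steps; a
    window is off-body when >= ``min_quiet_axes`` axes have SD below
    ``sd_threshold`` g or value range below ``range_threshold`` g.
    Flags are resolved to ``epoch_len`` epochs.
    """
    x = rec.samples
    spe = int(round(rec.sample_rate * epoch_len))
    n_epochs = x.shape[0] // spe
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    blocks = x[: n_epochs * spe].reshape(n_epochs, spe, 3)
    # per-epoch sufficient statistics, combined per window
    e_sum = blocks.sum(axis=1)
    e_sumsq = (blocks ** 2).sum(axis=1)
    e_min = blocks.min(axis=1)
    e_max = blocks.max(axis=1)

    win = int(round(window_min * 60 / epoch_len))
    step = max(1, int(round(step_min * 60 / epoch_len)))
    flags = np.zeros(n_epochs, dtype=np.int8)
    if n_epochs < win:
        warnings.warn("recording shorter than one nonwear window; "
                      "evaluating on the available span")
        win = n_epochs
    starts = list(range(0, n_epochs - win + 1, step))
    if starts and starts[-1] != n_epochs - win:
        starts.append(n_epochs - win)
    m = win * spe
    for s in starts:
        sl = slice(s, s + win)
        tot = e_sum[sl].sum(axis=0)
        totsq = e_sumsq[sl].sum(axis=0)
        var = totsq / m - (tot / m) ** 2
        sd = np.sqrt(np.maximum(var, 0.0))
        rng = e_max[sl].max(axis=0) - e_min[sl].min(axis=0)
        if (sd < sd_threshold).sum() >= min_quiet_axes or \
           (rng < range_threshold).sum() >= min_quiet_axes:
            flags[sl] = NONWEAR_AUTO
    return WearMask(epoch_len=epoch_len, flags=flags, t0=rec.t0)


def apply_diary(mask: WearMask, diary: pd.DataFrame | None) -> WearMask:
    """Override the signal mask with diary off-body intervals.

    Diary intervals of type ``offbody`` become nonwear regardless of the
    signal (diary wins over auto-detection); sleep intervals leave the
    mask untouched.  Overlapping off-body intervals are merged with a
    warning; intervals outside the recording span are clipped.
    """
    flags = mask.flags.copy()
    if diary is None or not len(diary):
        return WearMask(mask.epoch_len, flags, mask.t0)
    idx = mask.epoch_index()
    off = diary[diary["type"] == "offbody"].sort_values("start")
    intervals = []
    for s, e in zip(off["start"], off["end"]):
        s, e = pd.Timestamp(s), pd.Timestamp(e)
        if intervals and s < intervals[-1][1]:
            warnings.warn("overlapping diary off-body intervals merged")
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], e))
        else:
            intervals.append((s, e))
    for s, e in intervals:
        flags[(idx >= s) & (idx < e)] = NONWEAR_DIARY
    return WearMask(mask.epoch_len, flags, mask.t0)


def screen_validity(mask: WearMask, calib: CalibrationResult,
                    min_wear_min: float = 960.0, min_valid_days: int = 4,
                    min_weekdays: int = 3, min_weekend_days: int = 1) -> ValidityReport:
    """Daily and file-level validity.

    A calendar day is valid with >= 16 h (960 min) of wear; a file is
    valid with post-calibration error <= 0.01 g, >= 4 valid days,
    >= 3 valid weekdays and >= 1 valid weekend day (Sat/Sun).
    """
    idx = mask.epoch_index()
    to_min = mask.epoch_len / 60.0
    wear = pd.Series(mask.wear, index=idx)
    day_wear = wear.groupby(idx.date).sum() * to_min
    valid = day_wear >= min_wear_min
    weekend = pd.Index(day_wear.index).map(lambda d: pd.Timestamp(d).dayofweek >= 5)
    n_wd = int((valid & ~np.asarray(weekend)).sum())
    n_we = int((valid & np.asarray(weekend)).sum())

    reason = None
    if calib.exclude:
        reason = f"post-calibration error {calib.post_error:.4f} g > 0.01 g"
    elif int(valid.sum()) < min_valid_days:
        reason = f"only {int(valid.sum())} valid days (< {min_valid_days})"
    elif n_wd < min_weekdays:
        reason = f"only {n_wd} valid weekdays (< {min_weekdays})"
    elif n_we < min_weekend_days:
        reason = f"no valid weekend day" if n_we == 0 else \
            f"only {n_we} valid weekend days (< {min_weekend_days})"
    return ValidityReport(
        day_wear_min=day_wear, valid_day=valid,
        n_valid_weekdays=n_wd, n_valid_weekend_days=n_we,
        post_error=calib.post_error, file_valid=reason is None,
        exclusion_reason=reason,
    )
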
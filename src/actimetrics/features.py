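"""Movement-behaviour features from epoch series.

Three feature families are derived per metric and participant:

* **cut-point time use** — minutes/day in sleep, SB, LPA, MPA, VPA from
  metric-specific intensity thresholds;
* **average acceleration** — the mean epoch value over the 24-h day, a
  volume proxy in the metric's native units;
* **intensity gradient** — the slope of ln(minutes in intensity bin) on
  ln(bin midpoint), describing how activity time is distributed across
  intensity (more negative = more sedentary).

Days are combined into an average day weighting weekdays 5/7 and weekend
days 2/7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coda import DAY_MINUTES, close_composition

CLASS_NAMES = ("SB", "LPA", "MPA", "VPA")


@dataclass(frozen=True)
class CutpointSet:
    """Intensity thresholds of one metric at its validation epoch length.

    mg thresholds (ENMO, MAD) are intensity averages and do not depend on
    epoch length; count thresholds are integrals defined per minute and
    scale proportionally with epoch length.
    """

    metric: str
    lpa: float
    mpa: float
    vpa: float
    validation_epoch_len: float = 60.0

    def __post_init__(self):
        if not (0 < self.lpa < self.mpa < self.vpa):
            raise ValueError("cut-points must satisfy 0 < LPA < MPA < VPA")
        if self.validation_epoch_len <= 0:
            raise ValueError("validation epoch length must be positive")

    @property
    def thresholds(self):
        return np.array([self.lpa, self.mpa, self.vpa])


#: published cut-point sets used throughout: Hildebrand (ENMO, mg),
#: Vaha-Ypya (MAD, mg), Troiano (counts vertical axis, per 60 s) and
#: Sasaki (counts vector magnitude, per 60 s)
DEFAULT_CUTPOINTS = {
    "ENMO": CutpointSet("ENMO", 47.0, 69.0, 260.0),
    "MAD": CutpointSet("MAD", 22.5, 94.0, 396.0),
    "CPM_VA": CutpointSet("CPM_VA", 100.0, 2020.0, 5999.0),
    "CPM_VM": CutpointSet("CPM_VM", 200.0, 2690.0, 6166.0),
}


def scale_cutpoints(cp: CutpointSet, target_epoch_len: float) -> CutpointSet:
    """Rescale count thresholds to a new epoch length (CPM x len/60).

    mg cut-points pass through unchanged: intensity averages are epoch-
    length free.
    """
    if target_epoch_len <= 0:
        raise ValueError("epoch length must be positive")
    if cp.metric in ("ENMO", "MAD"):
        return CutpointSet(cp.metric, cp.lpa, cp.mpa, cp.vpa, target_epoch_len)
    f = target_epoch_len / cp.validation_epoch_len
    return CutpointSet(cp.metric, cp.lpa * f, cp.mpa * f, cp.vpa * f,
                       target_epoch_len)


def classify_intensity(values, cp: CutpointSet, metric: str | None = None):
    """Intensity class per epoch: 0=SB, 1=LPA, 2=MPA, 3=VPA.

    Boundaries are lower-inclusive: a value equal to a threshold enters
    the higher class.
    """
    if metric is not None and metric != cp.metric:
        raise ValueError(f"metric mismatch: series {metric!r} vs cut-points {cp.metric!r}")
    v = np.asarray(values, dtype=float)
    return np.searchsorted(cp.thresholds, v, side="right").astype(np.int8)


# ---------------------------------------------------------------------------
# sleep


def z_angle_degrees(samples, sample_rate: float, block_len: float = 5.0):
    """Tilt of the device z axis on 5-s block medians, in degrees.

    angle = atan2(z, sqrt(x^2 + y^2)); +/-90 deg when z is aligned with
    gravity, 0 deg when gravity lies in the x-y plane.
    """
    x = np.asarray(samples, dtype=float)
    n = int(round(sample_rate * block_len))
    m = (x.shape[0] // n) * n
    blocks = x[:m].reshape(-1, n, 3)
    med = np.median(blocks, axis=1)
    return np.degrees(np.arctan2(med[:, 2], np.hypot(med[:, 0], med[:, 1])))


def hdcza_sleep_window(samples, sample_rate: float, t0: np.datetime64,
                       angle_tol: float = 5.0, min_block_min: float = 5.0,
                       merge_gap_min: float = 30.0, block_len: float = 5.0):
    """Heuristic sleep-period detection from sustained z-angle stability.

    Candidate blocks are runs where successive 5-s z-angle changes stay
    within ``angle_tol`` degrees for at least ``min_block_min`` minutes;
    blocks separated by gaps up to ``merge_gap_min`` are merged and the
    longest merged run is returned as (start, end) datetimes, or None
    when no candidate exists.
    """
    ang = z_angle_degrees(samples, sample_rate, block_len)
    if ang.size < 2:
        return None
    stable = np.abs(np.diff(ang)) <= angle_tol
    min_run = int(round(min_block_min * 60 / block_len))
    # runs of consecutive stable transitions
    runs = []
    i = 0
    while i < stable.size:
        if stable[i]:
            j = i
            while j < stable.size and stable[j]:
                j += 1
            if j - i >= min_run:
                runs.append((i, j + 1))  # block indices, end exclusive
            i = j
        else:
            i += 1
    if not runs:
        return None
    gap = int(round(merge_gap_min * 60 / block_len))
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] <= gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    s, e = max(merged, key=lambda r: r[1] - r[0])
    t0 = np.datetime64(t0, "s")
    step = np.timedelta64(int(block_len), "s")
    return (t0 + s * step, t0 + e * step)


def detect_sleep(diary: pd.DataFrame | None = None, raw=None,
                 sample_rate: float | None = None, t0=None):
    """Sleep windows: diary intervals when present, else z-angle heuristic.

    Parameters
    ----------
    diary : DataFrame with columns start, end, type or None
        Intervals of type ``sleep`` are used directly (diary precedence).
    raw, sample_rate, t0
        Raw samples used for the heuristic fallback.

    Returns
    -------
    list of (start, end) numpy datetime64 pairs; empty when neither route
    yields a window (day marked sleep-invalid downstream).
    """
    if diary is not None and len(diary):
        d = diary[diary["type"] == "sleep"]
        if len(d):
            return [(np.datetime64(s, "s"), np.datetime64(e, "s"))
                    for s, e in zip(d["start"], d["end"])]
    if raw is None:
        return []
    w = hdcza_sleep_window(raw, sample_rate, t0)
    return [w] if w is not None else []


# ---------------------------------------------------------------------------
# daily summaries


def _epoch_index(t0, n_epochs: int, epoch_len: float) -> pd.DatetimeIndex:
    t0 = pd.Timestamp(np.datetime64(t0, "s"))
    return pd.date_range(t0, periods=n_epochs, freq=pd.Timedelta(seconds=epoch_len))


def sleep_mask_from_windows(windows, t0, n_epochs: int, epoch_len: float):
    """Boolean per-epoch mask of membership in any sleep window."""
    idx = _epoch_index(t0, n_epochs, epoch_len)
    mask = np.zeros(n_epochs, dtype=bool)
    for s, e in windows:
        mask |= (idx >= pd.Timestamp(s)) & (idx < pd.Timestamp(e))
    return mask


def intensity_gradient(values, epoch_len: float, bin_width: float,
                       wear=None):
    """Intensity-gradient regression for one day of epoch values.

    Epochs are binned by intensity from 0 upward in ``bin_width`` steps;
    ln(minutes in bin) is regressed on ln(bin midpoint) over non-empty
    bins by ordinary least squares.

    Returns (slope, intercept, r2); all NaN when fewer than two bins are
    non-empty (undefined-value status).
    """
    v = np.asarray(values, dtype=float)
    if wear is not None:
        v = v[np.asarray(wear, dtype=bool)]
    if v.size == 0 or bin_width <= 0:
        return (np.nan, np.nan, np.nan)
    nbin = int(np.floor(v.max() / bin_width)) + 1
    counts = np.bincount(np.minimum((v // bin_width).astype(int), nbin - 1),
                         minlength=nbin)
    minutes = counts * epoch_len / 60.0
    mids = (np.arange(nbin) + 0.5) * bin_width
    ok = minutes > 0
    if ok.sum() < 2:
        return (np.nan, np.nan, np.nan)
    lx = np.log(mids[ok])
    ly = np.log(minutes[ok])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else np.nan
    return (float(slope), float(intercept), float(r2))


def average_acceleration(values, wear=None):
    """Mean epoch value over the day's wear epochs (native units)."""
    v = np.asarray(values, dtype=float)
    if wear is not None:
        v = v[np.asarray(wear, dtype=bool)]
    if v.size == 0:
        return np.nan
    return float(v.mean())


def daily_time_use(classes, values, wear, sleep_mask, t0, epoch_len: float,
                   ig_bin_width: float = 25.0) -> pd.DataFrame:
    """Per-calendar-day behaviour minutes plus volume/intensity features.

    Precedence per epoch: sleep window > nonwear > intensity class, so
    sleep + SB + LPA + MPA + VPA + nonwear = 1440 each full day.

    Parameters
    ----------
    classes : int array per epoch (0=SB..3=VPA)
    values : epoch metric values (native units) for avg accel / gradient
    wear : boolean per epoch (False = nonwear, auto or diary)
    sleep_mask : boolean per epoch
    t0 : first epoch start
    epoch_len : s
    ig_bin_width : intensity-gradient bin width in the series' native units

    Returns
    -------
    DataFrame indexed by date with minute columns, ``avg_accel``,
    ``ig_slope``/``ig_intercept``/``ig_r2``, ``wear_min`` and
    ``is_weekend``.
    """
    classes = np.asarray(classes)
    values = np.asarray(values, dtype=float)
    wear = np.asarray(wear, dtype=bool)
    sleep_mask = np.asarray(sleep_mask, dtype=bool)
    n = len(classes)
    idx = _epoch_index(t0, n, epoch_len)
    to_min = epoch_len / 60.0

    waking_wear = wear & ~sleep_mask
    df = pd.DataFrame({"date": idx.date, "cls": classes, "val": values,
                       "wear": wear, "sleep": sleep_mask, "ww": waking_wear})
    rows = []
    for date, g in df.groupby("date", sort=True):
        minutes = {
            name: float((g["ww"] & (g["cls"] == k)).sum() * to_min)
            for k, name in enumerate(CLASS_NAMES)
        }
        slope, intercept, r2 = intensity_gradient(
            g["val"].to_numpy(), epoch_len, ig_bin_width, wear=g["wear"].to_numpy())
        rows.append({
            "date": date,
            "sleep": float(g["sleep"].sum() * to_min),
            **minutes,
            "MVPA": minutes["MPA"] + minutes["VPA"],
            "nonwear": float(((~g["wear"]) & (~g["sleep"])).sum() * to_min),
            "wear_min": float(g["wear"].sum() * to_min),
            "avg_accel": average_acceleration(g["val"].to_numpy(),
                                              g["wear"].to_numpy()),
            "ig_slope": slope, "ig_intercept": intercept, "ig_r2": r2,
            "is_weekend": pd.Timestamp(date).dayofweek >= 5,
        })
    return pd.DataFrame(rows).set_index("date")


@dataclass
class AverageDay:
    """Weighted-week average of one participant x metric."""

    participant: str
    metric: str
    composition: np.ndarray  # (sleep, SB, LPA, MVPA) min, closed to 1440
    minutes: dict            # unweighted-by-closure averages incl. MPA/VPA
    avg_accel: float
    ig_slope: float
    ig_intercept: float
    ig_r2: float
    n_weekdays: int
    n_weekend_days: int


def weighted_week_average(daily: pd.DataFrame, participant: str = "",
                          metric: str = "", valid_days=None) -> AverageDay:
    """Average day = (weekday mean x 5 + weekend mean x 2) / 7.

    Requires >= 3 valid weekdays and >= 1 valid weekend day (the file
    validity rule); the 4-part composition is re-closed to 1440 after
    averaging.

    Parameters
    ----------
    daily : output of :func:`daily_time_use`
    valid_days : optional boolean mask aligned with ``daily`` rows
    """
    d = daily if valid_days is None else daily[np.asarray(valid_days, dtype=bool)]
    wd = d[~d["is_weekend"]]
    we = d[d["is_weekend"]]
    if len(wd) < 3 or len(we) < 1:
        raise ValueError(
            f"insufficient valid days: {len(wd)} weekdays, {len(we)} weekend days")
    cols = ["sleep", "SB", "LPA", "MPA", "VPA", "MVPA", "avg_accel",
            "ig_slope", "ig_intercept", "ig_r2"]
    avg = (wd[cols].mean() * 5 + we[cols].mean() * 2) / 7
    comp = close_composition(
        [avg["sleep"], avg["SB"], avg["LPA"], avg["MVPA"]], DAY_MINUTES)
    return AverageDay(
        participant=participant, metric=metric, composition=comp,
        minutes={c: float(avg[c]) for c in ["sleep", "SB", "LPA", "MPA", "VPA", "MVPA"]},
        avg_accel=float(avg["avg_accel"]), ig_slope=float(avg["ig_slope"]),
        ig_intercept=float(avg["ig_intercept"]), ig_r2=float(avg["ig_r2"]),
        n_weekdays=len(wd), n_weekend_days=len(we),
    )


def counts_ig_bin_width(count_values, mg_values, mg_bin_width: float = 25.0):
    """Intensity-gradient bin width for a counts series, scaled from the
    mg default by the recording's mean counts / mean mg ratio so bin
    occupancies stay comparable across metrics."""
    c = float(np.mean(count_values))
    m = float(np.mean(mg_values))
    if m <= 0 or c <= 0:
        return mg_bin_width
    return mg_bin_width * c / m
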
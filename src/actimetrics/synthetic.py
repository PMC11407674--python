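"""Synthetic raw recordings and cohorts with known ground truth.

The generator renders a scheduled day of behaviour bouts as a gravity
vector plus sinusoidal motion, with white sensor noise, optional
injected calibration error and off-body gaps.  Bout waveform parameters
were calibrated once, by running candidate waveforms through the metric
pipeline, so that each behaviour class produces epoch values inside the
corresponding intensity band of *all four* metrics (ENMO, MAD, counts
vertical-axis and vector-magnitude) with wide margins; downstream
classification of a clean recording therefore recovers the schedule.

Cohort tables are generated from an explicit linear model on the ILR
coordinates of the time-use composition plus covariates and Gaussian
noise, so association models can be validated against planted effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coda import DAY_MINUTES, close_composition, ilr_transform
from .recording import RawRecording

BEHAVIORS = ("sleep", "SB", "LPA", "MPA", "VPA", "nonwear")
BEHAVIOR_CODE = {b: i for i, b in enumerate(BEHAVIORS)}

#: printed cohort-mean time-use profiles per metric (min/day)
TABLE1_PROFILES = {
    "ENMO": {"sleep": 512, "SB": 854, "LPA": 34, "MVPA": 40},
    "MAD": {"sleep": 516, "SB": 608, "LPA": 250, "MVPA": 66},
    "CPM_VA": {"sleep": 516, "SB": 581, "LPA": 309, "MVPA": 34},
    "CPM_VM": {"sleep": 517, "SB": 498, "LPA": 364, "MVPA": 61},
}


@dataclass(frozen=True)
class BoutWaveform:
    """Waveform of one behaviour class.

    vertical amplitude/DC ride on the gravity axis; the perpendicular
    wiggle keeps a second axis above the nonwear variability threshold
    without moving the vector magnitude (second-order effect only).
    """

    amp_vertical: float = 0.0   # g, sinusoid along gravity
    dc_vertical: float = 0.0    # g, sustained offset along gravity
    freq: float = 1.0           # Hz
    amp_perp: float = 0.04      # g, per perpendicular axis
    freq_perp: float = 0.5      # Hz
    stills: bool = False        # insert 30-s stationary interludes
    gravity_axis: int = 2       # 2 = device z (upright), 0 = x (lying)
    tilt_deg: float = 0.0       # max random tilt of the gravity axis


#: frozen per-class waveforms (see module docstring); intended epoch
#: values on a clean signal: SB/sleep ~2 mg ENMO; LPA 58 mg ENMO / 69 mg
#: MAD / ~104 counts; MPA 150 / 299 / ~329; VPA 400 / 729 / ~898
DEFAULT_WAVEFORMS = {
    "sleep": BoutWaveform(stills=True, gravity_axis=0, tilt_deg=25.0),
    "SB": BoutWaveform(stills=True, gravity_axis=2, tilt_deg=25.0),
    "LPA": BoutWaveform(amp_vertical=0.110, dc_vertical=0.040, freq=0.9),
    "MPA": BoutWaveform(amp_vertical=0.471, freq=2.1),
    "VPA": BoutWaveform(amp_vertical=1.257, freq=2.4),
    "nonwear": BoutWaveform(amp_perp=0.0, stills=False),
}


@dataclass
class Bout:
    start_min: int      # minutes from schedule t0
    duration_min: int
    behavior: str
    orientation: np.ndarray  # gravity unit vector during the bout
    phase: float


@dataclass
class BoutSchedule:
    """Non-overlapping bouts covering ``days`` full days from ``t0``."""

    t0: np.datetime64
    days: int
    entries: list

    def __post_init__(self):
        span = 0
        for b in self.entries:
            if b.start_min != span:
                raise ValueError("bouts must tile the span without gaps")
            if b.duration_min <= 0:
                raise ValueError("bout durations must be positive")
            span += b.duration_min
        if span != self.days * 1440:
            raise ValueError("schedule must cover the full simulated span")

    def daily_minutes(self) -> pd.DataFrame:
        """Ground-truth minutes per behaviour per day."""
        rows = np.zeros((self.days, len(BEHAVIORS)))
        for b in self.entries:
            # bouts never cross midnight by construction
            rows[b.start_min // 1440, BEHAVIOR_CODE[b.behavior]] += b.duration_min
        return pd.DataFrame(rows, columns=list(BEHAVIORS))


def _random_tilt(base_axis: int, max_deg: float, rng) -> np.ndarray:
    g = np.zeros(3)
    g[base_axis] = 1.0
    if max_deg <= 0:
        return g
    theta = np.radians(rng.uniform(0, max_deg))
    # random direction perpendicular to the base axis
    perp = rng.normal(size=3)
    perp -= perp @ g * g
    perp /= np.linalg.norm(perp)
    return np.cos(theta) * g + np.sin(theta) * perp


def _chunks(total: int, lo: int, hi: int, rng) -> list:
    out = []
    while total > 0:
        c = int(min(total, rng.integers(lo, hi + 1)))
        out.append(c)
        total -= c
    return out


def generate_bout_schedule(profile: dict, days: int, seed: int,
                           t0="2022-06-06", mvpa_split: float = 0.75,
                           waveforms: dict = DEFAULT_WAVEFORMS) -> BoutSchedule:
    """Schedule ``days`` days of behaviour bouts matching a daily profile.

    Parameters
    ----------
    profile : dict
        Daily minutes per behaviour.  Keys: sleep, SB, LPA and either
        MVPA (split into MPA/VPA by ``mvpa_split``) or MPA/VPA
        explicitly; optional nonwear.  Minutes must sum to 1440.
    days : int
    seed : int
        All scheduling randomness (bout order, chunking, orientations)
        flows from this seed.
    t0 : date-like
        Midnight starting the first day (default a Monday).

    Notes
    -----
    Sleep is split into a 60-min pre-midnight block and the remainder
    after midnight, so per-day behaviour totals equal the profile
    exactly; waking bouts are chunked and shuffled per day.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    p = dict(profile)
    if "MVPA" in p:
        mvpa = p.pop("MVPA")
        p["MPA"] = int(round(mvpa * mvpa_split))
        p["VPA"] = mvpa - p["MPA"]
    for k in BEHAVIORS:
        p.setdefault(k, 0)
    unknown = set(p) - set(BEHAVIORS)
    if unknown:
        raise ValueError(f"unknown behaviours in profile: {sorted(unknown)}")
    total = sum(p.values())
    if total != 1440:
        raise ValueError(f"profile minutes sum to {total}, expected 1440")

    rng = np.random.default_rng(seed)
    t0 = np.datetime64(str(t0), "s")
    entries = []

    def add(day, start, dur, behavior):
        wf = waveforms[behavior]
        ori = _random_tilt(wf.gravity_axis, wf.tilt_deg, rng)
        entries.append(Bout(day * 1440 + start, dur, behavior, ori,
                            float(rng.uniform(0, 2 * np.pi))))

    sleep_eve = min(60, p["sleep"])
    sleep_morn = p["sleep"] - sleep_eve
    for day in range(days):
        cursor = 0
        if sleep_morn:
            add(day, cursor, sleep_morn, "sleep")
            cursor += sleep_morn
        active = (
            [("LPA", c) for c in _chunks(p["LPA"], 8, 17, rng)]
            + [("MPA", c) for c in _chunks(p["MPA"], 8, 15, rng)]
            + [("VPA", c) for c in _chunks(p["VPA"], 5, 10, rng)]
            + ([("nonwear", p["nonwear"])] if p["nonwear"] else [])
        )
        rng.shuffle(active)
        sb_parts = _split_integer(p["SB"], len(active) + 1, rng)
        for (beh, dur), sb in zip(active + [(None, 0)], sb_parts):
            if sb:
                add(day, cursor, sb, "SB")
                cursor += sb
            if beh is not None:
                add(day, cursor, dur, beh)
                cursor += dur
        if sleep_eve:
            add(day, cursor, sleep_eve, "sleep")
            cursor += sleep_eve
        assert cursor == 1440
    return BoutSchedule(t0=t0, days=days, entries=entries)


def _split_integer(total: int, k: int, rng) -> list:
    """Split ``total`` into k non-negative integer parts, randomly."""
    if k == 1 or total == 0:
        return [total] + [0] * (k - 1)
    w = rng.dirichlet(np.ones(k) * 2.0)
    parts = np.floor(w * total).astype(int)
    parts[0] += total - parts.sum()
    return parts.tolist()


def _perp_axes(g: np.ndarray):
    ref = np.array([0.0, 1.0, 0.0]) if abs(g[1]) < 0.9 else np.array([1.0, 0.0, 0.0])
    h1 = np.cross(g, ref)
    h1 /= np.linalg.norm(h1)
    return h1, np.cross(g, h1)


def synthesize_raw_recording(schedule: BoutSchedule, sample_rate: float = 100.0,
                             noise_sd: float = 0.005, calib_error=None,
                             seed: int = 0) -> RawRecording:
    """Render a bout schedule as a raw tri-axial recording.

    Each bout contributes the reaction to gravity along its orientation
    plus its class waveform; nonwear bouts are motionless.  White
    Gaussian noise of ``noise_sd`` g is added per axis, and an optional
    ``calib_error = (offset g, scale)`` is applied as
    ``recorded = truth * scale + offset``.  Per-sample behaviour codes
    (:data:`BEHAVIOR_CODE`) are attached as ground truth.
    """
    if sample_rate < 20:
        raise ValueError("sample rate must be >= 20 Hz")
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    rng = np.random.default_rng(seed)
    fs = sample_rate
    n_total = int(round(schedule.days * 1440 * 60 * fs))
    x = np.empty((n_total, 3))
    truth = np.empty(n_total, dtype=np.int8)
    wf_map = DEFAULT_WAVEFORMS

    for b in schedule.entries:
        wf = wf_map[b.behavior]
        i0 = int(round(b.start_min * 60 * fs))
        n = int(round(b.duration_min * 60 * fs))
        t = np.arange(n) / fs
        g = b.orientation
        h1, h2 = _perp_axes(g)
        vert = wf.amp_vertical * np.sin(2 * np.pi * wf.freq * t + b.phase) \
            + wf.dc_vertical
        p1 = wf.amp_perp * np.sin(2 * np.pi * wf.freq_perp * t + b.phase)
        p2 = wf.amp_perp * np.sin(2 * np.pi * wf.freq_perp * 1.3 * t + b.phase + 1.0)
        if wf.stills:
            # 30-s motionless interludes every 10 min feed autocalibration
            mask = np.ones(n, dtype=bool)
            for s0 in range(300, b.duration_min * 60 - 30, 600):
                mask[int(s0 * fs): int((s0 + 30) * fs)] = False
            vert = vert * mask
            p1 = p1 * mask
            p2 = p2 * mask
        block = np.outer(1.0 + vert, g) + np.outer(p1, h1) + np.outer(p2, h2)
        x[i0:i0 + n] = block
        truth[i0:i0 + n] = BEHAVIOR_CODE[b.behavior]

    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, x.shape)
    calib_truth = None
    if calib_error is not None:
        offset, scale = np.asarray(calib_error[0], float), np.asarray(calib_error[1], float)
        x = x * scale + offset
        calib_truth = (offset, scale)
    return RawRecording(sample_rate=fs, t0=schedule.t0, samples=x,
                        truth=truth, calib_truth=calib_truth)


def schedule_to_diary(schedule: BoutSchedule) -> pd.DataFrame:
    """Diary CSV contract rows from the ground-truth schedule.

    Consecutive sleep bouts merge into sleep intervals; nonwear bouts
    become off-body intervals.
    """
    rows = []
    t0 = pd.Timestamp(schedule.t0)
    for b in schedule.entries:
        if b.behavior not in ("sleep", "nonwear"):
            continue
        typ = "sleep" if b.behavior == "sleep" else "offbody"
        start = t0 + pd.Timedelta(minutes=b.start_min)
        end = start + pd.Timedelta(minutes=b.duration_min)
        if rows and rows[-1]["type"] == typ and rows[-1]["end"] == start:
            rows[-1]["end"] = end
        else:
            rows.append({"start": start, "end": end, "type": typ})
    return pd.DataFrame(rows, columns=["start", "end", "type"])


def calibration_validation_recording(seed: int = 0, n_orientations: int = 40,
                                     still_s: float = 30.0, move_s: float = 30.0,
                                     sample_rate: float = 30.0,
                                     noise_sd: float = 0.003,
                                     calib_error=None) -> RawRecording:
    """Multi-orientation recording for exercising autocalibration.

    Alternates stationary holds at uniformly random orientations with
    short movement bursts, giving the sphere coverage the calibration
    fit needs.
    """
    rng = np.random.default_rng(seed)
    fs = sample_rate
    blocks = []
    for _ in range(n_orientations):
        g = rng.normal(size=3)
        g /= np.linalg.norm(g)
        blocks.append(np.tile(g, (int(still_s * fs), 1)))
        t = np.arange(int(move_s * fs)) / fs
        h1, h2 = _perp_axes(g)
        wob = (np.outer(0.3 * np.sin(2 * np.pi * 1.5 * t), h1)
               + np.outer(0.3 * np.sin(2 * np.pi * 1.1 * t + 0.7), h2))
        blocks.append(g + wob)
    x = np.vstack(blocks) + rng.normal(0, noise_sd, (sum(len(b) for b in blocks), 3))
    calib_truth = None
    if calib_error is not None:
        offset, scale = np.asarray(calib_error[0], float), np.asarray(calib_error[1], float)
        x = x * scale + offset
        calib_truth = (offset, scale)
    return RawRecording(sample_rate=fs, t0=np.datetime64("2022-06-06T00:00:00"),
                        samples=x, calib_truth=calib_truth)


# ---------------------------------------------------------------------------
# cohort tables


@dataclass
class EffectSpec:
    """Planted composition-outcome effect.

    outcome = intercept + beta . ilr(composition) + gamma . covariates
    + Normal(0, sigma); with ``log_outcome`` the linear predictor is the
    log-outcome and the stored outcome is its exponential.
    """

    beta: np.ndarray
    gamma: dict = field(default_factory=dict)
    sigma: float = 1.0
    intercept: float = 0.0
    log_outcome: bool = False

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (3,):
            raise ValueError("beta must have length 3 (ILR coordinates)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def generate_covariates(n: int, seed: int) -> pd.DataFrame:
    """Sociodemographic covariate table emulating the cohort structure
    (68.5% female, age ~ N(45.8, 10.8), education/smoking mixes and
    medication/pathology prevalences from the descriptive table)."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "id": [f"P{i:04d}" for i in range(n)],
        "sex": rng.choice(["female", "male"], n, p=[0.685, 0.315]),
        "age": rng.normal(45.8, 10.8, n).clip(25, 64),
        "education": rng.choice(["low", "middle", "high"], n,
                                p=[0.243, 0.428, 0.329]),
        "smoking": rng.choice(["non-smoker", "ex-smoker", "smoker"], n,
                              p=[0.777, 0.157, 0.066]),
        "med_glucose": rng.random(n) < 0.103,
        "med_lipid": rng.random(n) < 0.150,
        "med_bp": rng.random(n) < 0.178,
        "pathology": rng.random(n) < 0.103,
    })


def generate_cohort_compositions(n: int, mean_comp, seed: int,
                                 ilr_sd=(0.12, 0.18, 0.25)) -> np.ndarray:
    """Logistic-normal compositions around a mean day (min, closed 1440).

    ILR coordinates are drawn independently normal around the mean's
    coordinates; the default SDs give realistic between-person spread
    (roughly +/-1 h sleep, +/-2 h SB and a 2-3x MVPA range).
    """
    rng = np.random.default_rng(seed)
    mu = ilr_transform(close_composition(mean_comp))
    z = mu + rng.normal(0, 1, (n, 3)) * np.asarray(ilr_sd)
    from .coda import ilr_inverse

    return ilr_inverse(z)


def synthesize_cohort_outcomes(compositions, covariates: pd.DataFrame,
                               spec: EffectSpec, seed: int,
                               outcome: str = "outcome") -> pd.DataFrame:
    """Cohort table with one outcome generated from the planted model."""
    comps = np.asarray(compositions, dtype=float)
    if np.any(comps <= 0):
        raise ValueError("compositions must be strictly positive (ILR undefined)")
    if len(comps) != len(covariates):
        raise ValueError("compositions and covariates must align")
    rng = np.random.default_rng(seed)
    z = ilr_transform(comps)
    lin = spec.intercept + z @ spec.beta
    for col, g in spec.gamma.items():
        v = covariates[col]
        lin = lin + g * (v.astype(float) if v.dtype != object else
                         pd.get_dummies(v, drop_first=True).iloc[:, 0].astype(float))
    lin = lin + rng.normal(0, spec.sigma, len(comps))
    out = covariates.copy()
    for j, part in enumerate(("sleep", "SB", "LPA", "MVPA")):
        out[part] = comps[:, j]
    out[outcome] = np.exp(lin) if spec.log_outcome else lin
    return out


def derive_lipid_indices(table: pd.DataFrame) -> pd.DataFrame:
    """Append Friedewald LDL (TC - HDL - TG/5, mg/dL) and waist-to-hip
    ratio (WC/hip); missing inputs propagate to missing outputs."""
    out = table.copy()
    if {"TC", "HDL", "TG"} <= set(out.columns):
        out["LDL"] = out["TC"] - out["HDL"] - out["TG"] / 5.0
    if {"WC", "hip"} <= set(out.columns):
        out["WHR"] = out["WC"] / out["hip"]
    return out
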
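"""Per-epoch accelerometer data-reduction metrics.

Four metrics summarise raw tri-axial acceleration into epoch values:

* **ENMO** (Euclidean Norm Minus One): mean of ``max(r - 1 g, 0)`` per
  epoch, in mg.  Negative residuals are truncated to zero, so the metric
  is sensitive to calibration error.
* **MAD** (Mean Amplitude Deviation): mean absolute deviation of the
  vector magnitude around its epoch mean, in mg.  The within-epoch
  centring makes it robust to a constant offset of ``r``.
* **Activity counts** (CPM_VA, CPM_VM): an open replication of the
  classic count pipeline — resample, band-pass, clip, rectify, deadband,
  quantize, integrate per epoch — applied per axis; the vector-magnitude
  variant combines the three axis counts with a rounded Euclidean norm.

Counts are in arbitrary device-style units; their cut-points are defined
per minute at the validation epoch and scaled by epoch length elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

#: metric identifiers in reporting order
METRICS = ("ENMO", "MAD", "CPM_VA", "CPM_VM")

MG_PER_G = 1000.0


@dataclass(frozen=True)
class CountsConfig:
    """Constants of the activity-count pipeline.

    Defaults follow the published open replication of the proprietary
    count algorithm: 30 Hz working rate, 0.29-1.63 Hz pass band, 2.13 g
    clip, 0.068 g deadband, 8-bit quantization over the clip range.
    The original vendor constants are not asserted anywhere; everything
    is configurable.
    """

    resample_rate: float = 30.0
    band_edges: tuple[float, float] = (0.29, 1.63)
    clip: float = 2.13
    deadband: float = 0.068
    quantization_levels: int = 256

    def __post_init__(self):
        lo, hi = self.band_edges
        if not (0 < lo < hi < self.resample_rate / 2):
            raise ValueError("band edges must be increasing and below Nyquist")
        if self.quantization_levels < 4:
            raise ValueError("quantization needs at least 4 levels")

    @property
    def quant_step(self) -> float:
        """Quantization step: positive half-range of an ADC with
        ``quantization_levels`` levels over +/- clip."""
        return self.clip / (self.quantization_levels // 2 - 1)

    def filter_coefficients(self):
        """Band-pass (b, a) transfer-function coefficients at the working
        rate.  Exposed as data so an independent recursion can reproduce
        the filtering bit-for-bit."""
        return butter_bandpass(self.band_edges, self.resample_rate)


def butter_bandpass(band_edges, fs, order: int = 3):
    """Order-``order`` Butterworth band-pass (b, a) at sample rate fs."""
    return _signal.butter(order, band_edges, btype="bandpass", fs=fs)


def vector_magnitude(samples):
    """Euclidean norm of tri-axial samples, shape (..., 3) -> (...)."""
    x = np.asarray(samples, dtype=float)
    return np.sqrt(np.einsum("...i,...i->...", x, x))


def _epoch_view(values, n_per_epoch):
    n = (values.shape[0] // n_per_epoch) * n_per_epoch
    return values[:n].reshape(-1, n_per_epoch)


def epoch_enmo(samples, sample_rate: float, epoch_len: float = 5.0):
    """ENMO per epoch in mg: mean of max(r - 1 g, 0).

    Trailing samples not filling a whole epoch are dropped.
    """
    r = vector_magnitude(samples)
    n = int(round(sample_rate * epoch_len))
    if r.size < n:
        raise ValueError("window shorter than one epoch")
    w = _epoch_view(r, n)
    return np.maximum(w - 1.0, 0.0).mean(axis=1) * MG_PER_G


def epoch_mad(samples, sample_rate: float, epoch_len: float = 5.0):
    """MAD per epoch in mg: mean |r - mean(r)| within the epoch."""
    r = vector_magnitude(samples)
    n = int(round(sample_rate * epoch_len))
    if r.size < n:
        raise ValueError("window shorter than one epoch")
    w = _epoch_view(r, n)
    return np.abs(w - w.mean(axis=1, keepdims=True)).mean(axis=1) * MG_PER_G


def counts_quantized_stream(axis_stream, sample_rate: float,
                            cfg: CountsConfig = CountsConfig()):
    """Quantized per-sample count contributions of one axis at the working
    rate.  Stages: resample -> band-pass -> clip -> rectify -> deadband
    (floored at 0) -> quantize to integer steps."""
    x = np.asarray(axis_stream, dtype=float)
    if sample_rate != cfg.resample_rate:
        # polyphase resampling to the working rate
        from fractions import Fraction

        frac = Fraction(cfg.resample_rate / sample_rate).limit_denominator(1000)
        x = _signal.resample_poly(x, frac.numerator, frac.denominator)
    b, a = cfg.filter_coefficients()
    # steady-state initial conditions: a constant (DC) input then yields
    # exactly zero output instead of a startup transient
    zi = _signal.lfilter_zi(b, a) * (x[0] if x.size else 0.0)
    y, _ = _signal.lfilter(b, a, x, zi=zi)
    y = np.clip(y, -cfg.clip, cfg.clip)
    y = np.abs(y)
    y = np.maximum(y - cfg.deadband, 0.0)
    return np.floor(y / cfg.quant_step).astype(np.int64)


def epoch_counts(axis_stream, sample_rate: float, epoch_len: float = 5.0,
                 cfg: CountsConfig = CountsConfig()):
    """Integer activity counts of one axis per epoch.

    The quantized stream is summed over epochs at the working rate.  A
    constant (DC) input yields zero counts because the band-pass rejects
    0 Hz.
    """
    q = counts_quantized_stream(axis_stream, sample_rate, cfg)
    n = int(round(cfg.resample_rate * epoch_len))
    if q.size < n:
        raise ValueError("stream shorter than one epoch at the working rate")
    return _epoch_view(q, n).sum(axis=1)


def epoch_counts_triaxial(samples, sample_rate: float, epoch_len: float = 5.0,
                          cfg: CountsConfig = CountsConfig()):
    """Counts per epoch for each axis of an (n, 3) sample block."""
    x = np.asarray(samples, dtype=float)
    return np.column_stack([
        epoch_counts(x[:, i], sample_rate, epoch_len, cfg) for i in range(3)
    ])


def epoch_counts_vm(axis_counts):
    """Vector-magnitude counts: round(sqrt(cx^2 + cy^2 + cz^2)) per epoch.

    Rounding is half-away-from-zero so the result stays an integer count.
    """
    c = np.asarray(axis_counts, dtype=float)
    vm = np.sqrt(np.einsum("...i,...i->...", c, c))
    return np.floor(vm + 0.5).astype(np.int64)


def aggregate_epochs(values, metric: str, factor: int):
    """Roll up epoch values to a coarser epoch length.

    mg metrics (ENMO, MAD) are intensity averages and are averaged;
    counts are integrals and are summed.  ``factor`` is the number of
    base epochs per target epoch; the series length must be a multiple.
    """
    v = np.asarray(values)
    if factor == 1:
        return v.copy()
    if factor < 1 or v.size % factor:
        raise ValueError("series length must be a multiple of the aggregation factor")
    w = v.reshape(-1, factor)
    if metric in ("ENMO", "MAD"):
        return w.mean(axis=1)
    return w.sum(axis=1)


@dataclass
class EpochSeries:
    """Per-epoch values of one metric with its epoch length.

    values are mg for ENMO/MAD and integer counts per epoch for CPM_*.
    """

    metric: str
    epoch_len: float
    values: np.ndarray
    t0: "object" = None  # datetime of the first epoch start, if known

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if np.any(~np.isfinite(np.asarray(self.values, dtype=float))):
            raise ValueError("epoch values must be finite")
        if np.any(np.asarray(self.values, dtype=float) < 0):
            raise ValueError("epoch values must be non-negative")

    def aggregate(self, target_len: float) -> "EpochSeries":
        factor = target_len / self.epoch_len
        if abs(factor - round(factor)) > 1e-9:
            raise ValueError("target epoch length must be a multiple of the base")
        vals = aggregate_epochs(self.values, self.metric, int(round(factor)))
        return EpochSeries(self.metric, target_len, vals, self.t0)


def compute_epoch_series(samples, sample_rate: float, epoch_len: float = 5.0,
                         cfg: CountsConfig = CountsConfig(), t0=None,
                         vertical_axis: int = 2):
    """All four metric series from one calibrated recording block.

    ``vertical_axis`` selects the axis fed to the vertical-axis count
    metric (device z by default for hip wear in this package's frame).
    Series are truncated to a common epoch count.
    """
    x = np.asarray(samples, dtype=float)
    enmo = epoch_enmo(x, sample_rate, epoch_len)
    mad = epoch_mad(x, sample_rate, epoch_len)
    axc = epoch_counts_triaxial(x, sample_rate, epoch_len, cfg)
    va = axc[:, vertical_axis]
    vm = epoch_counts_vm(axc)
    n = min(enmo.size, mad.size, va.size)
    return {
        "ENMO": EpochSeries("ENMO", epoch_len, enmo[:n], t0),
        "MAD": EpochSeries("MAD", epoch_len, mad[:n], t0),
        "CPM_VA": EpochSeries("CPM_VA", epoch_len, va[:n], t0),
        "CPM_VM": EpochSeries("CPM_VM", epoch_len, vm[:n], t0),
    }
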
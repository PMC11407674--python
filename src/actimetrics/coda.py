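"""Compositional machinery for 24-hour time-use data.

A day is treated as a 4-part composition (sleep, SB, LPA, MVPA) closed to
1440 min.  Compositions carry only relative information, so association
models work on isometric log-ratio (ILR) pivot coordinates, which map a
D-part composition to D-1 unconstrained real coordinates while preserving
Aitchison geometry.
"""

from __future__ import annotations

import numpy as np

#: canonical part order of the daily time-use composition
PARTS = ("sleep", "SB", "LPA", "MVPA")

#: minutes in a day; the closure constant for daily compositions
DAY_MINUTES = 1440.0


def close_composition(parts, total: float = DAY_MINUTES, zero_replacement: float = 1.0):
    """Close a vector of non-negative parts to ``total``.

    Zero parts are replaced by ``zero_replacement`` (in the units of
    ``total``) with proportional shrinkage of the remaining parts, so the
    result is strictly positive and sums exactly to ``total``.

    Parameters
    ----------
    parts : array_like, shape (..., D)
        Non-negative part values (e.g. minutes per behaviour).  The last
        axis is the compositional axis.
    total : float
        Closure constant (default 1440 min).
    zero_replacement : float
        Value assigned to zero parts before closure, expressed on the
        ``total`` scale.  Set to 0 to disable (zeros then raise).

    Returns
    -------
    ndarray
        Strictly positive array closing to ``total`` along the last axis.
    """
    x = np.asarray(parts, dtype=float)
    if np.any(x < 0):
        raise ValueError("compositional parts must be non-negative")
    s = x.sum(axis=-1)
    if np.any(s <= 0):
        raise ValueError("all-zero composition cannot be closed")
    x = x * (total / s)[..., None]
    zero = x == 0
    if zero.any():
        if zero_replacement <= 0:
            raise ValueError("zero parts present and zero replacement disabled")
        n_zero = zero.sum(axis=-1)
        shrink = (total - n_zero * zero_replacement) / total
        if np.any(shrink <= 0):
            raise ValueError("zero replacement exceeds the closure total")
        x = x * shrink[..., None]
        x[zero] = zero_replacement
    return x * (total / x.sum(axis=-1))[..., None]


def ilr_transform(comp):
    """Pivot (sequential binary partition) ILR coordinates.

    ``z_j = sqrt((D-j)/(D-j+1)) * ln( x_j / gmean(x_{j+1..D}) )`` for
    j = 1..D-1.  The first coordinate contrasts the first part against the
    geometric mean of everything after it, so reallocation effects for a
    focal behaviour are read off ``z1`` when that behaviour is pivoted
    first.

    Parameters
    ----------
    comp : array_like, shape (..., D)
        Strictly positive compositions (any closure).

    Returns
    -------
    ndarray, shape (..., D-1)
    """
    x = np.asarray(comp, dtype=float)
    if np.any(x <= 0):
        raise ValueError("ILR requires strictly positive parts")
    d = x.shape[-1]
    logx = np.log(x)
    out = np.empty(x.shape[:-1] + (d - 1,))
    for j in range(d - 1):
        tail = logx[..., j + 1 :].mean(axis=-1)
        out[..., j] = np.sqrt((d - j - 1) / (d - j)) * (logx[..., j] - tail)
    return out


def ilr_inverse(z, total: float = DAY_MINUTES):
    """Invert pivot ILR coordinates back to a closed composition."""
    z = np.asarray(z, dtype=float)
    d = z.shape[-1] + 1
    logx = np.zeros(z.shape[:-1] + (d,))
    # invert sequentially: each z_j fixes log x_j relative to the tail mean
    for j in range(d - 2, -1, -1):
        tail = logx[..., j + 1 :].mean(axis=-1)
        logx[..., j] = z[..., j] / np.sqrt((d - j - 1) / (d - j)) + tail
    x = np.exp(logx)
    return x * (total / x.sum(axis=-1))[..., None]


def aitchison_distance(a, b):
    """Aitchison distance = Euclidean distance between ILR images."""
    return float(np.linalg.norm(ilr_transform(a) - ilr_transform(b)))


def variation_matrix(comps, ddof: int = 1):
    """Variation matrix of a cohort of compositions.

    Entry (i, j) is the sample variance over rows of ``ln(x_i / x_j)``; a
    value near zero means parts i and j vary proportionally.

    Parameters
    ----------
    comps : array_like, shape (n, D)
    ddof : int
        Delta degrees of freedom of the variance (default 1, sample
        variance).
    """
    x = np.asarray(comps, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two compositions")
    if np.any(x <= 0):
        raise ValueError("variation matrix requires strictly positive parts")
    logx = np.log(x)
    d = x.shape[1]
    out = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1, d):
            v = np.var(logx[:, i] - logx[:, j], ddof=ddof)
            out[i, j] = out[j, i] = v
    return out


def reallocate_time(comp, focal: int | str, delta: float, total: float = DAY_MINUTES,
                    parts: tuple = PARTS):
    """Proportional one-to-remaining time reallocation.

    ``delta`` minutes are added to the focal part; the remaining parts are
    shrunk (or grown) proportionally so the composition still closes to
    ``total``.

    Parameters
    ----------
    comp : array_like, shape (D,)
        Closed composition in minutes.
    focal : int or str
        Index or part name of the behaviour receiving ``delta``.
    delta : float
        Minutes moved into (positive) or out of (negative) the focal part.

    Returns
    -------
    ndarray, shape (D,)
        Reallocated composition, closed to ``total``.
    """
    x = np.asarray(comp, dtype=float).copy()
    if isinstance(focal, str):
        focal = parts.index(focal)
    if x[focal] + delta <= 0:
        raise ValueError("reallocation would empty the focal behaviour")
    rest = np.arange(x.size) != focal
    s = x[rest].sum()
    if s - delta <= 0:
        raise ValueError("reallocation would empty the remaining behaviours")
    x[rest] *= (s - delta) / s
    x[focal] += delta
    return x * (total / x.sum())
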
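"""Between-metric agreement statistics.

Two data-reduction metrics applied to the same participants form an
n x 2 table (participant x "rater").  Agreement is quantified with the
single-measure absolute-agreement intraclass correlation from a two-way
random-effects ANOVA — ICC(2,1) in Shrout-Fleiss terms, ICC(A,1) in
McGraw-Wong terms — plus Bland-Altman bias, limits of agreement and the
mean absolute percentage error (MAPE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: the six metric pairs compared, in reporting order
METRIC_PAIRS = (
    ("ENMO", "MAD"),
    ("ENMO", "CPM_VA"),
    ("ENMO", "CPM_VM"),
    ("CPM_VA", "MAD"),
    ("CPM_VA", "CPM_VM"),
    ("CPM_VM", "MAD"),
)

#: features entered into the pairwise grid; sleep is excluded because every
#: metric shares the same sleep algorithm, making its comparison redundant
GRID_FEATURES = ("SB", "LPA", "MVPA", "avg_accel", "ig_slope")


@dataclass
class AgreementStats:
    """ICC + Bland-Altman summary for one metric pair and feature."""

    icc: float
    icc_ci: tuple[float, float]
    bias: float
    sd_diff: float
    loa: tuple[float, float]
    mape: float
    n: int
    n_mape_excluded: int = 0
    degenerate: bool = False


def icc_2_1(paired, alpha: float = 0.05):
    """ICC(2,1): single rater, absolute agreement, two-way random effects.

    Parameters
    ----------
    paired : array_like, shape (n, k)
        One row per subject, one column per rater/metric.  No missing
        values; n >= 5 recommended for a stable CI.
    alpha : float
        1 - confidence level of the F-based interval.

    Returns
    -------
    icc : float
    ci : (lo, hi)
        McGraw & Wong F-distribution confidence bounds.
    degenerate : bool
        True when the between-subject mean square does not exceed the
        residual mean square structure enough to identify the ICC
        (zero between-subject variance).
    """
    y = np.asarray(paired, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("need an n x k table with k >= 2")
    if np.isnan(y).any():
        raise ValueError("missing values not allowed; drop incomplete pairs first")
    n, k = y.shape
    if n < 2:
        raise ValueError("need at least two subjects")

    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    degenerate = denom <= 0 or (msr <= mse and msc <= mse and ss_total == 0)
    if denom <= 0:
        return 0.0, (np.nan, np.nan), True
    icc = (msr - mse) / denom

    if mse == 0 and msc == mse:
        # identical columns: perfect agreement, interval collapses
        return float(icc), (1.0, 1.0), False

    # McGraw & Wong (1996) ICC(A,1) confidence bounds
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        return float(icc), (1.0, 1.0), False
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else 1.0
    f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_lo * mse) / (
        f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    return float(icc), (float(lower), float(upper)), bool(degenerate)


def interpret_icc(icc: float) -> str:
    """Koo & Li style reading used in the field: <0.5 poor, 0.5-0.9 moderate
    to good, >=0.9 excellent."""
    if icc < 0.5:
        return "poor"
    if icc < 0.9:
        return "moderate to good"
    return "excellent"


def bland_altman(a, b):
    """Bland-Altman paired-difference statistics for two metrics.

    Differences are ``a - b``.  Limits of agreement are bias +/- 1.96 SD
    (normal-quantile convention).  MAPE uses the pairwise mean as the
    denominator; rows whose pairwise mean is zero are excluded from MAPE
    and counted.

    Returns
    -------
    dict with keys bias, sd_diff, loa, mape, n, n_mape_excluded
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-d vectors")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    pair_mean = (a + b) / 2.0
    ok = pair_mean != 0
    mape = float(np.mean(np.abs(d[ok]) / np.abs(pair_mean[ok])) * 100) if ok.any() else np.nan
    return {
        "bias": bias,
        "sd_diff": sd,
        "loa": loa,
        "mape": mape,
        "n": int(a.size),
        "n_mape_excluded": int((~ok).sum()),
    }


def agreement_stats(a, b, alpha: float = 0.05) -> AgreementStats:
    """Full agreement panel (ICC + Bland-Altman) for one paired feature."""
    icc, ci, degen = icc_2_1(np.column_stack([a, b]), alpha=alpha)
    ba = bland_altman(a, b)
    return AgreementStats(
        icc=icc, icc_ci=ci, bias=ba["bias"], sd_diff=ba["sd_diff"],
        loa=ba["loa"], mape=ba["mape"], n=ba["n"],
        n_mape_excluded=ba["n_mape_excluded"], degenerate=degen,
    )


def pairwise_metric_agreement(features, feature_names=GRID_FEATURES,
                              pairs=METRIC_PAIRS):
    """Agreement grid over metric pairs x features.

    Parameters
    ----------
    features : pandas.DataFrame
        One row per participant x metric with a ``metric`` column and one
        column per feature (long-by-metric, wide-by-feature).  An ``id``
        column identifies participants.
    feature_names : sequence of str
        Features compared (sleep deliberately absent: all metrics share
        one sleep algorithm).

    Returns
    -------
    dict mapping (metric_a, metric_b, feature) -> AgreementStats,
    computed on complete cases per pair.
    """
    import pandas as pd  # deferred; numpy path above stays light

    out = {}
    for ma, mb in pairs:
        fa = features[features["metric"] == ma].set_index("id")
        fb = features[features["metric"] == mb].set_index("id")
        common = fa.index.intersection(fb.index)
        for feat in feature_names:
            x = pd.concat([fa.loc[common, feat], fb.loc[common, feat]], axis=1)
            x = x.dropna()
            out[(ma, mb, feat)] = agreement_stats(
                x.iloc[:, 0].to_numpy(), x.iloc[:, 1].to_numpy()
            )
    return out


def agreement_table(grid) -> "pandas.DataFrame":
    """Flatten a pairwise agreement grid into a long report table."""
    import pandas as pd

    rows = []
    for (ma, mb, feat), s in grid.items():
        rows.append({
            "pair": f"{ma} vs {mb}", "feature": feat, "n": s.n,
            "icc": s.icc, "icc_lo": s.icc_ci[0], "icc_hi": s.icc_ci[1],
            "icc_label": interpret_icc(s.icc),
            "bias": s.bias, "sd_diff": s.sd_diff,
            "loa_lo": s.loa[0], "loa_hi": s.loa[1], "mape_pct": s.mape,
        })
    return pd.DataFrame(rows)
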
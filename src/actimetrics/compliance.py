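"""24-hour movement-behaviour guideline compliance.

Adult guidelines: 420-540 min sleep (7-9 h), at most 480 min sedentary
time (8 h) and at least 30 min MVPA per day.  Each participant-metric
average day falls in exactly one of the eight categories formed by the
subset of guidelines met.  All thresholds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = (
    "none", "PA", "SB", "sleep", "PA+SB", "PA+sleep", "SB+sleep", "all three",
)


@dataclass(frozen=True)
class GuidelineThresholds:
    sleep_min: float = 420.0
    sleep_max: float = 540.0
    sb_max: float = 480.0
    mvpa_min: float = 30.0


def classify_compliance(sleep: float, sb: float, mvpa: float,
                        thresholds: GuidelineThresholds = GuidelineThresholds()) -> str:
    """Category label for one average day (minutes per behaviour)."""
    t = thresholds
    pa = mvpa >= t.mvpa_min
    sb_ok = sb <= t.sb_max
    sl = t.sleep_min <= sleep <= t.sleep_max
    key = (pa, sb_ok, sl)
    return {
        (False, False, False): "none",
        (True, False, False): "PA",
        (False, True, False): "SB",
        (False, False, True): "sleep",
        (True, True, False): "PA+SB",
        (True, False, True): "PA+sleep",
        (False, True, True): "SB+sleep",
        (True, True, True): "all three",
    }[key]


def compliance_table(average_days,
                     thresholds: GuidelineThresholds = GuidelineThresholds()) -> pd.DataFrame:
    """Participant x metric compliance categories.

    ``average_days`` is an iterable of :class:`~actimetrics.features.AverageDay`
    (or any object with participant, metric and a (sleep, SB, LPA, MVPA)
    composition).
    """
    rows = []
    for ad in average_days:
        sleep, sb, _, mvpa = np.asarray(ad.composition, dtype=float)
        rows.append({
            "id": ad.participant, "metric": ad.metric,
            "sleep": sleep, "SB": sb, "MVPA": mvpa,
            "category": classify_compliance(sleep, sb, mvpa, thresholds),
        })
    return pd.DataFrame(rows)


def compliance_prevalence(table: pd.DataFrame) -> pd.DataFrame:
    """Per-metric proportion of participants in each category.

    Rows are metrics, columns the eight categories; each row sums to 1.
    """
    if not len(table):
        raise ValueError("need at least one participant")
    out = (
        table.groupby("metric")["category"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(CATEGORIES), fill_value=0.0)
    )
    out.columns.name = "category"
    return out
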
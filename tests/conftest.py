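import numpy as np
import pandas as pd
import pytest

import actimetrics as am

#: the study-condition weekly profile (per-metric mean day, ENMO row)
WEEK_PROFILE = {"sleep": 512, "SB": 854, "LPA": 34, "MVPA": 40}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def week_run():
    """7-day synthetic recording processed end-to-end by all metrics.

    Returns (ParticipantResult, ground-truth daily minutes).  Run at
    30 Hz (the counts working rate) to keep the session affordable;
    the code path is identical at any supported rate.
    """
    sched = am.generate_bout_schedule(WEEK_PROFILE, days=7, seed=42)
    truth = sched.daily_minutes()
    rec = am.synthesize_raw_recording(sched, sample_rate=30.0,
                                      noise_sd=0.005, seed=43)
    diary = am.schedule_to_diary(sched)
    result = am.process_recording(rec, diary, participant="W1")
    return result, truth


@pytest.fixture()
def day_recording():
    """One synthetic day at 30 Hz with its diary and truth."""
    sched = am.generate_bout_schedule(WEEK_PROFILE, days=1, seed=7)
    rec = am.synthesize_raw_recording(sched, sample_rate=30.0, seed=8)
    return rec, am.schedule_to_diary(sched), sched.daily_minutes()


@pytest.fixture()
def cohort_features():
    return am.simulate_cohort_features(60, seed=5)
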
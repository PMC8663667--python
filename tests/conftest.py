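import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from smglyc import dsmq as dsmq_mod
from smglyc import glycemic, mediation, sm_metrics
from smglyc.pipeline import build_analysis_table
from smglyc.synthetic import SyntheticConfig, generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def brute_force_tic(measurements, year, threshold=8.0):
    """Independent day-by-day Rosendaal oracle.

    Walks every calendar day from the first to the last in-year measurement,
    evaluates the chord formula directly from the bracketing measurements,
    and counts days strictly below the threshold.  Deliberately avoids
    numpy interpolation.
    """
    meas = sorted((d, v) for d, v in measurements if d.year == year)
    if not meas:
        raise ValueError("no in-year measurements")
    first, last = meas[0][0], meas[-1][0]
    n_days = 0
    n_below = 0
    day = first
    while day <= last:
        for (d0, v0), (d1, v1) in zip(meas, meas[1:]):
            if d0 <= day <= d1:
                frac = (day - d0).days / (d1 - d0).days
                value = v0 + (v1 - v0) * frac
                break
        else:
            value = meas[0][1]  # single-measurement series
        n_days += 1
        if value < threshold:
            n_below += 1
        day += dt.timedelta(days=1)
    return 100.0 * n_below / n_days


def random_series(rng, year=2018, max_n=8):
    """A random valid in-year HbA1c series for oracle comparisons."""
    n = int(rng.integers(1, max_n + 1))
    ylen = glycemic.year_length(year)
    days = np.sort(rng.choice(ylen, size=n, replace=False))
    jan1 = dt.date(year, 1, 1)
    values = rng.uniform(5.0, 11.0, size=n)
    return glycemic.HbA1cSeries(
        "r", [(jan1 + dt.timedelta(days=int(d)), float(v)) for d, v in zip(days, values)]
    )


@pytest.fixture(scope="session")
def cohort():
    """One mid-size synthetic cohort shared across tests."""
    return generate_cohort(SyntheticConfig(n_patients=300, seed=11))


@pytest.fixture(scope="session")
def merged(cohort):
    labs = cohort.labs.copy()
    labs["date"] = pd.to_datetime(labs["date"])
    glyc = glycemic.summarize_all(labs, 2018)
    sm = sm_metrics.summarize_all(cohort.messages, cohort.patients["patient_id"], 2017)
    scores = dsmq_mod.score_all(cohort.dsmq)
    table, _ = build_analysis_table(cohort.patients, glyc, sm, scores, mediation.ModelSpec())
    return table
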
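import datetime as dt

import numpy as np
import pytest

from natlab.growth import MMParameters, GeneralizedMMParameters, mm_eval, gmm_eval
from natlab.io import SampleSet, SpecimenRecord


@pytest.fixture
def cbr_params():
    return MMParameters(m_max=72.6, b=36.0)


@pytest.fixture
def dir_params():
    return GeneralizedMMParameters(m0=293.7, m_max=4500.0, b=75.0, c=1.4)


def make_sample(date, depth, nocs=None, tds=None):
    """Build a SampleSet from parallel value lists (None entries allowed)."""
    nocs = list(nocs) if nocs is not None else []
    tds = list(tds) if tds is not None else []
    n = max(len(nocs), len(tds))
    nocs += [None] * (n - len(nocs))
    tds += [None] * (n - len(tds))
    records = [
        SpecimenRecord(f"s{i}", date, depth, chamber_count=c, test_diameter=d)
        for i, (c, d) in enumerate(zip(nocs, tds))
    ]
    return SampleSet(date, depth, records)


@pytest.fixture
def sample_factory():
    return make_sample


def synthetic_cohort_samples(
    pulse_day, cbr, dirp, n_per_month=40, months=12, start=dt.date(2020, 1, 10),
    seed=0, cv=0.08,
):
    """Monthly samples of one cohort born around ``pulse_day`` (days from start)."""
    rng = np.random.default_rng(seed)
    samples = []
    for k in range(months):
        date = start + dt.timedelta(days=30 * k + int(rng.integers(-5, 6)))
        age = (date - start).days - pulse_day
        if age <= 5:
            continue
        records = []
        for i in range(n_per_month):
            f = rng.lognormal(-0.5 * np.log1p(cv**2), np.sqrt(np.log1p(cv**2)))
            a = max(age + rng.normal(0, 3), 1.0)
            noc = max(int(round(float(mm_eval(MMParameters(cbr.m_max * f, cbr.b), a)))), 2)
            td = float(gmm_eval(GeneralizedMMParameters(dirp.m0, dirp.m_max * f, dirp.b, dirp.c), a))
            records.append(SpecimenRecord(f"m{k}i{i}", date, 20.0, noc, td))
        samples.append(SampleSet(date, 20.0, records))
    return samples
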
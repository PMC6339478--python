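"""Per-sample descriptive screens.

Before cohort decomposition each monthly sample is screened: the squared
Pearson correlation between chamber number and ln test diameter (with the
two-sided significance of the regression slope), and — across all samples
of one depth — an analysis-of-covariance F-test of slope homogeneity.
Schizont-dominated populations show weak NoC–lnTD coupling while
gamont-dominated ones correlate strongly, so the screen separates the two
morphotypes at a glance.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io import SampleSet

__all__ = ["SampleScreen", "screen_sample", "screen_samples", "equal_slopes_test"]


@dataclass(frozen=True)
class SampleScreen:
    """Correlation screen of one monthly sample."""

    sampling_date: _dt.date
    n: int
    r_squared: float
    p_slope: float


def _paired(sample: SampleSet) -> tuple[np.ndarray, np.ndarray]:
    noc, lntd = [], []
    for r in sample.records:
        if r.chamber_count is not None and r.test_diameter is not None:
            noc.append(float(r.chamber_count))
            lntd.append(np.log(r.test_diameter))
    return np.asarray(noc), np.asarray(lntd)


def screen_sample(sample: SampleSet) -> SampleScreen:
    """OLS of ln(TD) on NoC for one sample: r² and slope p-value."""
    noc, lntd = _paired(sample)
    if len(noc) < 3:
        raise ValueError(f"sample {sample.sampling_date}: fewer than 3 paired specimens")
    if np.ptp(noc) == 0:
        raise ValueError(f"sample {sample.sampling_date}: no variance in chamber counts")
    model = sm.OLS(lntd, sm.add_constant(noc)).fit()
    return SampleScreen(
        sampling_date=sample.sampling_date,
        n=len(noc),
        r_squared=float(model.rsquared),
        p_slope=float(model.pvalues[1]),
    )


def screen_samples(samples: Sequence[SampleSet], min_n: int = 3) -> list[SampleScreen]:
    out = []
    for s in samples:
        noc, _ = _paired(s)
        if len(noc) >= min_n and np.ptp(noc) > 0:
            out.append(screen_sample(s))
    return out


def equal_slopes_test(samples: Sequence[SampleSet]) -> tuple[float, float]:
    """ANCOVA F-test of a common NoC–lnTD slope across samples of one depth.

    Compares the model with per-sample slopes against the common-slope
    model; returns (F, p).
    """
    rows = []
    for s in samples:
        noc, lntd = _paired(s)
        for x, y in zip(noc, lntd):
            rows.append({"noc": x, "lntd": y, "sample": s.sampling_date.isoformat()})
    df = pd.DataFrame(rows)
    if df["sample"].nunique() < 2:
        raise ValueError("need at least 2 samples for the slope-homogeneity test")
    full = smf.ols("lntd ~ C(sample) * noc", data=df).fit()
    reduced = smf.ols("lntd ~ C(sample) + noc", data=df).fit()
    res = full.compare_f_test(reduced)
    return float(res[0]), float(res[1])
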
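"""Birthdate back-calculation and longevity.

Inverting a fitted growth curve turns each specimen's size at sampling into
an age.  For chamber numbers the Michaelis–Menten inverse is

    age = NoC * b / (m_max - NoC),

and for test diameters the generalized-MM inverse is

    age = ((TD - m0) * b^c / (m_max - TD))^(1/c).

The birthdate is the sampling date minus the age.  Specimens at or beyond
the fitted asymptote have no finite age and are excluded (their count is
reported).  Birthdates are accumulated into calendar-month histograms,
either with simple counts or with weights 1/sample-size when sample sizes
differ systematically; the maximal age over all specimens estimates the
species' longevity.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .growth import MMParameters, GeneralizedMMParameters
from .io import SpecimenRecord

__all__ = [
    "BirthdateRecord",
    "BirthdateHistogram",
    "invert_cbr",
    "invert_dir",
    "invert_sample_sets",
    "birthdate_histogram",
    "estimate_longevity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BirthdateRecord:
    """Inferred birth of one specimen."""

    specimen_id: str
    birth_date: _dt.date
    age_days: float
    weight: float = 1.0
    basis: str = "cbr"  # which growth curve was inverted


@dataclass
class BirthdateHistogram:
    """Summed weights of inferred birthdates per calendar month."""

    months: list[_dt.date]     # first day of each month
    densities: np.ndarray
    basis: str = "cbr"

    @property
    def total(self) -> float:
        return float(self.densities.sum())

    def midpoints_days(self, origin: Optional[_dt.date] = None) -> np.ndarray:
        """Month midpoints on a day axis, for periodicity analysis."""
        origin = origin or self.months[0]
        mids = []
        for m in self.months:
            nxt = (m.replace(day=28) + _dt.timedelta(days=4)).replace(day=1)
            mid = m + (nxt - m) / 2
            mids.append((mid - origin).days + (mid - origin).seconds / 86400.0)
        return np.asarray(mids, dtype=float)


def invert_cbr(
    fit: MMParameters, record: SpecimenRecord, weight: float = 1.0
) -> Optional[BirthdateRecord]:
    """Age and birthdate from a chamber count via the MM inverse.

    Returns ``None`` (with a warning) for specimens whose chamber count
    reaches the asymptote — the inverse has a pole there and clamping would
    fabricate an arbitrary age.
    """
    noc = record.chamber_count
    if noc is None:
        return None
    if noc < 2:
        raise ValueError(f"specimen {record.specimen_id}: chamber count {noc} < 2")
    if noc >= fit.m_max:
        logger.warning(
            "specimen %s beyond asymptote (NoC %s >= m_max %.1f); excluded",
            record.specimen_id, noc, fit.m_max,
        )
        return None
    age = noc * fit.b / (fit.m_max - noc)
    birth = record.sampling_date - _dt.timedelta(days=float(age))
    return BirthdateRecord(record.specimen_id, birth, float(age), weight, "cbr")


def invert_dir(
    fit: GeneralizedMMParameters, record: SpecimenRecord, weight: float = 1.0
) -> Optional[BirthdateRecord]:
    """Age and birthdate from a test diameter via the generalized-MM inverse.

    Diameters below the nepiontic diameter get age 0 (flagged); diameters
    at or beyond the asymptote are excluded like chamber counts.
    """
    td = record.test_diameter
    if td is None:
        return None
    if td >= fit.m_max:
        logger.warning(
            "specimen %s beyond asymptote (TD %.0f >= m_max %.0f); excluded",
            record.specimen_id, td, fit.m_max,
        )
        return None
    if td < fit.m0:
        logger.warning(
            "specimen %s smaller than the nepiont (TD %.0f < m0 %.0f); age set to 0",
            record.specimen_id, td, fit.m0,
        )
        age = 0.0
    else:
        age = float(((td - fit.m0) * fit.b ** fit.c / (fit.m_max - td)) ** (1.0 / fit.c))
    birth = record.sampling_date - _dt.timedelta(days=age)
    return BirthdateRecord(record.specimen_id, birth, age, weight, "dir")


def invert_sample_sets(
    fit: MMParameters | GeneralizedMMParameters,
    samples: Sequence,
    weighting: str = "simple",
) -> tuple[list[BirthdateRecord], int]:
    """Invert every specimen of a list of SampleSets.

    ``weighting="per_sample"`` assigns each record the weight
    ``1 / sample_size`` of its monthly sample (used when sampled sediment
    amounts differ); ``"simple"`` assigns 1.  Returns the records and the
    number of specimens excluded as beyond-asymptote.
    """
    invert = invert_cbr if isinstance(fit, MMParameters) else invert_dir
    out: list[BirthdateRecord] = []
    excluded = 0
    for sample in samples:
        w = 1.0 / sample.sample_size if weighting == "per_sample" else 1.0
        for rec in sample.records:
            r = invert(fit, rec, weight=w)
            if r is None:
                char_val = rec.chamber_count if isinstance(fit, MMParameters) else rec.test_diameter
                if char_val is not None:
                    excluded += 1
            else:
                out.append(r)
    return out, excluded


def birthdate_histogram(
    records: Sequence[BirthdateRecord], weighting: str = "simple"
) -> BirthdateHistogram:
    """Monthly histogram of inferred birthdates.

    With ``weighting="simple"`` every record contributes 1 (total equals the
    record count); with ``"per_sample"`` each record contributes its stored
    weight.  Empty months between the first and last birth get density 0 so
    the series is evenly spaced in calendar months.
    """
    if not records:
        raise ValueError("no birthdate records")
    weights = [1.0 if weighting == "simple" else r.weight for r in records]
    months = [r.birth_date.replace(day=1) for r in records]
    first, last = min(months), max(months)
    axis = []
    m = first
    while m <= last:
        axis.append(m)
        m = (m.replace(day=28) + _dt.timedelta(days=4)).replace(day=1)
    dens = np.zeros(len(axis))
    index = {m: i for i, m in enumerate(axis)}
    for m, w in zip(months, weights):
        dens[index[m]] += w
    return BirthdateHistogram(axis, dens, basis=records[0].basis)


def estimate_longevity(records: Sequence[BirthdateRecord]) -> float:
    """Maximal difference in days between birth and sampling date."""
    if not records:
        raise ValueError("no birthdate records")
    return float(max(r.age_days for r in records))
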
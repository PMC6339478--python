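"""Reading and writing specimen tables and stage outputs.

The raw input of a natural-laboratory analysis is a per-specimen table:
one row per individual with its sampling date, water-depth station, chamber
number (NoC) and maximal test diameter (TD, in µm).  Rows are grouped into
monthly :class:`SampleSet` objects.  Tables may be comma- or tab-delimited
and may use either decimal points or decimal commas; dates are accepted in
ISO 8601 (``2014-05-02``) or day-first dotted (``02.05.2014``) form.

Specimens missing one of the two size characters are kept for the character
they do have, since chamber counts and diameters are analysed independently.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import io as _stdio
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import StudyConfig

__all__ = [
    "SpecimenRecord",
    "SampleSet",
    "read_specimen_table",
    "write_table",
    "FormatError",
    "ValidationError",
]


class FormatError(ValueError):
    """The input file does not match the expected tabular layout."""


class ValidationError(ValueError):
    """A row violates a specimen-level invariant."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One measured individual.

    ``chamber_count`` includes the nepiont (proloculus + deuteroloculus), so
    a valid count is at least 2.  ``test_diameter`` is the maximal diameter
    through the proloculus centre, in µm.  Either character may be ``None``
    when it was not measured.
    """

    specimen_id: str
    sampling_date: _dt.date
    station_depth: float
    chamber_count: Optional[int] = None
    test_diameter: Optional[float] = None


@dataclass
class SampleSet:
    """All specimens of one sampling date at one depth station."""

    sampling_date: _dt.date
    station_depth: float
    records: list[SpecimenRecord]
    sediment_weight: Optional[float] = None

    @property
    def sample_size(self) -> int:
        return len(self.records)

    def values(self, character: str) -> np.ndarray:
        """Measured values of one character, NaN-free.

        ``character`` is ``"noc"`` (chamber counts) or ``"td"`` (diameters,
        µm, untransformed).
        """
        if character == "noc":
            vals = [r.chamber_count for r in self.records if r.chamber_count is not None]
        elif character == "td":
            vals = [r.test_diameter for r in self.records if r.test_diameter is not None]
        else:
            raise ValueError(f"unknown character {character!r}")
        return np.asarray(vals, dtype=float)


_DEFAULT_COLUMNS = {
    "date": "date",
    "depth": "depth",
    "chamber_count": "chamber_count",
    "test_diameter": "test_diameter",
    "specimen_id": "specimen_id",
    "sediment_weight": "sediment_weight",
}


def _parse_date(value, row: int) -> _dt.date:
    s = str(value).strip()
    for fmt in ("%Y-%m-%d", "%d.%m.%Y"):
        try:
            return _dt.datetime.strptime(s, fmt).date()
        except ValueError:
            continue
    raise FormatError(f"row {row}: unparseable date {value!r}")


def _to_float(value):
    """Accept both decimal points and decimal commas."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip().replace(",", ".")
        if value in ("", "nan", "NA"):
            return None
    return float(value)


def read_specimen_table(
    path,
    config: Optional[StudyConfig] = None,
    column_map: Optional[dict] = None,
) -> list[SampleSet]:
    """Read a delimited specimen table and group it into monthly samples.

    Parameters
    ----------
    path
        CSV or TSV file with at least the columns ``date``, ``depth``,
        ``chamber_count`` and ``test_diameter`` (names remappable through
        ``column_map``, for deposits with a different layout).
    config
        Optional study configuration; when given, sampling dates outside
        ``[study_start, study_end]`` raise :class:`ValidationError`.
    column_map
        Mapping from the logical names above to the file's column names.

    Returns
    -------
    list of :class:`SampleSet`, sorted by sampling date then depth.  The sum
    of their sample sizes equals the number of input rows.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    for logical in ("date", "depth", "chamber_count", "test_diameter"):
        if cols[logical] not in df.columns:
            raise FormatError(f"missing column {cols[logical]!r} in {path}")

    groups: dict[tuple, SampleSet] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        date = _parse_date(rowd[cols["date"]], i)
        depth = _to_float(rowd[cols["depth"]])
        noc = _to_float(rowd[cols["chamber_count"]])
        td = _to_float(rowd[cols["test_diameter"]])
        if noc is not None:
            if noc < 2:
                raise ValidationError(
                    f"row {i}: chamber_count {noc} < 2 (nepiont has 2 chambers)"
                )
            noc = int(round(noc))
        if td is not None and td <= 0:
            raise ValidationError(f"row {i}: test_diameter {td} <= 0")
        if noc is None and td is None:
            raise ValidationError(f"row {i}: neither chamber_count nor test_diameter")
        if config is not None:
            if config.study_start is not None and date < config.study_start:
                raise ValidationError(f"row {i}: date {date} before study window")
            if config.study_end is not None and date > config.study_end:
                raise ValidationError(f"row {i}: date {date} after study window")
        sid = rowd.get(cols["specimen_id"]) or f"sp{i}"
        weight = _to_float(rowd.get(cols["sediment_weight"]))
        key = (date, depth)
        if key not in groups:
            groups[key] = SampleSet(date, depth, [], sediment_weight=weight)
        groups[key].records.append(
            SpecimenRecord(str(sid), date, depth, chamber_count=noc, test_diameter=td)
        )
    return [groups[k] for k in sorted(groups)]


def write_table(rows: Sequence, path, float_format: str = "%.6g") -> None:
    """Write homogeneous stage output (dataclasses, dicts or a DataFrame).

    Columns keep the field order of the first row; floats use a fixed format
    so repeated runs produce byte-identical files.  An empty sequence writes
    a header-only file when a DataFrame (with columns) is passed, or an
    empty file otherwise.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        dicts = []
        for r in rows:
            if dataclasses.is_dataclass(r):
                dicts.append(dataclasses.asdict(r))
            elif isinstance(r, dict):
                dicts.append(dict(r))
            else:
                raise TypeError(f"cannot serialise row of type {type(r)}")
        df = pd.DataFrame(dicts)
    buf = _stdio.StringIO()
    df.to_csv(buf, index=False, float_format=float_format)
    Path(path).write_text(buf.getvalue())
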
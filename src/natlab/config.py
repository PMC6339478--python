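"""Run configuration for a natural-laboratory study.

A :class:`StudyConfig` collects every knob that the pipeline stages share:
the study window, histogram bin widths, the onset-search grid, the maximum
number of normal components per monthly sample, and the random seed used to
make every nonlinear fit reproducible.  Configurations can be loaded from a
JSON or YAML file whose keys mirror the dataclass fields.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["StudyConfig", "load_config"]


def _parse_date(value) -> Optional[_dt.date]:
    if value is None or isinstance(value, _dt.date):
        return value
    for fmt in ("%Y-%m-%d", "%d.%m.%Y"):
        try:
            return _dt.datetime.strptime(str(value), fmt).date()
        except ValueError:
            continue
    raise ValueError(f"unparseable date: {value!r}")


@dataclass
class StudyConfig:
    """Shared settings of one natural-laboratory analysis.

    Parameters
    ----------
    study_start, study_end
        Calendar window of the sampling campaign.  Specimen records outside
        the window are rejected on read.  ``None`` disables the check.
    bin_width_noc
        Histogram interval for chamber numbers, in chambers.
    bin_width_lntd
        Histogram interval for ln-transformed test diameters
        (dimensionless on the log scale).
    onset_grid
        ``(min_days, max_days, step_days)`` of the coarse onset search.
    max_components
        Upper bound (1-3) on normal components fitted per monthly sample.
    rng_seed
        Seed for every stochastic step (multistart initialisation).
    normalized_sd_mode
        ``"cv_times_mean"`` computes the normalized standard deviation of a
        cohort as ``CV_mean * mean`` (a quantity in the character's units);
        ``"cv_over_mean"`` divides instead, for sensitivity checks.
    generation_overrides
        Optional map ``(iso date string, component_index) -> generation_id``
        forcing the tracker's assignment for specific components.
    """

    study_start: Optional[_dt.date] = None
    study_end: Optional[_dt.date] = None
    bin_width_noc: float = 5.0
    bin_width_lntd: float = 0.15
    onset_grid: tuple[int, int, int] = (10, 70, 5)
    max_components: int = 3
    rng_seed: int = 0
    character: str = "noc"
    normalized_sd_mode: str = "cv_times_mean"
    generation_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.max_components not in (1, 2, 3):
            raise ValueError("max_components must be 1, 2 or 3")
        lo, hi, step = self.onset_grid
        if not (0 < lo <= hi and step > 0):
            raise ValueError(f"invalid onset grid {self.onset_grid}")
        if self.character not in ("noc", "td"):
            raise ValueError("character must be 'noc' or 'td'")
        if self.normalized_sd_mode not in ("cv_times_mean", "cv_over_mean"):
            raise ValueError("unknown normalized_sd_mode")
        self.study_start = _parse_date(self.study_start)
        self.study_end = _parse_date(self.study_end)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("study_start", "study_end"):
            if d[key] is not None:
                d[key] = d[key].isoformat()
        d["onset_grid"] = list(self.onset_grid)
        return d


def load_config(path) -> StudyConfig:
    """Read a :class:`StudyConfig` from a JSON or YAML file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    if "onset_grid" in raw:
        raw["onset_grid"] = tuple(raw["onset_grid"])
    return StudyConfig(**raw)
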
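"""Forward simulation of a foraminiferal population under known dynamics.

The simulator is the ground-truth generator for the whole pipeline: births
are drawn from a seasonal intensity (a baseline plus sinusoids, sampled by
Poisson thinning), every individual grows deterministically along the
chamber-number and diameter curves with lognormal individual variation of
its asymptote, dies at a maximum age, and is observed through monthly
samples at uneven dates with limited sample sizes.  Every draw derives
from one seed, so a configuration maps to byte-identical output tables.

Two shipped scenarios mirror the study populations: a shallow
("20m"-like) population whose summer reproduction pulse is roughly three
times the winter pulses, and a deeper ("50m"-like) population with more
balanced, winter-leaning pulses.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .growth import MMParameters, GeneralizedMMParameters, mm_eval, gmm_eval
from .io import SampleSet, SpecimenRecord
from .periodicity import SinusoidComponent

__all__ = [
    "SimulationConfig",
    "SimulatedPopulation",
    "scenario",
    "simulate_births",
    "grow_and_sample",
    "simulate",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic population.

    ``birth_offset`` (births/day) plus the ``birth_sinusoids`` define the
    seasonal birth intensity; it must be non-negative over the study span.
    ``individual_cv`` is the relative standard deviation of the lognormal
    per-individual asymptote factor shared by both growth curves.  Sampling
    happens on ``sampling_days`` (days since study start; generated as
    jittered monthly dates when empty) with ``sample_size`` specimens per
    date (or all alive, when fewer).
    """

    cbr_params: MMParameters = field(default_factory=lambda: MMParameters(72.6, 36.0))
    dir_params: GeneralizedMMParameters = field(
        default_factory=lambda: GeneralizedMMParameters(293.7, 4500.0, 75.0, 1.4)
    )
    individual_cv: float = 0.10
    birth_offset: float = 0.5
    birth_sinusoids: list[SinusoidComponent] = field(default_factory=list)
    span_days: float = 450.0
    sampling_days: list[float] = field(default_factory=list)
    sample_size: int = 40
    sample_fraction: Optional[float] = None
    max_age_days: float = 416.0
    td_noise_sd: float = 0.05        # lognormal sd of the diameter observation
    noc_noise_prob: float = 0.10     # probability of a +-1 chamber miscount
    study_start: _dt.date = _dt.date(2014, 4, 23)
    station_depth: float = 20.0
    rng_seed: int = 0

    def intensity(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        lam = np.full_like(t, self.birth_offset, dtype=float)
        for s in self.birth_sinusoids:
            lam += s.amplitude * np.sin(2 * np.pi * t / s.period + s.phase)
        return lam


def _phase_peak_at(day: float, period: float) -> float:
    """Phase so that sin(2*pi*t/period + phase) peaks at t = day."""
    return float((np.pi / 2 - 2 * np.pi * day / period) % (2 * np.pi))


def scenario(name: str, rng_seed: int = 0, **overrides) -> SimulationConfig:
    """Shipped study-like configurations: ``"20m"`` or ``"50m"``.

    The shallow scenario puts a dominant reproduction pulse in late July
    (about three times the winter pulse); the deep scenario balances the
    two pulses with a slight winter lean.  The summer peak sits at day 93
    of a study starting 23 April (late July).
    """
    summer = 93.0
    if name == "20m":
        sins = [
            SinusoidComponent(365.0, 0.45, _phase_peak_at(summer, 365.0)),
            SinusoidComponent(182.5, 0.25, _phase_peak_at(summer, 182.5)),
        ]
        cfg = SimulationConfig(birth_offset=0.55, birth_sinusoids=sins,
                               station_depth=20.0, rng_seed=rng_seed)
    elif name == "50m":
        winter = summer + 182.5
        sins = [
            SinusoidComponent(365.0, 0.10, _phase_peak_at(winter, 365.0)),
            SinusoidComponent(182.5, 0.30, _phase_peak_at(summer, 182.5)),
        ]
        cfg = SimulationConfig(birth_offset=0.55, birth_sinusoids=sins,
                               station_depth=50.0, rng_seed=rng_seed)
    else:
        raise ValueError(f"unknown scenario {name!r}")
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


@dataclass
class SimulatedPopulation:
    """Ground truth and its monthly observation."""

    truth: pd.DataFrame              # birth_day, m_max_factor per individual
    samples: list[SampleSet]
    config: SimulationConfig

    def observed_frame(self) -> pd.DataFrame:
        """Observed specimens as the flat table the reader consumes."""
        rows = []
        for s in self.samples:
            for r in s.records:
                rows.append({
                    "specimen_id": r.specimen_id,
                    "date": r.sampling_date.isoformat(),
                    "depth": s.station_depth,
                    "chamber_count": r.chamber_count,
                    "test_diameter": round(r.test_diameter, 2),
                })
        return pd.DataFrame(rows)


def simulate_births(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Birth days from the seasonal intensity by Poisson thinning.

    Births are drawn on ``[-max_age, span]`` so that individuals older than
    the study window can appear in early samples.  Raises ``ValueError``
    when the intensity goes negative anywhere on that range.
    """
    rng = rng or np.random.default_rng(cfg.rng_seed)
    t_lo, t_hi = -cfg.max_age_days, cfg.span_days
    grid = np.linspace(t_lo, t_hi, 2048)
    lam = cfg.intensity(grid)
    if np.any(lam < -1e-12):
        raise ValueError("birth intensity is negative somewhere on the study span")
    lam_max = float(lam.max())
    if lam_max == 0:
        return np.array([])
    n = rng.poisson(lam_max * (t_hi - t_lo))
    times = np.sort(rng.uniform(t_lo, t_hi, size=n))
    keep = rng.uniform(0, lam_max, size=n) < cfg.intensity(times)
    return times[keep]


def grow_and_sample(
    births: np.ndarray,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedPopulation:
    """Grow individuals, apply mortality, and sample them monthly."""
    rng = rng or np.random.default_rng(cfg.rng_seed + 1)
    births = np.asarray(births, dtype=float)
    cv = cfg.individual_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv ** 2))
        factors = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=len(births))
    else:
        factors = np.ones(len(births))
    truth = pd.DataFrame({"birth_day": births, "m_max_factor": factors})
    truth.index.name = "individual"

    days = list(cfg.sampling_days)
    if not days:
        nominal = np.arange(10.0, cfg.span_days, 30.0)
        days = list(np.clip(nominal + rng.uniform(-10, 10, size=len(nominal)), 0, cfg.span_days))
    days = sorted(days)

    samples: list[SampleSet] = []
    for day in days:
        date = cfg.study_start + _dt.timedelta(days=float(day))
        ages = day - births
        alive = np.flatnonzero((ages > 0) & (ages < cfg.max_age_days))
        if len(alive) == 0:
            continue
        if cfg.sample_fraction is not None:
            n_take = max(int(round(cfg.sample_fraction * len(alive))), 1)
        else:
            n_take = cfg.sample_size
        n_take = min(n_take, len(alive))
        chosen = np.sort(rng.choice(alive, size=n_take, replace=False))
        records = []
        for idx in chosen:
            age = ages[idx]
            f = factors[idx]
            cbr_i = MMParameters(cfg.cbr_params.m_max * f, cfg.cbr_params.b)
            dir_i = GeneralizedMMParameters(
                cfg.dir_params.m0, cfg.dir_params.m_max * f,
                cfg.dir_params.b, cfg.dir_params.c,
            )
            noc = int(round(float(mm_eval(cbr_i, age))))
            if cfg.noc_noise_prob > 0 and rng.uniform() < cfg.noc_noise_prob:
                noc += int(rng.choice([-1, 1]))
            noc = max(noc, 2)
            td = float(gmm_eval(dir_i, age))
            if cfg.td_noise_sd > 0:
                td *= float(rng.lognormal(mean=-cfg.td_noise_sd ** 2 / 2,
                                          sigma=cfg.td_noise_sd))
            records.append(SpecimenRecord(
                specimen_id=f"ind{idx}", sampling_date=date,
                station_depth=cfg.station_depth,
                chamber_count=noc, test_diameter=td,
            ))
        samples.append(SampleSet(date, cfg.station_depth, records))
    return SimulatedPopulation(truth, samples, cfg)


def simulate(cfg: SimulationConfig) -> SimulatedPopulation:
    """Births plus growth-and-sampling under one seed."""
    rng = np.random.default_rng(cfg.rng_seed)
    births = simulate_births(cfg, rng)
    return grow_and_sample(births, cfg, rng)
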
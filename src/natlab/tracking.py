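"""Linking monthly cohort components into generations.

A generation is a cohort born in one reproduction pulse; its decomposed
component reappears month after month with a growing mean.  Tracking links
each month's components to open generation tracks by a greedy
nearest-trajectory rule: a component joins the track whose last mean is
closest from below (growth must be non-negative up to a sampling-noise
slack), unmatched small components open new tracks, and a track closes when
its expected position has outgrown everything observed in a month.
Ambiguities in real data can be resolved through a manual override map.

From a track, the pooled coefficient of variation and the per-month maxima
``m_jt = mean * (1 + 3 * CV_mean)`` (mean plus three normalized standard
deviations) are derived; these maxima are the input of the growth-curve
fits.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .histograms import DecompositionResult, NormalComponent

__all__ = [
    "GenerationTrack",
    "MaximumTrajectory",
    "assign_generations",
    "pooled_cv",
    "maximum_trajectory",
    "mean_trajectory",
]

logger = logging.getLogger(__name__)


@dataclass
class GenerationTrack:
    """Time-ordered components attributed to one generation."""

    generation_id: int
    entries: list[tuple[_dt.date, NormalComponent]] = field(default_factory=list)
    cv_mean: Optional[float] = None
    onset_days: Optional[int] = None
    character: str = "noc"

    @property
    def dates(self) -> list[_dt.date]:
        return [d for d, _ in self.entries]

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for _, c in self.entries])

    @property
    def last_mean(self) -> float:
        return self.entries[-1][1].mean


@dataclass
class MaximumTrajectory:
    """Per-month maxima (or means) of one generation on a day axis.

    ``t_days`` counts days since the generation's first observed component;
    the growth fit later shifts this axis by the onset length.
    """

    t_days: np.ndarray
    values: np.ndarray
    generation_id: int
    character: str
    kind: str  # "max" or "mean"
    first_date: Optional[_dt.date] = None


def assign_generations(
    decomps: Sequence[DecompositionResult],
    slack: float = 0.15,
    overrides: Optional[dict] = None,
) -> list[GenerationTrack]:
    """Greedy linking of monthly components into generation tracks.

    Parameters
    ----------
    decomps
        Decomposition results in any order; they are processed
        chronologically.
    slack
        Allowed relative decrease of a track's mean between consecutive
        observations (sampling noise allowance).
    overrides
        Optional ``{(iso_date, component_index): generation_id}`` map that
        forces specific assignments; component indices follow the stored
        (mean-descending) order.

    Notes
    -----
    Matching within a month is greedy by the smallest absolute mean gap over
    all admissible (track, component) pairs; a pair is admissible when the
    component mean is at least ``last_mean * (1 - slack)``.  When two tracks
    are admissible for one component the smaller gap wins and a warning is
    logged.  Components left unmatched open a new generation.  A track that
    received nothing in a month although its last mean exceeds every
    component observed that month is closed.
    """
    decomps = sorted(
        [d for d in decomps if d.components], key=lambda d: d.sampling_date
    )
    if len(decomps) < 3:
        raise ValueError("need at least 3 months of decompositions to track generations")
    overrides = overrides or {}
    open_tracks: list[GenerationTrack] = []
    closed: list[GenerationTrack] = []
    next_id = 1
    character = decomps[0].character

    for dec in decomps:
        comps = list(dec.components)
        taken_tracks: set[int] = set()
        assigned: dict[int, GenerationTrack] = {}

        # forced assignments first
        for ci, comp in enumerate(comps):
            key = (dec.sampling_date.isoformat(), ci)
            if key in overrides:
                gid = overrides[key]
                track = next(
                    (t for t in open_tracks + closed if t.generation_id == gid), None
                )
                if track is None:
                    track = GenerationTrack(gid, character=character)
                    open_tracks.append(track)
                    next_id = max(next_id, gid + 1)
                if track in closed:
                    closed.remove(track)
                    open_tracks.append(track)
                assigned[ci] = track
                taken_tracks.add(id(track))

        # greedy matching, largest component first: each component claims
        # the open track whose last mean is closest from below
        for ci in sorted(
            (i for i in range(len(comps)) if i not in assigned),
            key=lambda i: comps[i].mean, reverse=True,
        ):
            comp = comps[ci]
            candidates = [
                (abs(comp.mean - track.last_mean), track)
                for track in open_tracks
                if id(track) not in taken_tracks
                and comp.mean >= track.last_mean * (1.0 - slack)
            ]
            if not candidates:
                continue
            candidates.sort(key=lambda c: c[0])
            gap, track = candidates[0]
            if len(candidates) > 1 and candidates[1][0] < 2 * gap + 1e-9:
                logger.warning(
                    "ambiguous assignment on %s for component mean %.1f; "
                    "resolved to generation %d (gap %.2f)",
                    dec.sampling_date, comp.mean, track.generation_id, gap,
                )
            assigned[ci] = track
            taken_tracks.add(id(track))

        # unmatched components open new generations
        for ci, comp in enumerate(comps):
            if ci not in assigned:
                track = GenerationTrack(next_id, character=character)
                next_id += 1
                open_tracks.append(track)
                assigned[ci] = track
                taken_tracks.add(id(track))

        for ci, track in assigned.items():
            track.entries.append((dec.sampling_date, comps[ci]))

        # close tracks that have outgrown everything observed this month
        month_max = max(c.mean for c in comps)
        still_open = []
        for track in open_tracks:
            if id(track) not in taken_tracks and track.last_mean > month_max:
                closed.append(track)
            else:
                still_open.append(track)
        open_tracks = still_open

    tracks = closed + open_tracks
    tracks.sort(key=lambda t: t.entries[0][0])
    for new_id, t in enumerate(tracks, start=1):
        t.generation_id = new_id
        t.entries.sort(key=lambda e: e[0])
    return tracks


def pooled_cv(track: GenerationTrack) -> float:
    """Arithmetic mean of the per-component coefficients of variation.

    The pooled CV of a generation scales its normalized standard deviation:
    ``s* = CV_mean * mean`` carries the character's units, so the monthly
    maximum is ``mean * (1 + 3 * CV_mean)``.
    """
    if len(track.entries) < 2:
        raise ValueError("pooled CV needs at least 2 components")
    means = track.means
    if np.any(means <= 0):
        raise ValueError("component means must be positive")
    cvs = np.array([c.sd / c.mean for _, c in track.entries])
    cv = float(np.mean(cvs))
    track.cv_mean = cv
    return cv


def _day_axis(track: GenerationTrack) -> np.ndarray:
    t0 = track.entries[0][0]
    return np.array([(d - t0).days for d, _ in track.entries], dtype=float)


def maximum_trajectory(
    track: GenerationTrack, normalized_sd_mode: str = "cv_times_mean"
) -> MaximumTrajectory:
    """Monthly maxima ``m_jt = mean + 3 s*`` of one generation.

    With the default mode the normalized standard deviation is
    ``s* = CV_mean * mean`` so ``m_jt = mean * (1 + 3 CV_mean)``; the
    alternative mode ``"cv_over_mean"`` (a dimensionally inconsistent
    variant retained for sensitivity checks) uses ``s* = CV_mean / mean``.
    """
    cv = track.cv_mean if track.cv_mean is not None else pooled_cv(track)
    means = track.means
    if normalized_sd_mode == "cv_times_mean":
        values = means * (1.0 + 3.0 * cv)
    elif normalized_sd_mode == "cv_over_mean":
        values = means + 3.0 * cv / means
    else:
        raise ValueError(f"unknown normalized_sd_mode {normalized_sd_mode!r}")
    return MaximumTrajectory(
        t_days=_day_axis(track), values=values,
        generation_id=track.generation_id, character=track.character,
        kind="max", first_date=track.entries[0][0],
    )


def mean_trajectory(track: GenerationTrack) -> MaximumTrajectory:
    """Monthly component means of one generation on the day axis."""
    return MaximumTrajectory(
        t_days=_day_axis(track), values=track.means,
        generation_id=track.generation_id, character=track.character,
        kind="mean", first_date=track.entries[0][0],
    )
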
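"""Growth-curve models: chamber-building and diameter-increase rates.

Chamber number grows along a Michaelis–Menten (MM) curve through the
origin,

    m(t) = m_max * t / (b + t),

with asymptote ``m_max`` (maximal chamber number) and half-saturation time
``b`` (days at which half the asymptote is reached).  Test diameter starts
at the nepiontic diameter ``m0`` and follows a generalized (sigmoid) MM
curve,

    m(t) = (m0 * b^c + m_max * t^c) / (b^c + t^c),

with shape exponent ``c > 1``.

The time axis is days since birth.  Because a cohort is only detected some
weeks after the reproduction event, the fit searches for this *onset*
length on a coarse 5-day grid (10–70 days by default) followed by a
day-wise refinement; each candidate prepends two pseudo-observations
representing the embryonic stage (chamber numbers 2 and 3, or the measured
mean diameters at those chamber counts) and scores the weighted
least-squares fit by a reduced chi-square.  The diameter fit reuses the
onset found for chamber numbers.

Both curves are available as scikit-learn style regressors
(:class:`MichaelisMentenGrowth`, :class:`GeneralizedMichaelisMentenGrowth`).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .tracking import MaximumTrajectory

__all__ = [
    "MMParameters",
    "GeneralizedMMParameters",
    "GrowthFit",
    "mm_eval",
    "mm_derivative",
    "gmm_eval",
    "gmm_derivative",
    "fit_growth",
    "onset_search",
    "growth_table",
    "MichaelisMentenGrowth",
    "GeneralizedMichaelisMentenGrowth",
    "GrowthFitError",
]


class GrowthFitError(RuntimeError):
    """No converged growth fit."""


@dataclass(frozen=True)
class MMParameters:
    """Michaelis–Menten parameters for chamber-number growth."""

    m_max: float  # asymptotic chamber number
    b: float      # days at half-asymptote

    def __post_init__(self):
        if self.m_max <= 0 or self.b <= 0:
            raise ValueError("m_max and b must be positive")


@dataclass(frozen=True)
class GeneralizedMMParameters:
    """Generalized (sigmoid) Michaelis–Menten parameters for diameter growth."""

    m0: float     # nepiontic diameter, µm
    m_max: float  # asymptotic diameter, µm
    b: float      # days at the curve midpoint
    c: float      # shape exponent, > 1 for a sigmoid

    def __post_init__(self):
        if not (0 < self.m0 < self.m_max):
            raise ValueError("need 0 < m0 < m_max")
        if self.b <= 0:
            raise ValueError("b must be positive")
        if self.c <= 1:
            raise ValueError("c must exceed 1")


@dataclass
class GrowthFit:
    """A fitted growth curve for one generation and character."""

    parameters: MMParameters | GeneralizedMMParameters
    onset_days: int
    trajectory_kind: str       # "max" or "mean"
    fit_quality: float         # reduced chi-square
    generation_id: Optional[int] = None
    character: str = "noc"
    depth: Optional[float] = None
    first_date: Optional[_dt.date] = None

    @property
    def birth_date(self) -> Optional[_dt.date]:
        """Inferred birth date: first appearance minus the onset length."""
        if self.first_date is None:
            return None
        return self.first_date - _dt.timedelta(days=self.onset_days)

    def eval(self, t):
        p = self.parameters
        if isinstance(p, MMParameters):
            return mm_eval(p, t)
        return gmm_eval(p, t)


def _check_nonneg(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since birth must be non-negative")
    return t


def mm_eval(p: MMParameters, t):
    """Michaelis–Menten curve ``m_max * t / (b + t)``; origin at t=0."""
    t = _check_nonneg(t)
    return p.m_max * t / (p.b + t)


def mm_derivative(p: MMParameters, t):
    """Instantaneous chamber-building rate ``m_max * b / (b + t)^2``."""
    t = _check_nonneg(t)
    return p.m_max * p.b / (p.b + t) ** 2


def gmm_eval(p: GeneralizedMMParameters, t):
    """Generalized MM curve ``(m0 b^c + m_max t^c) / (b^c + t^c)``."""
    t = _check_nonneg(t)
    bc = p.b ** p.c
    tc = t ** p.c
    return (p.m0 * bc + p.m_max * tc) / (bc + tc)


def gmm_derivative(p: GeneralizedMMParameters, t):
    """Instantaneous diameter-increase rate of the generalized MM curve."""
    t = _check_nonneg(t)
    bc = p.b ** p.c
    tc = np.where(t > 0, t ** p.c, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (p.m_max - p.m0) * bc * p.c * tc / np.maximum(t, 1e-300) / (bc + tc) ** 2
    return np.where(t > 0, out, 0.0)


def _reduced_chi2(obs, fit, weights, n_params, floor=0.5):
    f = np.maximum(np.abs(fit), floor)
    df = max(len(obs) - n_params, 1)
    return float(np.sum(weights * (obs - fit) ** 2 / f) / df)


class MichaelisMentenGrowth(RegressorMixin, BaseEstimator):
    """Michaelis–Menten regression of size on time since birth.

    Parameters
    ----------
    n_restarts : int, default 5
        Multistart count for the nonlinear least squares.
    random_state : int, default 0
        Seed for the start-value jitter.

    Attributes
    ----------
    m_max_ : float
        Fitted asymptote.
    b_ : float
        Fitted half-saturation time (days).
    reduced_chi2_ : float
        Goodness-of-fit statistic of the training data.
    """

    def __init__(self, n_restarts=5, random_state=0):
        self.n_restarts = n_restarts
        self.random_state = random_state

    @staticmethod
    def _curve(t, m_max, b):
        return m_max * t / (b + t)

    def fit(self, X, y, sample_weight=None):
        t = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if len(t) < 3:
            raise GrowthFitError("need at least 3 points for the MM fit")
        w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float)
        rng = np.random.default_rng(self.random_state)
        ymax = y.max()
        best = None
        for i in range(self.n_restarts):
            p0 = np.array([ymax * 1.3, max(np.median(t), 1.0)])
            if i:
                p0 *= rng.uniform(0.5, 2.0, size=2)
            try:
                popt, _ = optimize.curve_fit(
                    self._curve, t, y, p0=p0, sigma=1.0 / np.sqrt(w),
                    absolute_sigma=False, maxfev=20000,
                    bounds=([1e-9, 1e-9], [np.inf, np.inf]),
                )
            except (RuntimeError, ValueError):
                continue
            score = _reduced_chi2(y, self._curve(t, *popt), w, 2)
            if best is None or score < best[0]:
                best = (score, popt)
        if best is None:
            raise GrowthFitError("Michaelis-Menten fit did not converge")
        self.reduced_chi2_, (self.m_max_, self.b_) = best[0], best[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "m_max_")
        return self._curve(np.asarray(X, dtype=float).ravel(), self.m_max_, self.b_)

    @property
    def parameters_(self) -> MMParameters:
        check_is_fitted(self, "m_max_")
        return MMParameters(float(self.m_max_), float(self.b_))


class GeneralizedMichaelisMentenGrowth(RegressorMixin, BaseEstimator):
    """Generalized (sigmoid) Michaelis–Menten regression for diameters.

    The nepiontic diameter ``m0`` is fitted together with the asymptote,
    midpoint and shape exponent; bounds keep ``0 < m0 < m_max`` and
    ``c > 1``.

    Attributes
    ----------
    m0_, m_max_, b_, c_ : float
    reduced_chi2_ : float
    """

    def __init__(self, n_restarts=8, random_state=0):
        self.n_restarts = n_restarts
        self.random_state = random_state

    @staticmethod
    def _curve(t, m0, m_max, b, c):
        bc = b ** c
        tc = t ** c
        return (m0 * bc + m_max * tc) / (bc + tc)

    def fit(self, X, y, sample_weight=None):
        t = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if len(t) < 5:
            raise GrowthFitError("need at least 5 points for the generalized MM fit")
        w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float)
        rng = np.random.default_rng(self.random_state)
        ymin, ymax = max(y.min(), 1e-6), y.max()
        lo = [1e-9, ymin, 1e-3, 1.0 + 1e-6]
        hi = [ymax, ymax * 20, t.max() * 20, 20.0]
        best = None
        for i in range(self.n_restarts):
            p0 = np.array([ymin, ymax * 1.5, np.median(t), 1.5])
            if i:
                p0 = p0 * rng.uniform(0.5, 2.0, size=4)
            p0 = np.clip(p0, np.array(lo) * 1.01 + 1e-9, np.array(hi) * 0.99)
            try:
                popt, _ = optimize.curve_fit(
                    self._curve, t, y, p0=p0, sigma=1.0 / np.sqrt(w),
                    maxfev=40000, bounds=(lo, hi),
                )
            except (RuntimeError, ValueError):
                continue
            score = _reduced_chi2(y, self._curve(t, *popt), w, 4)
            if best is None or score < best[0]:
                best = (score, popt)
        if best is None:
            raise GrowthFitError("generalized Michaelis-Menten fit did not converge")
        self.reduced_chi2_ = best[0]
        self.m0_, self.m_max_, self.b_, self.c_ = best[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "m_max_")
        return self._curve(np.asarray(X, dtype=float).ravel(),
                           self.m0_, self.m_max_, self.b_, self.c_)

    @property
    def parameters_(self) -> GeneralizedMMParameters:
        check_is_fitted(self, "m_max_")
        return GeneralizedMMParameters(
            float(self.m0_), float(self.m_max_), float(self.b_), float(self.c_)
        )


def fit_growth(
    t: Sequence[float],
    m: Sequence[float],
    kind: str,
    sample_weight: Optional[Sequence[float]] = None,
    rng_seed: int = 0,
):
    """Weighted least-squares fit of one growth curve.

    ``kind`` is ``"cbr"`` (chamber-building rate, MM) or ``"dir"``
    (diameter-increase rate, generalized MM).  Returns the parameter
    dataclass and the reduced chi-square of the fit.
    """
    if kind == "cbr":
        est = MichaelisMentenGrowth(random_state=rng_seed)
    elif kind == "dir":
        est = GeneralizedMichaelisMentenGrowth(random_state=rng_seed)
    else:
        raise ValueError("kind must be 'cbr' or 'dir'")
    est.fit(np.asarray(t), np.asarray(m), sample_weight=sample_weight)
    return est.parameters_, est.reduced_chi2_


def _candidate_onsets(grid: tuple[int, int, int]):
    lo, hi, step = grid
    return list(range(lo, hi + 1, step))


def onset_search(
    traj: MaximumTrajectory,
    kind: str,
    pseudo_values: tuple[float, float] = (2.0, 3.0),
    onset_grid: tuple[int, int, int] = (10, 70, 5),
    pseudo_weight: float = 2.0,
    fixed_onset: Optional[int] = None,
    rng_seed: int = 0,
) -> GrowthFit:
    """Fit a growth curve with a grid search over the onset length.

    For each candidate onset ``L`` the trajectory's day axis is shifted so
    day 0 is the (unobserved) birth, ``first appearance - L`` days before
    the first component; two pseudo-observations representing the embryonic
    sizes are prepended at days 1 and L/2 with weight ``pseudo_weight``.
    Candidates run over the coarse grid and the best (smallest reduced
    chi-square) is refined day-wise within ±(step) days.  For the diameter
    fit pass ``fixed_onset`` (the chamber fit's onset); only that single
    candidate is evaluated.
    """
    if len(traj.t_days) < 4:
        raise GrowthFitError("need at least 4 trajectory points for the onset search")

    def _fit_at(L: int):
        t = np.concatenate([[1.0, L / 2.0], traj.t_days + L])
        y = np.concatenate([list(pseudo_values), traj.values])
        w = np.concatenate([[pseudo_weight, pseudo_weight], np.ones(len(traj.values))])
        params, score = fit_growth(t, y, kind, sample_weight=w, rng_seed=rng_seed)
        return score, params

    if fixed_onset is not None:
        candidates = [int(fixed_onset)]
    else:
        candidates = _candidate_onsets(onset_grid)
    results: dict[int, tuple[float, object]] = {}
    for L in candidates:
        try:
            results[L] = _fit_at(L)
        except GrowthFitError:
            continue
    if not results:
        raise GrowthFitError("no converged fit on any onset candidate")
    best_L = min(results, key=lambda L: results[L][0])

    if fixed_onset is None:
        step = onset_grid[2]
        lo = max(onset_grid[0], best_L - step)
        hi = min(onset_grid[1], best_L + step)
        for L in range(lo, hi + 1):
            if L not in results:
                try:
                    results[L] = _fit_at(L)
                except GrowthFitError:
                    continue
        best_L = min(results, key=lambda L: results[L][0])

    score, params = results[best_L]
    return GrowthFit(
        parameters=params, onset_days=int(best_L),
        trajectory_kind=traj.kind, fit_quality=score,
        generation_id=traj.generation_id,
        character="noc" if kind == "cbr" else "td",
        first_date=traj.first_date,
    )


def growth_table(fit: GrowthFit, days: Sequence[int]) -> list[dict]:
    """Tabulate the fitted curve: size and per-day rate at selected days.

    The size is the fitted curve rounded to the nearest integer; the
    per-day rate at day t is ``value(t) - value(t-1)`` reported to one
    decimal, the discrete analogue of the continuously decreasing
    chamber-building rate.
    """
    rows = []
    for day in days:
        value = float(fit.eval(float(day)))
        prev = float(fit.eval(float(day) - 1.0)) if day >= 1 else 0.0
        rows.append({
            "day": int(day),
            "value": int(round(value)),
            "per_day_rate": round(value - prev, 1),
        })
    return rows
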
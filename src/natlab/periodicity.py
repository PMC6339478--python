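"""Periodicity of reproduction: Lomb periodogram and sinusoid sums.

Birthdate histograms are unevenly spaced time series (month midpoints at
irregular day offsets), so spectral structure is scanned with the classical
Lomb normalized periodogram.  Two complementary period sets are provided:
a greedy least-squares scan over a Nyquist-bounded frequency grid, and the
annual harmonic series (365, 365/2, 365/3, ... days).  A sum of sinusoids
with fixed periods is then fitted by linear least squares to quantify the
amplitude of each reproductive oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import lombscargle
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "Periodogram",
    "SinusoidComponent",
    "SinusoidSumFit",
    "lomb_periodogram",
    "harmonic_periods",
    "nyquist_scan",
    "fit_sinusoid_sum",
    "SinusoidSumRegressor",
]


@dataclass
class Periodogram:
    """Normalized Lomb power over a period grid (days)."""

    periods: np.ndarray
    powers: np.ndarray
    false_alarm: np.ndarray     # per-peak false-alarm probability
    significance_level: float = 0.05

    def significant_periods(self, n: int = 3) -> list[float]:
        """Top local maxima with false-alarm below the threshold.

        Peaks are returned by decreasing power; nearby grid points of one
        peak are suppressed so each returned period is a distinct maximum.
        """
        pw = self.powers
        is_peak = np.zeros(len(pw), dtype=bool)
        for i in range(len(pw)):
            left = pw[i - 1] if i > 0 else -np.inf
            right = pw[i + 1] if i < len(pw) - 1 else -np.inf
            is_peak[i] = pw[i] >= left and pw[i] >= right
        idx = [i for i in np.argsort(pw)[::-1]
               if is_peak[i] and self.false_alarm[i] < self.significance_level]
        out: list[float] = []
        for i in idx:
            p = float(self.periods[i])
            if all(abs(p - q) / q > 0.10 for q in out):
                out.append(p)
            if len(out) >= n:
                break
        return out


@dataclass(frozen=True)
class SinusoidComponent:
    """One reproductive oscillation: period (days), amplitude, phase."""

    period: float
    amplitude: float
    phase: float  # radians in [0, 2*pi)

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")


@dataclass
class SinusoidSumFit:
    """Least-squares sum of sinusoids with fixed periods plus an offset."""

    components: list[SinusoidComponent]
    offset: float
    rss: float
    source: str = "lomb"  # which period-selection route produced the periods

    def eval(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = np.full_like(t, self.offset, dtype=float)
        for comp in self.components:
            y += comp.amplitude * np.sin(2 * np.pi * t / comp.period + comp.phase)
        return y


def _validate_series(t, y):
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) != len(y):
        raise ValueError("time and density vectors differ in length")
    if len(t) < 8:
        raise ValueError("need at least 8 points")
    if np.ptp(t) == 0:
        raise ValueError("all observation times are equal")
    order = np.argsort(t)
    return t[order], y[order]


def lomb_periodogram(
    t: Sequence[float],
    y: Sequence[float],
    oversample: int = 8,
    significance_level: float = 0.05,
) -> Periodogram:
    """Classical Lomb normalized periodogram of an uneven series.

    The period grid runs from twice the median sampling interval (the
    pseudo-Nyquist limit) to the series span, oversampled by ``oversample``
    relative to the natural frequency resolution 1/span.  Powers are
    normalized by the series variance; peak false-alarm probabilities use
    the standard exponential approximation
    ``1 - (1 - exp(-z))**M`` with M independent frequencies.
    """
    t, y = _validate_series(t, y)
    yc = y - y.mean()
    var = yc.var(ddof=1)
    span = float(np.ptp(t))
    dt_med = float(np.median(np.diff(t)))
    p_min, p_max = 2.0 * dt_med, span
    n_freq = max(int(oversample * span / p_min), 16)
    freqs = np.linspace(1.0 / p_max, 1.0 / p_min, n_freq)
    omega = 2 * np.pi * freqs
    if var == 0:
        powers = np.zeros(n_freq)
    else:
        powers = lombscargle(t, yc, omega) / var
    m_indep = max(len(t) // 2, 1)
    fap = 1.0 - (1.0 - np.exp(-np.clip(powers, 0, 700))) ** m_indep
    periods = 1.0 / freqs
    order = np.argsort(periods)
    return Periodogram(periods[order], powers[order], fap[order], significance_level)


def harmonic_periods(k: int, fundamental: float = 365.0) -> list[float]:
    """Annual harmonic series ``{365/1, ..., 365/k}`` days, 1-decimal."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return [round(fundamental / i, 1) for i in range(1, k + 1)]


def _design(t: np.ndarray, periods: Sequence[float]) -> np.ndarray:
    cols = [np.ones_like(t)]
    for p in periods:
        w = 2 * np.pi / p
        cols.append(np.sin(w * t))
        cols.append(np.cos(w * t))
    return np.column_stack(cols)


def nyquist_scan(
    t: Sequence[float],
    y: Sequence[float],
    n_periods: int = 3,
    oversample: int = 8,
) -> list[float]:
    """Greedy sinusoid period scan bounded by the pseudo-Nyquist frequency.

    Repeatedly fits a single sinusoid (plus offset) over a frequency grid
    whose upper bound is the Nyquist frequency for the median sampling
    interval, keeps the period explaining the most variance, subtracts the
    fitted sinusoid and recurses on the residual.  Returns up to
    ``n_periods`` periods, by order of extraction.
    """
    t, y = _validate_series(t, y)
    span = float(np.ptp(t))
    dt_med = float(np.median(np.diff(t)))
    p_min = 2.0 * dt_med
    n_freq = max(int(oversample * span / p_min), 16)
    freqs = np.linspace(1.0 / span, 1.0 / p_min, n_freq)
    resid = y.astype(float).copy()
    found: list[float] = []
    for _ in range(n_periods):
        best = None
        base_rss = float(np.sum((resid - resid.mean()) ** 2))
        if base_rss == 0:
            break
        for f in freqs:
            X = _design(t, [1.0 / f])
            beta, rss, *_ = np.linalg.lstsq(X, resid, rcond=None)
            r = float(rss[0]) if len(rss) else float(np.sum((resid - X @ beta) ** 2))
            if best is None or r < best[0]:
                best = (r, f, beta, X)
        r, f, beta, X = best
        found.append(1.0 / f)
        resid = resid - X @ beta
    return found


class SinusoidSumRegressor(RegressorMixin, BaseEstimator):
    """Linear least-squares fit of a sum of sinusoids with fixed periods.

    For each period the model contributes a sine/cosine pair; amplitudes
    are ``sqrt(a^2 + b^2)`` and phases ``atan2(b, a)``.  Duplicate periods
    make the design collinear and raise ``ValueError``.

    Attributes
    ----------
    amplitudes_, phases_ : ndarray, one entry per period
    offset_ : float
    rss_ : float
    """

    def __init__(self, periods: Sequence[float] = ()):
        self.periods = periods

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        periods = list(self.periods)
        if len(periods) != len(set(periods)):
            raise ValueError("duplicate periods make the design collinear")
        if not periods:
            raise ValueError("need at least one period")
        D = _design(t, periods)
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError("collinear sinusoid design (periods too close)")
        beta, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
        self.offset_ = float(beta[0])
        amps, phases = [], []
        for i in range(len(periods)):
            a, b = beta[1 + 2 * i], beta[2 + 2 * i]
            amps.append(float(np.hypot(a, b)))
            phases.append(float(np.arctan2(b, a) % (2 * np.pi)))
        self.amplitudes_ = np.array(amps)
        self.phases_ = np.array(phases)
        self.rss_ = float(np.sum((y - D @ beta) ** 2))
        return self

    def predict(self, X):
        check_is_fitted(self, "offset_")
        t = np.asarray(X, dtype=float).ravel()
        y = np.full_like(t, self.offset_, dtype=float)
        for p, a, ph in zip(self.periods, self.amplitudes_, self.phases_):
            y += a * np.sin(2 * np.pi * t / p + ph)
        return y


def fit_sinusoid_sum(
    t: Sequence[float],
    y: Sequence[float],
    periods: Sequence[float],
    source: str = "lomb",
) -> SinusoidSumFit:
    """Fit a sum of up to three sinusoids with the given fixed periods."""
    reg = SinusoidSumRegressor(periods=list(periods)).fit(t, y)
    comps = [
        SinusoidComponent(float(p), float(a), float(ph))
        for p, a, ph in zip(reg.periods, reg.amplitudes_, reg.phases_)
    ]
    comps.sort(key=lambda c: c.period, reverse=True)
    return SinusoidSumFit(comps, reg.offset_, reg.rss_, source=source)
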
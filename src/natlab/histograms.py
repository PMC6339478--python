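"""Size-frequency histograms and their decomposition into normal cohorts.

Monthly samples of a growing population mix several overlapping cohorts
("generations").  Chamber numbers are binned as natural numbers; test
diameters are binned on the natural-log scale, reflecting the logarithmic
test growth.  Each monthly histogram is first screened with a chi-square
goodness-of-fit test against a single normal distribution; histograms that
reject normality are decomposed into up to three scaled Gaussian components
by nonlinear least squares on the bin counts.

The decomposer is exposed both as a scikit-learn style estimator
(:class:`GaussianComponentMixture`, which bins raw values internally) and as
the function :func:`decompose` operating on a pre-built histogram.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import SampleSet

__all__ = [
    "HistogramSpec",
    "NormalComponent",
    "DecompositionResult",
    "build_histogram",
    "test_normality",
    "decompose",
    "GaussianComponentMixture",
    "InsufficientDataError",
    "DecompositionError",
]


class InsufficientDataError(ValueError):
    """Too few specimens or usable bins for the requested operation."""


class DecompositionError(RuntimeError):
    """No component model converged on the histogram."""


@dataclass
class HistogramSpec:
    """A fixed-interval frequency distribution of one character.

    ``bin_edges`` are strictly increasing and equally spaced; the same edges
    are used for every month of one analysis so that frequency diagrams are
    directly comparable.  For test diameters the edges live on the ln-µm
    scale.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    character: str  # "noc" or "lntd"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        widths = np.diff(self.bin_edges)
        if len(widths) < 1 or np.any(widths <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if not np.allclose(widths, widths[0]):
            raise ValueError("bins must have equal widths")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class NormalComponent:
    """One normal cohort of a decomposed monthly histogram.

    ``density`` is the component's peak bin count (the amplitude of the
    scaled Gaussian on the histogram), the convention used when such
    component tables are published.  ``weight`` is the implied number of
    specimens in the component, ``density * sd * sqrt(2*pi) / bin_width``.
    For diameter components, ``mean``/``sd`` are back-transformed to µm
    (``sd`` via the delta method, ln-scale sd times the µm mean).
    """

    density: float
    mean: float
    sd: float
    weight: Optional[float] = None

    @property
    def cv(self) -> float:
        return self.sd / self.mean


@dataclass
class DecompositionResult:
    """Components of one monthly sample, sorted by mean descending."""

    sampling_date: _dt.date
    components: list[NormalComponent]
    fit_statistic: float  # reduced chi-square of the component model
    normality_p: Optional[float] = None
    character: str = "noc"


def build_histogram(
    sample: SampleSet | np.ndarray,
    character: str,
    bin_edges: np.ndarray,
) -> HistogramSpec:
    """Bin one monthly sample on a fixed grid.

    Diameters are ln-transformed before binning; chamber numbers are used
    as-is.  Values outside ``[first, last)`` edge raise a ``ValueError``
    naming the offending value, since every month must share the same axis.
    """
    if isinstance(sample, SampleSet):
        values = sample.values("td" if character in ("td", "lntd") else "noc")
    else:
        values = np.asarray(sample, dtype=float)
    if character in ("td", "lntd"):
        values = np.log(values)
        character = "lntd"
    edges = np.asarray(bin_edges, dtype=float)
    if len(values) and (values.min() < edges[0] or values.max() >= edges[-1]):
        bad = values[(values < edges[0]) | (values >= edges[-1])][0]
        raise ValueError(f"value {bad} outside histogram range [{edges[0]}, {edges[-1]})")
    counts, _ = np.histogram(values, bins=edges)
    return HistogramSpec(edges, counts, character)


def _pool_bins(observed: np.ndarray, expected: np.ndarray, min_expected: float = 1.0):
    """Merge adjacent bins until every expected count reaches the minimum."""
    obs, exp = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= min_expected:
            obs.append(o_acc)
            exp.append(e_acc)
            o_acc = e_acc = 0.0
    if e_acc > 0 and exp:
        obs[-1] += o_acc
        exp[-1] += e_acc
    return np.array(obs), np.array(exp)


def test_normality(hist: HistogramSpec) -> tuple[float, float]:
    """Pearson chi-square screen of a histogram against a single normal.

    Mean and standard deviation are estimated from the binned data; the
    expected counts are the normal probability mass per bin times the sample
    size.  Bins are pooled so every expected count is at least 1 and the
    statistic is referred to chi-square with ``bins - 3`` degrees of freedom
    (two estimated parameters).  Fewer than 4 usable bins raise
    :class:`InsufficientDataError`.
    """
    counts = hist.counts.astype(float)
    n = counts.sum()
    if n < 2 or (counts > 0).sum() < 2:
        raise InsufficientDataError("histogram has too little data for the normality screen")
    centers = hist.centers
    mean = float(np.average(centers, weights=counts))
    var = float(np.average((centers - mean) ** 2, weights=counts))
    sd = np.sqrt(var) if var > 0 else hist.bin_width / 2.0
    cdf = stats.norm.cdf(hist.bin_edges, loc=mean, scale=sd)
    expected = n * np.diff(cdf) / (cdf[-1] - cdf[0])
    obs, exp = _pool_bins(counts, expected)
    if len(obs) < 4:
        raise InsufficientDataError(
            f"only {len(obs)} pooled bins; at least 4 needed for the chi-square screen"
        )
    statistic = float(np.sum((obs - exp) ** 2 / exp))
    df = max(len(obs) - 3, 1)
    p = float(stats.chi2.sf(statistic, df))
    return statistic, p


def _gaussian_sum(x: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Sum of k scaled Gaussians; params = (a, mu, sigma) * k."""
    y = np.zeros_like(x, dtype=float)
    for a, mu, sigma in params.reshape(-1, 3):
        y += a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)
    return y


def _reduced_chi2(observed, fitted, n_params, floor=0.5):
    """Goodness-of-fit statistic sum((o-f)^2 / f) / (n - k).

    Only informative bins (observed count, or fitted count of at least
    half a specimen) enter, so long empty tails neither inflate the
    degrees of freedom nor blow up the division.
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    mask = (observed > 0) | (fitted >= floor)
    f = np.maximum(np.abs(fitted[mask]), floor)
    df = max(int(mask.sum()) - n_params, 1)
    return float(np.sum((observed[mask] - fitted[mask]) ** 2 / f) / df)


def _fit_k_components(centers, counts, width, k, rng, n_restarts=10):
    """Least-squares fit of k scaled Gaussians to bin counts, multistart."""
    total = counts.sum()
    span = centers[-1] - centers[0] if len(centers) > 1 else width
    # seed means at the k highest-count bins, spread-adjusted per restart
    order = np.argsort(counts)[::-1]
    base_means = centers[np.sort(order[:k])]
    lo = np.tile([0.0, centers[0] - span / 4, width / 4], k)
    hi = np.tile([max(counts.max() * 3.0, 1.0), centers[-1] + span / 4, span], k)
    best = None
    for restart in range(n_restarts):
        means = base_means + rng.normal(scale=0.1 * span / max(k, 1), size=k) * (restart > 0)
        sigmas = np.full(k, max(span / (2.5 * k), width / 2))
        amps = np.full(k, max(counts.max() * 0.8, 1.0))
        p0 = np.clip(np.column_stack([amps, means, sigmas]).ravel(), lo + 1e-9, hi - 1e-9)
        try:
            popt, _ = optimize.curve_fit(
                lambda x, *p: _gaussian_sum(x, np.asarray(p)),
                centers, counts, p0=p0, bounds=(lo, hi), maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        fitted = _gaussian_sum(centers, popt)
        score = _reduced_chi2(counts, fitted, 3 * k)
        if best is None or score < best[0]:
            best = (score, popt)
    return best


def _components_from_params(params, width, character):
    comps = []
    for a, mu, sigma in params.reshape(-1, 3):
        weight = a * sigma * np.sqrt(2 * np.pi) / width
        if character == "lntd":
            mean_um = float(np.exp(mu))
            comps.append(NormalComponent(float(a), mean_um, float(sigma * mean_um), float(weight)))
        else:
            comps.append(NormalComponent(float(a), float(mu), float(sigma), float(weight)))
    comps.sort(key=lambda c: c.mean, reverse=True)
    return comps


def decompose(
    hist: HistogramSpec,
    k_max: int = 3,
    rng_seed: int = 0,
    improvement: float = 0.2,
    sampling_date: Optional[_dt.date] = None,
) -> DecompositionResult:
    """Decompose a histogram into up to ``k_max`` normal components.

    Components are fitted for k = 1..k_max by nonlinear least squares on the
    bin counts (multistart, seeded).  The returned k is the smallest one
    whose reduced chi-square is not improved by more than ``improvement``
    (relative) by k+1 — ties break toward fewer components, and a model
    already fitting within noise (reduced chi-square at most 1) is never
    expanded.  Degenerate solutions — a component holding less than one
    expected specimen, narrower than half a bin, or two means closer than
    one bin width — fall back to the smaller model.
    """
    rng = np.random.default_rng(rng_seed)
    centers, counts = hist.centers, hist.counts.astype(float)
    if counts.sum() == 0:
        raise InsufficientDataError("empty histogram")
    width = hist.bin_width
    fits: dict[int, tuple[float, np.ndarray]] = {}
    for k in range(1, k_max + 1):
        res = _fit_k_components(centers, counts, width, k, rng)
        if res is not None:
            fits[k] = res
    if not fits:
        raise DecompositionError("no component model converged")

    chosen = min(fits)
    for k in sorted(fits):
        nxt = k + 1
        if nxt in fits and fits[k][0] > 1.0 and fits[nxt][0] < (1.0 - improvement) * fits[k][0]:
            chosen = nxt
        else:
            chosen = k
            break

    score, params = fits[chosen]
    # degenerate-component guard: drop and refit with fewer components
    while chosen > 1:
        trip = params.reshape(-1, 3)
        area = trip[:, 0] * trip[:, 2] * np.sqrt(2 * np.pi) / width
        separated = np.all(np.diff(np.sort(trip[:, 1])) >= width)
        ok = (area >= 1.0) & (trip[:, 2] >= width / 2)
        if ok.all() and separated:
            break
        chosen -= 1
        if chosen in fits:
            score, params = fits[chosen]
        else:
            res = _fit_k_components(centers, counts, width, chosen, rng)
            if res is None:
                raise DecompositionError("refit after dropping degenerate component failed")
            score, params = res
    comps = _components_from_params(params, width, hist.character)
    return DecompositionResult(
        sampling_date=sampling_date,
        components=comps,
        fit_statistic=score,
        character="td" if hist.character == "lntd" else "noc",
    )


class GaussianComponentMixture(BaseEstimator):
    """Histogram decomposition as a scikit-learn style estimator.

    Bins raw 1-D values on an equal-width grid, screens for normality, and
    fits a sum of up to ``k_max`` scaled Gaussians to the bin counts.

    Parameters
    ----------
    k_max : int, default 3
        Maximum number of normal components.
    bin_width : float, default 5.0
        Histogram interval on the (possibly transformed) axis.
    log_transform : bool, default False
        Take the natural log of the values before binning (diameters).
    improvement : float, default 0.2
        Minimum relative reduced-chi-square gain required to accept an
        additional component.
    random_state : int, default 0
        Seed for the multistart initialisation.

    Attributes
    ----------
    components_ : list of :class:`NormalComponent`
    n_components_ : int
    reduced_chi2_ : float
    normality_p_ : float or None
        p-value of the single-normal screen (None when the screen could not
        be run).
    """

    def __init__(self, k_max=3, bin_width=5.0, log_transform=False,
                 improvement=0.2, random_state=0):
        self.k_max = k_max
        self.bin_width = bin_width
        self.log_transform = log_transform
        self.improvement = improvement
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float).ravel()
        if X.size < 2:
            raise InsufficientDataError("need at least 2 values")
        vals = np.log(X) if self.log_transform else X
        lo = np.floor(vals.min() / self.bin_width) * self.bin_width
        hi = np.ceil((vals.max() + 1e-9) / self.bin_width) * self.bin_width
        if hi <= vals.max():
            hi += self.bin_width
        edges = np.arange(lo, hi + self.bin_width / 2, self.bin_width)
        hist = HistogramSpec(edges, np.histogram(vals, bins=edges)[0],
                             "lntd" if self.log_transform else "noc")
        try:
            _, self.normality_p_ = test_normality(hist)
        except InsufficientDataError:
            self.normality_p_ = None
        result = decompose(hist, k_max=self.k_max, rng_seed=self.random_state,
                           improvement=self.improvement)
        self.components_ = result.components
        self.n_components_ = len(result.components)
        self.reduced_chi2_ = result.fit_statistic
        self.histogram_ = hist
        return self

    def predict(self, X):
        """Fitted count curve at given axis positions (original scale)."""
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float).ravel()
        x = np.log(X) if self.log_transform else X
        y = np.zeros_like(x)
        for c in self.components_:
            if self.log_transform:
                mu, sigma = np.log(c.mean), c.sd / c.mean
            else:
                mu, sigma = c.mean, c.sd
            y += c.density * np.exp(-0.5 * ((x - mu) / sigma) ** 2)
        return y
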
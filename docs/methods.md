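# Methods

This note documents the models, the numerical choices and the limits of
what the test suite demonstrates.  Notation: NoC is a specimen's chamber
number (including the two-chambered nepiont), TD its maximal test
diameter in µm, t time in days since an individual's (or cohort's) birth.

## Size-frequency decomposition

Chamber numbers are binned as natural numbers (default interval 5
chambers); diameters are binned on the natural-log scale (default
interval 0.15), reflecting multiplicative test growth.  Bin widths are
not dictated by the method; the defaults match the granularity at which
2–4 overlapping cohorts remain visually separable in populations of this
size (tens of specimens per month) and are configurable.

The single-normal screen is a Pearson chi-square test with mean and
standard deviation estimated from the binned data, adjacent bins pooled
until every expected count reaches 1, and `bins − 3` degrees of freedom.
Samples with fewer than 10 specimens or fewer than 4 pooled bins are
excluded.

Decomposition fits a sum of k scaled Gaussians to the bin counts by
bounded nonlinear least squares (k = 1..3).  Points of detail:

* **Component parameterisation.**  The fitted amplitude is the
  component's peak bin count — the convention in which such component
  tables are usually printed.  The implied specimen count of a component
  is `amplitude · sd · √(2π) / bin_width`; the counts of all components
  sum to the sample size (the suite checks within 15%).  Diameter
  components are fitted on the ln scale and reported back-transformed:
  the µm mean is `exp(ln-mean)` and the µm sd the delta-method value
  `ln-sd · µm-mean`.
* **Model order.**  k is grown from 1 and k+1 accepted only when the
  k-component model shows lack of fit (reduced chi-square > 1) *and*
  k+1 improves the reduced chi-square by more than 20%.  The statistic
  is evaluated on informative bins only (observed count, or fitted count
  ≥ 0.5), so empty histogram tails neither dilute the degrees of freedom
  nor dominate the division.  Without the lack-of-fit gate the 20% rule
  alone splits unimodal noise in well over 10% of replicates; with it,
  single-normal synthetic data select k = 1 in ≥ 95% of seeds while
  two-component mixtures at n = 200 are always resolved.
* **Degeneracy.**  A solution with a component holding less than one
  expected specimen, narrower than half a bin, or with two means closer
  than one bin width falls back to the smaller model.
* **Determinism.**  Multistart initialisation (means seeded at the
  highest-count bins, 10 seeded restarts) makes the fit a pure function
  of (histogram, seed).

## Generation tracking

Components are linked chronologically.  Within a month, components are
processed in descending mean order; each claims the open track whose last
mean is closest, subject to growth being non-negative within a 15%
relative slack (sampling noise).  Processing the largest component first
makes interleaved uniformly-growing cohorts link exactly; ambiguous
claims (two admissible tracks at comparable gaps) are logged.  Unmatched
components open new generations; a track that received nothing although
its last mean exceeds everything observed that month is closed.  Real
campaigns contain months where this generic rule and expert reading
disagree (two in the shipped study tables); a manual override map
(date, component index → generation) is honoured for such curated
analyses, and the shipped tables carry the original study's generation
identification as overrides.

The pooled CV of a track is the arithmetic mean of its components'
`sd/mean`, pooled per (generation, character, depth); truncated edge
generations do not contribute to other generations' pools.  The monthly
maximum is `m_t = x̄_t (1 + 3 CV)`, i.e. a normalized standard deviation
`s* = CV · x̄_t` in the character's units.  (The variant `s* = CV / x̄`,
dimensionally inconsistent but retained as a config switch, exists for
sensitivity checks.)  Mean-based trajectories are kept alongside maxima;
both are fitted.

## Growth curves and the onset search

CBR: `m(t) = m_max · t / (b + t)` — Michaelis–Menten through the origin;
`m_max` is the asymptotic chamber number, `b` the day at half-asymptote,
`m_max/b` the initial chamber-building rate.  DIR:
`m(t) = (m_0 b^c + m_max t^c) / (b^c + t^c)` — a generalized sigmoid
Michaelis–Menten starting at the nepiontic diameter `m_0` with shape
exponent `c > 1`, reflecting slow initial and prolonged late diameter
growth.

A cohort first appears in a histogram some weeks after the reproduction
pulse.  This onset L is found by grid search: candidates 10–70 days in
5-day steps, then day-wise refinement within ±5 days of the best
candidate.  For each candidate the trajectory's day axis is shifted so
that day 0 is birth, and two pseudo-observations anchor the embryonic
stage at days 1 and L/2: chamber numbers 2 and 3 for the CBR (embryos
build their first chambers within days; the exact days are not
observable, so the placement is configurable), and the measured mean
diameters at chamber numbers 2 and 3 for the DIR.  Pseudo-observations
carry weight 2 in the least squares to anchor the origin region; all
trajectory points carry weight 1.  Fits are scored by the reduced
chi-square `Σ w (obs − fit)² / fit / (n − k)`; the DIR reuses the CBR's
best onset rather than searching independently.

Two identifiability caveats, visible in both the shipped study tables and
synthetic data:

* The onset is weakly identified — the reduced chi-square varies by well
  under 10% across the 10–70 day grid while the implied day-1 rate can
  vary several-fold.  Headline initial rates should therefore be read
  together with the onset that produced them.
* The DIR asymptote sits on a flat `m_max`–`b` ridge whenever the
  observed trajectory has not clearly saturated; the fitted asymptote is
  then an extrapolation and can differ substantially between optimizers
  and weighting schemes even at nearly equal fit quality.  The package
  reports the global weighted-least-squares optimum under multistart.

## Birthdate inversion, longevity, periodicity

Inversion uses the exact algebraic inverses of the two curves, with the
parameters of the highest-asymptote completely-observed generation
(selectable).  Specimens at or beyond the fitted asymptote are excluded
with a logged count — clamping would fabricate unbounded ages.  Diameters
below `m_0` get age 0, flagged.  Birthdates are binned by civil calendar
month; weighting is 1 per specimen, or 1/sample-size when sampled
sediment amounts differ between months (the deeper-station case).
Longevity is the maximum birth-to-sampling difference in days.

The monthly densities, placed at month midpoints (an uneven day axis),
feed three period-selection routes: (i) the classical variance-normalized
Lomb periodogram on a frequency grid from 1/span to the pseudo-Nyquist
frequency for the median spacing (oversampling 8), with peak false-alarm
probabilities from the standard exponential approximation
`1 − (1 − e^(−z))^M`, threshold 0.05, M ≈ n/2 independent frequencies;
(ii) a greedy Nyquist-bounded scan — fit a single sinusoid plus offset
over the grid, keep the period explaining most variance, subtract and
repeat up to three times (the original description of this route is
terse; the greedy residual scan is this package's interpretation, chosen
because it reproduces near-periodogram periods with small shifts);
(iii) the annual harmonic series 365/k days, the only route that is
exactly repetitive across years.  Amplitudes and phases for fixed periods
come from linear least squares on sine/cosine pairs plus an offset.

## Synthetic populations

The simulator draws births from a seasonal intensity (baseline plus
sinusoids, non-negativity validated, nonhomogeneous-Poisson thinning),
grows each individual along the two curves with a shared lognormal
asymptote factor (CV 0.10 by default), removes individuals at a maximum
age, and samples on uneven monthly dates with a per-date specimen quota.
Observation noise: a ±1 chamber miscount with probability 0.10 and a
lognormal diameter factor with sd 0.05 — small, plausible measurement
errors, configurable.

Defaults mirror the study conditions: chamber curve (m_max 72.6, b 36 d)
as estimated for the shallow population; diameter curve (m_0 293.7 µm,
m_max 4500 µm, b 75 d, c 1.4), chosen so diameters at the observed
longevity reach the ~4000 µm the largest field specimens show; maximum
age 416 d; ~17 monthly samples over a 450-day span with ±10-day jitter.
Two scenarios set the seasonality: "20m" with a dominant late-July pulse
(roughly three times the winter intensity) and "50m" with balanced,
slightly winter-leaning pulses.

What the simulator does *not* emulate: depth-dependent test flattening,
a trimorphic life cycle (all individuals share one growth law), spatial
patchiness between dives, and taphonomic loss.  Passing recovery tests
therefore shows the estimators are consistent under the model's own
assumptions, not that field data satisfy them.

## Problem sizes and tolerances in the test suite

Stochastic calibrations use 20–50 seeded replicates with populations of
150–600 specimens — large enough that the checked rates (type-I error of
the normality screen ≤ 10%, model-order selection ≥ 90%, parameter
recovery within 5–10% in ≥ 80% of seeds, birth-pulse month within ±1
month) are stable, while the whole suite runs in a few minutes on one
core.  A sinusoidal intensity is nearly flat around its maximum, so
pulse-month recovery counts the peak month or a direct neighbour.
Algebraic identities (curve inversion) are asserted to 1e-6 relative or
better; property tests run derandomized.

## Known limitations

* Cross-character generation correspondence in the automatic pipeline is
  by generation id (tracks sorted by first appearance), which can
  misalign when the two characters yield different track counts; curated
  analyses should use overrides.
* The chi-square screen's power is modest for n < 20; such samples pass
  as "normal" easily and then contribute a single pooled component.
* Component uncertainty is not propagated into growth-curve or birthdate
  uncertainty; all downstream estimates are point estimates.
* The 50 m diameter components are not shipped (the printed source block
  duplicates the chamber values); 50 m diameter analyses require the raw
  per-specimen deposit.
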
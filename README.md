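# natlab

Population dynamics of larger benthic foraminifera (LBF) from repeated
field samples — the "natural laboratory" approach.  Given monthly samples
of a population in which every specimen's chamber number (NoC) and maximal
test diameter (TD, µm) have been measured, `natlab` estimates how fast the
species grows, when it reproduces, and how long it lives — without keeping
a single individual in culture.

The package targets micropalaeontologists and marine ecologists working
with species such as *Heterostegina depressa*, whose symbiont-bearing,
chambered tests record growth as a chamber count and a diameter.

## The method

1. **Cohort decomposition.**  Each monthly size-frequency histogram (NoC as
   natural numbers; TD on the natural-log scale) is screened with a
   chi-square goodness-of-fit test against a single normal distribution.
   Histograms that reject normality are decomposed into up to three normal
   components by nonlinear least squares — each component is one cohort
   ("generation") born in one reproduction pulse.
2. **Generation tracking.**  Components are linked month-to-month into
   generation tracks (greedy nearest-from-below matching with a
   sampling-noise slack, plus manual overrides for curated analyses).  Per
   track, the pooled coefficient of variation `CV` turns component means
   into monthly population maxima `m_t = x̄_t (1 + 3 CV)`.
3. **Growth curves.**  The chamber-building rate (CBR) follows a
   Michaelis–Menten curve through the origin, `m(t) = m_max t / (b + t)`;
   the diameter-increase rate (DIR) follows a generalized sigmoid form
   `m(t) = (m_0 b^c + m_max t^c) / (b^c + t^c)` starting at the nepiontic
   diameter `m_0`.  Because a cohort is only detected weeks after birth,
   the fit grid-searches this *onset* (10–70 days in 5-day steps, then
   day-wise), anchoring each candidate with embryonic pseudo-observations
   (chamber numbers 2 and 3; the measured mean diameters at those chamber
   counts).  The DIR reuses the CBR's onset.
4. **Birthdates and longevity.**  Inverting the fitted curves turns each
   specimen's size into an age: `age = NoC·b/(m_max − NoC)` for chambers,
   and the analogous closed form for diameters.  Birthdates accumulate
   into monthly histograms (optionally weighted by 1/sample-size) and the
   maximal age estimates longevity.
5. **Reproduction periodicity.**  The birthdate series (uneven month
   midpoints) is scanned with a classical Lomb periodogram, a greedy
   Nyquist-bounded frequency scan, and the annual harmonic series
   (365, 182.5, 121.7 days); sums of sinusoids with the selected periods
   quantify each oscillation's amplitude.

A forward simulator (`natlab.simulate`) generates populations with known
growth parameters, seasonal birth intensity, mortality and monthly uneven
sampling, so every stage is testable against ground truth.

## Worked example

The study tables shipped in `natlab.datasets` contain the published
monthly cohort components for *H. depressa* at Sesoko-Jima (20 m and 50 m
stations, May 2014 – July 2015).  Fitting the complete mid-study
generation at 20 m:

```python
from natlab.datasets import NEPIONT_DIAMETERS, published_generation_tracks
from natlab.growth import mm_eval, onset_search
from natlab.tracking import maximum_trajectory, pooled_cv

track = published_generation_tracks(20.0, "noc")[2]   # Generation 2
cv = pooled_cv(track)
fit = onset_search(maximum_trajectory(track), "cbr")
print(f"CV = {cv:.3f}")
print(f"onset = {fit.onset_days} d, m_max = {fit.parameters.m_max:.1f} chambers, "
      f"b = {fit.parameters.b:.1f} d")
print(f"day-1 rate = {mm_eval(fit.parameters, 1.0):.2f} chambers/day")
```

prints

```
CV = 0.104
onset = 22 d, m_max = 77.6 chambers, b = 40.9 d
day-1 rate = 1.85 chambers/day
```

i.e. the generation was already ~3 weeks old when first detected, builds
almost two chambers per day right after birth, and saturates towards ~78
chambers — reaching half of that within ~41 days of life.

For a full pipeline run from a specimen table (simulated here):

```bash
natlab simulate --scenario 20m --seed 3 --out sim.csv
natlab run-all sim.csv --seed 3 --outdir out/
```

which writes `screens.csv`, `components.csv`, `generations.csv`,
`growth_fits.csv`, `birthdates.csv`, `periodogram.csv` and a run log.

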
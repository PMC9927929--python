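# clincirc

Two-stage circadian rhythm detection for sparse clinical time series.

## The problem

Assessing whether a hospitalized patient's molecular clock is still running
means deciding, from a handful of blood samples (typically every 4 hours
over 24–48 hours), whether a clock-gene transcript oscillates with a
circadian (~24 h) period. Single-step methods struggle here: a cosinor fit
must estimate all four waveform parameters (mesor M, amplitude A, acrophase
φ, period τ) from as few as 7 points and is prone to overfitting, while the
Lomb-Scargle periodogram (L-SP) identifies the dominant harmonic but says
nothing about amplitude or phase — and over a single 24-h window it cannot
tell a monotone trend from a 24-h rhythm at all, because a straight line
projects its power onto the window's 24-h fundamental.

`clincirc` implements a sequential detector that combines the two methods
so each covers the other's blind spot, for the model

y(t) = M + A·cos(2π(t − φ)/τ) + ε(t)

1. **L-SP gate** — compute the Lomb-Scargle periodogram on the natural
   harmonic grid T/k and require the dominant period to lie in the
   circadian band (default 18–30 h).
2. **Loose period filter** — fit an unconstrained cosinor; reject series
   whose best-fitting period is excessively long or short (default outside
   15–40 h). This is the stage that removes trends the gate cannot see.
3. **Constrained characterization** — refit with τ constrained to the band
   and A capped at 2 sample SDs, then test the rhythm with the
   zero-amplitude F-test (α = 0.05). An accepted series is reported with
   its mesor, amplitude, relative amplitude A/M, acrophase and period.

Around the detector the package provides the standalone comparators (L-SP
frequency and p-value criteria, single-step cosinor), a seeded
sensitivity/specificity simulation benchmark, cohort-level statistics
(rhythmic-gene counts, χ² prevalence tests, covariate correlation, circular
acrophase summaries, Watson U², acrophase-on-event-time entrainment
regression), and wrapped-Gaussian circular density estimation of clinical
event times with bootstrap bands.

## Worked example

```python
import numpy as np
from clincirc import SampledSeries, clincirc_call, characterize, lsp_frequency_call

rng = np.random.default_rng(0)
t = np.arange(0.0, 48.1, 4.0)            # blood draws every 4 h for 48 h
expr = 9.1 + 2.6 * np.cos(2 * np.pi * (t - 7.5) / 24.0) + 0.8 * rng.standard_normal(t.size)
series = SampledSeries("patient-07", "PER3", t, expr)

call = clincirc_call(series)
print("circadian:", call.circadian)
print("dominant L-SP period:", call.periodogram.dominant_period, "h")
c = characterize(call)
print(f"mesor={c.mesor:.2f}  amplitude={c.amplitude:.2f}  "
      f"relative amplitude={c.relative_amplitude:.2f}")
print(f"acrophase={c.acrophase_h:.2f} h  period={c.period_h:.2f} h")
```

prints

```
circadian: True
dominant L-SP period: 24.0 h
mesor=8.95  amplitude=2.69  relative amplitude=0.30
acrophase=6.86 h  period=24.43 h
```

— the detector recovers the planted rhythm (true M = 9.1, A = 2.6,
φ = 7.5 h, τ = 24 h) to within the noise, and reports the phase as the
clock time of the fitted maximum. The same pipeline rejects what fools the
periodogram alone:

```python
trend = SampledSeries("patient-12", "CRP", t[:7], 4.0 + 0.9 * t[:7])
print(lsp_frequency_call(trend))            # True  (trend looks 24-h to L-SP)
print(clincirc_call(trend).circadian)       # False (rejected at: loose_period)
```

The same workflow is available from the shell:

```bash
clincirc fixtures --seed 1 --outdir fixtures          # synthetic cohort CSVs
clincirc detect --input fixtures/cohort_series.csv --out calls.csv
clincirc cohort --calls calls.csv --covariate fixtures/cohort_covariate.csv --out summary.csv
clincirc benchmark --detector clincirc --window 48 --noise 0.4 --nsims 5000 --seed 1 --out bench.csv
clincirc density --events fixtures/events.csv --nboot 1000 --seed 1 --out density.csv
```

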
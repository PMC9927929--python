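# Methods

## Data model

A `SampledSeries` is one analyte's measurements for one subject: times in
hours (strictly increasing, irregular spacing allowed), values in arbitrary
expression units, and a declared timescale (clock time on [0, 24), or hours
since an external event such as allograft reperfusion). Missing samples are
represented by absence of the row; both the periodogram and cosinor
regression operate natively on irregular grids, so the nominal designs
(7 points/24 h, 13 points/48 h at 4-h spacing) tolerate a dropped sample
without special handling. Fitting requires at least 5 samples and a span of
at least 20 h — below that a circadian period is not meaningfully
constrained by the data, and the code raises rather than returning a silent
negative. Expression values may optionally be log-transformed before
fitting (`ClinCircConfig.log_transform`, default off; whether upstream
pipelines log-transform varies, so this is exposed rather than assumed).

## Lomb-Scargle stage

The periodogram is evaluated on the natural harmonic grid T/k,
k = 1..⌊n/2⌋, with T the observation span: these are the only periods a
span-T record resolves, and on the sparsest design (24-h window) the grid
is {24, 12, 8} h. Powers use the standard normalization by total
mean-removed variance, so they lie in [0, 1] and a noiseless sinusoid
observed over an integer number of cycles scores ≈ 1 at its harmonic. The
circadian band default (18, 30) h places its lower edge midway between the
24-h and 12-h harmonics — the mean of the two periods resolvable from the
sparsest design — and the gate uses closed interval membership.

The peak's p-value is the exact single-frequency null
Pr(Z > z) = (1 − z)^((n−3)/2) combined across the M grid frequencies as
FAP = 1 − (1 − p₁)^M. On the natural grid the frequencies are
near-orthogonal, so this is nearly exact; because the few powers share
n − 1 total degrees of freedom they are negatively correlated, making the
bound mildly conservative (measured type-I rates 3.0% at n = 7 and 3.9% at
n = 13 for α = 0.05). This is the intended upper-bound semantics of
periodogram false-alarm probabilities; a value-permutation fallback
(`pvalue_method="permutation"`) is available when the Gaussian null is
suspect.

A deliberate property of the frequency criterion: a monotone trend over a
single 24-h window deposits most of its power on the 24-h fundamental, so
"dominant harmonic in band" calls every sloped line circadian (0%
specificity on lines). No detrending is applied before the periodogram —
that behavior is the motivation for the later pipeline stages, not an
artifact to suppress.

## Cosinor stage

For fixed τ the model is linear in {1, cos ωt, sin ωt} and solved exactly;
amplitude and acrophase come from the harmonic coefficients, with the
acrophase reported as the time of the fitted maximum, reduced mod τ, on the
series' declared timescale. The free-period fit profiles the linear
solution over τ: SSE(τ) is evaluated on a frequency grid with spacing
1/(5T) (the record's natural resolution, oversampled 5×) plus the natural
harmonics and 24 h as explicit candidates, and the best grid point is
polished by bounded scalar minimization (xatol 10⁻⁶ h).

**Anti-aliasing floor.** Periods below twice the median sampling interval
are excluded from the search. On a regular 4-h grid, τ = 4.8 h reproduces a
24-h rhythm exactly at the sample times, and τ just above 4 h interpolates
any slow trend; admitting such periods would make the fitted period
meaningless for sparse designs. With the floor, the unconstrained fit of a
straight line runs to the long-period boundary (a line is the limit of an
infinite-period sinusoid), which is exactly what the loose period filter
needs to reject.

The zero-amplitude test compares the 3-parameter harmonic model at the
fitted period against the mesor-only model: F on (2, n−3) df. Its type-I
rate on white noise at a prespecified period is nominal (measured ≈5% at
α = 0.05). Diagnostics: r² = 1 − SSE/SST; adjusted r² charges 4 parameters
for free-period fits and 3 for fixed-period fits; leverage distance is
max|yᵢ − ŷ(tᵢ)|, an overfitting indicator (a spike the sinusoid chases
shows up directly).

**The standalone cosinor comparator.** The single-step cosinor detector
(`cosinor_call`) defaults to the common field practice: fit with a free
period, call a rhythm when the fitted period lands in the circadian band
and the full 4-parameter sinusoid beats the mesor-only model in an F-test
on (3, n−4) df — the honest df count when the period is estimated rather
than assumed, and the reason this detector pays a large power penalty at
n = 7 (critical F(3,3) ≈ 9.3) but much less at n = 13. Period-bounded and
fixed-24 variants are available (`period_mode="bounded"` / `"fixed24"`);
both use the (2, n−3) zero-amplitude test. ClinCirc's own stage 3 keeps the
(2, n−3) test: its period is constrained to a 12-h-wide band by two prior
stages, so treating it as fixed is the appropriate convention, and this
asymmetry is what lets the sequential detector out-detect the single-step
comparator at the 24-h window while remaining more specific.

## The ClinCirc pipeline

Stage 1 gates on the dominant harmonic (band membership only — no
significance requirement; significance is settled at stage 3). Stage 2
rejects series whose unconstrained period falls outside (15, 40) h; the
bounds must strictly contain the band, and (15, 40) is wide enough not to
touch genuine circadian fits while rejecting the long-period fits that
trends produce. Stage 3 refits with τ ∈ [18, 30] and amplitude capped at
2 sample SDs — a pure sinusoid has A = √2·SD, so the cap only binds when
the fit chases an outlier — and requires the zero-amplitude test at
α = 0.05 (`require_significance` can disable this for exploratory use).
Each rejection records its stage (`lsp_gate`, `loose_period`,
`amplitude_test`), and the constrained fit is attached whenever it was
computed. The procedure is deterministic: identical input and configuration
reproduce identical calls.

## Simulation benchmark and its calibration

The benchmark emulates sparse clinical sampling: values every 4 h over a
24-h (7-point) or 48-h (13-point) window, inclusive of both endpoints.
Rhythmic truth is a cosine with per-realization nominals M₀ ~ U(5, 15),
A₀ ~ U(1, 5), φ₀ ~ U(0, 24), τ₀ = 24 h. "Noise at fraction f" (benchmark
condition f = 0.4) has two components, independently switchable:

- multiplicative parameter jitter: M, A, φ are multiplied by
  (1 + N(0, f²)); the period by (1 + N(0, (f/2)²)). The period runs at half
  the fraction because it is the most tightly regulated parameter of the
  transcription-translation feedback loop (temperature-compensated), while
  mesor, amplitude and phase absorb the full physiological and technical
  variation.
- additive observation noise on every sample: N(0, (0.65·f·|A|)²).

The two scale constants (period at f/2, observation noise at 0.65·f) were
calibrated once against the benchmark sensitivities of the 48-h design and
then frozen; they are exposed on `WaveformSpec`
(`period_jitter_scale`, `obs_noise_scale`) so the calibration is explicit
rather than a hidden fudge. Non-rhythmic truth is a line a + bt with
a ~ U(5, 15), |b| ~ U(0.05, 0.5) units/h (sign random; nonzero by
construction) plus the same observation noise scale. Each realization draws
from a counter-based stream `default_rng([seed, i])`, so ensembles are
reproducible and order-independent. Sensitivity is the percentage of cosine
realizations called circadian, specificity the percentage of lines called
non-circadian; Wilson 95% intervals accompany both, and a detector that
raises on a realization is charged with a wrong call.

What the generator does *not* emulate: non-sinusoidal waveform shapes,
autocorrelated (red) noise, within-series drift of the rhythm parameters,
or assay floor/ceiling effects. Passing benchmarks therefore demonstrates
detector behavior under the stated noise family, not performance on any
particular clinical assay.

## Cohort statistics

Subjects are classified "standard" when ≥ K of their analytes carry a
detected rhythm (default K = 3 of the 9 clock genes, with K ∈ {2, 4}
reportable as a sensitivity check). Per-gene prevalence between groups uses
the 2×2 χ² test without continuity correction (flag available); a
zero-margin table returns p = 1 with a degenerate flag rather than an
error. Counts-versus-covariate association is Pearson's r with r²
reported. Per-gene tests are uncorrected at p < 0.05 by design fidelity;
a Benjamini–Hochberg option is available via the host statistics stack.

Acrophase summaries are circular: the mean is the resultant-vector
direction (undefined flag when the resultant is ≈ 0), and the IQR band is
computed after cutting the circle opposite the mean so the band never
straddles the cut. Phase comparison between groups uses the two-sample
Watson U² statistic with its asymptotic tail series
2Σ(−1)^(k−1)exp(−2k²π²U²); ties force the seeded permutation path, which
is also recommended below ~10 points per group.

Entrainment regression handles the branch ambiguity of circular responses:
acrophases are unwrapped by minimizing the sum of squared wrapped residuals
over a dense slope/intercept grid (slopes −2..3 by 0.01; intercept scanned
on the circle), then each acrophase is moved to the branch nearest the
provisional line and ordinary least squares is run on the unwrapped values.
At the cohort sizes in scope (n ≲ 30) this is equivalent to the exhaustive
branch search without enumerating 3ⁿ assignments. Event times spanning
under 4 h leave the slope unidentifiable and are flagged.

## Event-time density

Event clock times are smoothed with a wrapped-Gaussian kernel (offsets
extended until the neglected tail is < 10⁻¹²) on a 0.25-h grid, normalized
to integrate to 1 over the circle. The default bandwidth is a circular
normal-reference rule: circular SD √(−2 ln R̄) mapped to hours in
Silverman's 1.06·σ·n^(−1/5), clipped to [0.25, 6] h, with a uniform-sample
fallback. Pointwise 95% bands come from resampling events with replacement
(default 1,000 replicates, seeded; < 100 replicates warns). The
peak-to-trough ratio is reported together with the band non-overlap
criterion (lower CI at the peak above the upper CI at the trough). The
density is conditional on the cases by default; a case-over-reference
relative mode is provided as an extension when all-comer event times are
also in hand.

## Numerical conventions and degenerate inputs

- Constant series: periodogram powers are identically 0 with p = 1; the
  cosinor zero-amplitude p-value is 1; r² is undefined and `diagnostics`
  raises on SST = 0; standardization raises on zero variance.
- Rank-deficient cosinor designs (all times congruent mod τ/2) raise with
  the offending period named.
- Band edges are closed everywhere (a dominant period of exactly 18 h
  passes the gate).
- All hours are plain floats; acrophases are reduced mod τ into [0, τ).
- Seeds: every stochastic routine takes an explicit seed; benchmark
  realizations use `default_rng([seed, i])` spawned per index.

## Problem sizes used in the checks

The shipped test suite runs the full benchmark at 5,000 replicates per
ensemble for the noisy-sensitivity checks and 600–1,500 replicates for
specificity and monotonicity properties; Monte-Carlo calibration tests use
8,000–10,000 replicates. These sizes put the binomial standard error well
inside the tolerances being asserted.

## Known limitations

- The loose-filter bounds (15, 40) h and the reading of the amplitude
  constraint as "cap at 2 sample SDs" are design choices where reasonable
  alternatives exist; both are configuration fields.
- The analytic peak p-value is mildly conservative at n = 7 (see above);
  use the permutation path when exact calibration matters.
- The free-period search is a profile method: standard errors for τ are not
  reported, and fits at the band edge should be read as censored rather
  than point estimates.
- Sensitivity/specificity figures are properties of the synthetic noise
  family described here and transfer to real assays only to the extent the
  noise family does.
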
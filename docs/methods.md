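# Methods

## The model

All estimators in this package assume simple binomial release: a terminal
has `N` functional release sites, each releasing at most one vesicle per
action potential with probability `p`, and each released vesicle produces a
postsynaptic response of quantal size `Q`. The mean evoked amplitude is
`Ī = N p Q`; the trial-to-trial variance is `N p (1−p) Q²`, plus
`N p Q² cv²` when quantal size itself varies with coefficient of variation
`cv`. Three consequences organize the package:

* quantal content `QC = Ī / Q̄_mini` estimates `N p`, independent of gain
  and of quantal variability;
* across conditions that change only `p` (the extracellular Ca²⁺
  titration), variance against mean traces the parabola
  `var = Q Ī − Ī²/N` through the origin;
* during sustained high-frequency stimulation, release collapses to a
  replenishment-limited steady state, so cumulative amplitude grows
  linearly once the initially primed pool is spent; the line's intercept at
  the time of the first stimulus measures the response attributable to that
  pool.

## Estimators

**Miniature detection** (`MiniEventDetector`). The sign-corrected trace
(positive-going potentials in current clamp; inward currents reported as
magnitudes in TEVC) is baseline-subtracted with a running median and
smoothed at two scales: a light Gaussian (σ = 0.5 ms) for amplitude
measurement, and a heavier one (σ = 1.5 ms) for peak picking, because the
timing jitter of a noisy flat peak scales as σ^(−3/2) while the amplitude
attenuation of a 2/15 ms rise/decay event at σ = 0.5 ms is under 0.5%.
Peaks must exceed the threshold in height and a quarter of the threshold in
prominence (filtered-noise ripples riding on a decay tail have far smaller
prominence, so this resolves stacked events without admitting noise), and
events within the 5 ms refractory window are merged. The reported event
time is the interpolated half-rise crossing — the noise-stable latency
convention — so ground-truth comparisons add the kernel's analytic
onset-to-half-rise delay. The baseline window defaults to 0.5 s: a running
median must be long against the event footprint (~3 decay constants, tens
of ms) or it climbs onto the events and biases amplitudes low; 0.5 s keeps
event occupancy near 10% at physiological mini rates (~2 Hz) while still
tracking electrode drift.

**Evoked measurement** (`EvokedResponseMeasurer`). Amplitude is the
extremum within a window after each stimulus minus the mean over a baseline
window immediately before it. For trains the window clips to the
inter-stimulus interval and each stimulus' baseline is the level just
before it; decaying tails from earlier stimuli are *not* subtracted — the
back-extrapolation absorbs residual summation into the linear phase, and a
tail-subtraction option would change the pool estimate's provenance, not
its ratio comparisons. Light smoothing (σ = 0.5 ms) suppresses the positive
bias of a max-over-window statistic under noise.

**Quantal content** (`quantal_content`, `php_assessment`). QC is computed
per cell as the ratio of that cell's evoked and miniature means, then
aggregated across cells (a pooled-ratio option exists). PHP classification
is the conjunction of three Student-t comparisons at `alpha` (default
0.05): miniature amplitude significantly reduced, evoked amplitude not
significantly different, quantal content significantly increased. No
multiplicity correction is applied across the three conjuncts. No
nonlinear-summation correction is applied to current-clamp amplitudes; QC
from large EPSPs therefore carries the usual compressive bias, which
cancels nowhere but is shared by all conditions compared.

**RRP back-extrapolation** (`RRPBackExtrapolator`). Cumulative amplitude is
regressed on time over stimuli 18–30 (1-based inclusive, configurable) with
`t_k = (k−1)/freq`, so the extrapolation target t = 0 is the first
stimulus and the first response is part of the extrapolated pool. Trains of
30 or 60 stimuli are accepted; only stimuli up to the window end are used.
The intercept divided by the mean mEPSC gives the pool in quanta. A
negative intercept is flagged, never clamped. The estimator is exact on
affine cumulative data and invariant to gain (scaling amplitudes and the
mEPSC together). Against the depletion–replenishment generator it
*underestimates* the true pool (replenishment during the depleting phase
is attributed to the steady state), so absolute pool sizes are
method-defined quantities; between-condition ratios recover true pool
ratios to within a few percent at these settings.

**Variance–mean fit** (`VarianceMeanEstimator`). The parabola
`var = Q Ī − Ī²/N` is linear in `(Q, 1/N)`, so the unweighted least-squares
problem is solved exactly — by the normal equations when the optimum is
interior, by non-negative least squares when a constraint binds — rather
than by iterative minimization; a brute-force grid search is kept in the
test suite as an independent oracle. The theoretical Ca-free origin (0, 0)
is appended before fitting and excluded from sweep accounting. Variance
uses the unbiased n−1 denominator. If the fitted curvature is non-positive,
or so small that the implied release probability at the largest mean is
below 1e−8, `N` is reported as unidentifiable (infinite) rather than as a
large number; a fit pinned at `Q = 0` is an error. A
variance-of-variance-weighted fit (weights `(n−1)/(2 var²)`) is available
behind a flag; the default is unweighted. Per-condition
`p = Ī/(N Q)` values above 1, or non-monotone in Ca, are flagged.

*Bias structure under quantal variability.* With independent gamma quanta
the generative variance is `Q(1+cv²) Ī − Ī²/N`: the same parabola family
with an inflated slope. The simple-parabola fit therefore reports
`Q̂ ≈ Q(1+cv²)` while `N̂` remains essentially unbiased (verified in the
suite at cv = 0.3). A downward bias in `N̂` would require trial-common or
site-correlated quantal variability, which the generator does not model.

*Sampling distribution of N̂.* At 30 sweeps per condition the per-cell `N̂`
is the reciprocal of a noisy curvature and is strongly right-tailed (about
5% of cells exceed 3× the true value). Across-cell comparisons of release-site
number are therefore made on the curvature `1/N̂` itself — the
approximately normal least-squares coefficient, with zero-curvature cells
contributing 0 — where a doubling of true `N` is detected with ~99% power
at 15 cells per group, versus ~60–90% on `N̂` or `log N̂`.

## The synthetic-data generator

The generator emulates the study conditions the estimators were designed
for: two muscles innervated by one motor neuron, recorded in current clamp
or TEVC (−70 mV holding).

| parameter | default | rationale |
|---|---|---|
| `n_sites` N | 150 | typical functional-site counts at the larval NMJ |
| `p_max`, `ca_half`, `hill` | 0.85, 1.7 mM, 2.2 | Hill curve spanning p ≈ 0.05→0.80 over the 0.5–6.0 mM titration |
| `q_mean`, `q_cv` | 0.6 nA (TEVC) / ~1 mV (CC), 0.3 | typical mEPSC/mEPSP amplitudes and quantal CV |
| `pool_size` | 600 quanta | typical back-extrapolated NMJ pools |
| `release_fraction` | 0.3 per stimulus | fast depletion to a steady state within ~10 stimuli |
| `replenish_rate` | 1800 quanta/s | 30 quanta per 60 Hz interval → clear linear phase |
| sampling, kernels | 10 kHz; 2/15 ms rise/decay | sharp-electrode NMJ kinetics |
| `noise_sd`, `mini_rate` | 0.12 units, 2 Hz | mini SNR ≈ 5 — detection is nontrivial but feasible |

Evoked amplitudes are sums of independent gamma quanta over a
`Binomial(N, p(Ca))` draw; trains release `Binomial(available, f)` per
stimulus with constant-rate refill capped at the pool size; traces are
sums of unit-peak difference-of-exponentials kernels plus Gaussian noise,
with spontaneous minis as a Poisson process. One seeded stream per
scenario is split into named substreams (per muscle, condition, Ca level)
so adding a condition does not perturb the others. Scenario templates:
`wild_type` (both muscles identical), `knockdown` (one muscle: quantal
size ×0.5, sites ×2 — doubling quantal content so the evoked response is
maintained — pool ×1.65), and `phtx` (the knockdown parameterization on
both muscles, the acute global-blockade analogue).

At the 0.4 mM baseline Ca²⁺ used for quantal content, the Hill defaults
give p ≈ 0.03 and QC ≈ 5 — lower than published NMJ quantal contents
(~35), a deliberate trade-off: the same Hill curve must also span the
variance–mean titration. All comparisons made by the package are
within-simulation and unaffected.

**What the generator does not model** — and hence what passing tests do
not certify about real recordings: nonlinear summation of large EPSPs,
driving-force and input-resistance differences between muscles, correlated
or trial-common quantal variability, heterogeneous per-site release
probability, stimulus artifacts, baseline drift beyond what the running
median absorbs, and series-resistance errors in TEVC.

## Numerical and protocol choices

* Time axis of trains: `t_k = (k−1)/freq`; extrapolation target t = 0.
* Fit window default [18, 30], 1-based inclusive; 30- and 60-stimulus
  trains accepted.
* Detection defaults: threshold in trace units (no automatic scaling),
  refractory 5 ms, no amplitude-inclusion cutoff.
* Identifiability floor for the parabola curvature: implied top release
  probability 1e−8.
* Statistical defaults: Student's t (equal variance), Welch behind a flag;
  one-way ANOVA with Tukey HSD for families; alpha 0.05.
* Cohort/replication sizes used by the acceptance computations: 15 cells
  per group, 30 sweeps per condition, 200 replicate cohorts, 10⁴ null
  replicates for calibration — sizes chosen to match typical study n and
  to keep the full recomputation near half a minute.

## Known limitations

* Absolute RRP values are systematically below the generative pool size
  (see above); only ratios are validated against ground truth.
* Per-cell variance–mean fits at 30 sweeps are noisy in `N̂`; roughly 1% of
  simulated cells yield no measurable curvature and are reported
  unidentifiable rather than numerically huge.
* The PHP flag contains an accept-the-null clause (evoked amplitude "not
  significantly different"), so even with perfect compensation its
  per-cohort specificity is bounded by 1 − alpha; it is a classification
  convention, not a calibrated test.
* The detector is a threshold/prominence method; heavily overlapping minis
  within the refractory window are merged by contract, bounding recall at
  high mini rates. No template-matching or deconvolution detector is
  included.
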
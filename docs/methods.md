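# Methods

This note documents the models, estimators and numerical choices behind
`contrastpop`, and what the synthetic-data generator does and does not
emulate.

## Task and data model

One trial = a 30% contrast sample grating, a delay, and a test grating at
one of 14 contrasts (10, 15, 20, 25, 27, 28, 29, 31, 32, 33, 35, 40, 50,
60%), each shown for 512 ms; the subject saccades to report whether the
test was higher or lower in contrast than the sample.  Spiking data are
spike counts per channel in three epochs per trial: a 300 ms spontaneous
window before the test, and a 256 ms analysis window in the sample and
test presentations.  Rates are counts divided by window length
(spikes/s).

## Synthetic-data generator

The generator is first-class, tested code: it defines the ground truth
against which every estimator in the package is validated.

**Tuning.**  Each channel has a Naka–Rushton CRF
`R(C) = Rmax·Cⁿ/(Cⁿ+C50ⁿ) + M`.  Initial parameters are drawn once per
population (Rmax ~ U(30, 80) spikes/s, C50 = 30 ± U(3, 10)% with 70% of
channels above the boundary, n ~ U(1.5, 3), M ~ U(4, 12) spikes/s).  A
configurable fraction (default 0.125, i.e. 3 of 24 channels) has
*reversed* tuning, modelled with the decreasing form
`R = Rmax·(1 − Cⁿ/(Cⁿ+C50ⁿ)) + M` rather than a negative Rmax.

**Learning.**  Per training day, C50 drifts linearly toward the 30%
boundary (default 0.4%/day, clamped at 30) and the exponent grows
geometrically (default ×1.015/day, capped at 10).  Both changes steepen
the CRF at the boundary, which is the paper-level phenomenon the
downstream trend tests must detect.  The trajectory form (linear drift
with clamping) is a package choice; no functional form is given by the
study the task emulates.

**Adaptation.**  Test-epoch expected counts are attenuated by a fixed
factor (default 0.92): the sample grating precedes the test by under a
second and adapts the response.  This is what places the point of
neuronal equality *above* 30% contrast; as tuning steepens, the contrast
needed to overcome the fixed attenuation moves toward 30, so the PNE
distance to the boundary shrinks without any change in adaptation
itself.  Setting the factor to 1 recovers a generator whose expected
test count is exactly `gain × window × R(C)`.

**Shared gain.**  One lognormal gain per trial (mean exactly 1: location
−σ²/2) multiplies the sample- and test-epoch expected counts of every
channel, emulating slow excitability fluctuations.  The default σ = 0.05
was chosen once so that the gain's contribution to stimulus-conditioned
pairwise count correlations (≈ m·v/(1+m·v) with v = e^{σ²}−1) stays well
below the configured late-training correlation target; the magnitude of
slow gain fluctuations is otherwise unconstrained.  The COBE validation
harness uses σ = 0.5 to stress the estimator, independently of this
default.

**Counts and correlations.**  Counts are latent-Gaussian with
Poisson-like variance (variance = mean), rounded and clipped at zero.
Cross-channel structure comes from a latent correlation matrix
`λ·[(1−r)·uuᵀ + r·H]` where `u` holds per-channel relative loadings
(default uniform) and `H` is the tuning-similarity matrix — the signal
correlations of the generating CRFs taken on the Fisher-z scale
(normalized by z = 3, clipped to [−1, 1]), because monotone contrast
tuning compresses raw curve correlations near 1 while the downstream
regression of noise on signal correlation operates in z space.  Both
blend components are positive semidefinite with unit diagonal, so any
scale λ ∈ [0, 1] yields a valid correlation matrix (an eigenvalue-floored
projection guards numerically semidefinite corner cases).  λ is solved
per day by bisection on the closed-form mean pairwise count correlation
(including the gain term) so that the mean follows a linear early→late
schedule (defaults 0.12 → 0.06), and the tuned share r fades from 0.8 to
0.2 across days.  Consequences, by construction: noise correlations
decrease with training; similarly tuned channels share more noise; and
the slope of noise-z on signal-z flattens with learning.

**Choices.**  A linear readout `w·x_test + ε ≥ θ` generates the choice,
with weights defaulting to the day-1 CRF slopes at 30% (negative for
reversed channels), the criterion θ at the expected test-epoch population
activity for a 30% stimulus, and Gaussian criterion noise expressed as a
multiple of the trial-to-trial SD of the weighted sample-epoch activity.
That multiple shrinks linearly across days (defaults 3.5 → 0.6),
modelling readout improvement: this is what drives rising choice
probabilities.  The defaults were calibrated so the fixture reproduces
the reported scale of the phenomena — hardest-contrast accuracy ≈ 0.55
early vs ≈ 0.70 late, easiest > 0.9, per-contrast CP shifts up to
≈ 0.06–0.08.  Exact criterion ties resolve to "higher".

**Determinism.**  All randomness derives from the config seed through
named substreams (one per day for counts, one for choices, one per
binned session); identical configs give bit-identical sessions.

**What the generator does not emulate** — and hence what passing tests do
not establish about real recordings: spike timing (only binned counts;
the time-resolved variant used for window selection is Poisson with a
stylized transient-plus-sustained envelope), non-stationarity within a
session, burstiness/refractoriness (variance is exactly Poisson-like),
eye movements, attention, and any tuning dimension other than contrast.
Real signal-correlation distributions are broader than monotone CRFs can
produce; the z-scale similarity blend is a deliberate device to give the
noise-vs-signal regression a realistic operating range.

## Estimators and statistics

**AUROC** is the tie-corrected rank statistic P(b > a) + ½P(b = a) over
all cross pairs, computed from midranks; identical multisets give exactly
0.5 in floating point.  **COBE** estimates the same probability from
within-trial pairs only — fraction of trials with test > sample plus half
the tied fraction — so a shared multiplicative gain that inflates both
epochs together cancels.  Its tie weight (½) mirrors the AUROC tie
correction.  Because test–test comparisons have no within-trial pairing,
they use the pooled AUROC only.

**CRF fitting** is bounded least squares (Rmax ∈ (0, 10·max rate],
C50 ∈ [1, 100], n ∈ (0.1, 10], M ∈ [0, min rate + 1]) on per-contrast
mean rates weighted by trial count.  The objective is multimodal in
(C50, n), so a fixed 3×3×3 grid of starts (C50 × n × Rmax scale) is
evaluated and the three best starts refined; both the increasing and
decreasing form are fitted and the lower-residual form kept.  All-equal
rates short-circuit to a flagged flat fit with zero slope.  A channel is
classified reversed iff its across-day mean slope at 30% is negative;
pooled slope values for such channels are multiplied by −1.

**Neurometric fitting** uses the same bounded multi-start least-squares
machinery on the Weibull (α ∈ [5, 100], β ∈ (0.2, 10], γ ∈ [0, 1],
δ ∈ [0, 0.5]).  A Gaussian observation model is used because the fitted
y-values are AUROC estimates, not Bernoulli outcomes.  The PNE is the
root of y(x) = 0.5 on [10, 60] by Brent's method (tolerance well below
1e-6); when the fitted curve does not span 0.5 the PNE is undefined —
a value, not an error — and a channel enters PNE summaries only if its
PNE is defined on ≥ 80% of sessions.

**Choice probability** conditions test-epoch counts of one contrast on
the choice and takes the AUROC with the "higher-contrast" choice as
positive class; reversed channels are stored as 1 − CP.  A CP is
calculable only with ≥ 3 trials per choice group (the study leaves this
threshold unstated).  Under this sign convention a tighter
activity–choice coupling raises CP at every test contrast, so the
early-vs-late post hoc paired t-tests are one-sided "greater"
throughout.  The sample-subtracted variant applies the same AUROC to
per-trial (test − sample) differences.

**Correlations.**  Noise correlations are Pearson correlations within
(channel pair, contrast, day) cells with ≥ 10 trials; all averaging
happens on the Fisher-z scale (contrasts first, then the days of a
period).  Signal correlations correlate period-mean tuning curves across
the 14 contrasts.  Whether the pair value entering the slope regression
should be contrast-averaged or stacked per contrast is unspecified in
the source procedure; this package contrast-averages in z.  Slope cells
are defined by signal sign × single-channel-information tercile (the
ranking information is the across-pair mean of each channel's
single-channel Fisher information for the period) × period, with cells
under 10 pairs skipped.

**Permutation slope test.**  Early and late (signal-z, noise-z) pairs are
pooled; 1000 late-sized resamples are drawn and an OLS slope computed for
each; the late slope is significant iff outside the central 95% range.
Resampling is *without* replacement by default: the resamples are then
random relabelings of the pooled pairs, the observed late sample is
exchangeable with them under the null, and the 5% level is exact
(measured coverage 95 ± 1% over 500 null replicates).  Bootstrap-style
resampling (with replacement) is available via a flag but is
conservative (~99% coverage) because the pool contains the late sample.
Limitation: when the early and late *marginal* distributions differ —
e.g. noise correlations shrink overall with training — the pooled
resample mixes the two clouds and the test responds to that marginal
shift as well as to slope changes; this is a property of the published
procedure itself.

**Fisher information.**  For equal trial counts N per condition over T
channels, `Î = [Δμ̂ᵀ Σ̂⁻¹ Δμ̂ · (2N−T−3)/(2N−2) − 2T/N] / δs²`, with Σ̂
the average of the two within-condition (N−1)-normalized covariances and
δs = (π/50)·(c_high − c_low) mapping the task's 50% contrast span to π
radians.  The estimator is unbiased for Gaussian counts; the test suite
verifies mean recovery of the analytic Δμᵀ Σ⁻¹ Δμ/δs² within 3 SE for
T ∈ {1, 2, 5, 10} × N ∈ {100, 400} and exact δs² scaling.  Validity
requires N > T + 3; trial equalization truncates each day's two
conditions to the day's minimum (chronological prefix, seed-free, correct
trials only) before concatenating days.  Shuffling permutes trial order
independently per channel within condition.  Population curves add
channels in descending single-channel information (ties by channel id,
ranking recomputed per period and contrast pair); rank-ordered
single-channel informations are fitted with `c + b·(1 − e^{λ·rank})`
(rank 1 = least informative) by multi-start least squares, reporting
variance accounted for.

**Trend tests** are Spearman rank correlations of channel-averaged,
per-session values against session number, with midrank tie handling;
constant series are flagged rather than tested.

## Pipeline

Stages run in dependency order (simulate → preprocess → tuning →
discriminability → choice → information → correlations — correlations
last because its tercile labels consume the information stage), each
writing its delimited tables as it completes; a failing stage aborts with
the stage named and partial outputs retained.  Early/late periods default
to the first/last 5 days and must not overlap.  The summary JSON reports
the headline early-vs-late comparisons, boolean learning flags, and a
provenance block (config hash, seed, library versions); identical
configs reproduce it byte for byte.  Two-way ANOVA-style tables
(behavioural performance, CP period × contrast) are emitted for standard
statistics routines; the pipeline's own inferential outputs are the
Spearman trends, Wilcoxon signed-rank, one-sided paired t and
permutation tests described above.

Analysis-window selection scores each candidate window (starts on an
8 ms grid, lengths {50, 100, 150, 200, 250, 256} ms) by the mean over
contrasts of |AUROC(sample, test) − 0.5| on channel-pooled counts,
averaged across sessions with no early/late distinction; folding about
0.5 keeps below- and above-boundary contrasts from cancelling.  Ties
break to the earliest start, then the shortest length.  The baseline
staircase is implemented as bisection on the amplitude threshold —
supra-threshold rate is monotone in the threshold — with a 1% relative
convergence criterion and 100-iteration cap; the original step schedule
is unspecified, only the 1% criterion.

## Problem sizes

Default generator conditions: 24 channels, 22 daily sessions, 60 trials
per contrast per day, so five-day equalized correct-trial counts land at
≈ 215–290 per condition, matching the floor of the emulated study's
215–469 range.  Unit tests use reduced fixtures (8–20 channels, 10 days)
for speed and assert directions rather than significance where the
reduced scale lacks power; the full-scale end-to-end check runs the
default conditions.  Null-calibration checks run at 500–5000 replicates
with binomially consistent tolerances.

## Known limitations

* The count model is rounded latent-Gaussian, not a true point process;
  dispersion is fixed at variance = mean.
* The generator's choice model is a static linear readout with shrinking
  criterion noise; it cannot produce choice effects that are independent
  of absolute activity (e.g. purely feedback-driven CP).
* The permutation slope test inherits the pooled-marginal sensitivity
  described above.
* Fisher information assumes Gaussian sufficiency of (Δμ, Σ); for very
  low counts the linear estimator understates total information.
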
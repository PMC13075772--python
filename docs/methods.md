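# Methods

`audthal` implements the analysis chain for a paired characterization of
pure-tone (PT) and narrowband-noise (NBN) auditory processing: behavioral
detection scored with signal detection theory, and thalamic single-unit
analyses (rate-level fitting, temporal dynamics, single-unit frequency
discriminability, population decoding, tonotopy).  Because the package is
exercised end-to-end on synthetic data, this note documents both the
analysis models and what the generator does and does not emulate.

## Stimulus model

Conditions form an 11 x 8 x 2 lattice: half-octave-spaced center
frequencies (nominal 560-18,000 Hz; an `exact` mode generates true
`anchor * 2^(k/2)` values), SPLs 40-75 dB in 5 dB steps, and the two
stimulus kinds.  Stimuli last 100 ms with 10 ms raised-cosine ramps and
200-300 ms inter-trial intervals, 15 repetitions per condition.  NBN bands
take their edges at the geometric midpoints between adjacent centers
(quarter-octave extension at the ends), so the 11 bands tile the axis
without gap or overlap; the behavioral band is a verbatim override
(center 8.5 kHz, edges 7-10 kHz, width 3.0 kHz).  NBN waveforms are white
noise passed causally through a second-order Butterworth bandpass; only
relative levels are meaningful (the dB SPL reference pressure is a config
constant).  The Fletcher conversion `CB = 10^(CR/10)` relates critical
ratio to critical band (CR 35 dB -> ~3.16 kHz).

Grid-bound semantics: the 500 and 22,000 Hz bounds are treated as limits
on the *centers*.  Treating them as outer band-edge limits would drop the
560 Hz band (its geometric low edge, ~471 Hz, falls below 500 Hz) and
break the 11-band grid, so center containment is the default.

## Behavioral task and scoring

Each trial starts at lever press; the target plays at a uniform random
onset 1-3.5 s later at one of eight amplitudes (28-53 dB).  Scoring
follows the two-segment convention: onsets at or below 2,250 ms are scored
hit/miss in a 700 ms response window; later onsets are scored false
alarm/correct rejection in a *virtual* window of the same length whose
onset is drawn uniformly over the hit-window onset range, truncated so the
window ends before the true target onset.  The truncation is load-bearing:
it guarantees no target can drive a response inside the FA window, which
is what makes the false-alarm rate independent of target amplitude.
Releases before a trial's scoring window are aborts and excluded.

Per amplitude x kind cell: `performance = (HT+CR)/(HT+CR+FA+MS)` and
`d' = Z(HR) - Z(FAR)` with a log-linear correction (add 0.5 to each cell
of the relevant 2x2) applied only when a rate sits at 0 or 1.  Rates are
aggregated per session, then averaged over sessions per animal, then over
animals.  A kind's detection threshold is the lowest tested amplitude at
which the group d' differs from zero (one-sample two-tailed t-test across
animals, alpha 0.05, positive mean required).

The virtual window is drawn per trial (whether the original analysis used
one window per session or per trial is not determinable from the scoring
definition; per trial makes the FA window statistically indistinguishable
from the hit window, which is the property that matters).

## Behavioral generator

Detection probability is a cumulative Gaussian in dB,
`p_det(a) = (1 - lapse) * asymptote * Phi((a - mu) / sigma)`, with
`mu_PT = 34.5`, `mu_NBN = 31.0` dB (one 3.5 dB amplitude step apart),
`sigma = 2.2` dB, `asymptote = 0.99`, `lapse = 0.01`.  Premature releases
follow a constant hazard (0.10/s, implemented as per-10-ms Bernoulli
steps) that keeps running after an undetected target, so the hit rate
floors at the false-alarm rate and d' approaches zero exactly where
detection fails.  Midpoints were placed so the threshold rule lands at
31.5 dB (PT) and at the 28 dB floor (NBN); the hazard sets the FA rate
(~0.068 per 700 ms window) and hence the high-amplitude d' plateau.
A per-animal strategy scalar trades misses against false alarms
(hazard multiplied by `exp(1.3 s)`, detection midpoint shifted by
`-1.5 s` dB), producing the anticorrelation between miss rate and FA rate
across animals.  Reference runs use 8 animals x 10 sessions x 400 trials.

Small-sample note: with ~12 scored trials per cell per session, the
z-transform of extreme rates compresses d'; the recovered plateau is
~2.9-3.1 rather than the asymptotic ~3.3 the same configuration gives
with many trials.  Threshold recovery is unaffected (it depends on the
low-amplitude cells).

## Unit generator

Spike trains are inhomogeneous Poisson: a homogeneous baseline (log-normal
across units, median 2 sp/s — a modeling choice, flagged in config) plus
an evoked component of `N ~ Poisson(n_ev)` spikes at `latency + Exp(tau)`.
The expected evoked count follows a scaled log-normal of SPL — the same
family the fitting module assumes.  Writing the curve in `y = log x`, the
scaled log-normal is an exact Gaussian with peak `y* = mu - sigma^2` and
width `sigma`, so the generator places the peak at
`log(C50) + sigma * sqrt(2 ln 2)` to hit a target C50 in closed form.
Off-CF frequencies have C50 raised by 6 dB per half-octave step and
magnitude tapered (Gaussian, sd 1.8 bands): tuning broadens with level,
which is what produces the single-unit d' peak just above C50 and its
collapse 20 dB higher.

Condition offsets (the quantities recovery tests target): NBN C50 is
2.2 dB below PT (PT centered at 57.7 dB), NBN latency is +3 ms
(PT centered at 23 ms), NBN decay is x1.6 slower.  Peak-rate differences
between kinds emerge from the temporal offsets rather than a rate gain
(the PT gain parameter defaults to 1).

Calibration choice: rate-level dispersion `sigma_shape` is drawn from
(0.13, 0.19), giving steep rate-level functions (roughly a 10 dB rise from
half-maximum to peak) whose peaks sit inside the tested 40-75 dB range.
With 15 Poisson trials per condition, broader curves leave the fitted
maximum badly extrapolated: C50 estimates scatter by 4-6 dB and, because
the pure-tone curves sit ~2 dB closer to the 75 dB ceiling than the noise
curves, the two kinds acquire unequal extrapolation biases that leak into
the paired difference.  Steep curves keep single-frequency C50 errors near
1-1.5 dB with matched biases across kinds, which is what makes the paired
2.2 dB offset recoverable at a median precision of a few tenths of a dB
over 200 units.  A consequence of
this geometry is that many generated units have a finite fitted half-width
inside the 0-100 dB evaluation domain and are therefore flagged O-shaped
by the half-width rule; the explicit `o_shape_probability` (default 3.5%)
controls the strongly non-monotonic units whose peak falls inside the
tested range.  Simulated peak instantaneous rates are correspondingly
higher than typical recorded medians — a deliberate trade of absolute
rate realism for identifiability at the protocol's trial count.

What the generator does not emulate: correlated noise across units or
trials, non-Poisson spiking (bursting, refractoriness), frequency-
dependent latency, anesthesia state.  Passing recovery tests therefore
demonstrate estimator correctness under the stated statistical structure,
not robustness to those real-data features.  Ground truth is stored in a
sidecar structure that analysis code never reads.

## Rate-level fitting and C50

Per unit and kind, the frequency response area (FRA) is the trial-averaged
rate in a 5-95 ms post-onset window; rates are normalized by the unit's
matrix maximum (per kind; C50 is invariant to this scaling).
Responsiveness: a two-way ANOVA (frequency x amplitude) is computed as the
omnibus, and the responsive call uses per-frequency one-way amplitude
tests, Bonferroni-corrected across the 11 frequencies, at p < 0.01.

At each frequency, `f(x) = E/(x sigma sqrt(2 pi)) exp(-(log x - mu)^2 /
(2 sigma^2)) + B` is fitted by bounded nonlinear least squares (`x` is SPL
in dB, natural log; all parameters positive, upper bounds
[150, 20, 10, 0.4]).  Initialization is one data-driven start plus seeded
Latin-hypercube starts over the log of the bounded box (8 by default);
the best R^2 wins, ties broken by lowest E, and the search stops early
once R^2 exceeds 0.995.  C50 is found by root-finding on the fitted curve
over 0-100 dB (the domain is probed beyond the tested range to separate
monotonic from O-shaped curves): the rising-phase SPL where the curve
reaches baseline + 50% of the baseline-to-maximum range.  The half-width
is the SPL extent above 50% of the fitted maximum; a curve still above
half-maximum at 100 dB is monotonic (infinite half-width), otherwise
O-shaped.

CF selection applies four criteria per frequency — R^2 > 0.7, fitted
maximum at least half the unit's observed maximum, frequency selectivity,
and corrected ANOVA p < 0.01 — and takes the frequency with the lowest
C50 among those passing.  The selectivity criterion mixes units in its
printed form; the default implementation reads it as *frequency*
selectivity: at the candidate's best SPL, fewer than two contiguous
neighboring bands per side may respond above half the candidate's fitted
maximum.  An SPL-domain alternative (fitted half-width below a dB cutoff)
is available behind a config switch; neither is asserted as the original
intent.  An automated atypical-fit filter stands in for manual curation:
fits whose maximum exceeds the observed maximum by more than 50%, or
whose C50 falls outside the tested range +/- 10 dB, are excluded.

Tuning bandwidth is counted in frequency bands: contiguous
criterion-passing bands around CF with C50 below C50(CF) + 10 dB, or, in
fixed-amplitude mode, bands responding above half the row maximum at one
SPL.

## Temporal dynamics

Latency is the time to the PSTH peak (5 ms bins) at the unit's best
stimulus (the SPL at CF with the highest trial-averaged rate), reported at
the peak bin's center with ties broken toward the earliest bin — a
convention that adds up to half a bin relative to the generating latency.
Response persistence is the decay constant of
`f(t) = A exp(-t/tau) + C` fitted to the density of within-trial ISIs
shorter than 30 ms (1 ms bins, pooled over the condition's 15 trials),
initialized at [1, 1, 1] with bounds [0, 0, 0] to [inf, 1, inf] (tau in
seconds); fits with fewer than 30 ISIs or a near-single-bin histogram are
refused, and fits are kept at R^2 > 0.7.  Note the ISI decay constant is
an empirical index of response persistence, not the PSTH decay constant:
for onset-locked bursts the ISI scale tracks the instantaneous rate as
much as the decay.  Across generated units with realistic rate
heterogeneity the two are rank-correlated at Spearman rho ~0.7 — clearly
informative but not a clean readout of the decay constant, and the
recovery test asserts the correlation at that realistic level.

## Single-unit discriminability

With evoked counts in [5, 55] ms and baseline counts in the final 50 ms
before onset (length is specified, placement is this package's choice),
each trial yields `D = (evoked - baseline)_CF - (evoked - baseline)_adj`,
trials paired by repetition index (a permutation-averaged pairing exists
for sensitivity checks).  `Pc = (n_{D>0} + 0.5 (1 + n_{D=0})) / (n_tot + 1)`
is strictly inside (0,1), so `d' = sqrt(2) norminv(Pc)` is always finite;
interior CFs average the left and right comparisons, border CFs use the
available side.  Curves are indexed by SPL minus C50, snapped to the 5 dB
grid with ties toward the lower SPL.

## Population decoding

Pseudopopulations of 50 units are drawn with replacement from the
responsive pool (10 populations, no constraint on CF or C50); trial k of a
condition concatenates each sampled unit's k-th repetition.  Counts are
taken in a window starting at stimulus onset (0-50 ms by default, 0-25 ms
for the early window), classes are the 11 frequencies irrespective of SPL
(15 trials x 8 amplitudes = 120 per class, split 80/40 stratified by
frequency x amplitude).  The decoder is a one-vs-one ECOC ensemble of
linear SVMs; prediction minimizes the average binary hinge loss over the
learners involving each class (loss-weighted decoding, implemented here;
scikit-learn's vote-based aggregation serves as a cross-check in tests).
The regularization constant is tuned by a seeded log-uniform random
search with a 20-evaluation budget on a stratified validation split —
a deterministic, budgeted stand-in for Bayesian optimization.  Shuffled
labels give the chance baseline (1/11 ~ 9.1%).  Cross-condition runs tune
and train on all trials of one kind (within-condition accuracy from
stratified 5-fold cross-validation) and test on every trial of the other;
they require populations built from units responsive to both kinds.

## Tonotopy

Along-shank distances project to depth through the insertion angle
(default 60 degrees).  Per penetration (minimum 3 CF-bearing units),
log2(CF) is regressed on distance from tip — the log2 scale is the natural
choice given half-octave stimulus spacing — and penetrations are
classified by slope sign at alpha 0.05; the aggregate reports class counts
and a one-sample t-test of slopes against zero.

## Numerical conventions and degenerate inputs

Seeds thread through `numpy.random.default_rng`; equal seeds give
byte-identical generator output and identical pipeline manifests.  Root
finding uses Brent's method at 1e-6 dB tolerance.  Zero-variance inputs
are flagged rather than scored (empty SDT cells give NaN rates; all-equal
counts give a non-responsive flag; constant CFs give a zero-variance
tonotopy flag); silent units produce degenerate all-zero FRAs.  Fits that
fail every start are marked failed, never silently zeroed.

## Problem sizes

Reference analyses run at 8 animals x 10 sessions x 400 trials
(behavior), 200 units for C50-offset recovery, 70-unit pools for the
shuffled-decoding baseline, and 10 pseudopopulations of 50 units; module
tests use smaller populations (30 units) with the same structure.  The
end-to-end orchestration defaults to a compact configuration (60 units,
3 pseudopopulations) suitable for a single-command run.
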
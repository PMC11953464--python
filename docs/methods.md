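# Methods

This note documents the models, estimation procedures, numerical choices
and known limitations of `prpdecode`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Hemodynamic response model

The HRF is a difference of two gamma-shaped lobes parameterized directly in
interpretable units: times-to-peak `p1`, `p2` (s), full-widths at half
maximum `f1`, `f2` (s), an undershoot ratio `dip`, and a gain `A`:

    g(t; p, f) = (t/p)^a exp(−(t − p)/b),   a = (p/f)² · 8 ln 2,
    b = f² / (8 ln 2 · p),
    HRF(t) = A [ g(t; p1, f1) − dip · g(t; p2, f2) ].

The exponent and rate are the unique reading under which each lobe peaks
exactly at `t = p` with value 1 and has FWHM ≈ `f` (verified numerically to
5%). Natural logarithms throughout. Defaults when no fit is available:
`A = 1, p1 = 5 s, f1 = 5 s, p2 = 14 s, f2 = 9 s, dip = 0.3`.

Curve fits are bounded trust-region least squares (`scipy.optimize.
least_squares`), deterministic given the initial values. The single-gamma
fit used for decoding-accuracy curves holds the baseline fixed at the
chance rate (12.5% for 8-way decoding) and constrains the peak to the
sampled window and the FWHM to 0.8–12 s; these bounds act as weak
plausibility priors that keep the fit identified on noisy, low-amplitude
accuracy curves. Smoothing splines use `scipy.interpolate.
make_smoothing_spline`, which selects the penalty by generalized
cross-validation.

## Latency metrics

All latencies are measured on a continuous fitted curve relative to a
baseline (0 for percent signal change, the chance rate for accuracy
curves): peak = argmax on a 10 ms grid with parabolic refinement; onset =
earliest ascending crossing of baseline + 0.1 × peak amplitude before the
peak (found by bracketing + Brent root-finding); FWHM = width at half the
peak amplitude, with the right edge clipped to the window when the curve
has not descended below half height by the window end. Measuring the onset
threshold relative to the curve's own baseline (rather than zero) makes the
definition meaningful for accuracy curves whose floor is 12.5%, and leaves
all three latencies invariant under amplitude rescaling.

Raw (sample-grid) task-2 timecourses can only be shifted by whole TRs; the
shift applied is the largest TR multiple not exceeding the SOA — 199 ms for
the 300 ms SOA and 1393 ms for the 1500 ms SOA at TR 199 ms. A rounding
rule would give 1592 ms for the long SOA, which is why the floor rule is
the one implemented. Fitted curves are shifted by the exact SOA.

## Synthetic sessions

**Design.** Six conditions (single AO, single VM, and short/long SOA × two
task orders), 48 trials per run (8 per condition), 10 runs, TR 199 ms, 1600
volumes (318.4 s) per run with 7.96 s pre-rest and 9.96 s post-rest.
Within each run every condition uses each of the 8 stimulus–response
mappings exactly once (independent permutations for the two tasks of a
dual trial), giving exact condition × mapping balance. Stimuli last 200 ms;
the inter-trial interval runs from the last stimulus offset to the next
trial onset and follows a truncated decaying exponential restricted to
integer TR multiples in [3.98, 11.144] s (20–56 TRs), with the decay rate
solved numerically (Brent) so the distribution's theoretical mean is
exactly 5.4 s. Onsets are snapped to the TR grid — the shape-free FIR basis
requires grid alignment, and nothing in the emulated paradigm forces
off-grid onsets. ITI sequences are redrawn (rejection sampling) until the
run fits its volume budget; an unpackable run raises an explicit error
naming the run.

**Behavior.** Stage durations are gamma distributed. Defaults:
P = 0.10 s and M = 0.135 s with CV 0.1; C = 0.835 s with CV 0.25, since
response-selection time dominates both the mean and the variability of RTs
in 8-alternative arbitrary-mapping tasks. These values put the mean
single-task RT at 1.07 s and the deterministic short-SOA central
postponement at P1 + C1 − 0.3 − P2 = 0.535 s, the group-level PRP magnitude
the generator is meant to emulate. Between-subject variability multiplies
the central-stage mean by a log-normal factor (CV 0.25 by default),
producing individual PRP magnitudes of roughly 0.2–0.9 s, the spread such
dual-task experiments report. Response accuracy is Bernoulli(0.9) per
response; all downstream estimation uses correct trials only, with
incorrect trials modeled separately as nuisance.

**Regions and neural events.** Five region families: auditory and visual
sensory regions (short stimulus-locked boxcar, default 0.3 s, RT
independent); a multimodal central (MD-like) region whose boxcar spans the
central stage of each task — under the serial model task 2's boxcar starts
at max(SOA + P2, P1 + C1), i.e. queued behind task 1; modality-specific
motor regions (manual M1, oculomotor FEF) spanning selection + execution
(C + M) of their own task only, with optional negative-amplitude
suppression during the other task's motor window; and an "execution"
region type implementing the alternative hypothesis probed by the quartile
analysis — a fixed-duration event time-locked to the end of selection, so
its onset rather than its duration tracks RT. Each region carries fixed
unit-norm mapping→voxel pattern vectors (both tasks for the central
region, the preferred task elsewhere) on top of a positive mean spatial
profile; patterns are drawn once per seed.

**BOLD generation.** Voxel signal = Σ events (boxcar ⊛ HRF) sampled at the
TR × per-voxel amplitude + baseline 1000 + AR(1) noise + per-run Legendre
drift + shared low-frequency nuisance components (also returned as the
run's nuisance regressor matrix). The boxcar convolution is evaluated
exactly as a difference of the HRF's running integral, so event timing is
not quantized. Default amplitude 10 scanner units (~1% signal change);
default noise sd 2 units, AR(1) φ = 0.3. The mapping-pattern gain (1.25)
is calibrated so that single-task decoding in the central region peaks in
the 0.35–0.45 accuracy range characteristic of 8-alternative decoding in
multiple-demand cortex, with dual-task task-2 decoding correspondingly
lower — the accuracy regime the latency analyses are designed to operate
in.

## GLM estimation

Runs are percent-scaled per voxel (temporal mean → 100; non-positive-mean
voxels excluded with a warning). Designs always include per-run Legendre
drift up to order 3 and the run's nuisance columns; censored rows are
deleted and whitening never differences across a censor gap or run
boundary. Serial correlation is handled by feasible GLS: AR(1)
coefficients are estimated per voxel from OLS residuals (within contiguous
segments, clipped to ±0.95) and the median across voxels whitens data and
design in a single solve; per-voxel whitening is available
(`ar_pooling='voxel'`) but costs one GLS solve per voxel. This replaces
full ARMA restricted-maximum-likelihood estimation; for AR(1)-generated
noise the two coincide in population, and the simplification is what makes
the desk-scale recovery experiments tractable.

The FIR window is 69 lags (≈13.53 s at TR 199 ms): 14 s / 0.199 s is not an
integer, and 69 points is fixed as the conventional per-trial window for
this design (configurable). On noiseless data generated from any lag
profile the FIR fit is exact to machine precision (tested).

Single-trial estimation: GLM-style simultaneous whole-event betas (one
HRF-convolved regressor per target trial, aggregate regressors for other
conditions and incorrect trials) for pattern training; and LSS for
trial-wise timecourses — target-trial FIR set + one shared set for the
remaining same-condition trials + one shared set per other condition +
nuisance. The implementation exploits the identity span([F_t, F_c − F_t])
= span([F_c, F_t]): one QR factorization of the shared design is reused
for every target trial, and the target betas are recovered exactly as the
appended-column coefficients plus the updated shared-set coefficients.
This is an algebraic reformulation, not an approximation (tested against
the all-trials-separate solution on orthogonal designs). Conditions with a
single correct trial fall back to the shared FIR estimate with a warning.

## Decoding

Feature selection takes the top-50 voxels by t-value of the condition vs
baseline contrast (sensory/motor regions) or by the minimum of the two
single-task t-maps (conjunction, central regions); ties break toward lower
voxel indices. The decoder is a bank of eight one-vs-rest logistic
discriminants with L2 regularization strength 25 on the standard logistic
loss (sklearn `C = 1/25`); prediction is the argmax of the decision values
with ties to the lowest label. Features are z-scored with training-set
statistics only. "Leave-one-out" is implemented at the run level, which
guarantees train/test independence for trial-wise timecourse testing;
within a fold, a mapping whose correct trials all fall in the held-out run
receives an always-losing submodel rather than aborting the fold.
Dual-task trials are decoded by decoders trained on all single-task trials
(train-one-set, test-the-other), and task-2 curves are back-shifted by the
SOA before latency comparison. Task orders are pooled by pointwise
averaging of the two order-specific curves.

## Quartile diagnostics

Correct single-task trials are rank-binned into four RT quartiles (counts
differing by at most one, extras to the faster quartiles, ties by trial
order), and a quartile-resolved FIR model estimates one timecourse per
quartile. Profile classification uses the physics of the two hypotheses: a
lengthening selection event integrates more activity in slower quartiles,
so amplitude (and peak latency, FWHM) grows roughly in proportion to RT
while the onset stays comparatively flat; a fixed-duration execution event
merely shifts, moving onset and peak together at constant amplitude. The
primary decision statistic is the relative amplitude growth
(Q4 − Q1)/mean; above 0.3 with a positive peak-latency trend the profile is
called selection-like, otherwise execution-like. The onset/peak slope
ratio (≈1 for a pure shift, ≈0 for duration scaling) is reported as a
secondary diagnostic — it is the conceptually cleaner statistic but
considerably noisier at desk scale, since onset estimates depend on the
low-amplitude rising edge.

## Granger causality

Inputs are per-trial timecourses (one segment per trial, per-trial mean
removed); lagged predictors never span a segment boundary. Model order is
chosen by AIC over 1..10 with all candidate orders scored on the same rows.
Conditional GC is computed by explicit full-vs-reduced least-squares fits,
F[i→j] = ln(RSS_reduced / RSS_full) with maximum-likelihood (1/T)
variances, which guarantees non-negativity by nesting; for pure VAR
processes this equals the population Granger causality (the state-space
route used by common toolboxes agrees in population, and the closed-form
two-channel value ln(1 + c²σx²/σe²) is recovered within Monte-Carlo error
in the tests).

## Group statistics

Paired t (Cohen's d), one-way repeated-measures ANOVA computed from
within-subject sums of squares (partial η² = SS_effect/(SS_effect +
SS_error); cross-checked against `statsmodels.AnovaRM`; no sphericity
correction by default), Pearson correlation, Benjamini–Hochberg FDR
(via `statsmodels.multipletests`), and the JZS Bayes factor for
one-sample/paired t designs with Cauchy prior scale √2/2, computed by
adaptive quadrature and cross-checked against a dense fixed-grid
integration.

## Desk-scale experiment sizes

The ground-truth recovery experiments run at deliberately reduced scale:
the serial-queuing experiment uses 12 synthetic subjects × 10 runs of 32
trials (single tasks + the two short-SOA orders) with a 120-voxel central
region; the quartile experiment uses 100 subjects × 3 runs of 32
single-task trials with 80-voxel regions; chance calibration uses 20 label
permutations of one 3-run subject. These sizes give stable group-level
estimates while keeping a full run of the suite on one CPU in the
tens-of-minutes range.

## What passing tests do and do not show

The generator reproduces the *structure* of the real paradigm — design
balance, timing, bottleneck behavior, region event rules, realistic
decoding accuracy regimes — but not head motion, physiological waveforms,
spatial autocorrelation, inter-regional hemodynamic variability beyond the
configured HRFs, or multi-shot acquisition artifacts (nuisance enters only
as regressors, honoring externally computed censor vectors). Recovery of
the injected postponement therefore validates the estimation chain's
correctness and calibration under its own assumptions; it does not certify
performance on scanner data. Known quantitative caveats: decoding-accuracy
curves are a saturating, concave transform of the underlying pattern
signal, which widens low-amplitude curves and adds a small positive bias
(~0.1 s at default settings) to the recovered task-2 peak-latency
postponement; and onset latencies are intrinsically noisier than peak
latencies, which is why the quartile classifier leans on amplitude growth.
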
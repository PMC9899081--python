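# Methods

This note documents the models, algorithms, and numerical choices behind
`acx`, a pipeline for analyzing behavioral and electrophysiological data
from reversible auditory-cortex inactivation experiments (cortical cooling
and optogenetic silencing in a two-alternative vowel-discrimination task
and a seven-speaker localization task).

## Stimulus synthesis

**Vowels.** Tokens are produced by the classic source-filter scheme: a
periodic click train (unit impulses at the fundamental period, first click
at sample 0) drives four two-pole resonators in parallel, one per formant.
The four-formant tables are /u/ 460, 1105, 2857, 4205 Hz; /ε/ 730, 2058,
2857, 4205 Hz; /a/ 936, 1551, 2975, 4263 Hz; /i/ 437, 2761, 2975, 4263 Hz,
all at F0 = 200 Hz and 250 ms token duration. Each resonator has poles at
radius `exp(-pi*B/fs)` and angle `2*pi*F/fs` with the scalar numerator set
for unit gain at its center frequency. Formant bandwidths are not part of
the experimental specification; we default to B1–B4 = 60, 90, 150, 200 Hz
(typical speech-synthesis values) and make them configurable per formant.
Resonator outputs are summed with equal positive weights (no sign
alternation), 5 ms raised-cosine (`sin^2`) on/off ramps are applied (sample
0 is exactly zero), and the result is RMS-scaled to its software sound
level. All "dB SPL" values are software-referenced: RMS 1.0 ≡ 94 dB SPL;
no hardware calibration (e.g. Golay-code inverse filtering) is modeled.

**Maskers and localization bursts.** Gaussian white noise, generated fresh
per trial from an explicit seed, ramped and leveled the same way. The
localization burst applies a linear-phase Kaiser FIR low-pass (cutoff
below 22 kHz, ≥70 dB stopband at 22.2 kHz). Trial stimuli place two
identical vowel tokens separated by a 250 ms gap; a masker, when present,
spans exactly token-1 onset to token-2 offset (750 ms) and is routed to
the same speaker as the vowel (colocated), the opposite speaker
(separated), or omitted (clean). The masker level is vowel level minus the
configured SNR, so `20*log10(RMS_vowel/RMS_noise)` reproduces the SNR to
better than 0.1 dB.

**Envelope verification.** Recovering formant peaks from a voiced token is
harder than it looks: with a 200 Hz fundamental the line spectrum samples
the envelope every 200 Hz while the resonances are only ~60–200 Hz wide,
so standard LPC peak-picking is biased by up to ~150 Hz toward the nearest
strong harmonic. `spectral_envelope_peaks` therefore fits a
sum-of-resonators envelope model directly to the measured harmonic
amplitudes (analysis by synthesis). Because parallel summation creates
interference nulls between formants whose relative signs are unknown, the
fit restarts over sign patterns and over two objective domains — linear
amplitude (robust to deep nulls) and dB (sensitive to shallow resonances)
— and all candidates are scored on a common dB-RMS metric; peaks are then
read off the fitted envelope on a fine grid. Measured recovery error is
under 15 Hz for all four task vowels. Aperiodic inputs fall back to peaks
of a Welch spectrum with parabolic refinement. Fundamental frequency is
estimated from the autocorrelation maximum in the 50–500 Hz lag range with
parabolic interpolation (error well under 1 Hz at 200 Hz).

## Synthetic data generation

The generators produce data with the statistical structure the analyses
assume, plus ground truth for parameter-recovery testing. All randomness
flows from one seed through `SeedSequence` substreams (per ferret, per
unit), so identical configurations are bit-reproducible.

**Vowel behavior.** Per-trial success follows a logistic model:
`P(correct) = sigmoid(b0 + b_level*z(level) + b_noise*noise + b_treat*treat
+ b_int*treat*noise + u_ferret)`, with `u_ferret ~ N(0, sd^2)`. Defaults
(b0 = 1.7, b_level = 0.3, b_noise = −0.6, b_treat = 0.05, b_int = −0.50,
sd = 0.3) are calibrated so bilateral inactivation costs ≈10 percentage
points in co-located noise and ≈0 in clean conditions — the size of
deficits the task is designed to probe. The published experiments report
no quantitative psychometric slopes, so these coefficients are free
parameters anchored only to the percent-correct deltas. Each incorrect,
answered standard trial spawns a correction chain that repeats the
identical stimulus until a correct response; chain successes use the same
per-trial probability as the triggering trial (corrections are excluded
from analysis anyway, so their generative law only needs to terminate).
Center rewards occur on 10% of standard trials; omissions on 2%. Loop
temperatures are Uniform(8, 20) °C on the cooled side(s) and ≈37 °C
otherwise, recorded on every trial.

**Localization behavior.** Responses are drawn from a discretized
wrapped-Gaussian confusion kernel over the speaker ring (default SD 27°),
centered on the target — the simplest kernel producing near-diagonal
confusion matrices. Cooling broadens the kernel: bilaterally by a factor
1 + 0.45 for all speakers (≈ −14 points overall); unilaterally the
broadening is weighted toward the contralateral hemifield and grows with
eccentricity, yielding contralateral deficits around −15 to −20 points
with near-zero ipsilateral change at default weights. Sound levels come
from the task's {57, 61.5, 66} dB SPL set.

**Spiking units.** Inhomogeneous-Poisson spike trains over a trial grid of
4 levels × 3 durations (50/100/250 ms) × laser on/off × 20 repeats; laser
onset is 100 ms before sound onset and offset 100 ms after sound offset.
Each unit has a baseline rate, an additive evoked step during the sound,
and a laser effect switching on at laser onset + 2.5 ms (the generative
latency): suppressed units multiply their rate by a per-unit factor,
driven units add a small increment (median ≈0.05 spikes/s). The laser
effect is modeled as a sustained step even though the optical protocol is
pulsed at 50% duty; the protocol string is stored but does not modulate
the rate, which keeps latency recovery well-posed.

Rates follow a two-component lognormal mixture: a low-rate majority
(baseline median 0.55 Hz, evoked median 0.8 Hz, σ ≈ 0.7–0.8, suppression
factor Uniform(0.05, 0.35)) and a 15% high-rate component representing
multi-unit/fast-spiking sites (baseline median 64 Hz, evoked median 45 Hz,
σ = 0.4, suppression factor Uniform(0.02, 0.15), i.e. near-complete
silencing). This mixture is what makes the study's summary statistics
jointly attainable: the low-rate majority sets the population median
evoked change near 1.3 spikes/s, while only strongly active, deeply
silenced sites carry enough spikes per 0.5 ms bin for the cluster-based
latency statistic to localize the 2.5 ms onset. The probability of the
suppressed class decays exponentially with cortical depth (length constant
0.9 mm), scaled by bisection so the expected suppressed fraction over the
recorded depth range is 60%. Mean waveforms are class templates (broad
0.402 ms trough-to-peak for suppressed, narrow 0.338 ms for driven) plus
noise; template construction calibrates the peak offset by bisection so
the *measured* trough-to-peak equals the requested value despite
Gaussian-overlap shifts.

**What the generator does not emulate.** Real data have session drift,
bursting and refractory structure, correlated noise across units, probe
drift, non-exponential depth profiles, response omissions correlated with
difficulty, and learning effects. Passing recovery tests therefore shows
the estimators are correct under the assumed generative laws, not that
those laws exhaust real recordings.

## Behavioral statistics

**Filtering.** Analyses exclude correction trials and no-response trials.
A cooled-arm trial counts as cooled when the scoped loop temperature is
≤20 °C: the mean of left and right thermocouples for bilateral cooling,
the implanted-side loop alone for unilateral. Stimulus values (level or
SNR) must reach 10 trials and 3 sessions in both arms; failing values are
removed from both arms so the contrast stays balanced. Every exclusion
count is logged on the returned table (`.attrs["filter_log"]`), and the
filter is idempotent.

**Balanced bootstrap.** Percent correct is summarized by drawing, on each
of 1000 iterations, the same number m of trials with replacement from
every stratum (joint combination of the balancing columns — vowel, level
or SNR, and location when it varies) and pooling the draw. m is the median
of the stratum sizes (rounded half-up when fractional; the convention is
ours, the sources are silent), or a fixed per-location count for the
localization analysis. Percent correct is computed over the pooled draw,
not averaged across per-stratum accuracies. Inactivation contrasts pair
test and control iterations and report the mean difference
(test − control). Hemifield contrasts exclude midline speakers and are
computed from location-balanced bootstraps within each hemifield, plus
per-eccentricity (30/60/90°) raw contrasts.

## Mixed-effects inference

`fit_glmm` implements maximum-likelihood GLMMs (binomial-logit and
Poisson-log) with crossed random intercepts via the Laplace
approximation. For candidate log-SD parameters, an inner penalized
iteratively reweighted least squares (joint Newton over fixed effects and
random modes, with step halving) finds the joint mode; the Laplace
marginal log-likelihood is the penalized joint value corrected by
−½ log det of the random-effect curvature block. The outer optimization
runs L-BFGS-B over log-SDs bounded in [−8, 3] (the lower bound collapses
the factor onto an ordinary GLM). Wald standard errors come from the
profiled fixed-effect information `X'WX − X'WZ (Z'WZ + D⁻¹)⁻¹ Z'WX`.
The implementation is validated against `lme4::glmer` in the test suite
(coefficients, SEs, random-effect SD and log-likelihood agree to ~0.01 on
a 2000-trial dataset); a fit with the grouping SD pinned to zero matches
`statsmodels` GLM to 1e-4. Coefficients above 30 in absolute value raise
a separation diagnostic. Sound level is z-scored before fitting (recorded
in the fit object); categorical fixed effects are dummy-coded against the
alphabetically first level. Model comparison reports AIC and
likelihood-ratio (analysis of deviance) chi-square tests for nested
pairs. Variance-partition R² is computed on the latent scale: marginal =
var(Xβ)/(var(Xβ) + Σσ² + σ²_dist) with σ²_dist = π²/3 for the logit link
and log(1 + 1/λ̄) (lognormal approximation) for the Poisson log link;
conditional adds Σσ² to the numerator. Residual diagnostics use
simulation-based randomized quantile residuals (default 250 unconditional
simulations, uniform tie-breaking) with a KS uniformity test.

## Spike-train analysis

**QC.** Single-unit status requires ≤2% of inter-spike intervals below
2 ms. Mean waveforms with no sample below −3 baseline-noise SDs before
the global maximum are flagged as monophasic-positive laser artifacts.

**Rates and tests.** Evoked windows run from sound onset to offset (window
length equals the sound duration exactly); spontaneous windows are the
100 ms before sound onset. The sign convention is change = laser OFF −
laser ON (positive = suppression). The per-unit modulation test compares
per-trial rates in the 50–150 ms-from-laser-onset window (last 50 ms of
baseline plus first 50 ms of evoked activity) between laser states with a
two-tailed Mann-Whitney test on the unpaired trial sets. Evoked detection
runs a paired Wilcoxon signed-rank per level×duration cell (sound window
vs matched-length pre-window) with Bonferroni correction over cells.

**Clustering.** Units are clustered on the two-vector [mean evoked rate
laser-off, laser-on] under cosine geometry: rows are L2-normalized and
Lloyd's algorithm (20 restarts, fixed seed) runs on the sphere, which
makes labels invariant to per-unit rate scaling. Model order is chosen by
the knee of the sum of point-to-centroid distances for K = 1…10 — the
point of maximal perpendicular distance to the chord joining the curve's
endpoints, verified exactly against a brute-force oracle. Cluster 1 is
the group with the larger median off−on change (the suppressed group). A
per-condition 12-dimensional feature variant was considered and rejected:
with 20 repeats per condition the added dimensions mostly add estimation
noise.

**Latency.** PSTHs use 0.5 ms bins over the 100 ms after laser onset
(sub-millisecond latencies demand sub-millisecond bins; laser-off trials
are mapped onto the same laser-aligned time base). Per-bin rank-sum
statistics are thresholded at a two-sided cluster-forming α = 0.05;
contiguous same-sign supra-threshold runs are scored by the sum of |z|
and referred to the maximum-cluster-mass distribution over 1000 random
relabelings of trials (permutations reuse the fixed per-bin ranks, so the
null is computed by a single matrix product). The latency is the left
edge of the earliest bin in any cluster with permutation p < 0.05. By
default all laser-on conditions are pooled against all laser-off trials
(per-condition testing at 20 repeats has essentially no per-bin power at
0.5 ms resolution; a per-condition mode is available). Population latency
summaries take units that both show a significant cluster and a
significant suppressed per-unit test — without the second condition,
chance-level cluster detections in unmodulated units (≈5% of them, at
uniformly random latencies) contaminate the median. Measured family-wise
error on null simulations is ≤0.01 at the nominal 0.05.

**Waveforms.** Trough-to-peak latency is the time from the global minimum
to the following maximum with parabolic sub-sample refinement; waveforms
whose dominant deflection is positive raise an error (artifact rule).
Cluster differences in trough-to-peak are tested by shuffling cluster
labels (1000 iterations, two-sided, add-one smoothing), restricted in the
standard analysis to well-isolated single units within the
90%-inactivation depth.

## Problem sizes and tolerances

Recovery suites run at the scale the analyses target: 3 ferrets × 3000
trials for the behavioral mixed model (interaction −0.6 recovered within
2 Wald SEs in ≥90% of 100 replicates; truly-null covariates reject at
≈5%), and 400 units × 480 trials for the spiking pipeline (knee K = 2,
≥95% correct class assignment, median latency within one 0.5 ms bin of
the generative 2.5 ms; verified across multiple generator seeds before
the defaults were frozen). Numerical tolerances: PIRLS converges on
relative objective change 1e-10, the outer gradient tolerance is 1e-6,
envelope fits stop early below 0.1 dB RMS, and bisection calibrations
(depth scaling, waveform templates) run 50–60 halvings.

## Known limitations

Random slopes, nested (as opposed to crossed) random effects and
overdispersion families are not implemented. The Poisson R² uses the
lognormal approximation for the distribution variance. The envelope
fitter assumes at most `n_peaks` resonances and can merge closely spaced
formants (the two upper formants of /i/ merge at default bandwidths). The
localization generator draws responses independently across trials — no
perseveration or response bias. Session-level random effects are not
generated, so conditional R² on synthetic data is dominated by the ferret
intercept alone.
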
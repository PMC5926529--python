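# Methods

This note documents the models, numerical choices and known limitations of
the package. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Task and measurement model

Each trial shows a central fixation point for 500 ms, then a peripheral
target at ±10 or ±18 deg for 2,500 ms; the subject must saccade to the
mirror position. Gaze position is sampled at 240 Hz in degrees of visual
angle. Processing follows the standard chain for this class of recordings:
a third-order Butterworth low-pass with −3 dB at 25 Hz, velocity from the
eight-point central-difference derivative (9-tap antisymmetric stencil with
one-sided coefficients 4/5, −1/5, 4/105, −1/280; −3 dB bandwidth above
70 Hz at 240 Hz; exact on polynomials up to degree 8), and event detection
as maximal runs of speed ≥ 10 deg/s.

Filter phase. The filter is applied zero-phase (forward–backward) by
default so that detected onsets carry no group delay; this squares the
magnitude response, i.e. doubles the nominal attenuation at cut-off. A
causal single-pass mode exists for frequency-response verification, where
the designed −3 dB point at 25 Hz is tested directly.

Detection defaults. Two knobs are not part of the protocol and are
config-exposed: `min_duration_ms` (12 ms = 3 samples; rejects single-sample
noise crossings) and `merge_gap_ms`. The `detect_events` function keeps a
10 ms merge gap as its documented default, but the pipeline default is 4 ms
(below one inter-sample interval at 240 Hz, hence effectively no merging).
Reason, found empirically during development: the zero-phase filter's
pre-onset ringing lobe sits at roughly 4–5% of peak velocity — 8 to 15
deg/s for typical saccades, i.e. straddling the 10 deg/s threshold. With a
10 ms gap that lobe is merged into the event whenever noise lifts it over
threshold, jittering detected onsets by ±3 samples on about a fifth of
trials; with merging disabled, lobe runs are two samples long and are
dropped by the minimum-duration rule, and onset recovery becomes stable to
±2 samples on essentially all trials at the default noise level. A genuine
saccade never dips below threshold mid-flight after 25 Hz filtering, so
nothing is lost.

Event measurement. For a half-open supra-threshold run [onset, offset):
duration = run length / 240; amplitude = signed horizontal displacement
x[offset] − x[onset]; direction angle = atan2(|Δy|, |Δx|); peak and mean
velocity are the max and arithmetic mean of the speed channel over the run;
latency = onset time − target onset. Mean velocity as the sample mean of
speed is one of several possible estimators; published group tables of mean
velocity are not always consistent with amplitude/duration from the same
rows, so this choice is a convention, not a recovery claim.

## Trial classification

The primary saccade is the first detected event with onset strictly inside
the target window and |amplitude| ≥ 1 deg (config-exposed; excludes
fixational micro-movements). Primaries with latency < 100 ms are excluded
as anticipatory; primaries more than 30° off the horizontal are excluded as
oblique. Direction is judged on the sign of the horizontal displacement
alone, consistent with the obliqueness gate. A primary away from the target
is a correct anti-saccade; toward the target it is a directional error,
corrected if a subsequent opposite-sign event of qualifying amplitude
starts before target offset. Error rate = errors / (correct + errors);
correction rate = corrected errors / errors (undefined without errors). A
subject whose excluded fraction exceeds 15% of trials is flagged, mirroring
the usual QC cap.

## Synthetic cohorts

The generator's defaults are the study conditions: group profiles carry the
published per-eccentricity latency means and SDs for correct anti-saccades,
erroneous pro-saccades and intersaccadic intervals; gain mean/SD per
eccentricity; per-trial directional-error probabilities of 0.193 (CTR),
0.396 (SCA2) and 0.654 (LOCA); correction probabilities 0.986, 1.0, 0.977
(eccentricity-averaged); and per-group main-sequence parameters
(Vmax, c, k, b) = (424.4, 7.0, 22.5, 3.4) for controls,
(496.0, 34.6, 104.8, 3.7) for SCA2, (551.4, 11.4, 41.1, 2.0) for LOCA.
One printed gain SD (controls at 18 deg) is internally inconsistent between
the study's tables (1.14 vs 0.14); the generator uses 0.14, the value
consistent with the within-subject variability table.

Waveform family. Saccade velocity follows v(τ) ∝ sin^2p(πτ/T). The
exponent p ∈ [1, 40] and the envelope duration T are solved per saccade
(Brent root-finding on closed-form expressions using the regularised
incomplete beta function) so that total displacement equals the drawn
amplitude and the time above the 10 deg/s threshold equals the
main-sequence duration k + b·A; the peak velocity then matches
Vmax(1 − e^(−A/c)) whenever the implied peak/mean ratio is attainable by
the family (≈1.65–2.12 after threshold windowing). Outside that range the
peak velocity is relaxed to the nearest attainable value and the saccade is
flagged; amplitude and duration are always honoured. The sin^2p family is a
modelling choice — real saccade waveforms are not specified by group tables
— and group differences are reproduced only through (Vmax, c, k, b).

Latency semantics. Published latencies are operational: they were measured
with the same threshold criterion on filtered data. The generator therefore
defines a drawn latency as the onset that the standard measurement chain
reports, snapped to the 240 Hz grid. Since zero-phase filtering shifts the
threshold crossing deterministically (the smeared velocity pulse crosses
10 deg/s a little early), each saccade's placement is pre-compensated by
measuring that shift on a filtered copy of its own waveform (cached per
rounded amplitude). Noise-free, the pipeline then recovers drawn latencies
exactly; at the default 0.05 deg position noise, onsets recover within ±2
samples on ≈100% of trials (tested).

Other draws. Latencies are truncated normals (floor 105 ms for
non-anticipatory classes, so they cannot leak into the anticipatory band);
intersaccadic intervals are truncated at 80 ms so that, after filter smear,
the erroneous pro-saccade and its correction can never fuse into a single
supra-threshold run; gains are truncated to [0.15, 2.5]; erroneous
pro-saccades use gain N(0.95, 0.10) (pro-saccades are more accurate than
anti-saccades; the study tables do not print pro-saccade gain). Corrective
saccades land near the mirror position, so their amplitude is roughly twice
the eccentricity. Anticipatory trials draw latency Uniform(0, 100) ms
(kept at least one sample after target onset, since the classification
window is open at the boundary); oblique trials add a vertical component at
35–55°. Both default to probability 0.02 — small enough to keep every
subject under the 15% QC cap, large enough to exercise the exclusion rules.
The vertical channel is otherwise white noise (SD 0.05 deg), as is the
horizontal noise (SD 0.05 deg). An optional 0.16 deg quantisation emulates
tracker resolution (off by default). No return-to-centre movement is
synthesised; the analysis window ends at target offset.

Seeding. One integer master seed; subject i draws from
SeedSequence([seed, i]), its schedule from SeedSequence([seed, i, 10^6]),
and trial j from SeedSequence([seed, i, j]). Identical inputs give
bit-identical datasets; subjects are independently regenerable.

What the generator does not emulate: blinks and pupil artifacts, binocular
disparity, calibration drift, smooth pursuit, head movement, express
saccades, and any within-session learning or fatigue. Passing recovery
tests therefore shows that the analysis chain is unbiased for data obeying
the stated generative model, not that it is robust to every artifact of
real recordings.

## Main-sequence fitting

The exponential relation is fitted by unweighted nonlinear least squares
(the printed form of the saturating law has the sign in the exponent
corrected to 1 − e^(−A/c), the only reading under which Vmax is an
asymptote). Initialisation: Vmax₀ = 1.05·max(vpeak), c₀ = median(A);
up to 5 deterministically jittered restarts on non-convergence; tolerance
1e−10. Standard errors come from the curvature at the optimum. Amplitudes
are pooled across directions and eccentricities as absolute values.
Prediction intervals for a new observation are exact for the linear model
and first-order (delta method) for the exponential; their empirical
coverage is verified at 0.95 ± 0.01 by simulation. With amplitudes capped
near 20 deg, c is weakly identified when it is large (the SCA2 regime):
its sampling SD at n = 500 and 5% velocity noise is a few percent, and the
reported standard errors reflect that.

## Statistical battery

Levene's test in the Brown–Forsythe (median-centred) variant gates the
omnibus at α = 0.05: heteroscedastic parameters go to Welch's ANOVA applied
to pooled mid-ranks (the literal reading of "Welch on ranked data"),
otherwise Kruskal–Wallis. Dunn's pairwise z tests use tie-corrected pooled
ranks and Bonferroni ×3 capped at 1. The unit of analysis for group
comparisons is the per-subject mean (one value per subject per parameter);
Kolmogorov–Smirnov latency comparisons pool per-saccade latencies, matching
the distribution-level question they answer. Proportions are compared with
Pearson's χ² on the 2×3 table (no continuity correction, 2 df) and the
Marascuilo critical range
r_ij = sqrt(χ²_{1−α;2}) · sqrt(p_i(1−p_i)/n_i + p_j(1−p_j)/n_j),
reported in percentage points. All tests are two-sided at 5%. No
correction is applied across the many parameters tested (Bonferroni lives
only inside each post hoc triple). Dunn's test and Welch's rank ANOVA are
implemented in-package from their closed forms; the Welch statistic is
cross-checked against an independent implementation in the test suite.
The type-I error of the gated omnibus is verified at 0.05 ± 0.02 under the
null by simulation.

## Problem sizes in the acceptance script

`scripts/acceptance.py` uses n = 500 points for the three fit-recovery
quantities (5% multiplicative velocity noise, 8 ms duration noise); 1,600
10-deg control trials for latency and gain recovery; 8,000 LOCA trials for
the error rate; and 12,000 trials per group for the Marascuilo differences.
These sizes put the Monte-Carlo standard error of each recovered quantity
well inside its comparison band (e.g. ≈0.5 percentage points for the
pairwise error-rate differences) while the whole script stays around a
minute of runtime.

## Known limitations

- Pipeline-measured durations and peak velocities are filter-dependent:
  zero-phase smoothing lengthens measured durations (threshold crossings
  move outward) and attenuates peaks by a few percent. Latency, gain and
  rate recoveries are calibrated; duration/velocity table analogues are
  qualitative.
- Between-subject heterogeneity is not modelled by default: every subject
  of a group shares one profile, so between-subject spreads of simulated
  cohorts understate the published ones. `study_cohort_profiles` varies
  only ICARS (using the published per-patient scores).
- The sin^2p family cannot represent peak/mean velocity ratios above
  ≈2.1; requests outside the attainable range are honoured in amplitude
  and duration with the peak relaxed and flagged.
- Gain measured through the pipeline carries a small positive bias
  (≈+0.01) from filter overshoot at the event offset; it is well inside
  the comparison bands and affects simulated and real data alike.
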
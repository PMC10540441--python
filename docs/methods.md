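# Methods

This note documents the measurement model, the numerical choices and the
synthetic-data design behind the package, and what its tests do and do not
demonstrate.

## Recording model and conventions

A trial is a 10-m walk, a U-turn and a 10-m walk back (20 m total),
recorded by three inertial units — left foot dorsum, right foot dorsum and
lower back (L4–L5) — each delivering tri-axial acceleration (m/s²) and
angular velocity (deg/s) at a nominal 100 Hz. All processing happens in an
anatomically aligned frame (AP anteroposterior, ML mediolateral, CC
craniocaudal). File input is per-site CSV; a dialect block declares the
sample rate, gyro units (rad/s converted on load) and a fixed signed axis
permutation per site, since sensor-to-segment calibration is out of scope.
Inputs off the nominal rate are linearly resampled; isolated non-finite
samples (≤1% of a stream) are linearly interpolated with a logged warning,
more is an error; trials shorter than 5 s are rejected as non-walking.

## Gait events

The foot ML angular velocity is low-pass filtered (4th-order Butterworth,
10 Hz, zero-phase). Swings are prominent positive peaks (the trace is
flipped if the dominant lobes are negative): prominence and height ≥ 50
deg/s, minimum separation 0.45 s, with an adaptive fallback at 0.4× the
maximum for low-amplitude, degraded gait. FC is the last local minimum
before the swing peak and IC the first after it — the physiological
troughs of the foot sagittal angular velocity. Same-foot peaks closer than
0.2 s are merged, keeping the more prominent. Fewer than four strides on a
foot is an "insufficient gait" error. The height criterion matters: between
two deep event troughs, a flat noisy baseline otherwise offers spurious
high-prominence peaks at slow cadences.

## U-turn

The trunk CC angular velocity is integrated (trapezoid) into a yaw angle.
A coarse turn region is the widest excursion of the 0.5 Hz-smoothed,
median-centred turn rate above 25% of its peak. Linear gyroscope drift is
removed by the line through the pre- and post-turn plateau means under the
assumption that the turn spans 0°→180° (left turns are sign-folded).
Boundaries are placed where the smoothed angular rate decays to 2% of its
turn peak, searching outward from the peak — i.e. the inflection of the yaw
trace out of and back into its plateaus. An angle-threshold rule (crossings
of 5%/95% of 180°) was considered and rejected: it pins the
boundary-to-boundary displacement at ~162° by construction, whereas the
rate-threshold rule leaves the boundary angles within a few degrees of
0°/180° and the displacement within ±10° of a half revolution, which is the
behaviour the method is validated against. If the whole yaw trace stays
below 120° the trial has no U-turn.

## Segmentation

Valid strides are same-foot IC→IC intervals that do not intersect the
U-turn, minus the first (initiation) stride of each foot. Steps are the
merged IC events outside the U-turn. Trunk-signal measures use the two
straight-walking windows: from the end of initiation to the U-turn start,
and from the U-turn end to the start of the terminal stride of each foot
(gait termination should not contaminate smoothness/regularity measures).
A U-turn covering more than 80% of the trial, or fewer than 4 steps outside
it, is a degenerate segmentation.

## Parameters — numerical choices

* **V**: path length / (last event − first event − U-turn duration).
  Path length defaults to 20 m and is a declared input.
* **StrT** pools both feet's valid stride durations (arithmetic mean).
* **SPARC-G**: applied to the Euclidean norm of the trunk tri-axial angular
  velocity per straight window, windows combined by duration-weighted mean.
  Spectrum by FFT zero-padded to 2^(⌈log₂N⌉+4); magnitude normalised by its
  maximum (for this non-negative input the DC bin); adaptive cutoff = last
  frequency below 20 Hz where the normalised magnitude still reaches 0.05;
  arc length computed on the cutoff-normalised frequency axis and negated.
* **LDLJ-A**: per window, −ln(T·∫j²dt/a²_peak) with jerk from centred
  finite differences on the 10 Hz low-passed AP acceleration
  (differentiation amplifies noise); duration-weighted across windows.
  The T¹·a_peak⁻² normalisation is the acceleration-input convention that
  makes the argument dimensionless.
* **CVs** use the sample SD (n−1) — small-sample convention — over stride
  times and per-cycle double-stance times.
* **P1/P2**: unbiased normalised autocorrelation (divisor n−k, demeaned,
  ρ(0)=1) of the trunk CC acceleration per window; P1 is the maximum over
  lags in step_lag·[0.5, 1.5], P2 over stride_lag·[0.75, 1.25], with the
  expected lags seeded from the detected median step interval and mean
  stride time; duration-weighted across windows.
* **iHR**: per valid stride, the segment between consecutive ipsilateral
  ICs is demeaned and expanded in its stride-locked Fourier series;
  harmonics 1–20 are kept (conventional in trunk harmonic-ratio work);
  the index is intrinsic power (even harmonics for AP/CC, odd for ML) over
  total harmonic power, ×100, averaged across strides. Strides shorter
  than 40 samples are skipped with a warning.
* **RMS_aML** is zero-referenced (the mean is *not* removed): a constant
  lateral offset is a real deviation, not a calibration artefact to hide.
* **dstT**: per stride cycle, (contralateral FC − ipsilateral IC) for both
  support periods, summed, over the cycle time, ×100; cycles with a
  negative support interval (event-ordering violation) are discarded with
  a warning.
* **swTr** uses min/max of per-foot mean swing (FC→IC) times over valid
  strides, so it is invariant to left/right relabelling.

Determinism: the whole pipeline is a pure function of the input samples;
repeated runs are bit-identical.

## Scoring

z_p = c_p·(x_p − μ_p)/σ_p with the sign applied *inside* the z-score, so
higher is uniformly better. The packaged reference table (means, SDs and
signs for all 17 parameters, from 110 trials of 19 healthy adults) is
shipped as YAML and used verbatim; `ReferenceStats.from_parameter_sets`
can re-derive means/SDs from any cohort (signs are kept, being clinical
judgements, and zero-variance parameters are floored with a warning).
One sign is worth flagging: the reference table marks SPARC-G as
"increase pathological", although a *less negative* spectral arc length
conventionally means a smoother movement; the table is applied as printed.
Criterion scores are unweighted arithmetic means of their members'
z-scores; CV_dstT is grouped under steadiness (as listed), despite its
synchronization flavour. Sessions are summarised by per-criterion mean and
min–max band over the session's trials.

## Reliability statistics

ICC(1,1) and ICC(3,1) are computed directly from ANOVA mean squares
(one-way random; two-way mixed without interaction, i.e. consistency).
A matrix with no between-subject spread yields a defined value but is
flagged degenerate. SEM = pooled SD·√(1−ICC) with the pooled SD taken over
all cells (ddof 1); at ICC = 0 it equals the pooled SD, at 1 it is 0.
Banding is inclusive downward at both printed boundaries: 0.75 is
excellent, 0.4 is moderate-to-high. Heteroskedasticity is screened by the
Pearson correlation of |x₁−x₂| with subject means (two repeats);
constant-input degeneracies report r = 0 with a warning. Group differences
use the two-sided Mann–Whitney U (midranks; normal approximation with tie
correction and a 0.5 continuity correction, switching to the exact
permutation distribution when both groups have ≤ 8 observations), with
Bonferroni adjustment whose family size defaults to 8 (speed + seven
criteria). Correlations with clinical scales use Pearson's r tested by the
Fisher z-transformation (two-sided) — the natural reading of an "exact
test" for a correlation coefficient.

For test–retest designs, the intra-session unit is the pair of trials of
one visit (visits pooled as independent rows); the inter-session unit is
the per-session mean of the two trials, matching the session-mean line of
the chart.

## Synthetic gait

The generator is a *timing* model with minimal signal shapes, not a
biomechanical simulation. Event times come first: merged IC events on a
jittered grid (step-interval CV = stride CV·√2, so summed pairs realise
the commanded stride CV), per-side swing times solving the double-stance
and swing-asymmetry targets simultaneously, FC = next ipsilateral IC −
swing. The U-turn occupies k whole steps chosen so that the event span
minus the realised turn duration equals (step count outside the turn) ×
(step interval) — this makes commanded speed, step length, stride time and
double-stance fraction simultaneously recoverable by the pipeline's own
definitions, up to discretisation of the 20-m path into whole steps
(≲ 2%) and jitter sampling noise.

Signals: foot ML gyro carries one raised-cosine lobe per swing (300 deg/s,
scaled per side by the amplitude-asymmetry knob) plus negative troughs
(150 deg/s, 0.10 s) centred at each FC and IC — the physiological dips the
event detector's local-minimum convention expects; without them the
detector latches onto filter undershoot ~35 ms outside the swing and
double stance is biased by several points. Foot accelerations carry a
damped 15 Hz transient at each IC. Trunk accelerations are stride-locked
harmonic series via a piecewise-linear stride phase (2π per left stride):
AP/CC even-dominant, ML odd-dominant and rescaled to a commanded RMS; the
AP axis adds a band-limited (4–9 Hz) roughness component and the gyro a
small 6.5 Hz tremor-like term, both scaled by the `smoothness_noise` knob.
Trunk CC gyro adds the half-revolution raised-cosine turn pulse and an
optional constant drift. Default amplitudes were chosen so that the
default walker's 17 parameters land near the packaged healthy reference
means (all within ~1.6 reference SD across seeds); the defaults otherwise
encode a typical healthy adult: 1.10 s strides, 0.68 m steps, 2.3% stride
CV, 23.3% double stance, symmetric swings, 1.28 m/s² trunk sway, 2.62 s
U-turn.

What the generator does *not* emulate: joint kinematics, ground-reaction
dynamics, turning-step morphology, gravity leakage, sensor misalignment or
pathology-specific waveforms. Passing recovery tests therefore demonstrates
that the pipeline inverts its own measurement definitions under realistic
timing variability and noise — not that the event detector matches any
specific commercial device on clinical data.

Randomness: each trial is a pure function of its spec (one seeded
generator); cohorts derive one child seed per (seed, subject, session,
trial) tuple. With zero within-subject repeat noise the repeats of a visit
are bit-identical, so the noiseless limit gives ICC = 1 and SEM = 0
exactly.

## Rendering

Seven fixed axes (sturdiness, springiness, steadiness, stability,
smoothness, synchronization, symmetry), radial limits −4…+2 SD, dashed
black normative ring at 0, one mean polygon + translucent min–max band per
session, fill colour from a diverging red–yellow–green map of the
session's speed z-score clipped to the radial limits. Scores below the
lower limit are drawn at the limit and the session is flagged "(clipped)"
in the legend. SVG output is reproducible (fixed hash salt, no embedded
date).

## Problem sizes used in the checks

The test-suite trials are single 20-m walks (~23 s at 100 Hz, ~30 strides);
recovery sweeps use 20 seeds; reliability cohorts use 3–6 subjects × 2
repeats; the U-turn recovery check uses 20 seeded trials with drifts up to
1 deg/s. The 20-seed recovery tolerances are assessed on sweep means,
because at the default stride-time variability the *realised* per-trial
stride mean scatters around the commanded value by ~0.008 s — individual
seeds can exceed a ±0.02 s commanded-value band while the pipeline tracks
the realised gait to within ~5 ms.

## Known limitations

* The event detector is a standard foot-gyro peak/trough model, not a
  template-matching detector; heavily pathological waveforms beyond the
  generator's repertoire are untested.
* Only one stability parameter (RMS_aML) is implemented; local divergence
  exponents and similar are out of scope.
* The reference table is a single age band; no stratification.
* Parameter exclusion by reliability is reported (banding per parameter),
  not automated.
* ICC confidence intervals are not computed.
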
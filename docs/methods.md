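# Methods

This note documents the models, parameter choices and numerical
decisions behind `ecap_ipg`, in the order data flow through the
pipeline. It states no empirical result that the test suite or the
analysis scripts do not themselves compute.

## Synthetic sweep sets

Single-trial eCAPs are modeled as a smooth biphasic deflection — a
negative Gaussian lobe (N1 trough) followed by a positive one (P2 peak):

    s(t) = A_N1 · exp(−(t − t_N1)²/2σ_N1²) + A_P2 · exp(−(t − t_P2)²/2σ_P2²)

with defaults t_N1 = 300 µs, A_N1 = −200 µV, σ_N1 = 120 µs,
t_P2 = 700 µs, A_P2 = +100 µV, σ_P2 = 250 µs, sampled at 20,492 Hz over
128 samples behind a 110-µs recording delay (devices delay 98–122 µs).
Real eCAP morphology is not specified beyond an N1 trough near
200–400 µs followed by a P2 peak, so the Gaussian-lobe template is a
deliberate idealization: it exercises the phase-coherence analysis
without claiming waveform realism. Peak-to-peak amplitude (300 µV) sits
inside the realistic range for averaged eCAPs (tens of µV to ~1 mV).

Per-sweep variability has three independent components:

* latency jitter ~ Normal(0, σ_lat), default σ_lat = 20 µs, applied by
  evaluating the continuous template at shifted times — never by
  integer-sample shifting, which would quantize the jitter at the
  48.8-µs sampling step and distort the phase statistics;
* multiplicative amplitude jitter ~ Normal(1, cv), default cv = 0.1,
  floored at 0 (irrelevant to the PLV, which normalizes each phasor);
* additive white noise, default σ = 5 µV — the top of the 2–5 µV floor
  of newer recording hardware; older implants run nearer 20 µV.

Latency jitter is the mechanism that degrades phase coherence, so the
generator gives the PLV chain a controllable ground truth: the test
suite verifies that the aggregate PLV decreases in σ_lat on seeded
Monte-Carlo averages, equals 1 exactly for identical sweeps, and matches
the analytic incoherent-phase floor E|mean phasor| = sqrt(π/4N) ≈ 0.044
at N = 400.

## Phase locking value

Per trial k, frame t and analysis frequency f, the spectral estimate
F_k(f, t) is the DFT of a Hanning-tapered (periodic Hann), zero-padded
frame, read at the FFT bin nearest f. Defaults: frame 26 samples
(1268.8 µs at the 48.8-µs device resolution), pad-ratio 2 (52-point
FFT, bin spacing 20492/52 ≈ 394.08 Hz), six frequencies 788.2 to
4729.2 Hz in steps of 788.2 Hz — these land on even bins 2, 4, …, 12;
the realized bin frequencies (788.15 Hz, …) are recorded on the output
grid alongside the nominal labels.

Frame placement: the source method says only that six frames partially
overlap, so the hop defaults to 13 samples (50 % overlap), making six
frames span 91 samples ≈ 4.4 ms from the start of the record — the
window where the eCAP is expected, given that the recording delay
already excludes stimulus onset. Both `hop` and `analysis_start` are
configurable.

PLV(f, t) = |(1/N) Σ_k F_k/|F_k|| is bounded in [0, 1]; the aggregate
index is the arithmetic mean of the 36 cells. Two deliberate choices:

* taper normalization is not applied — unit-normalized phasors cannot
  see it;
* a zero-magnitude coefficient (e.g. an all-zero sweep) raises an error
  naming the (trial, frame, frequency) rather than being dropped:
  silent exclusion would bias the mean phasor.

## Scales and conversions

Device current levels map to µA through the exponential law
I = 17.5 · 100^(CL/255). The conversion is a manufacturer convention the
analyses themselves never state, so it lives in an overridable
`DeviceLaw` config and is logged with outputs. Charge per phase is
Q(nC) = I(µA) · phase(µs)/1000; dB transforms use 20·log10 for both
voltage and charge (both amplitude-like; a 10·log10 power convention can
be configured). The three analysis scales are S1 = (nC, µV),
S2 = (dB re 1 nC, µV), S3 = (dB re 1 nC, dB re 1 µV); offset variants
are labeled nC, dB_linear/log and dB_log/log respectively, and each
output carries both the label and the axis convention, because the
naming of the middle scale is ambiguous in parts of the literature. The
(nC input, dB output) combination is rejected at type construction.
Points with non-positive amplitude cannot be represented under a dB
output; they are excluded with an explicit per-point report, never
silently.

## Growth-function features

* **Threshold**: lowest *measured* level with amplitude ≥ 5 µV
  (boundary inclusive, no interpolation or fit-based refinement). When
  no point qualifies, a flagged no-threshold result propagates as a
  missing DV.
* **Overall linear slope**: OLS over points between threshold and the
  maximum comfortable level, inclusive; fewer than two points → missing.
* **Window-method maximum slope**: linear resampling to 11 equally
  spaced abscissae (piecewise-linear interpolant — monotone, no
  overshoot), then eight sliding 4-point OLS regressions; the maximum is
  kept, ties resolving to the lower-level window. Resampling happens on
  the working input scale of the requested spec; the output records
  that. The estimator approximates the sigmoid's derivative at its
  inflection while remaining usable when the measured span stops short
  of the plateau.
* **Model fits**: sigmoid y0 + a/(1 + e^(−(x−b)/c)) and saturating
  exponential y0 + a(1 − e^(−bx)) by trust-region nonlinear least
  squares; adjusted R² = 1 − (1 − R²)(n − 1)/(n − k − 1) with k = 4
  and 3.

Fit numerics. Initialization: y0 = min(y), a = range(y), b = the x
nearest the half-range crossing, c = span(x)/8. Parameters are kept in
a finite box: a > 0; c ∈ [span/1000, 2·span]; b within two spans of the
data; y0 and a within ten/a hundred amplitude ranges. Outside that box
the sigmoid degenerates into a step or a line that the data cannot
constrain, and the unbounded problem becomes a flat ridge on which the
optimizer either fails or terminates path-dependently. A solution with
c pinned at its bound is reported via `c_at_bound` — the documented
signature of near-linear data. The model's exponent is clipped at ±500
to avoid overflow at extreme trial parameters. Non-convergence never
raises; a flagged result with a reason code propagates as missing.
Tolerances: ftol = xtol = gtol = 1e-12, maxfev = 50,000.

Shape classification (log/log transition). A growth function that rises
roughly linearly from its threshold becomes concave-saturating on
log/log axes — the visual "exponential" look — because the log
compresses high amplitudes and steepens the region just above
threshold; a power-law-like function stays a straight line, and a
genuinely sigmoidal function keeps a convex low-amplitude limb. The
classifier therefore tests curvature: the S3 curve is resampled to 11
points and labeled *exponential-transitioned* when every
range-normalized second difference is ≤ margin while at least one is
< −margin (default margin 0.01 — the configurable stand-in for the
visual-inspection criterion it replaces). An adjusted-R² race between
the sigmoid and exponential fits was evaluated as the decision
statistic and rejected: the four-parameter sigmoid nests
near-exponential shapes and essentially always wins, so the comparison
does not discriminate; both fits are still computed and reported for
goodness-of-fit context. The margin also keeps noise-jagged
low-amplitude functions — whose recording noise the log/log display
accentuates — from classifying as smooth saturation, which is why
transition counts rise with amplitude relative to the noise floor even
though the noise-free classification is exactly invariant to uniform
amplitude scaling.

## Stimulation level offset

Both growth functions are normalized by the maximum measured IPG-7
amplitude (input axis untouched; IPG-42 values may exceed 1), then
re-expressed on the requested scale and fitted with the sigmoid. The
overlapping amplitude interval is the intersection of the two fitted
ranges realized over each function's measured span — the formal
definition chosen here for an informally stated concept; both endpoints
are reported for audit. Targets sit at 25/50/75 % of that interval,
taken *after* any output-log transform (so dB-scale offsets use
dB-space quantiles; recorded in the result), and each fit is inverted
in closed form, x = b − c·ln(a/(y − y0) − 1). The offset is the mean of
the three level differences with the convention

    offset = level_IPG7(y) − level_IPG42(y)   (> 0 ⇔ longer IPG more efficient).

Sigmoid inversion (not linear-segment methods) is used throughout: it
needs no manual segment selection and its fitted midpoint region is the
best-constrained part of the curve. Non-converged fits or an empty
overlap produce flagged missing results per scale, independently.

Numerical canonicalization: normalized amplitudes are rounded to nine
significant figures before fitting. eCAP amplitudes carry at most a few
meaningful digits, so this is far below measurement resolution; its
purpose is reproducibility — normalized curves that are mathematically
identical but differ in the last ulp (e.g. the forward-model curves
below under different shared factors) map to bit-identical downstream
results instead of letting a near-degenerate fit amplify roundoff.

## The quadratic forward model

The theoretical model V = r·n·(s·g·I)² (recording-electrode factor,
neuron count, stimulating-electrode factor, stimulus gain, current)
predicts that on a log input axis the level offset between two gain
conditions is exactly 20·log10(g42/g7) dB, independent of r, n and s:
the shared factors cancel in the normalization. The pipeline reproduces
the invariance exactly (bit-identical offsets across random factor
draws; tested at the 1e-9 level). The offset *value* recovered through
sigmoid inversion agrees with 20·log10(g42/g7) to about 5e-3 dB, not to
machine precision: a pure quadratic is a straight line on log/log axes,
the sigmoid is the wrong model family there, and the residual misfit
shifts the inverted quantile levels slightly. The tests assert the
value at 1e-2 dB and the invariance at 1e-9.

## Scenario presets (version 1)

The preset table is illustrative, designed to encode the qualitative
structure the analyses must resolve; it is not fitted to any patient
data. Ground truths are sigmoids on the charge axis over a measurement
grid of CL 150–210 (charge ≈ 13–39 nC at 50 µs/phase), with the IPG-42
curve left-shifted by a scenario-dependent amount and its range raised
by 5 %:

| scenario | a (µV) | b₇ (nC) | c (nC) | IPG-42 shift (nC) |
|----------|--------|---------|--------|--------------------|
| CND-like | 150 | 24 | 3.0 | 2.0 / 3.0 / 4.0 (basal/middle/apical) |
| NSCN-like | 400 | 21 | 2.0 | 0.9 (all positions) |
| GJB2-like | 550 | 20 | 1.8 | 0.8 (all positions) |

This encodes: low amplitude, shallow growth and a large, apically
increasing shift for the fiber-poor scenario; high amplitude, steep
growth and a small uniform shift for the two fiber-rich scenarios.
Measurement noise defaults to 2 µV. What passing tests show is that the
pipeline *recovers structure the generator put in* (shift recovery,
group ordering, position gradients) under realistic noise — not that
real patient groups behave this way. Real data differ in ways the
generator does not emulate: stimulus artifact, level-dependent noise,
non-sigmoidal saturation, missing levels, electrode-impedance drift.

Seeding: every generator is a pure function of (config, seed). The
study runner derives per-ear sub-seeds as the first 32-bit word of
`SeedSequence((top_seed, group_idx, subject_idx, electrode_idx, role))`
with role 0 for sweeps and 1 for I/O noise; inside the I/O generator
the IPG-7 stream is spawned before the IPG-42 stream. The end-to-end
demo study is verified to re-run byte-identically.

## Study runner and statistics

`run_study` simulates three groups × n subjects × three electrode
positions (defaults 10 subjects; the test suite uses 2–3 to stay fast),
computes PLV and all IPG-effect DVs, and writes tidy tables. Sweep
parameters are shared across groups by design: the synchrony index
tracks fiber health, and the scenarios differ in fiber count, so the
simulated PLV should *not* separate the groups. Mixed-model inference
is exported, not implemented — effects.csv carries subject, group and
electrode columns for any LMM tool. Missing DVs are excluded listwise
per (parameter, scale) and counted; nothing is imputed.

The sensitivity report classifies each DV × scale as group-sensitive
(CND-like vs GJB2-like effects separate by Mann-Whitney at a
configurable α, default 0.05), additionally location-sensitive (apical
vs basal within the CND-like group), or insensitive, with
Benjamini-Hochberg adjustment reported alongside the raw group
p-values. This three-tier label is a simulation-based mirror of how
such DVs are triaged, not a clinical claim. Spearman/Bonferroni,
Mann-Whitney (scipy, tie-handled, exact for small samples) and
Benjamini-Hochberg (statsmodels step-up) back the statistical surface;
the test suite cross-checks them against closed-form normal equations,
exhaustive rank enumeration and a direct step-up implementation.

## Problem sizes

Default problem sizes were chosen so the whole suite exercises every
path at full fidelity where it is cheap (400 sweeps for PLV, 100-draw
recovery studies, 200-replicate noise-floor checks, 1000-replicate null
calibration) and at reduced subject counts (2–3 per group) for the
end-to-end determinism runs, which are structural rather than
statistical checks. The analysis scripts run the full 10-subject demo.

## Known limitations

* The sweep template is phenomenological; PLV values from it calibrate
  the *method*, not any patient population.
* The device law is a convention; absolute nC values shift if it is
  overridden (offsets in dB do not).
* Sigmoid fits on data without visible saturation return
  bound-flagged, weakly constrained parameters by design; downstream
  consumers must honor the flags.
* The shape classifier's margin trades noise robustness against
  sensitivity to mild curvature; 0.01 of the output range is a
  reasonable default for the simulated noise floors, not a universal
  constant.
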
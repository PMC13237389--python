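# ecap-ipg

Analysis pipeline for the **interphase-gap (IPG) effect** and
**neural synchrony** in electrically evoked compound action potentials
(eCAPs) from cochlear-implant users — with a first-class synthetic-data
module, so every stage is testable and reproducible without patient data.

## The scientific problem

The eCAP is a whole-nerve response of the cochlear nerve to a biphasic
current pulse, recorded through the implant itself. Lengthening the
silent interval between the two pulse phases (the interphase gap, here
7 µs vs 42 µs) makes stimulation more efficient; how strongly a given
eCAP measure responds to that change — the IPG effect — is used as a
window on how many responsive nerve fibers sit near the electrode.
Separately, the trial-to-trial phase coherence of the raw eCAP sweeps
indexes the *health* (temporal precision) of those fibers. Comparing the
two across patient groups and electrode positions requires a pipeline
that computes, consistently and on several quantitative scales:

* **Phase locking value (PLV).** For N repeated sweeps, short-time
  Fourier spectra `F_k(f, t)` are taken on Hanning-tapered 26-sample
  frames (1268.8 µs at the 20,492-Hz device sampling rate, pad-ratio 2)
  at six frequencies from 788.2 to 4729.2 Hz, and

  `PLV(f, t) = | (1/N) Σ_k F_k(f, t) / |F_k(f, t)| |`,

  averaged over the 6 × 6 time-frequency grid into one synchrony index
  in [0, 1].

* **Growth-function features.** From each amplitude-growth (I/O)
  function: the 5-µV eCAP threshold, the maximum amplitude, the dynamic
  range, the overall linear slope (OLS between threshold and the maximum
  comfortable level), and the window-method maximum slope (resample to
  11 points, eight sliding 4-point regressions, keep the steepest).

* **Sigmoidal regression and the stimulation level offset.** Normalized
  growth functions are fitted with
  `eCAP_N = y0 + a / (1 + exp(−(x − b)/c))`; the offset is the mean
  difference in stimulation level between the two IPG conditions at 25,
  50 and 75 % of the overlapping amplitude range, obtained by closed-form
  inversion of the fits. A saturating exponential
  `y = y0 + a·(1 − e^(−bx))` is fitted alongside for goodness-of-fit
  comparison on log/log axes.

* **Quantitative scales.** Levels are converted from device current-level
  units to charge (nC) and dB re 1 nC; amplitudes to µV and dB re 1 µV.
  Slopes and offsets are computed on µV/nC, µV/dB re 1 nC and
  dB re 1 µV/dB re 1 nC (the linear-input/log-output combination is
  deliberately unsupported).

* **IPG effects and statistics.** `effect = DV_IPG42 − DV_IPG7` per
  (subject, electrode, parameter, scale), plus Spearman/Bonferroni,
  Mann-Whitney U and Benjamini-Hochberg utilities. Mixed-model group
  inference is *exported, not implemented*: the effects table is tidy
  long-format, ready for any LMM tool.

The synthetic module generates 400-sweep eCAP recordings (biphasic N1/P2
template, per-sweep latency/amplitude jitter, additive noise floor),
paired-IPG growth functions from sigmoidal ground truth with
group-scenario presets (CND-like, NSCN-like, GJB2-like) and
electrode-position gradients, and the theoretical forward model
`V = r·n·(s·g·I)²`, whose dB-scale offsets are provably independent of
the shared factors r, n, s — a property the pipeline reproduces exactly.

## Worked example

```python
import ecap_ipg as eig

# neural synchrony: 400 simulated sweeps with 20-µs latency jitter
sweeps = eig.simulate_sweeps(eig.SweepSimConfig(seed=1))
grid = eig.plv_from_sweeps(sweeps)
print(f"aggregate PLV over {grid.values.size} time-frequency cells: {grid.aggregate:.3f}")

# IPG effect: paired growth functions from the CND-like apical preset
io7, io42 = eig.simulate_io_pair(eig.scenario_config("CND", "apical", seed=1))
for label, res in eig.offset_all_scales(io7, io42).items():
    unit = "nC" if label == "nC" else "dB"
    print(f"stimulation level offset [{label}]: {res.offset:.3f} {unit}")

effects = {(r.parameter, r.scale): r.effect for r in eig.compute_ipg_effects(io7, io42)}
print(f"IPG effect on max amplitude: {effects[('max_amplitude', 'uV')]:.1f} uV")
print(f"IPG effect on threshold:     {effects[('threshold', 'nC')]:.2f} nC")
```

prints

```
aggregate PLV over 36 time-frequency cells: 0.246
stimulation level offset [nC]: 4.309 nC
stimulation level offset [dB_linear/log]: 1.664 dB
stimulation level offset [dB_log/log]: 1.853 dB
IPG effect on max amplitude: 6.3 uV
IPG effect on threshold:     -0.98 nC
```

The PLV of 0.246 reflects the 20-µs jitter and 5-µV noise floor of the
default sweep simulation (identical noise-free sweeps would give exactly
1). The positive offsets say the 42-µs IPG reaches equal normalized
amplitude at lower stimulation levels — the apical CND-like preset
encodes a 4-nC ground-truth shift, recovered here from noisy data. The
negative threshold effect points the same way: the longer gap reaches
the 5-µV criterion at lower charge.

## Analysis scripts

Numbered drivers under `analysis/` rerun the full study on synthetic
data and write their tables under `results/`:

1. `01_simulate_data.py` — sweep sets at several jitter levels; paired
   growth functions for all scenario presets.
2. `02_neural_synchrony.py` — PLV per sweep set; verifies the
   `sqrt(π/4N)` incoherent-phase floor and the monotone degradation of
   PLV with latency jitter.
3. `03_growth_function_features.py` — thresholds, amplitudes, slopes and
   shape classifications for every function.
4. `04_level_offsets.py` — offsets on all scales; noise-free recovery of
   constructed shifts; forward-model invariance demonstration.
5. `05_ipg_effect_study.py` — end-to-end demo study (3 groups × 10
   subjects × 3 electrodes) with the sensitivity report.

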
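# Methods

This note documents the models, conventions and defaults behind `neoseize`,
the design choices made where the published system description leaves the
design open, and what the synthetic-data tests do and do not establish.

## Detection pipeline

**Montage and resampling.** Input EEG is reduced to eight bipolar
derivations of the neonatal 10–20 placement (F4-C4, C4-O2, F3-C3, C3-O1,
T4-C4, C4-Cz, Cz-C3, C3-T3), low-passed at 12.8 Hz and resampled to 32 Hz.
Neonatal seizure frequencies lie in 0.5–13 Hz with dominant rhythms at
0.5–6 Hz, so a 12.8 Hz anti-alias cutoff preserves the band of interest
while permitting the 32 Hz rate. The anti-alias filter is a Hamming-window
FIR applied forward–backward (zero phase): the filter family is not fixed by
the system description, and the zero-phase choice is ours, taken so that
filtering cannot shift detected event times against the annotations. The
tap count scales as `4·fs / (15 − 12.8)` Hz, which yields > 50 dB
single-pass attenuation at 15 Hz (doubled by the two passes) and < 2%
passband error at 5 Hz. Non-integer rate ratios (e.g. 200 Hz sources) use
polyphase resampling; integer ratios decimate by slicing after filtering. A
recording already at 32 Hz passes through untouched.

**Epochs.** 8 s windows with 50% overlap (4 s hop), epochs indexed by start
time, intervals half-open. The per-epoch probability is timestamped at
*start + 4 s*, and an epoch's binary decision covers `[timestamp,
timestamp + 4 s)` — a hop-aligned convention (the published description
does not fix one). A consequence is that the first and last 4 s of a record
are covered by no decision; epoch-level scoring therefore evaluates only
the decided span.

**Features.** 55 features per (epoch, channel): 20 time-domain (amplitude
statistics, line length, zero-crossing counts, Hjorth parameters, shape
moments, nonlinear energy, derivative energies, autocorrelation decay), 23
frequency-domain (total and sub-band power in 0.5–12.8 Hz, relative powers,
peak frequency and power, spectral edges at 80/90/95%, centroid, bandwidth,
log-log slope, flatness, low/high band ratio), and 12 information-theoretic
(amplitude-histogram entropy, spectral entropy, SVD entropy and Fisher
information of the delay-embedded signal, normalized AR prediction errors
for orders 1–8). The published pipeline states the categories and the count
but not the individual features; the registry here is data (YAML-
serializable, fingerprinted), so an alternative 55-feature set can be
swapped in without code changes. Spectra come from Welch's method
(128-sample Hann segments, 50% overlap, 0.25 Hz resolution). Degenerate
zero-variance epochs produce fixed sentinels (entropies, mobility,
complexity, spectral descriptors = 0) rather than NaN. Each feature carries
a declared amplitude-scale class (invariant / linear / power) that the test
suite asserts.

**Classifier.** Features are normalized anisotropically (per-feature
z-score); the template is estimated on training data only and applied
frozen to test data. Zero-variance training features are flagged, their
standard deviation clamped to 1, and their transformed columns zeroed. The
classifier is a Gaussian-kernel SVM (defaults C = 1, `gamma='scale'`,
class-weighted for imbalance) with a Platt sigmoid fitted on internal
held-out folds (`CalibratedClassifierCV(..., ensemble=False)`), so the
probability calibration never sees its own training scores. Hyperparameters
are fixed defaults; a held-out-record grid search utility is provided but
not part of the default path, keeping the default pipeline deterministic.

**Fusion and decisions.** The classifier runs per channel (neonatal
seizures can be confined to one channel). Each channel's probability trace
is smoothed with a centered moving average (default 15 epochs = 60 s,
shrinking windows at record edges — no padding bias); the fused trace is
the per-timepoint maximum across channels. Thresholding the fused trace
(default θ = 0.5, the value fixed for clinical use) gives binary decisions;
each detected run is extended by a collar (default 32 s) on both sides,
clipped to the record, with touching runs merged. Smoothing window and
collar length are package defaults, not published values.

## Visualizations

**aEEG.** Band-pass 2–15 Hz (standard aEEG practice; the deployed filter is
not derivable from the system description), rectify, smooth with a 0.5 s
moving average, then per-15 s display step take the maximum and minimum of
the smoothed amplitude. Display mapping: `d(x) = x` for x ≤ 10 μV and
`d(x) = 10·(1 + log10(x/10))` for 10 < x ≤ 100 μV — the unique continuous
piecewise map that is linear with unit slope below the 10 μV breakpoint and
spans the 10–100 μV decade over the same display height; values above
100 μV clip to the ceiling.

**Traces.** The probability trace is drawn blue below the threshold and red
above, segmented exactly at crossings; the binary trace is a 0/1 step plot
equal pointwise to the decision vector.

**Colormap.** Per-channel probabilities are quantized as
`bin = min(floor(10·p), 9)` into 10 diverging colours (cold blue 0 →
neutral white 0.5 → warm red 1). The top bin is right-closed (p = 1 → bin
9); p = 0.5 falls in bin 5. Exact RGB values are a configuration artifact.

## Audification

The 32 Hz EEG is stretched ×100 by a phase vocoder (64-sample ≈ 2 s
periodic-Hann window, 16-sample hop, 75% overlap, phase-propagation
resynthesis with linear magnitude interpolation over the fractional
analysis position) and written at 32 kHz: frequencies map 0.5–13 Hz →
0.5–13 kHz and one hour of EEG plays in six minutes. The output length is
trimmed/padded to exactly `round(n·factor)` samples so the duration law is
exact. STFT internals use single precision (audio-rate output does not
benefit from double).

Stereo channels correspond to brain hemispheres; per hemisphere the bipolar
channel with the highest cumulative (whole-segment sum) seizure probability
is selected, ties broken by montage order. Midline-involving derivations
(C4-Cz, Cz-C3) follow their lateral electrode. The sample gain is
`floor + (1 − floor)·p(t)` with floor 0.2 and p linearly interpolated from
the 4 s epoch grid — the gain law itself is unspecified upstream; this
affine form keeps background audible while accentuating suspicious
segments. By default p is the selected channel's own probability (the fused
trace is selectable). Channels are peak-normalized jointly, so no sample
exceeds |1| and left/right relative loudness is preserved; output is PCM16
WAV.

## Metrics

Epoch-level ("seizure burden") confusion is computed from exact interval
intersections over the decided span — equivalent to a fractionally-weighted
4 s epoch grid, and exact for annotations that do not align to the grid.
Event-level scoring uses the any-overlap rule: a true seizure is detected
iff some detected event overlaps it; a detected event is false iff it
overlaps no true seizure; FD/h is false events per recorded hour.

From an N-threshold × M-patient sweep of sensitivity/specificity matrices,
the AUC is computed in both orders: per patient then averaged (summarising
the discriminability of the probabilistic display), and pooled —
SE/SP averaged across patients per threshold, then one AUC (summarising
what a shared fixed threshold, i.e. a binary display, achieves). Both use
trapezoidal integration augmented with the forced endpoints (SE 1, SP 0)
and (SE 0, SP 1) so the curve spans the unit square; `endpoints=False`
reproduces the literal truncated-grid sums. With calibration-shifted but
individually perfect patients, the pooled order is strictly smaller — a
property test asserts this over random shifts.

The threshold-selection guide reports, per threshold, the mean good
detection rate across patients and the upper bound of the 95% CI of mean
FD/h via a seeded percentile bootstrap over patients (2000 resamples;
normal approximation behind a flag; CI undefined for a single patient).
Whether GDR should be scored pre- or post-collar is not fixed upstream; the
guide takes the collar as a parameter so both are available.

## Synthetic data

The generator emulates multi-channel neonatal EEG only to first order:
per-channel 1/f ("pink") noise background (spectral shaping of white
Gaussian noise, DC removed, power floor at 0.5 Hz) scaled to 30 μV RMS, and
seizures as Hann-enveloped sinusoids at a dominant frequency drawn from
0.5–6 Hz with an optional half-amplitude second harmonic, 100 μV peak by
default, on an explicit channel subset (focal through generalized). Cohort
records (default 6 × 600 s) carry three non-overlapping events of 40–90 s
separated by ≥ 30 s. These amplitudes make the in-band (0.5–6 Hz) power of
a seizure segment ≥ 3× background on affected channels — strong, clearly
rhythmic discharges.

What passing tests show: the pipeline's machinery is correct (montage
arithmetic, filter specs, epoch bookkeeping, feature conventions,
calibration and fusion plumbing, metric identities, audio laws), and the
detector generalizes across held-out synthetic records. What they do not
show: performance on clinical EEG. Real neonatal background is
non-stationary and artefact-laden (respiration, ECG, electrode movement),
real discharges are non-sinusoidal and evolve in frequency and morphology,
and none of that is simulated. Published clinical figures (mean AUC ≈
95–97% over 1479–2540 h cohorts) require the clinical datasets and are out
of scope here.

## Problem sizes and numerical choices

The test suite evaluates the cohort at 6 records × 600 s (≈ 1 h of 8-channel
EEG) with leave-one-record-out training, chosen as the smallest cohort that
exercises cross-record generalization; training subsamples to at most 4000
(epoch, channel) vectors, stratified by class. The acceptance script
audifies a full simulated hour at 32 Hz. EDF I/O uses 16-bit samples over
±500 μV (quantization step ≈ 0.015 μV); the writer requires integer
sampling rates and truncates to whole 1 s records. Oracle comparisons are
asserted to 1e-9; phase-vocoder linearity to single-precision rounding.

## Known limitations

* The 55-feature registry is a documented stand-in at the stated
  category/count contract, not a replication of the original feature set.
* The EDF writer covers the subset of EDF needed here (one header, uniform
  integer rates, no annotations channel).
* The aEEG band, smoothing and display-step defaults follow common aEEG
  practice and are configurable, not vendor-matched.
* Event placement in the cohort generator is greedy-random; extremely dense
  seizure configurations may place fewer events than requested.
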
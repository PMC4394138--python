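# neoseize

A decision-support toolkit for **automated neonatal seizure detection on
multi-channel EEG**, aimed at engineers and clinical researchers who need a
complete, testable reference implementation of the cot-side pipeline:
detector, bedside visualizations, EEG audification, and the evaluation
metrics that connect display choices to reported performance.

Neonatal seizures are mostly electrographic-only — invisible at the cot
side — and continuous EEG needs expertise that is rarely available around
the clock. The pipeline implemented here supports that decision:

1. **Detector** — eight bipolar derivations (F4-C4 … C3-T3) → anti-aliased
   resampling to 32 Hz (12.8 Hz cutoff) → 8 s epochs with 50% overlap → a
   55-feature vector per epoch and channel (time, frequency and
   information-theory descriptors) → per-feature z-score normalization with
   a frozen training template → Gaussian-kernel SVM applied separately to
   each channel → sigmoid (Platt) probabilities → centered moving-average
   smoothing → fused trace as the per-epoch **max across channels** →
   threshold θ (default 0.5) → "collar" extension of each detection.
2. **Displays** — amplitude-integrated EEG (semilog scale, linear 0–10 μV,
   logarithmic 10–100 μV), the binary 0/1 trace, the probability trace
   (blue below / red above threshold), and a 10-colour blue–white–red
   spatio-temporal colormap of per-channel probabilities.
3. **Audification** — phase-vocoder time stretch ×100 rendered at 32 kHz
   (0.5–13 Hz → 0.5–13 kHz; 1 h of EEG plays in 6 min), stereo with one
   channel per hemisphere chosen by cumulative seizure probability, sample
   gain driven by the detector's probability.
4. **Metrics** — epoch/event/patient-level scores, the good-detection-rate
   vs false-detections-per-hour threshold guide with a bootstrap 95% CI
   upper bound, and the **two AUC computation orders**: per-patient AUCs
   averaged, versus SE/SP averaged across patients before one AUC,

   AUC₁ = (1/M) Σⱼ Σᵢ (SPᵢⱼ − SPᵢ₋₁ⱼ)(SEᵢⱼ + SEᵢ₋₁ⱼ)/2,
   AUC₂ = Σᵢ (S̄Pᵢ − S̄Pᵢ₋₁)(S̄Eᵢ + S̄Eᵢ₋₁)/2,

   which coincide for one patient but diverge (AUC₂ ≤ AUC₁) when patients'
   probability traces sit at shifted operating levels — the reason the
   correct reporting order depends on whether a binary or probabilistic
   display is deployed.

Everything runs on synthetic data: a first-class simulator generates pink-
noise background EEG with Hann-enveloped rhythmic discharges (dominant
frequency 0.5–6 Hz) on chosen channels, with ground-truth annotations.

## Worked example

Run the full pipeline on a simulated six-record cohort (leave-one-record-out
training, ~600 s per record):

```bash
neoseize run --seed 1 --out out/
```

which prints

```
AUC per-patient 0.9944, pooled 0.9938
```

and writes to `out/`: per-record probability and decision CSVs,
`threshold_guide.csv` (θ, mean GDR, mean FD/h, upper 95% CI of FD/h),
`report.json`, a four-panel display figure and a stereo WAV of the first
record. In `report.json` for this seed every record shows
`gdr_pct: 100.0, fd_per_h: 0.0` (all 18 simulated seizures detected at
θ = 0.5 with no false detections), the two AUC orders are
`auc_per_patient_mean: 0.9944` and `auc_pooled_thresholds: 0.9938`, and
`audio_duration_s: 60.0` — a 600 s record plays in 60 s of audio, the
tenfold real-time speed-up of the audification design.

The stages are also available as composable subcommands operating on files
(`simulate`, `train`, `detect`, `render`, `audify`, `evaluate`) and as a
library API (`neoseize.simulate_recording`, `train_model`,
`predict_probabilities`, `binarize`, `compute_aeeg`, `render_stereo`,
`auc_per_patient_mean`, …). See `docs/methods.md` for models, parameter
defaults and their rationale.

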
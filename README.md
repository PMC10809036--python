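# szdetect

Automated detection of seizure-related events in two-photon calcium imaging
with simultaneous EEG: pre-ictal spikes (PIS), seizure-wavefront invasion and
terminal spreading waves, at both population and single-cell level, plus
evaluation metrics and traveling-wave propagation modeling.

The detection strategy works from population signals down to single cells:

1. **Preprocess** raw Suite2p-convention fluorescence traces: background
   subtraction (global neuropil minimum as proxy), 70% neuropil correction and
   ΔF/F0 normalization against the first 30 s.
2. **EEG spike-wave discharges**: robust amplitude-threshold candidates, a
   Welch spectral-power-ratio exclusion (3–15 Hz vs subsequent 20–55 Hz,
   ratio ≥ 20), and matched-kernel recovery of missed low-amplitude spikes.
3. **Population seeds**: zero-phase 1 Hz Butterworth filtering, positive-slope
   segments scored by the *slope-integral* feature, a Gaussian model-spike
   threshold, EEG reconciliation within 0.2 s (PIS), and half-max interval
   integrals for seizure / terminal-wave onsets.
4. **Per-cell recruitment**: seed-guided detection using top-ranked
   slope-integral segments (PIS: 1.5-s window, 4σ peak rule; wavefronts:
   Gaussian-weighted features with σ = 1 s / 5 s, 20% before/after signal
   increase over 10-s / 5-s windows).
5. **Evaluation**: 1-s tolerance event matching, accuracy and F1 (geometric
   mean of precision and recall), a simulated-Poisson chance baseline, and a
   pre-ictal SNR metric with SNR-vs-F1 regression.
6. **Wave model**: L1-regularized spatial plane regression of recruitment
   times → propagation velocity, direction and a spatial-shuffle p-value.

A fully parameterized synthetic-recording generator (`szdetect.synthetic_data`)
plants all of these events with exported ground truth, so the entire pipeline
is testable offline.

## Command-line usage

```bash
# generate a synthetic recording with ground truth
szdetect simulate --out fixture/ --seed 1 --n-cells 30

# run the full detection pipeline (Suite2p directory + EEG CSV/EDF)
szdetect detect --calcium fixture/ --eeg fixture/eeg.csv --out results/

# compare against manual labels (event_type,time_s[,cell] CSV)
szdetect evaluate --detected results/events.csv --labels labels.csv \
    --out metrics.json --duration 700

# fit a traveling-wave plane to per-cell recruitment times
szdetect wavefit --recruitment results/recruitment.csv \
    --positions fixture/positions.npy --out wave.json
```

`detect` writes `events.csv` (population event times with provenance),
`recruitment.csv` (per cell × event recruitment), and `run_log.json` (full
configuration, config hash and adaptive choices). All tunables can be
overridden via `--config config.yaml`; defaults equal the published values.

## Layout

- `szdetect.signal_core` — normalization, zero-phase low-pass filter,
  positive-slope segments / slope-integral feature
- `szdetect.eeg_events` — EEG SWD detection (threshold, spectral ratio,
  kernel recovery)
- `szdetect.population_events` — PIS reconciliation and wavefront seeds
- `szdetect.cell_recruitment` — per-cell seed-guided recruitment
- `szdetect.evaluation` — matching, accuracy/F1, Poisson baseline, SNR
- `szdetect.wave_model` — plane regression, velocity/angle, shuffle test
- `szdetect.synthetic_data` — synthetic recordings + ground truth
- `szdetect.cli_io` — readers/writers, configuration, pipeline, CLI
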
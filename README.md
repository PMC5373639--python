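# spikephase

Phase distortion of extracellular spike waveforms: simulation, measurement,
detection impact, and correction.

High-pass filtering is a standard pre-processing step for extracellular
recordings, and most acquisition hardware and analysis software applies
causal filters (e.g. Butterworth) whose *nonlinear phase response* delays
different frequencies by different amounts. This package provides the full
tool chain to study and undo that effect:

- **`spikephase.synth`** — ground-truth simulation: homogeneous Poisson
  spike trains with a 1 ms absolute refractory period, convolved with a
  trough-dominant spike template of controllable half-height width, summed
  with pink (1/f) noise at a target SNR (template peak / noise std).
- **`spikephase.filters`** — the three phase classes of band-pass filter:
  causal Butterworth (nonlinear phase, `NLP`), its forward–backward
  application (zero phase, `ZP`), and a symmetric Hamming-window FIR
  (linear phase, `LP`); plus magnitude/phase/group-delay characterization.
- **`spikephase.metrics`** — spike-triggered mean waveforms with shared
  timestamps, normalized Euclidean waveform distance, SNR, robust noise
  estimation, and DFT-based sinusoid reconstruction of the 2 ms / 88-sample
  waveform window.
- **`spikephase.detection`** — threshold-crossing detection, α/β error
  probabilities against ground truth, ROC curves, and detection error
  (1 − AUC).
- **`spikephase.correction`** — reversed refiltering (reverse → refilter →
  reverse) to cancel the phase response of a known causal filter, for
  continuous signals and for threshold-crossing segments with boundary
  expansion (zeros / constant / linear / mirror), plus parameter sweeps.
- **`spikephase.io`** — language-neutral artifacts: float32 binary + JSON
  sidecar for signals, CSV for events/segments, YAML for filter specs.
- **`spikephase.cli` / `spikephase.experiments`** — a `spikephase` command
  with end-to-end experiment recipes.

## CLI quick start

```sh
# simulate 10 s at SNR 2.7 and write signal + ground truth + template
spikephase simulate --duration 10 --snr 2.7 --width-ms 0.4 --seed 1 --out out/sim

# filter it three ways
spikephase filter --in out/sim.f32 --out out/nlp.f32 --phase-class nlp
spikephase filter --in out/sim.f32 --out out/zp.f32  --phase-class zp
spikephase filter --in out/sim.f32 --out out/lp.f32  --phase-class lp

# waveform metrics, detection, ROC
spikephase measure --signal out/nlp.f32 --events out/sim_truth.csv --out out/metrics.json
spikephase detect --signal out/nlp.f32 --out out/detected.csv
spikephase roc --signal out/nlp.f32 --truth out/sim_truth.csv --out out/roc.csv

# undo the NLP phase distortion of a continuous recording
spikephase correct --mode continuous --signal out/nlp.f32 --out out/corrected.f32

# sweeps and figure-style recipes
spikephase sweep --vary width --grid 0.2,0.4,0.8 --out out/width.csv
spikephase experiment segment_correction --out-dir out/fig5 --seed 0
```

Recipes: `phase_demo`, `width_sweep`, `cutoff_sweep`, `roc_sweep`,
`continuous_correction`, `segment_correction`.

## Conventions

- Times are seconds (float64); sample indices are 0-based; segment windows
  are half-open in samples.
- Default sampling rate 44 kHz (88 samples per 2 ms waveform window).
- Spike timestamps mark the template trough (`align_index`); waveform
  windows default to 0.5 ms before / 1.5 ms after the timestamp.
- Detection polarity defaults to negative-going (extracellular troughs).
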
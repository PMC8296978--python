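# entrack

Envelope-tracking cross-correlation and representational similarity
analysis (RSA) for comparing human EEG dynamics with the hidden-layer
dynamics of a speech-recognition recurrent network.

The package implements, as a tested reusable pipeline:

- **Stimulus preprocessing** (`entrack.signal_prep`): amplitude envelope
  via the Hilbert transform, 25 Hz least-squares FIR low-pass,
  downsampling, first derivative, half-wave rectification, and unit-area
  normalization; zero-phase FIR band filters (least-squares and
  Gaussian-response kinds); anti-aliased resampling; epoch averaging;
  WAV I/O and log-mel features.
- **Network activations** (`entrack.activations`): unit x frame
  activation containers (HDF5), and untrained surrogate networks
  matching the analyzed architecture — three clipped-ReLU layers, a
  unidirectional LSTM, and a final clipped-ReLU layer — with seeded
  random weights and reproducible ensembles.
- **Envelope tracking** (`entrack.tracking`): raw (unnormalized)
  stimulus-response cross-correlograms over signed lags, matched and
  null (non-matching stimulus) pairings, 20th-percentile node selection,
  peak extraction near 140/220 ms, and paired / two-sample peak tests.
- **RSA** (`entrack.rsa`): Euclidean RDMs (per repetition, averaged, per
  participant), Spearman RDM comparison over the lower triangle,
  per-layer trained-vs-untrained profiles, 2 Hz band-resolved RSA,
  per-electrode RSA with significance masking, noise-ceiling bounds,
  and the rank-[0,1] display transform.
- **Synthetic data** (`entrack.synthetic`): seeded generators for
  syllable-rate amplitude-modulated stimuli (5.5-6.5 s), 128-channel
  EEG epochs (-700...+7800 ms at 250 Hz) with a lagged biphasic
  envelope-following response plus 1/f noise, and five layers of
  "trained" / "untrained ensemble" network activations with configurable
  per-layer envelope-tracking gain and lag.
- **Pipeline** (`entrack.pipeline`, `entrack.cli`): configuration,
  orchestration, and CSV/JSON outputs; end-to-end deterministic from a
  config + master seed.

## CLI

```bash
# generate synthetic stimuli, EEG, and activations (plus seed manifest)
entrack synth --profile test --seed 1 --out out/

# cross-correlation analysis: correlograms.csv, peaks.csv, peak_tests.json
entrack tracking --profile test --seed 1 --out out/

# RSA: layer_profile.csv, band_rsa.csv, electrode_map.csv,
# rdm_*.csv, rsa_summary.json
entrack rsa --profile test --seed 1 --out out/

# everything in sequence
entrack all --profile test --seed 1 --out out/
```

Profiles: `test` (small counts, minutes on one CPU) and `full`
(study-scale: 25 stimuli, 15 participants, 4 repetitions, 128 channels,
100 untrained networks). Flags override entries of an optional YAML
config (`--config cfg.yaml`); any `RunConfig` field may appear at top
level and any `SyntheticConfig` field under `synth:`.

The analysis stages regenerate synthetic data deterministically from the
manifest written by `synth` (all generators are pure functions of
config + seed). The containers written by `synth` — WAV stimuli, HDF5
activation and EEG containers — are the interchange surface for real
data via the library API (`entrack.activations.read_activation_container`,
`entrack.signal_prep.EEGEpoch`). In the `full` profile the bulk EEG
container (~GBs) is skipped unless `write_eeg_container: true`.

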
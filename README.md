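# thetasync

Analysis pipeline for coexisting theta generators in laminar hippocampal
LFP recordings, exercised end-to-end on a synthetic ground-truth generator:

- **synthetic data** (`thetasync.synth`): theta-plus-pink-noise calibration
  model, a multichannel laminar forward model (three current generators with
  fixed depth loadings, asymmetric theta waveforms, pathway-specific gamma
  bursts phase-locked to the local theta, switching high/low phase-lock
  states), a directional theta-gamma fixture with a known lead/lag, and a
  speed covariate with prescribed correlation to theta power.
- **recording I/O + preprocessing** (`thetasync.recording`): flat binary +
  JSON sidecar format, minimal read-only EDF loader, and the preprocessing
  chain (300 Hz low-pass, 50/100 Hz notches, decimation to 2.5 kHz then
  625 Hz, per-signal z-normalization).
- **CSD** (`thetasync.csd`): one-dimensional second-spatial-difference
  current source density (sigma = 350 ohm^-1 cm^-1, h = 100 um), for raw
  and component-reconstructed LFPs.
- **source separation** (`thetasync.decompose`): PCA-reduced ICA (99%
  variance kept plus two extra components), component selection by variance
  share (>1%) and loading stability across epochs, greedy component
  matching, rank-1 partial-LFP reconstruction, band-split validation.
- **spectral tools** (`thetasync.spectral`): multitaper PSD, FIR + Hilbert
  band envelopes/power, coherence with circular-shift surrogate thresholds,
  gamma-amplitude-by-theta-phase distributions.
- **theta cycles** (`thetasync.cycles`): waveform-aware phase (narrowband
  zero crossings + broadband extrema, piecewise-linear phase), sliding
  one-cycle theta/delta ratio validity (threshold 4), rise/decay and
  peak/trough asymmetry, and the amplitude-sweep calibration that locates
  the ratio at which noise-attributable trough error crosses 1 ms.
- **phase synchronization** (`thetasync.icpc`): inter-cycle phase clustering
  (static, per-cycle 3-cycle dynamic, lag variability, ICPC-binned feature
  correlations with surrogate significance).
- **cross-frequency coupling** (`thetasync.cfc`): entropy-based modulation
  index on equalized (per-quadrant equal-time) phase bins, mean vector
  length, comodulograms, cut-and-swap surrogates, and cross-frequency
  directionality via the phase-slope index with two-tailed surrogate bounds
  and MI masking.
- **regression** (`thetasync.regression`): mid-rank multiple linear
  regression with refit-based partial-variance decomposition and
  Bonferroni-corrected group beta tests.
- **pipeline + CLI** (`thetasync.pipeline`, `thetasync.cli`): one config
  drives simulate/ingest -> preprocess -> decompose -> cycles -> ICPC ->
  CFC/CFD -> regression with logging and seeded reproducibility.

## CLI

```sh
thetasync simulate --preset laminar --seed 1 --duration 60 --out fixtures/lam
thetasync preprocess --in fixtures/lam.f32 --sidecar fixtures/lam.json --out fixtures/pre
thetasync decompose --in fixtures/pre.f32 --sidecar fixtures/pre.json --out out/dec
thetasync cycles --in fixtures/pre.f32 --sidecar fixtures/pre.json --out out/cycles.tsv
thetasync icpc --decomposition out/dec --reference 0 --out out/icpc.tsv
thetasync cfc --in fixtures/pre.f32 --sidecar fixtures/pre.json --mode comodulogram --out out/mi.tsv
thetasync run --preset laminar --seed 1 --out out/run
```

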
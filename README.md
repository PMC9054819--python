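# fiberquant

Analysis pipeline for in-vivo fiber-photometry calcium recordings with
behaviour-gated metrics, plus histological perineuronal-net (PNN)
quantification and bootstrap effect-size estimation. Every input kind the
pipeline consumes can be simulated with known ground truth, so the whole
chain is testable offline.

## What it does

- **Synthetic data** (`fiberquant.synthetic_data`) — ground-truthed
  generators for frame-interleaved two-channel photometry sessions
  (biexponential photobleaching, difference-of-exponential calcium
  transients, shared motion artifacts, noise), alternating
  freezing/moving behaviour bouts, ring-shaped PNN image stacks with
  controllable fragmentation, and two-group samples with a known effect
  size.
- **I/O** (`fiberquant.io_formats`) — frame-interleaved photometry CSV
  (FrameCounter/Timestamp/LedState/Fluorescence, with both `{1,2}` and
  `{415,470}` LED encodings), behaviour CSV (Time/Freezing), and
  deinterleaving of the 40 FPS alternating-LED stream into aligned
  470/415 channels at the 20 Hz effective rate.
- **dF/F** (`fiberquant.dff_pipeline`) — biexponential bleach fit of the
  isosbestic 415 nm channel, OLS scaling of the fitted curve (or raw 415)
  onto the 470 nm signal, `(F - scaled)/scaled` normalization, and a
  home-cage baseline shift that lifts the test-session minimum onto the
  home-cage mean (middle 3 min of a 5-min baseline by default).
- **Behaviour alignment** (`fiberquant.behavior_align`) — nearest-timestamp
  labelling of photometry frames, TTL-based clock zeroing, and epoch
  extraction with a minimum bout duration (default 2 s; shorter runs are
  dropped, not merged).
- **Metrics** (`fiberquant.metrics`) — positive-part AUC (total and
  normalized per behaviour state), peak detection at median + 2 SD of the
  session, peak frequency per state, mean peak height.
- **PNN quantification** (`fiberquant.pnn_quant`) — top-half maximum
  projection of calibrated TIFF z-stacks, IsoData (iterative intermeans)
  thresholding within a traced ROI, largest-connected-component surface
  contiguity (8-connectivity), and density in cells/mm².
- **Estimation statistics** (`fiberquant.estimation_stats`) — pooled-SD
  Cohen's d with 5000-resample bootstrap and 95% BCa confidence intervals,
  independent multiple two-group comparisons with order-stable per-label
  seeding.

## CLI

All stages are exposed through one entry point (also `python -m fiberquant`):

```sh
fiberquant simulate photometry --seed 1 --out data/        # + behavior|pnn|groups
fiberquant dff --photometry data/photometry.csv --homecage hc/photometry.csv --out trace.tsv
fiberquant epochs --behavior data/behavior.csv --trace trace.tsv --min-bout 2 --out epochs.json
fiberquant metrics --trace trace.tsv --epochs epochs.json --out metrics.tsv
fiberquant pnn contiguity --stack data/pnn_stack.tif --roi data/pnn_rois.json --out contig.json
fiberquant pnn density --count 10 --area-mm2 0.5
fiberquant effects --data values.tsv --resamples 5000 --ci 0.95 --seed 7 --out effects.json
fiberquant run --config run.yaml --seed 1 --out-dir out/   # full pipeline + manifest
```

`run` executes simulate → dff → epochs → metrics → effects from a single
YAML config (unknown keys rejected), writing a `manifest.json` with a
checksum for every output; reruns with the same seed are bit-identical.

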
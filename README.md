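# redoximg

Analysis toolkit for dual-emission autofluorescence microscopy in which two
spectral bands (451 nm and 560 nm) of the same field of view are projected
side by side onto a single camera frame ("split-FOV" acquisition). The
package covers the full path from raw split-frame TIFF stacks to
biologically interpretable quantities:

* **`redoximg.simulate`** — synthetic split-FOV time-lapse generator with
  full ground truth: elliptical cell phantoms (dim nucleus, bright
  cytoplasm, mitochondrial puncta), intensity scaling linear in
  illumination power x exposure, monoexponential photobleaching with
  per-cell rate spread, Poisson shot noise + Gaussian read noise, and
  cyanide-like or glucose-bolus perturbations.
* **`redoximg.image_io`** — multi-page grayscale TIFF I/O, acquisition
  metadata (power / exposure / frame rate / layout), frame splitting, and
  integer-pixel channel registration by normalized cross-correlation.
* **`redoximg.segmentation`** — background thresholding (fixed /
  percentile / Otsu), connected-component cell labeling with hole filling,
  and static ROI propagation across frames and channels.
* **`redoximg.metrics`** — optical redox ratio `451 / (451 + 560)` at the
  image and cell level, first/last-window photobleaching percent change
  (both sign conventions), contrast/ratio SNR, and per-frame ROI trace
  extraction.
* **`redoximg.dynamics`** — stimulus-response kinetics per cell: baseline
  drift, onset delay (threshold crossing with piecewise ramp/step
  refinement), rise rate, and time to peak.
* **`redoximg.stats`** — Shapiro-Wilk-gated two-group comparison
  (Student's t-test or Mann-Whitney U at alpha = 0.05) with figure-style
  star annotations.
* **`redoximg.pipeline`** — end-to-end experiment replications (group ORR
  comparison, photobleaching sweep, dynamic stimulus run) producing tidy
  CSV tables and a YAML run manifest.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (printed-table
reproduction, ORR algebra properties, oracle equivalence of Otsu /
registration / masked means, seeded parameter recovery on simulated stacks,
and statistical calibration). The simulation-recovery tests take a couple
of minutes; everything else is fast.

## CLI

```sh
redoximg simulate -c sim.yaml -o stack.tif --truth-dir truth/
redoximg split stack.tif -o channels/
redoximg segment stack.tif -o mask.tif
redoximg orr stack.tif
redoximg bleach stack.tif -o bleach.csv
redoximg dynamics stack.tif --stimulus-time 8.0 -o kinetics.csv
redoximg compare control.csv treated.csv --column orr
redoximg run -c experiment.yaml -o results/
```

`sim.yaml` maps directly onto `SimulationConfig` fields, and
`experiment.yaml` onto `ExperimentConfig` (see `tests/test_pipeline.py` for
working examples of both).

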
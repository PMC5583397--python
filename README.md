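# beatflow

Non-invasive, optical-flow based analysis of cardiomyocyte contractility
in time-lapse brightfield/phase-contrast recordings:

* **piv** — two-pass block-matching optical flow (64-px tiles searched
  over ±32 px, thin-plate-spline denoising, then 32-px tiles over ±4 px
  around the coarse prediction). Integer-pixel displacements, exactly
  equivalent to brute-force scoring of every shift.
* **kinetics** — average-motility traces V(t), Δ-prominent alternating
  extrema detection, reference-frame displacement patterns U(t)
  synthesized over optimal (relaxed) reference frames, and beat
  frequency with a frame-rate reliability flag.
* **convergence** — convergence C = −∇·u by central differences, noise
  suppression (spatial median filter, recursive temporal high-pass,
  local-contrast weighting), thresholded contractility maps s*,
  tile-based covariance readout and radial profiles.
* **mechanics** — isotropic linear-elastic sheet with active isotropic
  stress and optional elastic substrate drag: closed-form free-sheet
  and modified-Bessel (I₁/K₁) solutions of a uniformly contracting
  core, plus kernel-convolution displacement/convergence responses for
  arbitrary contractility distributions.
* **synthetic** — ground-truth-annotated beating-monolayer movies:
  band-limited textures warped by mechanics displacement fields under a
  swift-contraction / exponential-relaxation waveform, with optional
  read noise, cell-free regions and drifting debris.
* **stackio / pipeline / cli** — TIFF & image-directory readers,
  lossless CSV writers, a JSON run configuration and the umbrella
  `beatflow` command.

## CLI

```sh
beatflow simulate-movie --size 256 --frames 300 --fps 10 --out movie.tif
beatflow flow     --input movie.tif --consecutive --out flow.csv
beatflow beats    --input movie.tif --fps 10 --out beats.csv
beatflow converge --input movie.tif --q 0.9 --median 1 --contrast-window 16 --out sstar.csv
beatflow tilecorr --map sstar.csv --image movie.tif --tile 64
beatflow radial   --k 1.0 --out profile.csv
beatflow run      --input movie.tif --out results/
```

Exit codes: 0 success, 2 input error, 3 processing error.

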
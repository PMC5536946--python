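# nanopack

Quantification toolkit for membrane-protein nanocluster packing.

Many plasma-membrane proteins — the SNARE protein syntaxin 1A is the model
case — organize into nanoclusters of ~50–75 molecules and 50–60 nm diameter
at densities of 14–19 clusters/µm².  How tightly the molecules pack inside a
cluster is invisible to direct super-resolution imaging, but it leaves
quantitative fingerprints: packing restricts lateral mobility (slower FRAP
recovery), and it sterically shields epitopes so that antibody staining
under-reports densely packed pools.  `nanopack` implements the full analysis
stack for these readouts, together with a synthetic-data layer that generates
every input with known ground truth:

* **`nanopack.simulate`** — clustered molecule fields (Poisson cluster
  process), antibody labelling as random sequential adsorption with a hard
  exclusion footprint, confocal/STED image rendering (Gaussian PSF, Poisson +
  read noise), a finite-difference diffusion FRAP simulator, pH-quench image
  pairs, x-z slice stacks and paired EF/WB tables.
* **`nanopack.spots`** — STED membrane-sheet morphometry: difference-of-
  Gaussians filtering, local-maxima spot detection, circular-ROI intensities
  with a weak-spot gate, Gaussian line-scan sizing
  (FWHM = 2√(2 ln 2)·σ·pixel) with R² ≥ 0.9 and nearest-neighbour gates, and
  per-sheet summaries against the confocal channel.
* **`nanopack.frap`** — trace extraction with background correction, ±15%
  focus-drift QC, hyperbola-with-offset fitting
  F(t) = F₀ + A·t/(t½ + t) with an R² ≥ 0.7 acceptance rule, trace
  averaging, and half-time vs expression-level statistics.
* **`nanopack.localization`** — per-cell pH 4.3 / pH 7.4 quench ratios, and
  cytosolic fractions from membrane contours expanded ±5 px, with 6%
  channel bleed-through correction.
* **`nanopack.accessibility`** — thresholded epifluorescence per cell with
  DAPI nucleus counting, EF/WB ratio-of-ratios accessibility quantification,
  and the toxin co-expression comparison with autofluorescence gating and
  size-corrected intensities.

The package is a library: import it from Python, or start from the short
narrative scripts in `examples/` (one per capability).

## Worked example

```bash
$ python examples/sted_spot_morphometry.py
true clusters:        220  (17.0 /um^2)
detected spots:       220  (17.0 /um^2)
mean spot intensity:  300.2 a.u.
mean spot size:       70.1 nm (from 182 size-eligible spots)
bound antibodies:     2318 of 13824 epitopes
```

A synthetic membrane sheet is generated at ~16 clusters/µm², stained in
silico (note that only ~17% of epitopes carry an antibody — steric
shielding inside 55 nm clusters), rendered as a confocal/STED pair and run
through the spot pipeline.  The recovered density matches the generated
field, and the ~70 nm mean size is the 50–60 nm cluster convolved with the
60 nm STED point-spread function.

```bash
$ python examples/frap_half_time.py
drift over recording: 0.04 %  (retained; limit 15 %)
half-time of recovery: 20.6 s  (R^2 = 0.9976, accepted)
true diffusion coefficient: 0.1 um^2/s
```

The recovery half-time is inversely proportional to the lateral diffusion
coefficient, so relative half-times compare mobilities across constructs.

```bash
$ python examples/efwb_accessibility.py
...
arithmetic mean +- SEM:  3.14 +- 0.39
geometric mean:          2.86   (truth 3.0)
paired t-test (non-normalized ratios): t = 2.65, p = 0.0200
```

Fourteen simulated transfection pairs with wild batch-to-batch variation
still recover the 3-fold accessibility difference, because the per-pair
EF/WB ratio-of-ratios cancels every multiplicative nuisance.

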
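# phenodiel

Diel-cycle phenotyping of plant rosettes from top-view time-lapse imagery.

Growth of *Arabidopsis*-style rosettes is not constant over the 24-h
light/dark cycle: expansion rate rises and falls with the photoperiod, and
leaf movement at dawn transiently shrinks the projected outline.  Measuring
this requires segmenting every frame of a multi-day time lapse — RGB frames
during the light period (**VIS**) and near-infrared grayscale frames during
the dark period (**NIR**) — and turning per-plant areas into growth rates.
`phenodiel` is a library (plus a thin CLI) for exactly that workflow, aimed at
plant scientists running low-cost top-view imaging rigs.

## Method

- **VIS segmentation** — per-channel range thresholding in RGB, HSV or CIELAB
  (or grayscale Otsu), followed by speckle removal and hole filling.  Plants
  are numbered left to right, or from user-supplied seed coordinates.
- **NIR segmentation** — colour gates are useless on grayscale night frames,
  so each plant is tracked with a two-region Chan-Vese active contour
  minimising

  `E = mu·|∂Ω| + λ_in·Σ_in (I − c_in)² + λ_out·Σ_out (I − c_out)²`

  where `c_in`, `c_out` are the region mean intensities.  The last VIS mask of
  the preceding light period initialises the first night frame; each converged
  mask seeds the next frame.  A *forward* pass (expansion-biased) and a
  *reverse* pass from the following morning's mask (contraction-biased) are
  run and their area series averaged.
- **Illumination correction** — NIR frames carry a smooth LED falloff field;
  it is estimated robustly (sliding median + quadratic surface fit) and
  subtracted before thresholding or contour evolution.
- **Growth traits** — projected rosette area `PRA` (px and mm² via the pixel
  calibration) and relative expansion rate
  `RER = (ln PRA₂ − ln PRA₁)/(t₂ − t₁)` in day⁻¹: *daily* RER from each light
  period's endpoints, and *diel* RER at full temporal resolution after a
  10-frame sliding-median smoothing.
- **Synthetic scenes** — a generator renders growing lobed rosettes on
  textured soil (VIS) and under radial falloff (NIR) with exact per-frame
  ground-truth masks and areas, so every stage can be validated without real
  imagery.

## Worked example

`examples/03_nir_dark_period.py` simulates one full dark period of a 2×2 tray
and tracks it with Chan-Vese propagation:

```
dark period: frames [36, 72)
PRA MAPE vs ground truth: 0.09% (averaged forward/reverse passes)
worst per-frame Dice of the forward pass: 0.9982
```

The mean absolute percentage error of the propagated areas against the
generator's exact rasterised areas is well under 1%, and every night frame's
mask overlaps the truth with Dice ≈ 1.  The other scripts in `examples/`
cover scene simulation, VIS thresholding, RER computation and the full
end-to-end pipeline (including detection of the post-dawn PRA dip that leaf
movement produces in the dip-bearing preset and not in the dip-free one).

## Command line

```sh
phenodiel simulate --preset wt --days 3 --grid 2x3 --seed 1 --out scene/
phenodiel run --config pipeline.yaml          # end-to-end: masks + traits + RER
phenodiel segment-vis --config ... --out-masks masks/
phenodiel segment-nir --config ... --seed-mask m.png --direction both ...
phenodiel traits --pra traits.csv --config ... --out rer.csv
```

The YAML config holds the photoperiod schedule, pixel calibration, threshold
ranges, Chan-Vese and illumination parameters (see
`tests/test_pipeline.py::TestConfigAndOutputs` for a complete example).

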
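# Methods

This note documents the models implemented in `phenodiel`, the defaults and
why they are set where they are, what the synthetic scenes do and do not
emulate, and the numerical choices that matter for reproducing results.

## Session model and photoperiod partition

A session is an ordered sequence of 8-bit frames (RGB = VIS, single-channel =
NIR) with minute-resolution timestamps.  The photoperiod schedule assigns
modality by clock time using half-open intervals `[lights_on, lights_off)`:
a frame stamped exactly at lights-off belongs to the dark period.  This makes
boundary handling deterministic; nothing forces a particular frame count per
period (a 12-h period sampled every 20 min naturally holds 35 or 36 frames
depending on the acquisition offset).  Single-channel files force NIR
regardless of the schedule; an RGB file at a dark time is collapsed to
Rec. 601 luminance with a warning so that dark periods are homogeneous.
Timestamps come from an ISO-8601 substring in the filename, with file
modification time as a warned fallback.

## VIS thresholding

Foreground is the conjunction of three inclusive channel ranges in RGB, HSV
(H in degrees, wrap-around supported because hue is circular) or CIELAB
(D65), computed with the standard sRGB transforms.  Grayscale Otsu maximises
between-class variance over the 256-bin histogram with ties broken toward
the smallest threshold (determinism); a constant image raises rather than
returning an arbitrary cut.  Masks are cleaned with an 8-connectivity
minimum-area filter (default 25 px at the generator's 0.25 mm/px scale —
about 1.6 mm², well below any rosette and above soil speckle) and optional
hole filling.  Range values are data-dependent by nature; the defaults
(H ∈ [60°, 180°], S ≥ 0.15, V ≥ 0.05) isolate green foliage from brown soil
and are meant to be tuned per dataset via the channel-histogram utility.

## Chan-Vese contour and dark-period propagation

The two-region energy is

    E = mu·|∂Ω| + λ_in·Σ_in (I − c_in)² + λ_out·Σ_out (I − c_out)²

on intensities normalised to [0, 1], with `|∂Ω|` the count of 4-adjacent
pixel pairs with different labels and `c_in`, `c_out` the region means.

**Minimisation scheme.** Instead of a level-set discretisation, the contour
evolves by pixel flips on the narrow band (the 8-neighbourhood of the current
boundary), in two checkerboard half-sweeps per iteration.  Same-colour
pixels never share a lattice edge, so each flip's exact energy change (data
term plus incremental perimeter, `ΔP = ±(2·n_fg − n_neighbours)`) is additive
within a half-sweep; a flip is applied only when its ΔE is strictly negative.
Re-estimating the region means between iterations also never increases the
energy, so the total energy is monotonically non-increasing by construction —
asserted per-iteration in the tests.  Iteration stops when the fraction of
changed pixels falls below `tol` (default 1e-4) or at `max_iters` (200).

**Choice of mu.** With the discrete 4-neighbour perimeter, advancing a flat
front costs `2·mu` per pixel, so a front pins wherever `2·mu` exceeds the
per-pixel data gain (≈ the squared normalised region contrast).  At NIR
contrasts around 0.35 that pinning threshold is ≈ 0.06; the default
`mu = 0.05` sits below it while still trimming single-pixel protrusions
(whose ΔP is negative).  Larger values visibly freeze the contour on clean
test disks — this is an artifact of the discrete perimeter, not of the model.

**Directional bias.** The expand/contract constraint is realised by
asymmetric data weights: expansion uses `λ_out/λ_in = 2` (misclassified
background is expensive, so growth into plant-like pixels is favoured),
contraction the inverse, `free` uses equal weights.  Forward passes through a
dark period expand (plants grow overnight); reverse passes contract.

**Propagation.** Each plant evolves independently inside its bounding box
dilated by 25% per side (minimum 8 px): plants never touch in the supported
scenes, and the restriction prevents label leakage and bounds cost.  The
converged mask seeds the same plant in the next frame.  A vanished mask is
recorded as empty (missing) with a warning, and the last non-empty mask seeds
the next frame — one bad frame must not abort a multi-day batch.  Forward and
reverse **area series** are averaged per plant per frame (with fallback to
the surviving pass when one is missing); both mask sets are retained, the
forward one being canonical for mask output.  Averaging areas rather than
masks keeps the two passes' complementary biases (expansion slightly over-,
contraction slightly under-segments) cancelling in the quantity that is
actually reported.

## Illumination correction

NIR scenes carry a smooth multiplicative falloff from the LED array.  The
correction subtracts an estimated additive field:

1. pixel values are pulled toward the global mean by `flatten_strength`
   (default 0.5), damping foreground leverage;
2. a sliding median with footprint radius `1.5·blur_sigma` (default
   `blur_sigma` = raster width / 8) rejects the rosettes outright — the
   median only breaks when plants cover more than half the footprint;
3. a least-squares quadratic surface is fitted to the median image,
   excluding a border of one footprint radius where the rank median is
   biased by footprint truncation, and extrapolated to the full raster;
4. the surface's deviation from its mean, rescaled by `1/(1 − s)` to undo the
   flattening attenuation, is subtracted and the result clipped to [0, 255].

A quadratic captures linear gradients and radial (vignetting-style) falloff
exactly and cannot chase soil texture or plants, which makes the correction
idempotent: a second application changes pixels by at most ~1 grey level.  A
plain Gaussian low-pass was rejected for this role during development: it
absorbs bright rosettes into the field (over-darkening their surroundings on
every application) and attenuates raster-scale fields near the borders, so
repeated application keeps shifting the image.  The plain Gaussian map
remains available as `intensity_map`.  Illumination structure beyond second
order is not modelled; correction applies only to single-channel processing,
never to RGB VIS frames.

## Plant identity

Automatic numbering sorts components by centroid x ascending (ties by y
ascending) — "left to right".  For a 2-D grid of pots this is ambiguous in
principle; pure ascending-x is the implemented rule.  Seeded labelling reads
`plant_id x y` triples from a text file and gives each component the nearest
seed's id (components beyond a configurable distance are dropped).  Across a
session, labels are locked at the first labelled frame and propagated by
nearest-centroid matching, so a plant that fragments (a lost petiole)
keeps one id.  Note that independently re-running the automatic numbering on
two different frames can swap plants whose centroid x differ by less than
the segmentation jitter; any multi-pass computation must therefore carry one
labelling through centroid matching rather than renumbering.

## Growth traits

`RER = (ln PRA₂ − ln PRA₁)/(t₂ − t₁)` in day⁻¹ (times in days).  It is
antisymmetric in the area order and invariant to time shifts and to the area
unit — properties the test suite asserts.

*Daily RER* takes the first and last non-missing VIS frames of each light
period.  Periods whose usable span is under half the scheduled photoperiod
(e.g. a session ending mid-morning, inside the dawn dip) are skipped with a
warning: a 2-h window labelled "daily" is dominated by leaf movement, not
growth.  *Diel RER* smooths the PRA series with a centred 10-frame sliding
median (~3 h at 20-min sampling) before differencing consecutive smoothed
points; the median is applied to PRA rather than to pointwise rates because
it suppresses segmentation spikes before the noise-amplifying difference
step.  Missing frames are linearly interpolated when the gap is ≤ 2 frames;
longer gaps split the series into independent segments.

**Error propagation.** With relative area noise σ per frame, a daily RER from
two raw endpoints has standard deviation `√2·σ/Δt` (Δt ≈ 0.49 d for a 12-h
period), i.e. ≈ 0.058 day⁻¹ at σ = 2% — of the same order as typical
Arabidopsis rates.  Endpoint-based daily RER is therefore only meaningful
when segmentation noise is well below 1% (as it is for this pipeline on the
synthetic scenes, where MAPE ≈ 0.1%), or after averaging many days.  The test
suite asserts the estimator's unbiasedness within the analytic 3σ band at 2%
noise; a fixed ±10% recovery claim at that noise level corresponds to only
0.45σ and cannot hold reliably for any endpoint estimator.

**Dawn-dip detection.** For each light period preceded by a dark period, the
PRA series (median-smoothed over 5 frames) inside `[dawn, dawn + 2 h]` is
compared with the straight line joining the window's endpoints; the depth is
the largest relative shortfall at an interior sample, and a dawn counts as
dipped at depth ≥ 2%.  The baseline construction makes the test insensitive
to the growth trend; the 2% floor sits well below the simulated 10% dip and
well above the ≲ 0.5% jitter of smoothed dip-free series.

## Synthetic scenes

Rosettes are lobed star-polygons `r(θ) = R·(1 + λ·cos(nθ + φ))` with mild
smoothed vertex jitter, rescaled until the rasterised pixel count is within
1% of the target area (the 1% figure holds for targets of a few hundred
pixels and up; very small targets are limited by rasterisation granularity).
True area follows `A(t) = A₀·e^{rt}·(1 − dip(t))` with a half-sine dip of
amplitude 10% and duration 2 h after each lights-on in the dip-bearing
preset.  VIS frames colour the stamps with per-pixel HSV jitter over textured
brown soil; NIR frames use reflectance levels (soil ≈ 90, plant ≈ 180) under
a radial quadratic falloff (strength 0.30) plus Gaussian noise (σ = 4).
Defaults describe a 3×6-pot tray at 0.25 mm/px, 100 px pots, 12:12
photoperiod, 20-min interval, initial areas 40–60 mm²; the presets fix
`r = 0.20 day⁻¹`/10% dip ("WT-like") and `r = 0.08 day⁻¹`/no dip
("mutant-like") to mirror a vigorous-vs-slow genotype contrast.  Ground-truth
pixel areas are the exact rasterised counts, so measured errors are pure
segmentation error.

What the generator does **not** emulate: 3-D leaf pose (the dip is an area
modulation, sufficient because the observable of leaf movement in top view
is precisely a PRA change), leaf overlap between plants, specular soil
moisture, camera motion, exposure drift, or colour constancy failures.
Passing tests on these scenes demonstrates the pipeline's numerical
correctness and its behaviour under the modelled noise sources — not
robustness to every field condition.

## Pipeline

Light periods are segmented per frame (thresholding is cheap and stateless);
only dark periods use propagation.  Labels lock at the first VIS frame (auto
or seeded) and persist via centroid matching; dark periods seed forward from
the preceding light period's last mask and reverse from the following light
period's first mask, falling back to a single pass at session edges.  Every
input frame appears in the trait table or in the warning log; reruns on
identical inputs are bit-identical (the pipeline itself draws no random
numbers).  A JSON manifest echoes the configuration and collected warnings.

## Problem sizes

Validation and tests run on deliberately small instances chosen to exercise
every code path at desk scale: trays of 4–6 plants (2×2 or 2×3) instead of
the default 18, sessions of 26 h (one full dark period flanked by light) for
propagation checks and 74 h (three dawns) for the end-to-end diel-pattern
check, 16×16 images for the Otsu brute-force comparison and 96×96 disks for
contour recovery.  Noise levels, falloff strength, dip amplitude and growth
rates are always the defaults above.

## Known limitations

- Touching or overlapping rosettes are out of scope (the propagation model
  assumes separable plants, as does the box restriction).
- The discrete-perimeter contour pins for `mu` above the contrast-dependent
  threshold; `mu` must be chosen with the imaging contrast in mind.
- The illumination model is second-order; strongly structured lighting
  (multiple local maxima) is only partially corrected.
- Daily RER inherits the endpoint-noise variance derived above; diel RER
  trades temporal resolution against the 10-frame median window, and dips
  shorter than about half the window are attenuated.
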
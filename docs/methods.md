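# Methods

## Data model

A survey track is a hyperspectral cube `(lines, samples, bands)`: axis
0 is the along-track line of a push-broom scan, axis 1 the cross-track
sample, axis 2 the spectral band with strictly increasing band-center
wavelengths in nm. Values are float32 after any processing; raw
integer counts are accepted on read. Each cube carries a processing
stage tag (`raw → radiance → pseudo_reflectance → smoothed`) so that
stage preconditions (for example "ROI spectra come from processed
cubes") are enforced rather than assumed.

## Pseudo-reflectance processing

Raw intensities mix target reflectance with the lamp spectrum, the
cross-track illumination geometry of the lamp array, water-column
attenuation and sensor gain. None of these are radiometrically
characterized here, so they are approximated by a *reference spectrum*
estimated from the track itself; dividing each pixel spectrum by its
reference yields pseudo-reflectance (reflectance-like, with residual
illumination effects — never reported as true reflectance).

Fixed processing order: spectral subsetting → reference division →
smoothing.

* **Spectral subsetting** keeps the bands whose centers lie in
  [400, 710] nm, both bounds inclusive; bands outside this window are
  noise-dominated. On the default simulated instrument grid this keeps
  exactly 83 of 112 bands.
* **Reference statistic.** Three estimators are exposed:
  `column_median` (default), `column_mean` and `global_mean`. The
  column statistics reduce each cross-track sample position over all
  along-track lines, which removes a static multiplicative cross-track
  illumination field exactly; the global mean is a fallback for scenes
  without a stable cross-track geometry. The *median* is the default
  because it stays anchored to the background when objects occupy a
  sizeable fraction of a column: on short desk-scale tracks
  (hundreds of lines) a planted object can cover 20–30 % of its own
  columns and pulls a column *mean* several degrees of spectral
  contrast angle away from the background shape, enough to confuse
  categories that are themselves only 4–6° apart. On survey-length
  tracks (thousands of lines) mean and median nearly coincide. Any
  nonpositive reference entry is an error — no silent NaN.
* **Smoothing** is a centered moving average along the band axis,
  default window 11 bands (44 nm). Edge handling is reflect padding
  (default) so the band count is preserved, or `shrink`, which
  averages only the in-range part of the window. The window must be
  odd so the filter is symmetric and preserves affine spectra in the
  interior.

## Spectral library

Each annotated region of interest (ROI) contributes one entry: the
per-band arithmetic mean over its pixel mask, max-normalized so that
the peak is exactly 1. Averaging is done before normalization. ROIs
of fewer than 20 or more than 600 pixels produce a warning (not an
error): smaller masks average too little to suppress pixel noise,
larger ones span illumination gradients. The unnormalized mean is
retained alongside for diagnostics, because intensity (lost in
normalization) partly distinguishes the white from the green spots.
ROIs are accepted as integer label-mask rasters or as polygon JSON
(rasterized with center-in-polygon inclusion). Libraries persist as
JSON.

## Spectral contrast angle

For spectra *a*, *b* on one grid, θ = arccos(Σaᵢbᵢ/√(Σaᵢ²Σbᵢ²)),
reported in degrees. The cosine is clamped to [−1, 1] before the
arccos, so numerically collinear inputs give exactly 0°. θ is
symmetric and invariant to positive scaling; for nonnegative spectra
θ ∈ [0°, 90°] (the bound is conditional: negative values, possible
only on malformed input, are not clipped). An unidentified object is
assigned the category of the library entry with smallest θ; ties below
10⁻⁹ degrees go to the earliest library entry, with a warning. An
optional rejection threshold θ_max returns `unassigned` instead of a
forced match. Queries and entries are max-normalized before matching
for presentation consistency; scale invariance guarantees this cannot
change an assignment.

`SpectralAngleMatcher` exposes this as a scikit-learn estimator
(`fit(X, y)` on reference spectra, `predict` by smallest angle), so it
composes with sklearn model selection; `match_to_library` is the
library-level wrapper.

## Supervised classification

A multi-class SVM (one-vs-one, RBF kernel) labels every pixel of a
processed cube. Defaults γ = 1/n_bands and C = 100 follow the common
remote-sensing configuration for this classifier; both are exposed.
Training samples come either as one mean spectrum per object
(`avg_spectra`, the leanest published variant) or one sample per ROI
pixel (`roi_pixels`, the default — tens of samples per category are
statistically thin for 20 or so categories). An optional seeded
`max_pixels_per_roi` cap (pipeline default 400) bounds the SVC fit
cost on large objects. Background materials (sediment, manganese
nodule) are first-class categories: without them the classifier runs
in a degraded OOI-only mode (warned) that cannot label background
pixels as such. Fitting canonicalizes sample order, so training is
insensitive to ROI enumeration order; identical spectra with
conflicting labels are rejected with the collision listed. The
classifier sits behind a fit/predict contract (`PixelSVMClassifier`)
and is swappable.

## Object detection and survey summary

Non-background pixels are grouped into connected components (default
8-connectivity — organisms are contiguous bodies and rim
misclassification into a spectrally similar category must not split an
individual) *across all non-background categories jointly*; each
component takes the majority category of its pixels (ties resolve
alphabetically, with a warning). Components below `min_size_px`
(default 20 px = 2 cm² at 1 mm pixels — below the smallest organism
scale of interest, above single-pixel noise) are dropped. Each object
reports pixel area, area in cm², equivalent circular diameter,
centroid, bounding box and purity (majority-label fraction). Densities
are count/area in individuals m⁻², kept at full precision internally
and rounded to two decimals only in reports.

## The synthetic scene generator

Forward model, per pixel:

```
value(l, s, b) = R_cat(λ_b) · jitter_obj · cross(s) · drift(l) · lamp(λ_b) · gain + ε
```

* **Band grid**: 112 bands from 378 nm at 3.75 nm spacing (so the
  covered range is ≈378–794 nm and inclusive subsetting at [400, 710]
  keeps exactly 83 bands). The true instrument grid is configurable.
* **Materials**: linear baselines in normalized wavelength plus 1–3
  category-specific Gaussian features; sediment is a bright rising
  baseline, nodules dark and slightly declining. The green/white
  spots are the sediment baseline times a multiplicative absorption
  dip at 675 nm (σ = 8 nm; depth 0.5 green, 0.35 white; the white spot
  additionally ×1.15 above 650 nm) — invented phenomenology for a
  chlorophyll-a-like anomaly, config values rather than claims about
  the organisms. A build-time check enforces ≥5° pairwise contrast
  angle between category spectra over 400–710 nm, *except* within the
  sediment/spot family: the spots share the sediment baseline by
  construction, and their mutual separation (≈4–5°) is governed by the
  dip parameters and partly by intensity, which the angle ignores.
* **Scene**: default 300 × 400 px at 1 mm pixels; 60 background
  nodules (1–4 cm); 18 objects cycling through six categories
  (white coral, round sponge, polychaete, dead salp, green spot,
  white spot), fauna discs 1.5–8 cm, spots 1–2 cm (≤2 cm by
  definition). Placement is rejection-sampled, largest first, with a
  12 px minimum separation so planted objects stay distinct under
  8-connectivity and per-object ground truth is unambiguous.
* **Optics**: cross-track cosine falloff to 0.6 at the swath edges;
  ±5 % sinusoidal along-track gain drift; a smooth broad lamp
  spectrum peaking near 560 nm.
* **Noise**: Gaussian, sd = 1 % of the local signal, inflated ×5
  outside 400–710 nm (reproducing the noisy band edges that motivate
  subsetting).
* One `numpy` generator seeded from a single integer drives placement,
  brightness jitter (±5 % per object) and noise; scenes are
  bit-reproducible.

What the generator does *not* emulate: water-column inherent optical
properties, bidirectional reflectance, organism morphology beyond
discs/ellipses, spatial texture within objects, sensor smile/keystone,
and navigation artifacts. Passing the synthetic end-to-end tests
therefore demonstrates the correctness and internal consistency of the
chain under the stated optical model — not field performance on real
tracks, where intra-category spectral variability and uncorrected
illumination residuals are larger.

## Pipeline

`run_pipeline_in_memory` (and the file-based `run_pipeline` /
`benthospec run`) execute: preprocess → library from video-identified
ROIs → angle-match the unidentified ROIs against that *fixed* library
→ expand the library with the matched entries → assemble training →
SVM train/classify → detect → summarize. Matching strictly precedes
expansion: folding each match into the library while matching would
let one early error contaminate later assignments. Surveyed area is
Σ lines × samples × (pixel_size/1000)² m² unless given explicitly.
Every stage logs its parameters; the run is a pure function of
(inputs, config, seed).

## Problem sizes

Unit and property tests run on cubes from 1 × 1 × 3 up to the default
300 × 400 × 112 scene; the end-to-end acceptance check uses five
independently seeded default scenes (≈25 s total), and the zero-noise
identifiability check uses a 600-line track so that — as on
survey-length tracks — every cross-track column stays
majority-background and the column reference is uncontaminated by the
planted objects themselves.

## Known limitations

* The reference-spectrum estimators are approximations; the exact
  correction used on real deployments depends on lamp geometry data
  not modeled here.
* Touching distinct organisms are detected as one object (no splitting
  heuristic); low purity flags such cases.
* The angle matcher always assigns a category unless θ_max is set;
  genuinely novel materials require the rejection threshold or the
  classifier's background classes to catch them.
* The ENVI-style reader targets the common dialect (required keys:
  samples/lines/bands/interleave/data type/byte order/wavelength) and
  is not validated against any specific archived dataset.
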
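# benthospec

Taxonomic classification of benthic megafauna and sediment anomalies
from underwater hyperspectral imagery (UHI).

## The problem

Push-broom underwater hyperspectral imagers record a full reflectance
spectrum for every millimetre-scale seafloor pixel. Because marine
organisms carry characteristic *optical fingerprints*, a UHI survey can
identify benthic megafauna in situ — without physical sampling — and
reveal sub-centimetre organisms and sediment anomalies (for example
chlorophyll-*a*-bearing "green/white spots" with a reflectance minimum
near 675 nm) that standard RGB video cannot resolve. `benthospec`
implements the full analysis chain for such surveys:

1. **Pseudo-reflectance processing** — raw cubes are spectrally
   subset to the low-noise 400–710 nm window, divided per pixel by a
   scene-derived reference spectrum, and smoothed with an 11-band
   (44 nm) moving average. The output approximates reflectance up to
   residual illumination effects, hence *pseudo*-reflectance.
2. **Spectral library** — mean spectra over annotated regions of
   interest (20–600 px) become named, taxonomy-annotated reference
   fingerprints, max-normalized.
3. **Spectral contrast angle matching** — an unidentified object with
   spectrum *a* is compared against each reference *b* through

   cos θ = Σᵢ aᵢbᵢ / √(Σᵢ aᵢ² · Σᵢ bᵢ²),

   and assigned the category of the smallest θ (θ = 0° means identical
   spectral shape; θ ≤ 90° for nonnegative spectra).
4. **SVM pixel classification** — an RBF-kernel support vector machine
   (γ = 1/n_bands, C = 100) trained on the expanded library (video-
   identified + angle-identified objects, plus sediment/nodule
   background) labels every pixel of a track.
5. **Object detection and survey summary** — connected non-background
   components become objects of interest (OOIs) with majority-vote
   categories; counts over the surveyed area give densities in
   individuals m⁻².

A synthetic seafloor-scene generator (sediment + manganese-nodule
background, 16 fauna and 3 anomaly material models, cross-track
illumination, band-dependent noise) makes every stage testable at desk
scale with exact ground truth.

## Worked example

```python
from benthospec.evaluate import evaluate_scene
from benthospec.simulate import default_scene_config

ev = evaluate_scene(default_scene_config(seed=1))
s = ev.result.summary
print(s.to_frame().to_string(index=False))
print(f"total OOIs: {s.total_ooi_count} over {s.surveyed_area_m2:.3f} m^2")
print(f"pixel accuracy vs truth: {ev.pixel_accuracy:.1%}")
```

This simulates a 300 × 400 px, 112-band survey track (1 mm pixels, 18
planted objects across six categories), runs the full chain — the
reference library is built from a stratified half of the objects, the
rest are identified by smallest contrast angle before SVM training —
and scores the result against the scene's ground truth:

```
    category  count  density_per_m2  density_per_m2_2dp
 coral_white      3            25.0                25.0
  green_spot      3            25.0                25.0
  polychaete      3            25.0                25.0
   salp_dead      3            25.0                25.0
sponge_round      3            25.0                25.0
  white_spot      3            25.0                25.0

total OOIs: 18 over 0.120 m^2
pixel accuracy vs truth: 100.0%
```

All 18 planted objects are recovered with their true categories; the
densities (25 m⁻² per category) are the counts over the 0.12 m² track.

The same workflow is available from the shell:

```sh
benthospec simulate --seed 42 --out scene/
benthospec preprocess --cube scene/scene.bsq --out pr.bsq
benthospec rgb --cube pr.bsq --out track.png        # R 645 / G 571 / B 473 nm
```

Cubes are read and written in the standard ENVI-style container
(`key = value` header + flat BSQ/BIL/BIP binary).

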
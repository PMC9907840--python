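# vesswall

Layer-resolved quantification of immunohistochemical staining in arterial
cross-sections.

In small-vessel pathologies such as CADASIL, the question is not only *whether*
a protein is deposited in the vessel wall but *where*: the tunica intima,
media, or adventitia. Visual scoring of DAB-stained brightfield sections is
subjective and hard to compare across markers. `vesswall` replaces it with an
objective pipeline: given an RGB photomicrograph of an annular vessel
cross-section and a binary wall mask, it

1. **unmixes** the image into hematoxylin and DAB concentration maps by color
   deconvolution in optical-density space (Beer–Lambert: `OD = M·c` with `M`
   the 3×3 stain-vector matrix, default the standard published H-DAB basis);
2. **parameterizes** the wall by normalized depth `d ∈ [0, 1]` from the lumen
   to the outer edge (distance-transform ratio, or a classical spoke/ray
   construction) and by 20 equal angular sectors;
3. **profiles** staining as a 100-bin histogram of thresholded DAB pixels
   along depth — the *staining distribution* — and sums the normalized
   density over the equal-width thirds (bins 0–32, 33–65, 66–99) to score
   intima, media and adventitia;
4. **compares** markers by the inverse Jensen–Shannon distance between mean
   distributions, `sim(p, q) = 1 / sqrt(JSD(p, q))` with base-2 logs so the
   distance lies in [0, 1];
5. **tests** medial enrichment across vessels with a one-sided Welch
   two-sample t-test and a one-sided label-permutation test on the difference
   of group means, `p = (1 + #{perm ≥ obs}) / (n_perm + 1)`;
6. **embeds** per-sector 100-dimensional staining profiles with t-SNE to
   visualize marker overlap, plus a quantitative nearest-neighbor overlap
   report.

A synthetic vessel generator (`VesselSpec` / `generate_vessel`) renders
brightfield-like annular vessels with known geometry, layer-specific DAB
deposition, hematoxylin counterstain, nuclei and OD noise, so the whole
pipeline is testable against ground truth without tissue images.

## Worked example

```python
import vesswall as vw

# a synthetic vessel with DAB concentrated in the media (40% fill) and
# light background staining elsewhere (5%)
spec = vw.VesselSpec(stain_fill_fraction=(0.05, 0.4, 0.05), noise_sd=0.02, seed=7)
vessel = vw.generate_vessel(spec, vessel_id="demo")

od = vw.rgb_to_optical_density(vessel.image)
conc = vw.separate_stains(od)                       # H / DAB / residual maps
geom = vw.build_geometry(vessel.wall_mask)          # depth, 100 bins, 20 sectors
stained = vw.threshold_stained(conc.dab, geom.wall, "otsu")
dist = vw.staining_distribution(stained, geom.bin_map, marker="NOTCH3")
scores = vw.layer_scores(dist, geom.partition)

print(f"stained pixels: {stained.n_stained} (Otsu threshold {stained.threshold_value:.3f} OD)")
print(f"layer scores   intima={scores.intima:.3f}  media={scores.media:.3f}  adventitia={scores.adventitia:.3f}")
```

prints

```
stained pixels: 4425 (Otsu threshold 0.128 OD)
layer scores   intima=0.068  media=0.793  adventitia=0.139
```

79% of the staining density lies in the medial third — the expected readout
for a media-enriched marker (the residual intima/adventitia mass is the 5%
background fill plus the outward bias of annular bin areas). Comparing this
vessel with an intima-enriched one:

```python
other = vw.generate_vessel(vw.VesselSpec(stain_fill_fraction=(0.4, 0.05, 0.05),
                                         noise_sd=0.02, seed=8))
conc2 = vw.separate_stains(vw.rgb_to_optical_density(other.image))
g2 = vw.build_geometry(other.wall_mask)
d2 = vw.staining_distribution(vw.threshold_stained(conc2.dab, g2.wall, "otsu"), g2.bin_map)
print(f"JS distance: {vw.js_distance(dist.density, d2.density):.3f}")
print(f"similarity (inverse JS distance): {vw.similarity(dist.density, d2.density):.3f}")
```

```
JS distance: 0.652
similarity (inverse JS distance): 1.535
```

Two media-enriched vessels typically score similarity ≳ 20 against each
other, so 1.5 marks these two profiles as clearly distinct.

## Command line

The same stages are exposed as a CLI for shell use:

```sh
vesswall simulate --n 8 --seed 17 --out data/            # synthetic cohort
vesswall unmix --image img.tiff --out maps/
vesswall threshold --dab maps/dab.tiff --wall wall.png --method otsu --out stained.png
vesswall geometry --wall wall.png --bins 100 --sectors 20 --out geom/
vesswall quantify --stained stained.png --bins geom/bins.tiff --marker NOTCH3 \
    --vessel v01 --out dist.csv
vesswall run --config cfg.json                           # full pipeline
```

`vesswall run` consumes a manifest CSV (`image, wall_mask, marker,
vessel_id`) and writes per-vessel distributions, per-marker means, layer
scores and enrichment tests, the similarity matrix with a ranked
similarity-to-reference table, sector features, the t-SNE embedding and a
JSON run record — deterministically for a fixed config.

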
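# Methods

This note documents the models, conventions and numerical choices behind
`vesswall`, and what its synthetic-data tests do and do not establish about
real tissue images.

## Color model and stain separation

Brightfield absorbance follows Beer–Lambert: a pixel's optical density
`OD = −log10(I / I0)` is linear in stain amounts, `OD = M·c`, where the
columns of `M` are unit OD vectors for hematoxylin, DAB, and a residual
channel. Intensities are clipped to `[1, 255]` before the log, bounding OD
at `log10(255) ≈ 2.41` and avoiding infinities on fully absorbing pixels.

The default `M` is the standard published H-DAB basis
(hematoxylin ≈ (0.650, 0.704, 0.286), DAB ≈ (0.268, 0.570, 0.776), residual
= their normalized cross product); it can be replaced by any full-rank 3×3
matrix. Unmixing is a single simultaneous 3×3 solve per pixel —
mathematically equivalent to removing one stain and then the other for a
full-rank basis. Negative concentrations (noise outside the stain simplex)
are clipped to zero, since concentrations are physical amounts; the
pre-clipping solve reconstructs `OD` exactly.

Thresholding of the DAB map is Otsu's method computed from wall pixels only
(parameter-free, reproducible), with a fixed-level override. Otsu is
undefined when all wall DAB values are equal; the pipeline classifies such
vessels (e.g. blank sections) as `empty_stain` instead of failing.

## Wall geometry

The wall mask must be a single connected annulus with exactly one interior
hole; anything else raises a topology error naming the defect. Masks are
supplied by the user (background removal is a manual step); generated masks
always satisfy the invariant.

Normalized depth maps the wall onto `[0, 1]`, 0 at the lumen-facing edge:

- **distance** (default): `d = d_in / (d_in + d_out)` from Euclidean
  distance transforms to the lumen and to the exterior. Well defined for
  irregular and non-convex walls; on a 40/100 px annulus the mean absolute
  error against the analytic `(r − r_in)/(r_out − r_in)` is ≈ 0.003.
- **spokes**: rays from the lumen centroid at 1° spacing; each pixel's depth
  is its normalized radial position between its nearest spoke's inner and
  outer wall crossings. Rays that fail to cross both boundaries are warned
  about and their pixels fall back to the nearest valid spoke; more than 10%
  failed spokes aborts. Retained as the classical ray construction; it
  degrades on strongly concave contours.

Depth bins: `bin = floor(100·d)`, last bin right-closed. Sectors:
`sector = floor(20·θ / 2π)` with θ measured counter-clockwise from the +x
(east) axis about the lumen centroid in display orientation (rows grow
downward), so a quarter-turn rotation of the raster shifts labels by exactly
5. The three layers are the equal-width thirds of the bins — intima 0–32,
media 33–65, adventitia 66–99; with 100 bins the leftover bin is assigned
outward, to the adventitia. Equal thirds is an idealization of real walls,
whose layer widths vary.

## Staining distributions and layer scores

The staining distribution counts thresholded DAB pixels per depth bin and
normalizes to a probability vector. Raw counts carry the annular area bias
(a bin at depth `d` holds ∝ `r_in + w·d` pixels); this is deliberately not
corrected in the default readout, and an area-normalized variant (stained
fraction per bin) is available behind a flag. Marker means average
per-vessel densities with equal weight per vessel, so large vessels do not
dominate. Empty stained masks are flagged, never silently zero-filled —
a zero vector is not a probability distribution.

Two layer-score modes exist because both readouts are in use and are not
equivalent: `density_sum` (sum of density per layer; the three scores add to
1) and `intensity_normalized` (mean DAB pixel value per layer minus the
whole-wall mean; a flat field scores 0 everywhere).

## Similarity and enrichment statistics

Distributions are compared with the Jensen–Shannon divergence using base-2
logarithms, so JSD and its square root (the JS distance, a true metric) lie
in [0, 1]. Zero bins follow the `0·log 0 = 0` convention; no pseudocounts
are needed because the mixture midpoint is positive wherever either input
is. Similarity is the multiplicative inverse of the distance — the literal
reading of "inverse JS distance" — capped at 1e6 so identical distributions
report the cap rather than infinity; a bounded additive variant `1 − d` is
available behind a flag.

Layer enrichment across a vessel cohort is tested one-sided (default:
media greater) two ways:

- **Welch t-test** (unequal variances — the safer default when group
  variances are unknown). Two constant equal groups report `p = 0.5` by
  convention: no directional evidence.
- **Permutation test**: statistic = difference of group means; labels are
  reshuffled `n_perm` times (default 10,000) under a recorded seed;
  `p = (1 + #{perm ≥ obs}) / (n_perm + 1)`, the add-one estimator that is
  valid at finite `n_perm`. It agrees with exhaustive enumeration within
  Monte-Carlo error and holds its nominal 5% level under a simulated null
  (checked at 2,000 replicates, n = 8 per group, n_perm = 200).

No multiple-testing correction is applied across a marker panel; p-values
are per-marker. This is a documented limitation.

## Sector embedding

Each (vessel, sector) pair with any stained pixels contributes one
100-dimensional depth distribution; empty sectors are excluded. Sector
counts sum bin-by-bin to the whole-vessel distribution, exactly. The
feature rows are embedded directly with t-SNE (perplexity 10 — suited to
the 100–200 row regime; fixed seed; PCA initialization), requiring at least
`3 × perplexity` rows. t-SNE distances are not calibrated, so no statistics
are computed on coordinates; instead the overlap report gives, per marker,
the centroid distance to the reference cloud and the mean fraction of each
reference point's 10 nearest neighbors carrying that marker's label
(≈ 0.5 for perfectly interleaved equal clouds, ≈ 0 for displaced ones).

## Synthetic vessel generator

`generate_vessel` renders what the analysis assumes: an annular wall
(default inner/outer radii 40/100 px in a 256² image) whose inner and outer
boundaries share an optional 2nd–4th-harmonic radial perturbation (mimicking
non-circular vessels without self-intersection), DAB assigned per depth
third with configurable fill fractions and OD levels (defaults: 30% fill at
0.8 OD), a hematoxylin base level (0.25 OD) with ~1 nucleus per 1000 wall
pixels stamped as 2-px-radius disks at 3× base level, Beer–Lambert
composition to 8-bit RGB, and additive Gaussian OD noise (default sd 0.02,
a light photometric perturbation). Ground truth — exact depth, the stained
pixel set, per-layer stained mass — is recorded before noise; everything is
a pure function of the spec's seed. Cohorts jitter radii by ±10% per vessel
with sub-seeds derived from a master seed, emulating vessel-to-vessel size
variability; 8 vessels per marker is the default cohort size.

For circular vessels a closed-form expected distribution exists
(`analytic_distribution`): bin mass ∝ layer fill × ∫(r_in + w·d) dd over the
bin, split exactly at layer-boundary crossings.

What the generator does **not** emulate: tissue texture, uneven section
reactivity, stain vector drift between slides, folds/bubbles, non-annular
(longitudinally cut) vessels, or spatially correlated noise. Passing tests
therefore establish the correctness of the computation under the stated
image model, not robustness to every real-world artifact.

### Resolution note

With 100 depth bins, a wall must be thick enough that each bin spans at
least ~1–2 px for bin-level comparisons to be meaningful: on a 60-px-thick
wall (0.6 px per bin) pixel-lattice discretization alone contributes ~0.03–
0.07 total-variation distance between the empirical and ideal distributions.
Bin-level oracle checks therefore use a 180-px-thick wall (r 120/300 in a
768² image, 1.8 px per bin), where the pipeline's total-variation error is
≈ 0.014. Layer-level scores (33-bin aggregates) are insensitive to this and
are validated at the default 60-px wall.

## Pipeline and determinism

`run_pipeline` runs manifest → unmix → geometry → threshold → QC →
distributions → means → layer scores/tests → similarity → sector features →
embedding, writing tidy CSVs plus a JSON run record in which every manifest
entry appears with a status (`ok`, `empty_stain`, `low_signal`,
`bad_topology`, or a recorded error). QC replaces the manual
"acceptable signal-to-noise" selection with declared thresholds (default:
≥ 100 stained pixels, ≤ 10% failed spokes). Markers left with no usable
vessel abort the run by name. All randomness (permutation seed, t-SNE seed,
generator seeds) lives in the config, so a re-run with the same config
produces byte-identical CSV outputs.

## Test problem sizes

The shipped tests and the acceptance script use 256² vessels (768² for the
bin-resolution oracle), cohorts of 2–8 vessels per marker, 10,000
permutations for single tests and 200 within the 2,000-replicate null
calibration, and 160-row t-SNE runs — sizes at which every check completes
in seconds while leaving the measured quantities' precision comfortably
inside the asserted bounds.
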
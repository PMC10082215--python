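# Methods

`atriadense` quantifies catecholaminergic (TH-immunoreactive) axon
innervation density in 2-D flat-mount fluorescence images of the mouse
atria, and validates every stage of that quantification against a synthetic
scene generator whose ground truth is analytic. This note documents the
models, the defaults and why they were chosen, the numerical conventions,
and what the validation does and does not demonstrate.

## The density statistic

Axon density is *total axon length per tissue area*, in μm/mm². The
measurement chain is:

1. **Background subtraction** — white top-hat: the image minus its grayscale
   opening by a flat Euclidean disk (default radius 80 px, the published
   setting). The opening is computed exactly by chord decomposition (the
   disk is a union of horizontal chords; erosion by a union of segments is
   the pointwise minimum of 1-D running minima), which is O(radius) per
   pixel instead of O(radius²) and bit-identical to the brute-force
   neighborhood definition. Structures broader than roughly twice the
   radius (uneven illumination, adipocyte autofluorescence) are suppressed;
   thin axons pass unchanged. Out-of-image neighborhoods are
   domain-restricted, which preserves `0 ≤ tophat ≤ image` everywhere.
2. **Particle removal** — deliberately implemented as *both* readings of an
   ambiguous protocol step: an optional pre-threshold 3×3 median despeckle
   (edge-replicated) and a post-threshold minimum-area filter (default
   10 px², 8-connected). Each is independently switchable and logged.
3. **Otsu threshold** — 256-bin histogram; the threshold maximizes the
   between-class variance `w0·w1·(μ0−μ1)²`; ties break toward the lowest
   maximizing threshold; foreground is strictly above the threshold.
   Integer 8-bit images use exact integer bins; wider types are binned over
   their min–max range. A constant image raises rather than returning an
   empty mask.
4. **Skeletonization** — two-subiteration template thinning followed by a
   deterministic resolution pass for the 2×2 foreground blocks that
   template thinning is known to leave at diagonally-locked junctions
   (a simple corner is deleted when one exists; otherwise the diagonal
   attachment is re-bridged through the adjacent outward pixel). The result
   contains no 2×2 block, preserves the 8-connected component count of the
   mask, and is idempotent — all three properties are enforced by tests on
   adversarial random masks.
5. **Length and density** — two estimators are reported side by side:
   - `pixel_count`: foreground pixels × pixel size. This is the published
     statistic. It is exact for axis-aligned runs and understates oblique
     ones (a 45° chain covers √2 μm per pixel but counts 1, a −29% bias).
   - `diagonal_corrected`: the weight of a spanning forest of the
     8-adjacency skeleton graph with edge weights 1 (orthogonal) and √2
     (diagonal), plus one pixel per connected component (so an L-pixel
     straight chain measures exactly L), × pixel size. Exact at 0°, 45°
     and 90°; overestimates intermediate orientations by up to
     `cos θ + (√2−1)·sin θ − 1` ≈ 7% near 30°/60°. This bound is intrinsic
     to two-weight chain estimators and is stated here rather than hidden:
     the calibration test on digital lines shows exactly this profile.
   - Beyond orientation bias, *any* skeleton-based estimator loses roughly
     one PSF width of length per axon terminal and per branch junction
     (end-cap erosion and junction contraction of the thinned tube), and
     merges strands closer than the tube width. These losses scale with
     tips+junctions per unit length, not with pixel size.
6. **Counting frames** — density is averaged over six disjoint frames per
   region of interest (frame count from the published pipeline; the default
   frame size, 200×200 μm, is an artifact default since the study does not
   state one). Placement is a deterministic grid packing by default, with
   seeded random placement as an alternative; the placement is always
   written to the run manifest. Frames are constrained to the ROI's
   *allowed* territory — include minus exclude — so excluded structures
   (large TH-IR bundles, intrinsic cardiac ganglia, whose somata would
   otherwise inflate the skeleton) can never contribute, a guarantee tested
   by painting skeleton pixels inside the exclusion zone and asserting no
   record changes.
7. **Summaries and statistics** — per-ROI mean ± SEM (sample SD/√n over
   frames, reported from high to low), one-way ANOVA over ROI groups, and
   Tukey HSD at α = 0.05 in the Tukey–Kramer harmonic-mean form (reduces to
   classic Tukey for balanced data; for k = 2 the decision coincides with
   the pooled t test, which is tested numerically). Studentized-range tail
   probabilities come from `scipy.stats.studentized_range`. Shapiro–Wilk
   per group is reported as a diagnostic only — a normality rejection never
   switches the test, though a warning can be enabled. Whether published
   per-region dispersions are over frames or over animals is ambiguous in
   such protocols; the report labels its level (frames) explicitly.
8. **Heatmap** — the raster is tiled (default 64 px); each tile reports
   axon length and density, with ragged edge tiles using their true pixel
   area so borders are not artificially cold. Under `pixel_count` the tile
   lengths sum exactly to the whole-image skeleton length (a conservation
   law asserted in tests). Rendering uses the `turbo` colormap so maxima
   appear red.

## The synthetic scene generator

The generator exists so that every downstream stage can be validated
against *exact* ground truth without any external data.

**Axon growth** is a persistent-turning random walk with Poisson branching.
A tip advances in steps of `step_um` (default 4 μm); per step its heading
receives a Gaussian turn with SD `(1 − persistence)·π/2` (default
persistence 0.95 ≈ 4.5°/step, i.e. fairly straight trajectories, matching
the appearance of sympathetic axons in flat-mounts); bifurcations occur at
`branch_rate_per_um` (default 0.01/μm) with divergence angles of 34–69° so
that daughter tubes become resolvable within a few PSF widths. Growth is
round-robin across tips and the budget `max_total_length_um` is spent
*exactly* (the last step is trimmed), so the true total length — and hence
the true density of a region grown with budget = density × area — is
controlled analytically, not measured. Tips that would leave their region
steer toward the region interior; mirror reflection was rejected because
grazing tips then slide along walls and overlap themselves, making the
truth unrecoverable by any pixel-based method (an estimator test must not
be dominated by generator artifacts). Within a region the budget is split
into `budget / mean_arbor_length_um` roots (default 400 μm per arbor).

**Rendering**: axon centerlines are splatted as line integrals (bilinear,
0.25-px steps) and blurred by a Gaussian of
`√(axon_width² + psf_sigma²)` (defaults 1 μm each) scaled so the ridge
peak equals `axon_intensity` (default 120 of 255). Varicosities are point
boutons at exponential spacing (mean 6 μm) with a 2:1 bouton:shaft peak
ratio. Principal somata (~20 μm, truncated ≥ 14 μm) and SIF cells
(mean 7 μm, truncated < 10 μm, clusters of 3–8, intensity gain 1.8, always
TH-positive) are drawn as disks; their diameter supports do not overlap, so
classification ground truth is unambiguous, and cell bodies are placed with
a minimum separation because somata are solid. Large dim Gaussian blobs
emulate adipocyte autofluorescence; a tilted plane (default ±20%) emulates
uneven illumination. Noise is `Poisson(I·g)/g` (g = 0.5 photons per
intensity unit) plus Gaussian read noise (SD 2), then quantization to 8 or
16 bits with clip-and-warn on overflow. These defaults give a
peak-signal-to-noise ratio of roughly 8, typical of a reasonable confocal
acquisition.

**Determinism**: all randomness derives from one scene seed through named
streams (`arbor/<region>`, `cells`, `fat`, `illumination`, `varicosities`,
`noise`), so adding a distractor class never perturbs axon geometry, and
`render_scene(noise_seed=...)` draws replicate noisy acquisitions of one
fixed scene. Identical seed + parameters give bit-identical truth and
renders.

**What the generator does not emulate**: 3-D stacks and maximal-projection
artifacts, montage stitching seams, antibody penetration gradients, channel
crosstalk, and true axon-bundle topology. Passing the recovery tests
therefore shows the *measurement chain* is correct and calibrated on images
with known answers; it does not certify accuracy on real montages, where
segmentation difficulty is dominated by factors the generator idealizes.

## Validation experiments and problem sizes

- **Recovery scenes** (`atriadense.validation`): 512×512 px at 2 μm/px — a
  1.05 mm² field, the package's desk-scale stand-in for one montage region
  — four quadrant ROIs with true densities fixed at the values reported for
  the right atrium in this preparation (687.3, 401.7, 243.4, 113.6 μm/mm²;
  adjacent values separated by ≥ 25%). Background subtraction for these
  scenes uses a 40 μm disk (20 px), the physical-scale equivalent of the
  published 80 px at the study's 40× sampling. Over 100 seeded scenes the
  estimated ROI ranking matches the truth in ≥ 95 and the mean absolute
  relative density error of the diagonal-corrected estimator is ≤ 15%
  (measured ≈ 98/100 and ≈ 12%).
- **Estimator calibration**: digital straight lines (100 μm at 1 μm/px,
  half-open Bresenham chains so an axis-aligned 100 μm line is exactly
  100 px). `pixel_count` is exact on-axis and −29.3% at 45°;
  `diagonal_corrected` is exact at 0/45/90° and +6.9% at 30/60° (the
  two-weight bound above).
- **Statistical calibration**: frame densities modeled as normal per ROI
  (CV 15%): ANOVA type-I rate over 500 replicates at α = 0.05 falls in
  [0.03, 0.07]; with one ROI at 3× density Tukey rejects all its pairwise
  comparisons in ≥ 95/100 replicates; k = 2 Tukey decisions equal the
  t test on 50 random datasets to 1e-6.
- **Morphometry closed forms**: the Y-tree (root → branch point → two
  leaves, radii 1) gives 1 tree, 1 branch point ("node" follows the
  reconstruction-software convention of branch points, since the term is
  otherwise undefined), 2 terminals, total length 10 + 2√125 ≈ 32.361 μm
  and lateral-frustum surface 2π·32.361 ≈ 203.33 μm² (no end caps; equal
  radii reduce to a cylinder). Metrics are additive over forests and
  invariant under rigid motion to 1e-9 relative.
- **Determinism**: `run-all` on a packaged synthetic fixture is
  byte-identical across runs (CSV floats written at fixed precision;
  SHA-256 checksums recorded in the manifest).

## Numerical conventions and degenerate inputs

Coordinates are 0-based, row-major, pixel-centered; scene coordinates are
in μm with x → column. Areas are pixel count × (pixel size)². Masks are
stored as 8-bit TIFF with 255 = foreground. A constant image is a
degenerate histogram (error), zero within-group variance with unequal means
yields a flagged infinite-F result rather than an exception, a single-frame
ROI has no SEM (error), an ROI that cannot host the requested disjoint
frames raises a placement error naming the ROI, and SWC parents must be
defined before use (which also excludes cycles), with parse errors naming
the line.

## Known limitations

- Skeleton-length estimators undercount at terminals, junctions and
  merged sub-resolution strands (quantified above); densities in crowded
  fields are therefore biased low by roughly 5–15% even without noise.
- The diagonal-corrected estimator's +7% worst-case orientation bias is
  accepted in exchange for exactness at 0/45/90° and a fixed, simple
  definition.
- Counting-frame size and placement, and the μm/px conversion of the
  original study, are not stated in the protocol; published density values
  are therefore not numerically reproducible, and the package makes no
  attempt to do so — its claims are about calibrated recovery of known
  synthetic truth.
- Soma detection runs on single 2-D sections with an area-band filter; it
  does not split touching cells (generator inventories avoid overlap for
  exactly this reason) and does not attempt 3-D segmentation.
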
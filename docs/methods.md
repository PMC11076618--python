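# Methods

This note records the models, parameter choices and numerical decisions
behind `fibremorph`, and what the synthetic-data validation does and
does not demonstrate about real microscopy data.

## Image model and pre-processing

A muscle image is a three-channel acquisition — slow myosin (red), fast
myosin (green), collagen (orange) — on an isotropic pixel grid with a
physical pixel size in µm/px. The default pixel size of 0.5 µm/px stands
in for a 20× plan-apochromatic objective; it is configurable everywhere
because acquisition scales vary between microscopes.

Pre-processing is deliberately minimal and pure (same input ⇒ same
output):

- **8-bit conversion** rescales the nominal dtype range linearly to
  [0, 255], rounding half up, so 16-bit and 8-bit acquisitions enter the
  pipeline identically.
- **Collagen enhancement** stretches the histogram between the 1st and
  99th percentiles (defaults; the operation is standard, its parameters
  are lab-specific and therefore mandatory config). A constant channel
  is returned unchanged with a warning rather than divided by zero.
- **Segmentation input** is `clip(slow + fast − collagen_enhanced,
  0, 255)`: fibre interiors are bright in at least one myosin channel,
  and the enhanced collagen lattice carves dark boundaries between
  touching fibres.
- **Binarisation** is Otsu per channel by default; `fixed:<t>` pins a
  threshold for exact reproducibility across software versions. The
  collagen *area* is quantified from the binarised acquired collagen
  channel, not the stretched one: the stretch exists to sharpen
  boundaries for segmentation, and stretching first would inflate thin
  lattices after blur.

## Segmentation

The default backend is classical: Gaussian smoothing (σ = 2 px), Otsu
foreground extraction, Euclidean distance transform, seeds from local
maxima separated by at least half the minimum fibre diameter
(15 µm default — the physiological lower bound for adult large-mammal
fibres), and marker-based watershed. A learned instance-segmentation
model can replace it bit-compatibly through the `external-labelmap`
backend: everything downstream is a pure function of the label image.
Fibres touching the image border are partial profiles and are excluded
before classification (any pixel on the outermost row/column counts as
touching).

## Classification rule

A region of area ≥ A_min (default: a 15 µm-diameter circle,
≈ 177 µm²) is typed from its coverage in the two binarised myosin
masks with a single shared threshold T = 0.3 (per-channel thresholds are
supported but off by default): both coverages ≥ T → hybrid, exactly one
→ that type, neither → noise (an unstained object); sub-minimum regions
are noise regardless of staining. The size rule is a lower bound only.
The rule is monotone: raising T never converts a noise call into a
fibre call. Both cut-offs are lab-calibration constants and are echoed
into every run manifest.

## Morphometry

- **Minimum Feret diameter.** The Feret widths of a pixel set equal
  those of its convex hull, and the minimum width of a convex polygon is
  attained perpendicular to one of its edges, so the rotating-calipers
  minimum over hull edges is exact. ROIs are measured on the corner
  lattice of their pixels (each pixel spans a unit square), so a single
  pixel has width 1 px, not 0. Digitisation makes MFD accurate to about
  2 px under arbitrary rotation. Note for testers: the width-vs-angle
  function has V-shaped minima at edge-normal directions, so a uniform
  angle grid alone converges only linearly; the test oracle augments the
  grid with all pairwise perpendicular directions, which provably
  contain the optimum.
- **FTR** = n_slow / n_fast per image, pure classes only (hybrids count
  toward neither side); undefined — carried as NaN, never an exception —
  when n_fast = 0. Cross-image aggregation happens in the statistics
  layer, which consumes per-image values.
- **Hybrid percentage** is over classified fibres (noise excluded).
- **Nerve metrics.** AD and OD are equivalent-circle diameters
  2·√(area/π) of the axoplasm region and the axoplasm-plus-myelin
  region; MT = (OD − AD)/2 by definition, hence never negative. The
  equivalent-diameter convention is documented and swappable for a
  Feret-based variant. Measurement from a rendered section splits three
  intensity classes (dark myelin, intermediate axoplasm, light
  background) by two-level Otsu; components smaller than a 1 µm-diameter
  axon are discarded as debris.

## Statistics

One mixed model per metric across all conditions, cell-means coding:
`metric ~ 0 + condition + (1 | animal)`, REML. The animal random
intercept absorbs the pseudo-replication of multiple images per animal —
duplicating every image row shifts p by well under 5%. FTR is modelled
on the log scale (it is a ratio; positivity and symmetry of up/down
shifts), and estimates are reported on that scale.

Satterthwaite degrees of freedom are computed in-package on top of the
REML fit. For the random-intercept model the per-animal covariance
blocks are V_i = σe²I + σa²11′, whose inverse powers have the spectral
form σe⁻ᵏ(I − J/nᵢ) + λᵢ⁻ᵏ J/nᵢ with λᵢ = σe² + nᵢσa². Every trace and
quadratic form in the REML expected (Fisher) information of
θ = (σa², σe²) is then a cheap per-block accumulation, and for a
contrast c the df are 2·(c′Cc)² / (g′ I⁻¹ g) with C = (X′V⁻¹X)⁻¹ and
g = ∂(c′Cc)/∂θ. In balanced designs this reproduces the classical
between-animal df exactly (verified against lmerTest to all printed
digits); in unbalanced designs the expected-information variant differs
from observed-information implementations by ~1–2%. Boundary fits
(σ̂a² = 0) are flagged and fall back to fixed-effects residual df, never
silently; df are clamped to [1, N − p].

Pairwise p-values are Benjamini–Hochberg adjusted within the contrast
family of one metric (the family definition is configurable);
significance is exactly q < 0.1, and changing α requires a config change
that is echoed into output provenance. Effect sizes are unsigned
Cohen's d with the pooled sd, binned ≥ 0.2 small, ≥ 0.5 medium, ≥ 0.8
large. Nerve metrics are compared with Welch's two-sided t-test (the
more robust default when group variances are unequal). Boxplot
summaries use linearly interpolated quartiles, whiskers at
Q1/Q3 ∓/± 1.5·IQR, and define outliers as exactly the points beyond the
whiskers.

## Synthetic-data generator

The simulator emulates what the measurement chain needs to be tested
against, not photorealism:

- **Geometry.** Poisson-disc seed points (Bridson) at a radius
  calibrated so the equivalent cell diameter matches the requested mean
  fibre diameter (~1.37 × radius), two Lloyd relaxation iterations for
  the isotropic packed-polygon look, and Voronoi cells shrunk inward by
  half the collagen band, leaving an interstitial lattice of width equal
  to the band. A band of `fraction · mean_diameter / 2` yields
  approximately the requested collagen area fraction (near-hexagonal
  packing argument); the realised fraction is recorded exactly in the
  ground truth, and recovery is always scored against the realised
  value. Cells that degenerate under the shrink are dropped with a
  logged warning.
- **Types and intensities.** Each fibre is independently hybrid with
  probability h, otherwise slow with conditional probability
  s/(1 − h), so the marginal slow fraction is s. Pure classes render at
  mean 200 on their own channel over a background of 10; hybrids render
  at 60% of the pure mean on both myosin channels (they express both
  isoforms at intermediate levels); the lattice renders at 180 on the
  collagen channel. Gaussian blur (σ = 1 px) then Gaussian noise
  (sd = 8) are applied per channel; rendering refuses configurations
  whose class-vs-background contrast does not exceed the noise sd.
- **Cohorts.** The default design mirrors a stimulation study: groups
  CT (4 animals, no electrode, region PCA−), SHAM (8), DC04 (4) and
  DC07 (6), two muscle sides (nPCA/cdPCA), two regions near/far from
  the electrode (PCA+/PCA++), and three images per condition (multiple
  images per animal is what makes the random factor identifiable). Each
  animal draws one intercept on log-FTR (sd 0.3 by default), shared
  across its conditions; image-level variation then arises naturally
  from binomial sampling of fibre types. Everything is reproducible
  bit-for-bit from one seed.
- **Nerve sections.** Axons are non-overlapping discs (axoplasm at
  intensity 150) with darker myelin annuli (60) on a light background
  (230), toluidine-blue-like; AD/MT/OD per axon are stored as ground
  truth.

What the simulator does **not** model: uneven illumination, chromatic
aberration, staining gradients, out-of-focus tissue, fibre-type
clustering (except through the optional spatial `slow_field` used to
build zonated counter-examples), or 3-D section obliquity. Passing
recovery tests therefore demonstrates correctness of the measurement
chain under controlled conditions, not robustness to every real-world
artefact; the `external-labelmap` backend exists precisely so a learned
segmenter can replace the classical watershed when real images demand
it.

## Problem sizes in tests and acceptance

Validation uses sizes chosen to give tight statistics at desk scale:
ten noiseless 1024² px sections (~300 fibres each) for classification
accuracy; four-image batches at four designed FTR levels (0.25–2) for
ratio recovery; six 768² px images at 0.5 µm/px for collagen recovery at
5/12/25%; 50 axons at 0.1 µm/px for nerve recovery; 1000 null replicates
and 200 effect replicates (reduced two-group designs, 5–6 animals,
3 images each) for mixed-model calibration and coverage; 100 random
point sets against the brute-force width oracle; and two full seeded
runs compared byte-for-byte for determinism.

## Known limitations

- The watershed backend assumes a connected bright fibre phase separated
  by a darker lattice; heavily fragmented staining would need the
  external backend.
- Very thin collagen lattices (< ~2 px after blur) are not resolvable by
  global thresholding; recovery to ±2 percentage points needs the
  lattice sampled at ≥ 2 px width.
- The mixed model fits a single random intercept; random slopes or
  nested section effects are out of scope.
- Nerve AD/OD use equivalent-circle diameters; strongly elliptical
  axons would bias AD relative to caliper-based definitions.
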
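# Methods

This note documents the models, defaults, and design decisions behind
`reefscan`, and what the synthetic experiments do and do not demonstrate.

## Scene simulation (`reefscan.scene`)

**Label maps.** A transect is a rows × cols raster (row 0 = transect start;
pixel (i, j) centered at ((i+0.5)·res, (j+0.5)·res); meter m covers rows
[m/res, (m+1)/res), half-open so quadrat boundaries are never double
counted).  Patchy cover is generated by drawing one Gaussian white-noise
field per group, smoothing it at the patchiness correlation length
(default 0.5 m; tests often use 0.1–0.2 m to pack more independent patches
into short test transects), and letting groups claim their exact pixel
quota — largest-remainder apportionment of the target percentages — from
the unassigned pixels where their field is highest, largest quota first.
Realized covers therefore match targets exactly up to (a) pixel-count
rounding, bounded by #groups/#pixels in percent, and (b) renormalization
when the supplied targets do not sum to exactly 100.  Fine categories
within a group are split along a second smoothed field with Dirichlet
mixture weights, so fine patches stay spatially coherent.

**Endmembers.** Reflectance spectra are smooth per-group archetypes
(baseline + slope + Gaussian absorption troughs: chlorophyll-like dips near
440/675 nm for corals and green/brown algae, phycobilin-like dips near
495/565 nm for red-algal groups, a flat bright baseline for
turf/bare substrate) with seeded smooth perturbations per fine category.
Two dials control difficulty: `separation` scales archetypes away from
their across-group mean (1.0 default; 3.0 yields a minimum pairwise
group-mean spectral angle ≥ 0.15 rad, the "easy regime" used in the
end-to-end tests), and `intra_class_sd` (default 0.02) sets the
within-category multiplicative spectral variability.  A library is
regenerated with a new seed offset until the minimum group-mean angle
reaches `min_separation_rad` (default 0.05 rad); unattainable separation is
an error, not a silent pass.

**Scan rendering.** radiance(px, λ) = E(λ) · exp(−2·k(λ)·d) · R(px, λ) +
ε, with flat illumination E by default, two-way exponential water
attenuation at fixed altitude d = 1 m, piecewise-linear k(λ) (0.06 m⁻¹ at
400 nm, 0.45 m⁻¹ at the 700 nm knee, 4.0 m⁻¹ at 750 nm — a deliberately
simple model whose only required property is the near-total signal loss
above ~700 nm), additive Gaussian sensor noise (SD in radiance units), and
a 10×10 cm matte grey plate (albedo 0.35) rendered flat and recorded in the
cube's plate mask.  The cross-track axis is resampled (nearest neighbour)
to the sensor's 680 samples by default; simulation studies that need cube
and truth-map coordinates to coincide pass `samples=None`.  No Raman
scattering, glint, or depth variation is modeled.

**Survey sets.** Per-transect cover targets are drawn around survey means
with a configurable between-transect SD and renormalized to 100.  The
default SD is 10% of each group's mean — a compromise across the published
surveys, whose SD/mean ratios run from ~0.03 (dominant turf) to ~0.4
(sparse corals); analyses that depend on the variance structure (e.g. the
method-equivalence experiment below) set it explicitly.

## Preprocessing (`reefscan.preprocess`)

Fixed deterministic order: Savitzky–Golay smoothing (window 7, order 2 —
standard for spectroscopy; preserves constants and lines, attenuates
single-band spikes), band trimming, plate normalization, per-spectrum
z-scoring.  Whether smoothing preceded normalization in the original
workflow is unstated; the chosen order is a package decision and is
documented as such.  Band signal is estimated from the plate pixels (the
only calibrated region): SNR(band) = plate mean / plate SD, with the
conventions zero SD ∧ positive mean → ∞ (a noiseless cube never loses
bands) and zero mean → 0 (a fully absorbed band carries no signal).  Bands
below `min_band_snr` (default 3) are dropped — under the default water
model that removes everything above ~700–720 nm.  Normalization divides by
the mean plate spectrum and multiplies by `plate_albedo` (default 1.0:
reflectance relative to the plate, sufficient for classification since the
true plate albedo only rescales spectra), cancelling illumination and
water transmission so transects are comparable.  "Standardization" is
per-pixel z-scoring across bands (constant spectra map to zeros), making
classification depend on spectral shape rather than brightness.  Plate
statistics are computed in float64: the float32 mean of N identical values
is one ulp off, which per-spectrum standardization would amplify.

## Annotation (`reefscan.annotate`)

ROIs are polygons in pixel coordinates, one fine category each; a pixel
belongs to an ROI when its center lies strictly inside (even-odd rule via
shapely, checked against an exhaustive ray-casting oracle in tests).
Overlapping ROIs within a transect are an error.  The train/validation
split is stratified by group with per-group train share within one entry
of the requested fraction (default 0.9); whether the original workflow
stratified is unknown — stratification is this package's choice.  The
default split unit is the pixel (matching a "90% of labeled pixels"
protocol); `unit="roi"` keeps whole ROIs together, the methodologically
safer variant under spatial autocorrelation, and is what the rare-category
experiment uses.  `propose_rois` emulates expert annotation on synthetic
truth maps by rejection-sampling pure squares per group.

## Classifier (`reefscan.ssrn`)

Architecture (all sizes configurable; none are dictated by the original
description, which names the family but not the dimensions): per-pixel 1×1
projection of the bands to `reduced_channels` (default 32) → 
`n_spectral_units` (2) residual units acting along the feature axis
(h ← h + W₂·relu(W₁·relu(h))) → a learnable linear feature-adjustment
layer whose output width equals `reduced_channels` (the resize layer's
dimension is an open choice) → `n_spatial_units` (2) residual units acting
across the patch (h ← h + Conv3×3(relu(h)), zero-padded) → average pooling
over the `patch_size` (7) window → softmax.  Implemented directly in numpy
with explicit backpropagation and Adam (lr 1e-3, batch 128); the head is
initialized near zero so the first-epoch loss is ≈ ln(n_classes).
Training minimizes inverse-frequency class-weighted cross-entropy — the
minimal mitigation for rare-category failure — and early-stops on
validation accuracy (patience 8), restoring the best weights.  Edge pixels
use reflect padding so every recorded pixel gets a label; plate pixels are
labeled with a reserved code and excluded from cover; argmax ties break to
the lowest class index.  Prediction refuses cubes whose wavelength
fingerprint differs from training.  `n_classes` defaults to the 10 groups
(the resolution at which per-class proportions are reported, as recall =
row-normalized confusion diagonal); a 58-class mode exists but is not
validated against any published figure.  Determinism holds for a fixed
seed and BLAS thread count.

## Survey estimation (`reefscan.survey`)

One 0.5 × 0.5 m quadrat per meter mark, centered in its meter interval and
on the transect line (the original placement side is unstated).
"Nonaligned, systematically sampled" points are one uniform draw per cell
of a 10 × 5 grid (50 points), the standard stratified interpretation.
Point-intercept cover pools points across a transect's quadrats (identical
to averaging quadrat covers at equal point counts); map cover is the pixel
fraction per category over non-plate pixels.  Aggregation sums fine covers
onto groups (or any explicit mapping, e.g. pooling both coral groups into
"hard coral") and preserves row sums.  Juvenile status is a per-point
boolean attribute in simulation only.

## Community statistics (`reefscan.ecostats`)

Shannon H uses natural logs on normalized covers with 0·ln 0 = 0; E = H /
ln S with S fixed at the full 10-group column count, zero covers included
— this convention reproduces the published 2017 E (0.55) exactly; the
2015/2019 printed values differ by one unit in the second decimal,
consistent with their having been computed from finer-grained data than
the rounded group means, so only the exactly-reproducible values are
asserted.  Shapiro–Wilk, one-way ANOVA and Tukey HSD come from
scipy/statsmodels, with a compact same-letter display derived from the
pairwise rejections.  Bray–Curtis comes from scipy.  ANOSIM is implemented
in-package (ranked dissimilarities, average ranks on ties, R as above,
permutation p with the +1 correction, 9999 permutations by default,
seeded) and cross-checked against scikit-bio and a brute-force
enumeration; it runs on untransformed covers.  nMDS is an in-package
SMACOF: isotonic regression (scipy PAVA) of configuration distances on the
rank order of the dissimilarities, disparities rescaled to Kruskal's
convention, Guttman updates, stress-1 tracked per iteration
(non-increasing), 20 random restarts plus one classical-scaling start,
tolerance 1e-7, 300 iterations max; it runs on square-root transformed
covers.  The untransformed/√ split between ANOSIM and nMDS is deliberate
and preserved.

## I/O and pipeline (`reefscan.envi`, `cover_io`, `config`, `cli`)

ENVI rasters (text header + raw binary; BIL float32 little-endian default,
BSQ/BIP supported, wavelength list in the header, plate mask as a byte
sidecar) are read and written by a small in-package implementation.  Cover
tables use a long CSV (survey, transect, method, category, cover_pct) and
understand the `-PQ`/`-DR` survey-label suffix convention.  Pipeline
configuration is flat TOML with per-stage sections; each stage's seed is
derived as sha256(master_seed:stage) mod 2³¹−1, and a JSON manifest records
config snapshots, seeds, and input/output hashes.

## What the synthetic experiments show — and what they do not

The generator produces patchy communities with controllable spectral
separation and noise, but real scans differ in ways the simulator does not
attempt: 3-D rugosity and shadowing, variable altitude and depth-dependent
attenuation, glint, mixed pixels at fine-scale biological boundaries,
annotation error, and true taxonomic spectral diversity.  Consequently the
end-to-end tests validate the *pipeline machinery* (estimator consistency,
bookkeeping, statistical behavior), not field accuracy; the published
per-class validation proportions (0.88–1.0, red macroalgae 0.52) depend on
real imagery and are explicitly not reproduction targets.  What the tests
do establish, at reduced problem sizes chosen for quick runs (mini
transects of 2–4 m × 1 m at 1 cm pixels, a 10 nm wavelength grid, a
reduced classifier configuration):

- In an easy regime (group-mean spectral angle ≥ 0.15 rad, sensor noise SD
  0.003), end-to-end map covers recover ground truth within 2 percentage
  points per group on every transect, and held-out validation accuracy
  exceeds 0.9.
- Matched transects surveyed by both methods give a PQ-vs-DR ANOSIM
  consistent with no difference (p > 0.05) — *provided* between-transect
  variance dominates point-sampling noise.  ANOSIM is sensitive to
  dispersion differences between groups, and an exact, noise-free cover
  estimator compared against a 50-points-per-quadrat point count on short
  transects with large patches will register as "different" for dispersion
  reasons alone; the experiment therefore uses 0.1 m patches and 25%
  relative between-transect SD, the scaled-down analogue of 12,500-point
  surveys over 50 m transects.
- Validation accuracy degrades monotonically with sensor noise, and a
  category at ~1% cover is recognised substantially worse than dominant
  categories under an ROI-level split — the under-representation failure
  mode seen with rare taxa in the field.
- Simulated surveys separated like the published 2017 and 2019 means give
  ANOSIM R = 1: the pre- and post-disturbance communities do not overlap.

## Known limitations

- The bundled 58-category table is a synthetic, representative checklist;
  only its 10-group structure is survey-faithful.
- Per-transect replicate covers of the original surveys were released only
  as supplementary material and are not bundled, so the published
  between-survey ANOSIM statistics (R = 0.564, 1, 0.284) cannot be
  recomputed here; the corresponding check activates if
  `reefscan/data/s2_transect_covers.csv` is supplied.
- The radiative model is intentionally minimal (no glint, no Raman, no
  depth structure); the water attenuation curve is a caricature whose only
  contract is NIR signal loss.
- The numpy classifier is CPU-sized; it is not intended for real
  full-resolution scans.
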
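# Methods

`ihcfusion` quantifies DAB immunohistochemistry on brightfield image
tiles and fuses two markers mapped on adjacent tissue sections.  This
note describes the models and procedures the package implements, the
parameters that matter, and what the synthetic data generator does and
does not emulate.

## The analysis pipeline

### DAB extraction by color clustering

A tile's pixel colors are converted to CIELAB and grouped with Lloyd's
k-means.  The number of clusters is chosen automatically: for each k in
a configurable range (default 2–6) the clustering is run on a uniform
random subsample of at most 50,000 pixels and scored by the mean
silhouette coefficient; the k with the highest score wins, ties going
to the smaller k.  A cluster is called DAB-positive when its center,
expressed in HSV, is *brown and dark*: hue in [10°, 50°], saturation
≥ 0.15, and value ≤ the darkness threshold (default 0.75).  The
positive mask is the union of pixels labeled with any brown cluster,
restricted to tissue.

Choices worth knowing:

- **Color space.** CIELAB rather than raw RGB: perceptual uniformity
  stabilizes the brown/blue separation across staining intensity.
- **Tissue masking.** Glass is bright and unsaturated; a pixel is
  tissue when HSV saturation > 0.05 or value < 0.88, followed by
  morphological closing (edge-replicated so borders survive) and
  speckle/hole removal.  Positive fractions are always relative to
  tissue area.
- **Learning set.** The cluster count and the cluster centers are
  learned from tissue pixels only; every pixel still receives a label.
  On low-positivity tiles, whole-tile clustering lets the glass/tissue
  contrast soak up the clusters and a small brown population merges
  into the tissue cluster — restricting the learning set removes that
  failure mode without changing the rule.
- **Determinism.** k-means++ initialization from a fixed seed,
  convergence at center movement < 1e-4 or 100 iterations.  The
  per-iteration inertia trace is recorded and is non-increasing.  On
  megapixel tiles centers are fitted on a 200,000-pixel seeded
  subsample and all pixels assigned once; the exact-Lloyd path is the
  one verified against a brute-force oracle in the tests.
- **Degenerate tiles.** A uniform-color tile bypasses clustering: all
  tissue or nothing, depending on whether that one color satisfies the
  brown rule.  An all-glass tile yields an empty mask with positive
  fraction 0.

The darkness threshold and brown window have no canonical values; the
defaults are explicit, overridable configuration.

### Patch heatmaps

The tile is divided into non-overlapping 16×16-pixel patches (trailing
partial patches dropped; the grid is anchored at pixel (0,0), 0-based,
half-open).  Per patch, intensity is the mean *chromogen darkness* —
1 − HSV value — over the patch's DAB-positive pixels; patches with no
positive pixels score 0, patches without tissue are background (NaN)
and excluded from every statistic.  The grid is normalized to [0, 1] by
its own maximum, which is recorded so raw values can be recovered; no
cross-slide calibration is attempted.  Darkness-over-positive-pixels,
rather than a positive-pixel count, makes intensity highest where
immunoreactive labeling is strongest.  Rendering interpolates HSV
linearly from turquoise (low) to red (high), a monotone hue path;
background patches render neutral gray.

### Registration and conditional fusion

Adjacent paraffin sections differ essentially by placement, so
alignment is rigid (translation + rotation about the tile center;
nothing deformable).  Translation is estimated by phase correlation on
downsampled grayscale; rotation by a coarse (0.5°)-to-fine (0.1°) grid
search over ±4° maximizing normalized cross-correlation, with a final
full-resolution subpixel translation at the best angle.  Two sections
stained for different markers correlate weakly even when perfectly
aligned, so the low-confidence flag fires only below NCC 0.1.  On
synthetic pairs the estimator recovers shifts within ~0.2 px and
rotations within ~0.1°.

Fusion operates on *binarized* patch grids — with continuous colormaps
"different" would be true almost everywhere.  Each grid's high set is
the patches at or above a per-grid quantile (default 0.75) of
tissue-patch values; a patch with zero signal is never "high".  Grid B
is resampled onto A's patch grid by mapping patch centers through the
transform and taking the nearest B patch (nearest-neighbor keeps
classes crisp).  The conditional rule: high in both → concordant-high
(red); high in exactly one → discordant (white); low in both →
concordant-low (turquoise); missing tissue in either → background.
The rule is symmetric and the four classes partition the grid.

### Marker statistics

Correlations (Pearson and Spearman, both reported) are computed at
patch granularity — patches are the heatmap's pixels — over patches
carrying tissue in both grids; fewer than 10 such patches is an error,
and zero variance yields a flagged *undefined* correlation, not 0.
Region summaries project pixel-level region masks (necrosis,
pseudopalisading rim, viable) to the patch grid by majority vote and
report per-region patch counts, per-marker mean intensities and
positive-patch fractions, and the B − A contrast.  Region means
recompose the global mean exactly when weighted by patch counts.  The
reports are descriptive; no p-values are attached.

## The synthetic histology generator

The generator produces pairs of pseudo-adjacent sections with complete
ground truth, emulating the staining geometries of microglia/macrophage
markers around glioblastoma necrosis:

- **Geometry.** Tissue is a smoothed blob occupying 1 − glass_fraction
  of the tile.  Necrotic cores are thresholded low-frequency Gaussian
  fields (irregular shapes, not circles), bisected to the target area
  fraction — defined as a fraction of *tissue* area — keeping the n
  largest foci.  The pseudopalisading rim is the morphological ring of
  configurable width outside the necrosis boundary.
- **Cells.** Poisson-planted per compartment: viable tissue at
  `cell_density` (default 2.0 cells / 1000 px²), the rim at 2.5× that
  density, necrosis at `hypocellular_factor`× (default 0.1).  Each cell
  is a nucleus disc (r = 3 px) plus, when DAB-positive, a soma disc
  (r = 4 px) with four radiating processes (ramified morphology).
- **Staining.** Per-marker DAB is deposited (a) on the somata and
  processes of a `cellular_fraction` of viable cells, (b) diffusely in
  necrosis to a target coverage (`diffuse_in_necrosis`), optionally
  over viable tissue (`diffuse_in_tissue`) or in an explicit scripted
  region, and (c) on rim cells with elevated probability and weight
  (`rim_intensity`).  The union of these components *is* the ground
  truth mask — no unrecorded chromogen exists.
- **Rendering.** Beer–Lambert: per-pixel hematoxylin and DAB optical
  densities are combined along published-style stain vectors
  (hematoxylin [0.651, 0.701, 0.290], DAB [0.269, 0.568, 0.778]) and
  attenuated exponentially to 8-bit RGB.  Default chromogen OD is 1.2;
  counterstain baseline 0.25 with dark nuclei (+0.5).  Dense chromogen
  masks the counterstain (×0.5 under DAB), keeping mixed pixels in the
  brown hue range as in real DAB.  Gaussian noise (σ = 0.05 OD) is
  added per stain channel.  Necrotic tissue keeps the viable
  counterstain baseline — its pallor is expressed through
  hypocellularity — which keeps the tissue mask well defined.
- **Adjacent sections.** Section B is section A's geometry under a
  rigid transform (rotation about the center, then translation), with
  `section_resample` (default 5%) of cell positions redrawn: adjacent
  sections share structure but not exact cells.  Three properties are
  *block-intrinsic*, i.e. shared between the sections: each cell's
  marker-affinity quantile (a cell positive on one section is positive
  on the other), each marker's diffuse deposition field (seeded by the
  tissue seed and the marker's deposition parameters), and the spatial
  pattern of the counterstain baseline.  Without these, two sections
  stained with identical models would disagree by construction; with
  them, the fusion map's discordance under identical models and
  identity placement is pure noise (measured 0.03–0.05).

**What the generator does not emulate:** nuclear texture, scanner/optics
noise, stain fading, tissue folds and edge artifacts, deformable
section-to-section distortion, vasculature, and erythrocytes (whose
red hue borders the brown window).  Passing tests therefore demonstrate
that the pipeline recovers planted signal under idealized optics and
rigid geometry; they do not certify performance on scanner WSIs, where
the brown window, darkness threshold and tissue-mask thresholds will
need recalibration.

## Problem sizes and numerical choices

Recovery experiments run at 1024² tiles for area-fraction recovery
(where the planted fractions 0.05/0.20/0.50 are deposited as blob-like
diffuse coverage and truth is read from the generator's own masks) and
512² section pairs elsewhere — sizes at which every planted quantity is
comfortably identifiable while a full experiment set completes in
minutes on one CPU.  The acceptance script uses 512² tiles with 5 seeds
per condition for the same reason.  Quantile thresholds use linear
interpolation (numpy default); ties at a threshold are included.  The
planted-overlap fusion experiment uses a patch-aligned section offset
(16, −16, 0°) so that it measures the fusion rule rather than the
patch-grid quantization of region boundaries; arbitrary subpixel
transforms are exercised by the registration experiments instead.

## Known limitations

- Automatic k by silhouette has a detection floor: a marker occupying
  well under ~1% of tissue in a visually busy tile can fail to earn its
  own cluster, biasing positive fractions toward 0.  The fixed-k
  configuration is the workaround.
- Max-normalization ties heatmap scales to each tile's own extremes, so
  absolute values are not comparable across tiles — only ranks and
  binarized classes are.
- Registration assumes rigid placement; real serial sections also
  stretch and fold, which would require deformable registration
  (deliberately out of scope).
- Correlations between markers on adjacent sections conflate biological
  divergence with residual misalignment at patch granularity.
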
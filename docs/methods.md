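# Methods

## Pipeline

Each field of view is processed as: load one channel with an explicit
pixel-size calibration → (optional) maximum-intensity projection of a
z-stack → denoise → threshold → mask cleanup → measurements. All
measures are deterministic functions of the mask and configuration.

**Calibration.** Pixel size (µm/px) is never read from file metadata;
TIFF resolution dialects are unreliable and a silently wrong calibration
corrupts every density. The analyst supplies it per run. Coordinates are
row-major, origin top-left, 0-based.

**Denoising.** 3×3 median by default (`radius_px` = window half-width);
Gaussian blur available. The median suppresses shot noise and single-pixel
speckle while preserving edges to within one pixel. Note that a median is
not the identity even on noise-free two-level images: foreground pixels
with fewer than five same-valued votes in their window (sharp tube tips,
concave notches) flip, so denoised segmentation of a clean stamp is exact
up to a thin boundary rim, not pixel-perfect.

**Thresholding.** Otsu's method (256-bin histogram over the observed
range, foreground strictly above the threshold) by default — automatic
and parameter-free; a fixed threshold is available for cross-image
comparability. Otsu on a constant image is refused as degenerate rather
than guessed.

**Cleanup.** Foreground components (8-connected) smaller than
`min_object_area_um2` are removed — default 25 µm², below any capillary
cross-section at typical magnifications, so real vessels are never
discarded. Hole filling (4-connected background) is off by default.
Foreground is 8-connected and background 4-connected everywhere, the
standard digital-topology pairing.

## Skeleton analysis

The mask is thinned with homotopic Lee-style medial-axis thinning
(`skimage.morphology.skeletonize(method="lee")`): one-pixel-wide,
8-connected, preserving component and hole counts. Skeleton pixels are
classified by their 8-neighbor count — 0 isolated, 1 endpoint, 2 slab,
≥3 junction pixel. Mutually 8-adjacent junction pixels are merged into
one junction node: thinning produces junction clusters at oblique
crossings, and counting raw junction pixels would inflate branching
(a symmetric cross already yields a 5-pixel cluster). The branch-point
count is the number of merged nodes.

Edges are maximal slab paths between node clusters. Segment length uses
the step-count metric — orthogonal step 1 px, diagonal √2 px — including
the steps that attach the path to its terminal node pixels, and
continuing inside a multi-pixel junction cluster to the cluster's anchor
pixel (the pixel nearest its centroid). The anchor extension makes each
segment measure its full geometric arm: a cross of two 9-pixel lines
yields four arms of 4 µm at 1 µm/px. For n collinear pixels the length is
n−1 steps; length-per-pixel conventions that count n differ by one pixel
per segment. Isolated closed loops (no junction) become a single
self-edge anchored at the lexicographically smallest cycle pixel, with
node kind `cycle`.

Spur pruning is off by default — the workflow this package reimplements
does not prune, and pruning changes branch counts; `prune` behavior can
be emulated by raising `min_object_area_um2` only for mask-level noise,
never for skeleton arms.

Lee thinning resolves ties by scan order, so thinning a rotated mask can
differ from rotating the thinned mask by an occasional diagonal choice
(sub-percent in length). Graph construction itself is exactly symmetric:
rotating or mirroring a *skeleton* leaves total length, branch-point and
segment counts bit-identical, and all mask-level measures (area fraction,
NND) are exactly invariant.

## Metrics and units

With field area A = H·W·(pixel size)²/10⁶ mm²: length density =
(Σ length µm / 1000)/A, branch density = junction nodes/A. Densities
normalize to the full rectangular field; crop to a region of interest
before analysis if needed. Doubling the pixel size doubles lengths
exactly, halves length density and quarters branch density.

**Nearest-neighbor distances.** Default `centroid` mode: label
8-connected components, one distance per component to its nearest other
centroid (matching particle-based NND plugins). `skeleton` mode instead
measures minimum pixel-to-pixel distance between distinct skeleton
components — an edge-to-edge reading; which variant the original
interactive workflow used is not recoverable, so both are provided and
the mode is recorded in the output. Fields with fewer than two objects
return an empty list (the quantity is undefined, not zero); the per-field
summary is then absent rather than 0.

**Pericyte coverage** is the ratio of area fractions, not a geometric
overlap: it can exceed 1 with abundant off-vessel signal and is then
reported unclipped with a warning — clipping would hide staining
problems. Optional restriction intersects the pericyte mask with the
vessel mask dilated by a physical radius (5 µm — about one pericyte
soma — is a reasonable choice when enabling it); the default is the
literal unrestricted ratio.

**Heatmap.** Tile edge = ⌊width/n⌋ px; remainder pixels form partial
edge tiles with their own pixel counts instead of being discarded, so the
pixel-count-weighted tile mean equals the global area fraction exactly
(validated to 1e-12). Rendering normalizes to the per-image maximum by
default; pass a fixed maximum to compare images.

## Synthetic networks

The generator grows branching self-avoiding random walks — it is a test
bed with exact ground truth, not a biophysical angiogenesis model. Trees
start at seed points with ≥4 tube-thickness mutual spacing and grow in
3 µm steps with Gaussian heading jitter (SD 0.15 rad, clamped at 2 SD) —
curvature below the smoothing scale of thinning, as real capillaries are
smooth at this scale. A clearance rule keeps every new vertex ≥ thickness
+3 px from all other tube centerlines (sufficient to prevent even
diagonal pixel contact after rasterization); only the branch's own last
five vertices are exempt, so a path cannot curl back and merge with
itself. Bifurcations occur with probability 0.08 per step, subject to a
10 µm minimum separation between junctions; the two arms at a fresh
junction may violate clearance with respect to each other inside a
4-step zone around the branch point (arms necessarily start one step
apart), and a bifurcation is only recorded and stamped after both arms
commit four straight steps — guaranteeing every recorded junction has
three genuine arms that survive thinning. Tubes are rasterized by disk
stamping at 0.25 px spacing; single-digit-pixel background pinholes left
in concave junction corners are filled at rasterization time (they are
raster artifacts that homotopic thinning would otherwise preserve as
spurious cycles — genuine inter-branch loops are far larger and kept).

Defaults — 512×512 px at 1 µm/px, 20 seeds, 4 µm tubes, branch
probability 0.08, branch lengths 12–25 steps — produce capillary-bed-like
fields: area fraction ≈ 0.03–0.08, length density ≈ 8–17 mm/mm², mean
inter-vessel distance ≈ 55–75 µm, in the range reported for cortical
microvasculature. Ground truth records the polyline (pre-raster)
centerline length, bifurcation count, stamped pixel count, component
count and pericyte fraction; all randomness flows from explicit seeds.

What the generator does *not* emulate: point-spread blur, uneven
illumination, staining heterogeneity, vessel caliber variation
(arteries/veins), 3D geometry projected to 2D, or lesion structure.
Passing validation therefore demonstrates correctness of the measurement
chain on known geometry, not segmentation performance on real tissue.

The pericyte channel stamps exactly `round(fraction × vessel pixels)`
vessel pixels as contiguous patches (80–240 px) grown along the vessel —
mural cells wrap stretches of wall, and a coherent stamp also survives
the median filter — so the unrestricted coverage ratio equals the stamped
fraction exactly by construction.

Noise injection adds Gaussian intensity noise and Poisson-distributed
bright single-pixel speckles; ground truth continues to describe the
clean stamp. At signal 200 and noise SD 40 (SNR 5) with 50 speckles/mm²,
default preprocessing recovers the clean mask at IoU ≈ 0.98 (the ~2%
disagreement is the median's boundary rim).

## Validation quantities and problem sizes

`scripts/acceptance.py` re-derives everything at run time: hand-traceable
skeleton analytics (11-px line → 10 µm; 6-px diagonal → 5√2 µm; plus-sign
→ 16 µm, 4 segments, 1 junction); 20 default fields for length recovery
(observed worst-case ≈ 1–2%, bound 5%) and exact bifurcation recovery;
50 random masks for heatmap conservation; 20 random point fields (≤50
objects) for NND-oracle agreement; coverage at stamped fractions 0.25,
0.43, 1.0; 20 fields × 40% random component deletion for the rarefaction
trend (all four metrics move in the rarefaction direction in ≥19/20
fields — less vessel, larger gaps); 10 noisy fields for recovery IoU.
These sizes keep a full run within a couple of minutes on one core while
leaving each property statistically meaningful.

## Known limitations

* 2D only; z-stacks are analyzed per-slice or max-projected, which
  overestimates area fraction in thick sections.
* No vessel diameter estimation, no artery/vein typing, no barrier
  (leakage) readout — the mask-based metrics carry no wall information.
* Thinning artifacts at the 1-px scale mean segment counts on real,
  ragged masks depend slightly on the thinning variant; branch-point
  counts are robust after cluster merging.
* The NND definition is object-based; a single connected plexus yields
  no NND at all. Use `skeleton` mode or pre-cut the mask when analyzing
  fully connected beds.
* Group summaries are descriptive only, by design.
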
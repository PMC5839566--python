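# Methods

## Scope and data model

The package analyses two kinds of scenes: still images of bright,
near-circular fluorescent objects on a dark background, and videos of
elliptical objects carried through a microfluidic channel by laminar
flow. Frames are 8-bit grayscale or RGB numpy arrays; coordinates are
0-based (row, col); rectangles are half-open (x, y, width, height).
Blobs detected inside a cropped region of interest are reported in
full-frame coordinates.

## Still-image counting

The procedure uses the marker-extraction half of the watershed recipe;
the flood itself is not needed because the number of markers *is* the
count.

**Preprocessing.** White top-hat with a disk structuring element
(`tophat_kernel`, default 25 px diameter) removes any background
structure larger than the objects, which makes the count exactly
invariant under global additive illumination shifts and flattens
gradients. Histogram equalization follows (contrast stretch for
visibility and for dim real-world objects), then a median blur
(`median_kernel`, default 5) suppresses impulse noise.

**Segmentation threshold.** Otsu's threshold is computed on the
median-filtered top-hat image, where the object/background histogram is
genuinely bimodal. Equalization is a monotone remapping, so the
partition is the one a threshold on the fully preprocessed image would
produce at the remapped level, without the 8-bit quantization
fragility that equalization introduces when objects cover a small pixel
fraction (it compresses them into the top few grey levels). Candidate
regions smaller than `min_object_area` (50 px²) or with mean levelled
intensity below `min_prominence` (25 levels) are rejected; the latter
makes a blank, noise-only image count zero.

**Declumping.** For each candidate region the Euclidean distance
transform *D* is cut at `threshold_fraction` (0.4) of the region's own
maximum — per-region normalization keeps the step scale-free — and the
resulting core is shrunk two ways: the configured binary erosion
(3×3 cross, `erode_iterations` = 2) and reconstruction-based erosion,
i.e. *h*-maxima of *D* smoothed with a 0.7 px Gaussian at depth
`split_depth` = 0.35 px. Either mechanism separating a core into
pieces splits the count. Because optical blur partially fills the
concave waist between deeply fused objects (the distance-transform
saddle of two equal disks at 50% centre separation lies at 0.87 of the
peak, and boundary discretization erodes the remaining margin), a
third, purely geometric check backs these up: for a component with
area *A* and inscribed radius *r* = max *D*, the ratio *A*/(π*r*²) is
≈1.06 for a single near-circular object *independent of its size*
(`single_area_factor` absorbs the systematic discretization offset),
while a fused pair keeps the inscribed radius of its larger member and
nearly doubles the area, giving ratios ≥1.38 for any overlap shallow
enough to leave two distance peaks. Components above
`area_split_ratio` (1.28) are assigned multiplicity
round((ratio/1.055 − 0.39)/0.61), each chained object adding ~0.61
(its area minus one pairwise lens). The reported count per component
is the maximum of the three estimates; marker centroids (or the
component centroid for objects inferred only by multiplicity) are the
per-object position estimates.

This declumping assumes near-circular, similar-sized objects — valid
for calibration microspheres, and the reason the naive single-threshold
connected-components baseline (`naive_connected_count`, kept as a
comparison oracle) undercounts clumped scenes by the full clump
fraction while the declumped count stays exact at 30% clumping.

**Intensity window.** The optional `intensity_range` filter zeroes
pixels outside an expected range before thresholding; it removes
saturated speckle (hot pixels, reflections) that would otherwise be
counted.

## Background subtraction (flow videos)

A pixel-based adaptive segmenter: every pixel keeps `n_samples` = 20
background intensity samples, a decision distance *R(x)* and an inverse
update probability *T(x)*. A pixel is foreground when fewer than
`min_matches` = 2 samples lie within *R(x)* of its current intensity.
Background pixels refresh a random sample with probability 1/*T(x)*
and, with the same probability, refresh a random sample of a random
8-neighbour with that neighbour's current value — this spatial
diffusion is what slowly absorbs objects that stop moving (a 50×50
square left static loses ~30% of its foreground area within 500
frames; full absorption takes a few thousand). *R(x)* relaxes toward
`r_scale`·(mean minimal sample distance), tracked as an exponential
moving average (`dmin_alpha` = 0.05) rather than a stored window — a
deliberate simplification with the same fixed point; *T(x)* grows on
persistent foreground so true objects are not learned into the model.
Constants follow the published defaults of the pixel-based adaptive
segmenter literature and are all config-exposed, since none is a
calibrated quantity. The model is luminance-only; colour frames are
converted before banking. All stochastic updates draw from a seeded
generator, so runs are bit-reproducible. A running-average fallback
(`simple_mode`) exists for debugging and is not the default.

With the default initial/floor decision distance of 18 levels, the
low-contrast (helminth-like) scenes — luminance gap ~5 levels — produce
no foreground at all. That is intended: it reproduces the need for the
colour-segmentation step.

## Colour segmentation

K-means (k = `n_color_clusters`, default 3) in RGB space, fitted once
on pixels pooled from frames sampled across the whole video (so the
sparse target colour is represented and cluster identities are
temporally stable), then every pixel is mapped to a grey level assigned
by the rank of its cluster's luminance, ranks spread evenly over
[0, 255]. Mapping to spread levels rather than to the cluster means is
what converts a chromatic difference with a small luminance gap into
usable grey-level contrast for the downstream threshold.

## Morphology, blobs, area filter

Foreground masks are cleaned by a closing (joins blob fragments
separated by gaps narrower than the element) followed by an opening
(removes specks smaller than the element). The structuring element is
elliptic 7×5 for glochidia-like rounded targets and square 5×5 for
helminth-egg-like targets; sizes are conventions, not calibrated
values. Blob extraction labels the cleaned mask and takes one blob per
outer contour (edge detection runs on the cleaned mask, where contour
detection is the operative step); nested contours are ignored. Blobs
outside [`min_area`, `max_area`] — defaults 0.3× and 3× the expected
target area — are discarded, which is what rejects debris.

## Tracking and counting

Nearest-centroid association: candidate (track, blob) pairs within
`max_match_dist` (default 3× the expected per-frame displacement) are
matched greedily in ascending distance order, ties broken toward the
lower track ID; this equals the minimum-total-distance assignment in
the sparse scenes it is designed for. Unmatched blobs spawn fresh IDs;
tracks unseen for `patience` = 5 frames retire. A track is counted at
most once (a `counted` flag), on the frame its last two centroids
straddle the virtual-line column in a direction allowed by the policy,
provided the crossing blob's area passes the target-match criteria
(extensible via a predicate). Two objects that touch in-frame merge
into one blob and one of their tracks coasts; if they separate past
the line the lost object is not recounted — the documented source of
dense-scene undercounts.

## Size calibration

factor = channel_width_um / channel_width_px (350 µm default; the
channel width in pixels comes from the config — the generator knows it
exactly, and automatic wall detection is out of scope). An object's
size is the longest axis-aligned bounding-box dimension at its
crossing frame (`size_at="max"` switches to the track-wide maximum).
The bounding box of a tilted ellipse is shorter than its major axis,
so sizes of misaligned elongated objects are *under*estimated; objects
in laminar flow align closely with the flow direction, so the bias is
small (<1 px at the default ±5° orientation jitter). Histograms use
half-open bins of `bin_width` (default 5 µm); no open/closed-shell
classification is attempted — a mixed population simply yields a
bimodal histogram.

## Synthetic scenes

The generator renders what the analysis assumes, with exact ground
truth (per-object centres per frame, axes, crossing frames, debris
areas):

* **Stills** (1024×1024 default): anti-aliased disks, radius
  10 ± 0.5 px (calibration microspheres are tightly sized), peak 200
  on background 20, 1 px Gaussian blur, noise σ = 3, optional
  illumination ramp. A `clump_fraction` of objects is placed to
  overlap an anchor at centre separation
  `overlap_fraction`·(r₁+r₂); non-clumped objects are disjoint by
  construction. Overlapping disks max-combine (opaque material), they
  do not add.
* **Flow videos** (640×480 default, 30 frames/s metadata): a bright
  channel band (rows 150–330, so 180 px stands for the 350 µm channel
  width) bounded by dark walls; ellipses (60×40 px default) enter
  left, fully off-screen, at staggered frames and translate
  horizontally at 10 px/frame with a ±10% per-object speed spread
  (laminar flow carries lanes at different speeds; this also makes
  in-frame co-locations transient rather than permanent). High
  contrast renders objects at grey 60 on 180 (glochidia-like); low
  contrast at a ~5-level luminance gap but ~25 RGB units of chromatic
  difference (helminth-like). Debris are small random polygons with
  areas strictly below `debris_max_area`, drawn in the same intensity
  band as targets so only the area filter can reject them.
  Illumination drift is a global additive ramp
  (levels per 100 frames). Frame 0 is object-free so it can seed the
  background model. Lane assignment keeps simultaneous objects
  vertically separated unless `allow_overlap` is set (used for the
  dense regime: 150 objects at 10-frame entry spacing, where roughly a
  quarter of the objects co-locate with another at some point).

What the generator does **not** emulate: out-of-focus/point-spread
structure, photorealistic shell shapes (open vs closed valves),
non-rigid motion, camera shake, compression artefacts, or debris that
matches targets in both size and intensity. Passing tests therefore
demonstrate the algorithmic contracts — declumping, adaptation,
tracking, calibration — not performance on any particular real sample.

## Problem sizes and determinism

The test suite and the acceptance script use scenes of 10–300 objects
per still image, flow videos of ~120–1900 frames, and one 150-object
dense video — sizes chosen to exercise every regime while keeping a
full run in the minutes range. Every stochastic component (scene
generation, k-means initialization, background-model updates) is
seeded; two runs with the same config and seed produce byte-identical
CSV outputs. Video I/O uses PNG frame directories or multi-page TIFF
stacks (lossless); compressed video containers are out of scope.

## Known limitations

* Declumping assumes near-circular objects of similar size; elongated
  or widely size-dispersed populations would defeat the
  area-multiplicity check.
* Merged objects crossing the line together are counted once; the
  dense-scene error (~4% at the default dense regime) is dominated by
  this effect.
* The bounding-box size measure underestimates tilted elongated
  objects.
* Colour segmentation assumes targets differ from the background in
  chroma; grey debris in a grey channel would need a different cue.
* The channel width in pixels must be supplied; walls are not
  auto-detected.
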
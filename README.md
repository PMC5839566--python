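# flowcount

Counting and sizing microscopic objects in micrographs and microfluidic
flow videos — the kind of analysis needed when screening fluorescent
calibration beads, helminth (*T. muris*) eggs in fecal suspensions, or
glochidia (freshwater-mussel larvae) during artificial propagation,
where manual counts under a microscope are slow and error-prone.

Two pipelines are provided, together with a synthetic scene generator
that renders every study condition with exact ground truth, so each
stage is testable without real specimens.

**Still images** (fluorescent objects on a dark background) are counted
with a declumping procedure derived from watershed marker extraction:

1. preprocess: white top-hat (background levelling), histogram
   equalization, median blur;
2. optional intensity window (zero pixels outside an expected range);
3. threshold (Otsu on the levelled image) → candidate regions;
4. Euclidean distance transform *D(x)*; each candidate is cut at
   0.4 · max *D* of its own region and shrunk (binary erosion and
   reconstruction-based *h*-maxima of *D*) until touching neighbours
   separate; a scale-free area-multiplicity check
   (area / π·max *D*² ≳ 1.3 ⇒ fused objects) backs up the shrink step;
5. connected components of the markers give the count.

**Flow videos** (objects translating through a microfluidic channel)
are analysed frame by frame:

ROI crop → *(low-contrast samples only)* k-means colour segmentation →
pixel-based adaptive background subtraction (per-pixel sample bank *B*,
decision distance *R(x)*, update rate 1/*T(x)*) → morphological
erosion/dilation with an elliptic (glochidia) or rectangular (helminth)
structuring element → Canny/contour blob detection → area filter →
nearest-centroid greedy tracking → a track is counted once when its
centroid crosses a virtual line and its blob matches the target
criteria. Blob sizes are converted to micrometres with the factor
calibrated from the known channel width (350 µm by default):
size = max(bbox width, bbox height) · (350 µm / channel width in px).

Accuracy is summarized as the mean absolute percentage error
MAPE = mean |software − manual| / manual × 100 over counting
experiments.

## Worked example

Generate a synthetic flow video of 10 glochidia-like objects plus
debris, describe the channel geometry in a config, then count and size:

```sh
$ flowcount synth flow --n-objects 10 --n-debris 20 --seed 7 --out video.tiff
wrote 265 frames to video.tiff (10 objects)
$ cat glochidia.yaml
sample_type: glochidia
flow:
  roi: {x: 0, y: 144, width: 640, height: 192, mode: glochidia}
  channel_width_px: 180
$ flowcount flow video.tiff --config glochidia.yaml --out-dir results/
count: 10
median size: 115.7 um (n=10)
outputs in results/
```

The count (10) matches the generator's ground truth; the debris
particles are rejected by the area filter and never tracked. The
180 px channel width calibrates 350/180 ≈ 1.94 µm/px, and the median
size of 115.7 µm corresponds to the true simulated major axes
(≈109–127 µm); `results/` contains the crossing-event log, per-object
sizes, a size histogram and a JSON summary. The same works for still
images:

```sh
$ flowcount synth still --n-objects 12 --seed 5 --out-dir synth/
wrote synth/image.png with 12 objects
$ flowcount still synth/image.png
count: 12
```

And count-accuracy summaries from a CSV of (manual, software) pairs:

```sh
$ flowcount eval pairs.csv
...
MAPE: 11.21% (11% at integer rounding)
```

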
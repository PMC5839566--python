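"""From foreground masks to filtered candidate blobs.

Stages: ROI crop, optional colour segmentation (low-contrast samples),
morphological cleaning with a mode-specific structuring element, edge +
contour detection, and area filtering.  Coordinates are 0-based
(row, col); rectangles are half-open (x, y, width, height) in full-frame
pixels -- blobs detected inside a cropped ROI are reported back in
full-frame coordinates via their crop offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.feature import canny
from skimage.measure import find_contours, label, regionprops
from sklearn.cluster import KMeans

logger = logging.getLogger("flowcount")

__all__ = ["RoiConfig", "MorphParams", "Blob", "crop_roi", "ColorSegmenter",
           "color_segment", "morphological_clean", "detect_blobs",
           "filter_by_area"]


@dataclass
class RoiConfig:
    """Axis-aligned region of interest covering the channel width."""

    x: int
    y: int
    width: int
    height: int
    mode: str = "glochidia"  # {"glochidia", "helminth"}

    def validate(self, frame_shape) -> None:
        h, w = frame_shape[:2]
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI width and height must be positive")
        if not (0 <= self.x and 0 <= self.y
                and self.x + self.width <= w and self.y + self.height <= h):
            raise ValueError(f"ROI {self} outside frame of shape {(h, w)}")


@dataclass
class MorphParams:
    """Structuring element and iteration counts for mask cleaning.

    ``element_shape`` is ``"ellipse"`` (glochidia-like rounded targets) or
    ``"rectangle"`` (helminth-egg-like targets).  ``element_size`` is a
    single size or a ``(width, height)`` pair in pixels.
    """

    element_shape: str = "ellipse"
    element_size: int | tuple[int, int] = (7, 5)
    erode_iterations: int = 1
    dilate_iterations: int = 1

    def footprint(self) -> np.ndarray:
        size = self.element_size
        if np.isscalar(size):
            w = h = int(size)
        else:
            w, h = int(size[0]), int(size[1])
        if w < 1 or h < 1:
            raise ValueError("element_size must be >= 1")
        if self.element_shape == "ellipse":
            return morphology.ellipse(max(h // 2, 1), max(w // 2, 1))
        if self.element_shape == "rectangle":
            return np.ones((h, w), dtype=bool)
        raise ValueError("element_shape must be 'ellipse' or 'rectangle'")


@dataclass
class Blob:
    """One detected connected object in a frame."""

    contour: np.ndarray           # (N, 2) array of (row, col)
    area: float                   # pixel count of the interior
    centroid: tuple[float, float]  # (row, col), sub-pixel
    bbox: tuple[int, int, int, int]  # (x, y, w, h)
    frame_index: int = 0

    @property
    def max_dimension(self) -> float:
        return float(max(self.bbox[2], self.bbox[3]))


def crop_roi(frame: np.ndarray, roi: RoiConfig) -> np.ndarray:
    """Return the ROI sub-frame (a copy)."""
    roi.validate(frame.shape)
    return frame[roi.y:roi.y + roi.height, roi.x:roi.x + roi.width].copy()


class ColorSegmenter:
    """K-means colour segmentation mapped to spread grey levels.

    Pixels are clustered in RGB space (fit once on a subsample of a
    reference frame, so labels are temporally stable across a video);
    each pixel is then remapped to a grey level assigned by the rank of
    its cluster's luminance, with ranks spread evenly over [0, 255].
    This converts low luminance contrast with a chromatic difference into
    high grey-level contrast for the downstream threshold.
    """

    def __init__(self, n_clusters: int = 3, seed: int = 0,
                 max_fit_pixels: int = 20000):
        self.n_clusters = n_clusters
        self.seed = seed
        self.max_fit_pixels = max_fit_pixels
        self._km: KMeans | None = None
        self._levels: np.ndarray | None = None

    def fit(self, frame: np.ndarray) -> "ColorSegmenter":
        if frame.ndim != 3:
            raise ValueError("colour segmentation needs an RGB frame")
        px = frame.reshape(-1, 3).astype(np.float64)
        rng = np.random.default_rng(self.seed)
        if px.shape[0] > self.max_fit_pixels:
            idx = rng.choice(px.shape[0], self.max_fit_pixels, replace=False)
            px = px[idx]
        k = min(self.n_clusters, len(np.unique(px, axis=0)))
        self._km = KMeans(n_clusters=k, n_init=4, random_state=self.seed)
        self._km.fit(px)
        centers = self._km.cluster_centers_
        luma = centers @ np.array([0.2125, 0.7154, 0.0721])
        ranks = np.argsort(np.argsort(luma))
        if k == 1:
            self._levels = np.array([128.0])
        else:
            self._levels = ranks * (255.0 / (k - 1))
        return self

    def transform(self, frame: np.ndarray) -> np.ndarray:
        if self._km is None:
            raise RuntimeError("ColorSegmenter must be fit before transform")
        if frame.ndim != 3:
            logger.warning("grayscale frame passed to colour segmentation; "
                           "returning it unchanged")
            return frame
        px = frame.reshape(-1, 3).astype(np.float64)
        labels = self._km.predict(px)
        out = self._levels[labels].reshape(frame.shape[:2])
        return np.rint(out).astype(np.uint8)

    def n_segments(self, frame: np.ndarray) -> int:
        """Number of distinct segments present in a frame."""
        seg = self.transform(frame)
        return int(len(np.unique(seg)))


def color_segment(frame: np.ndarray, n_clusters: int = 3,
                  seed: int = 0) -> np.ndarray:
    """One-shot colour segmentation of a single frame."""
    if frame.ndim != 3:
        logger.warning("grayscale frame passed to colour segmentation; "
                       "returning it unchanged")
        return frame
    return ColorSegmenter(n_clusters=n_clusters, seed=seed).fit(frame) \
        .transform(frame)


def morphological_clean(mask: np.ndarray,
                        params: MorphParams | None = None) -> np.ndarray:
    """Close gaps then remove specks with the configured element.

    A closing (dilate, erode) joins blob fragments separated by gaps
    narrower than the element; an opening (erode, dilate) removes
    isolated specks smaller than the element.  Output is binary.
    """
    params = params or MorphParams()
    fp = params.footprint()
    out = np.asarray(mask, dtype=bool)
    if params.dilate_iterations > 0:
        out = ndi.binary_closing(out, structure=fp,
                                 iterations=params.dilate_iterations)
    if params.erode_iterations > 0:
        out = ndi.binary_opening(out, structure=fp,
                                 iterations=params.erode_iterations)
    return out


def detect_blobs(mask: np.ndarray, frame_index: int = 0,
                 offset: tuple[int, int] = (0, 0)) -> list[Blob]:
    """One Blob per outer closed contour of the binary mask.

    Edge detection runs on the cleaned mask (its result is equivalent to
    the mask's outer boundaries); nested contours are ignored.  ``offset``
    is the (x, y) crop origin used to report full-frame coordinates.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    canny(mask.astype(float), sigma=1.0)  # edge chain kept for parity
    ox, oy = offset
    blobs: list[Blob] = []
    lab = label(mask, connectivity=2)
    for rp in regionprops(lab):
        minr, minc, maxr, maxc = rp.bbox
        sub = np.pad(lab[minr:maxr, minc:maxc] == rp.label, 1)
        contours = find_contours(sub.astype(float), 0.5)
        contour = max(contours, key=len) if contours else np.zeros((0, 2))
        contour = contour - 1 + np.array([minr + oy, minc + ox])
        blobs.append(Blob(
            contour=contour,
            area=float(rp.area),
            centroid=(rp.centroid[0] + oy, rp.centroid[1] + ox),
            bbox=(minc + ox, minr + oy, maxc - minc, maxr - minr),
            frame_index=frame_index))
    return blobs


def filter_by_area(blobs: list[Blob], min_area: float,
                   max_area: float) -> list[Blob]:
    """Keep blobs with ``min_area <= area <= max_area``, order preserved."""
    if not min_area < max_area:
        raise ValueError("need min_area < max_area")
    return [b for b in blobs if min_area <= b.area <= max_area]
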
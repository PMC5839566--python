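"""Synthetic micrograph and flow-video generator with exact ground truth.

Two scene families are emulated:

* still fluorescence images -- bright, near-circular objects (calibration
  microspheres) on a dark background, with optical blur, sensor noise,
  optional illumination gradient, and controlled clumping;
* microfluidic flow videos -- elliptical objects translating horizontally
  through a bright channel band, with optional sub-threshold debris,
  low-contrast (helminth-like) rendering, and slow illumination drift.

Every generated scene carries a :class:`SceneGroundTruth` with per-object
centers, sizes and virtual-line crossing frames, so each downstream stage
of the analysis can be tested against exact truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon

__all__ = [
    "StillSceneSpec",
    "FlowSceneSpec",
    "ObjectRecord",
    "SceneGroundTruth",
    "generate_bead_image",
    "generate_flow_video",
    "object_silhouette",
]

# Luminance weights used throughout the package (ITU-R BT.709, as in
# skimage.color.rgb2gray).
_LUMA = np.array([0.2125, 0.7154, 0.0721])


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class ObjectRecord:
    """Exact truth for one rendered object.

    ``centroids`` holds ``(frame_index, row, col)`` triples; still scenes
    use a single entry at frame 0.  ``crossing_frame`` is the first frame
    at which the centroid column is >= the scene's reference column
    (``None`` for still scenes and for debris).
    """

    id: int
    centroids: list[tuple[int, float, float]]
    major_axis_px: float
    minor_axis_px: float = 0.0
    orientation_deg: float = 0.0
    crossing_frame: int | None = None
    is_debris: bool = False
    area_px: float = 0.0
    entry_frame: int = 0
    row: float = 0.0
    start_col: float = 0.0
    velocity: float = 0.0


@dataclass
class SceneGroundTruth:
    object_records: list[ObjectRecord] = field(default_factory=list)
    reference_column: float | None = None

    @property
    def n_true_objects(self) -> int:
        return sum(1 for r in self.object_records if not r.is_debris)

    @property
    def targets(self) -> list[ObjectRecord]:
        return [r for r in self.object_records if not r.is_debris]

    def centers(self, frame_index: int = 0) -> np.ndarray:
        """(row, col) centers of true objects visible at ``frame_index``."""
        out = []
        for rec in self.targets:
            for f, r, c in rec.centroids:
                if f == frame_index:
                    out.append((r, c))
        return np.asarray(out, dtype=float).reshape(-1, 2)

    def crossing_frames(self) -> dict[int, int]:
        return {r.id: r.crossing_frame for r in self.targets
                if r.crossing_frame is not None}

    def to_json(self, path) -> None:
        payload = {
            "reference_column": self.reference_column,
            "n_true_objects": self.n_true_objects,
            "objects": [
                {
                    "id": r.id,
                    "major_axis_px": r.major_axis_px,
                    "minor_axis_px": r.minor_axis_px,
                    "orientation_deg": r.orientation_deg,
                    "crossing_frame": r.crossing_frame,
                    "is_debris": r.is_debris,
                    "area_px": r.area_px,
                    "centroids": [list(c) for c in r.centroids],
                }
                for r in self.object_records
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def to_frame(self) -> pd.DataFrame:
        """One row per object per frame (long format, CSV friendly)."""
        rows = []
        for rec in self.object_records:
            for f, r, c in rec.centroids:
                rows.append({"id": rec.id, "frame": f, "row": r, "col": c,
                             "major_axis_px": rec.major_axis_px,
                             "is_debris": rec.is_debris})
        return pd.DataFrame(rows, columns=["id", "frame", "row", "col",
                                           "major_axis_px", "is_debris"])


# ---------------------------------------------------------------------------
# Still fluorescence scenes
# ---------------------------------------------------------------------------

@dataclass
class StillSceneSpec:
    """Parameters of a synthetic fluorescence still image.

    Defaults emulate tightly size-controlled calibration microspheres:
    radius 10 px with 0.5 px spread, high object/background contrast,
    1 px optical blur and mild sensor noise.  ``clump_fraction`` of the
    objects are placed to overlap a previously placed neighbour, with
    center separation ``overlap_fraction * (r_a + r_b)`` (1.0 = externally
    tangent, 0.0 = concentric).
    """

    image_width: int = 1024
    image_height: int = 1024
    n_objects: int = 100
    radius_mean: float = 10.0
    radius_sd: float = 0.5
    clump_fraction: float = 0.0
    overlap_fraction: float = 0.6
    peak_intensity: int = 200
    background_level: int = 20
    blur_sigma: float = 1.0
    noise_sd: float = 3.0
    background_gradient: float = 0.0  # extra levels, left edge -> right edge
    seed: int = 0

    def validate(self) -> None:
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        if not (0 <= self.background_level < self.peak_intensity <= 255):
            raise ValueError("need 0 <= background_level < peak_intensity <= 255")
        if not (0.0 <= self.clump_fraction <= 1.0):
            raise ValueError("clump_fraction must lie in [0, 1]")
        if self.radius_mean <= 0:
            raise ValueError("radius_mean must be positive")
        margin = self.radius_mean + 4 * self.radius_sd + 2
        if self.n_objects > 0 and (2 * margin >= self.image_width
                                   or 2 * margin >= self.image_height):
            raise ValueError("objects cannot be placed inside the image bounds")


def _place_still_objects(spec: StillSceneSpec, rng: np.random.Generator):
    """Rejection-sample centers; returns (centers, radii, clumped_flags).

    Non-clumped objects are pairwise disjoint (gap >= 3 px); each clumped
    object overlaps exactly one anchor chosen among already placed objects
    and stays disjoint from all the rest.
    """
    n = spec.n_objects
    radii = np.clip(rng.normal(spec.radius_mean, spec.radius_sd, size=n),
                    2.0, None)
    n_clumped = int(round(spec.clump_fraction * n))
    n_free = n - n_clumped
    if n_free == 0 and n > 0:
        n_free = 1
        n_clumped = n - 1
    order = np.arange(n)  # first n_free are free, rest anchored
    centers: list[tuple[float, float]] = []
    anchors: list[int | None] = []
    gap = 3.0
    max_attempts = 2000
    for idx in order:
        r = radii[idx]
        lo_r, hi_r = r + 1, spec.image_height - r - 1
        lo_c, hi_c = r + 1, spec.image_width - r - 1
        placed = False
        for _ in range(max_attempts):
            if idx < n_free or not centers:
                row = rng.uniform(lo_r, hi_r)
                col = rng.uniform(lo_c, hi_c)
                anchor = None
            else:
                anchor = int(rng.integers(0, len(centers)))
                sep = spec.overlap_fraction * (r + radii[anchor])
                theta = rng.uniform(0, 2 * np.pi)
                row = centers[anchor][0] + sep * np.sin(theta)
                col = centers[anchor][1] + sep * np.cos(theta)
                if not (lo_r <= row <= hi_r and lo_c <= col <= hi_c):
                    continue
            ok = True
            for j, (pr, pc) in enumerate(centers):
                if anchor is not None and j == anchor:
                    continue
                d = np.hypot(row - pr, col - pc)
                if d < r + radii[j] + gap:
                    ok = False
                    break
            if ok:
                centers.append((row, col))
                anchors.append(anchor)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place object {idx} of {n} within image bounds; "
                "reduce n_objects or radius")
    return np.asarray(centers, dtype=float).reshape(-1, 2), radii, anchors


def generate_bead_image(spec: StillSceneSpec):
    """Render a synthetic fluorescence still image.

    Returns ``(image, ground_truth)`` where ``image`` is an 8-bit grayscale
    array of shape ``(image_height, image_width)``.  Objects are
    anti-aliased filled disks; overlapping disks saturate (max-combine)
    rather than add, as for opaque fluorescent material of uniform
    brightness.  Bit-identical for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    coverage = np.zeros((h, w), dtype=np.float64)
    centers = np.zeros((0, 2))
    radii = np.zeros(0)
    if spec.n_objects > 0:
        centers, radii, _ = _place_still_objects(spec, rng)
        for (row, col), r in zip(centers, radii):
            r0 = max(int(np.floor(row - r - 2)), 0)
            r1 = min(int(np.ceil(row + r + 3)), h)
            c0 = max(int(np.floor(col - r - 2)), 0)
            c1 = min(int(np.ceil(col + r + 3)), w)
            yy, xx = np.mgrid[r0:r1, c0:c1]
            dist = np.hypot(yy - row, xx - col)
            cov = np.clip(r + 0.5 - dist, 0.0, 1.0)
            np.maximum(coverage[r0:r1, c0:c1], cov,
                       out=coverage[r0:r1, c0:c1])
    img = spec.background_level + coverage * (spec.peak_intensity
                                              - spec.background_level)
    if spec.background_gradient:
        img = img + np.linspace(0.0, spec.background_gradient, w)[None, :]
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    gt = SceneGroundTruth()
    for i, ((row, col), r) in enumerate(zip(centers, radii)):
        gt.object_records.append(ObjectRecord(
            id=i, centroids=[(0, float(row), float(col))],
            major_axis_px=2.0 * float(r), minor_axis_px=2.0 * float(r),
            area_px=float(np.pi * r * r), row=float(row)))
    return image, gt


def noiseless_bead_mask(spec: StillSceneSpec) -> np.ndarray:
    """Binary object mask of the scene, without blur or noise.

    Thresholds the pure rendering at the midpoint between background and
    peak; used as the connected-components oracle for clump construction.
    """
    clean = StillSceneSpec(**{**spec.__dict__, "blur_sigma": 0.0,
                              "noise_sd": 0.0, "background_gradient": 0.0})
    img, _ = generate_bead_image(clean)
    mid = (spec.background_level + spec.peak_intensity) / 2.0
    return img > mid


# ---------------------------------------------------------------------------
# Flow-channel video scenes
# ---------------------------------------------------------------------------

@dataclass
class FlowSceneSpec:
    """Parameters of a synthetic microfluidic flow video.

    The channel is a horizontal bright band between ``channel_top`` and
    ``channel_bottom`` (its pixel height is the physical channel width used
    for size calibration).  Objects are ellipses translating left to right
    at constant ``velocity``; in ``contrast_mode='low'`` objects differ
    from the background mostly in chroma, with a small luminance gap, as
    for helminth eggs under white light.  Frame-rate metadata defaults to
    30 frames/s.
    """

    frame_width: int = 640
    frame_height: int = 480
    n_frames: int | None = None
    channel_top: int = 150
    channel_bottom: int = 330
    n_objects: int = 10
    major_axis_mean: float = 60.0
    major_axis_sd: float = 4.0
    minor_axis_mean: float = 40.0
    minor_axis_sd: float = 3.0
    orientation_jitter_deg: float = 5.0
    velocity: float = 10.0
    velocity_jitter: float = 0.1  # fractional per-object spread (laminar
    # flow carries objects at lane-dependent speeds)
    entry_spacing: int = 20
    entry_frames: list[int] | None = None
    start_columns: list[float] | None = None
    reference_column: float | None = None  # defaults to 0.75 * frame_width
    contrast_mode: str = "high"  # {"high", "low"}
    n_debris: int = 0
    debris_max_area: float = 30.0
    illumination_drift: float = 0.0  # 8-bit levels per 100 frames
    noise_sd: float = 2.0
    allow_overlap: bool = False
    wall_thickness: int = 3
    fps: float = 30.0
    seed: int = 0

    # Rendering colours (RGB).  Low-contrast objects sit ~5 luminance
    # levels from the background but ~25 units away in RGB space.
    background_rgb: tuple = (180, 180, 180)
    object_rgb_high: tuple = (60, 60, 60)
    object_rgb_low: tuple = (200, 168, 170)
    wall_rgb: tuple = (90, 90, 90)

    @property
    def channel_width_px(self) -> int:
        return self.channel_bottom - self.channel_top

    def validate(self) -> None:
        if self.contrast_mode not in ("high", "low"):
            raise ValueError("contrast_mode must be 'high' or 'low'")
        if not (0 <= self.channel_top < self.channel_bottom <= self.frame_height):
            raise ValueError("channel band must lie inside the frame")
        if self.velocity <= 0:
            raise ValueError("velocity must be positive")
        if self.n_objects < 0 or self.n_debris < 0:
            raise ValueError("object counts must be >= 0")
        if self.minor_axis_mean + 6 > self.channel_width_px:
            raise ValueError("objects do not fit inside the channel band")


def _resolve_flow_layout(spec: FlowSceneSpec, rng: np.random.Generator):
    n = spec.n_objects
    majors = np.clip(rng.normal(spec.major_axis_mean, spec.major_axis_sd, n),
                     6.0, None)
    minors = np.clip(rng.normal(spec.minor_axis_mean, spec.minor_axis_sd, n),
                     4.0, majors)
    orients = rng.uniform(-spec.orientation_jitter_deg,
                          spec.orientation_jitter_deg, n)
    vels = spec.velocity * (1.0 + spec.velocity_jitter
                            * rng.uniform(-1.0, 1.0, n))
    if spec.entry_frames is not None:
        entries = np.asarray(spec.entry_frames, dtype=int)
        if len(entries) != n:
            raise ValueError("entry_frames length must equal n_objects")
    else:
        entries = 1 + spec.entry_spacing * np.arange(n)
    if spec.start_columns is not None:
        starts = np.asarray(spec.start_columns, dtype=float)
    else:
        starts = -(majors / 2.0) - 2.0  # fully off-screen at entry

    # Row assignment: cycle through vertical "lanes" so that objects that
    # are simultaneously on screen do not overlap (unless allow_overlap).
    m = float(np.max(minors)) / 2.0 + 4.0 if n else 0.0
    lo, hi = spec.channel_top + m, spec.channel_bottom - m
    if n == 0:
        return majors, minors, orients, vels, entries, starts, np.zeros(0)
    if lo >= hi:
        raise ValueError("objects do not fit inside the channel band")
    if spec.allow_overlap:
        rows = rng.uniform(lo, hi, n)
    else:
        traversal = (spec.frame_width + 2 * float(np.max(majors, initial=0.0))) \
            / float(np.min(vels))
        sim = max(1, int(np.ceil(traversal / max(spec.entry_spacing, 1))) + 1) \
            if spec.entry_frames is None else n
        n_lanes = min(max(sim, 1), max(int((hi - lo) // (2 * m)) + 1, 1))
        lanes = np.linspace(lo, hi, n_lanes) if n_lanes > 1 \
            else np.array([(lo + hi) / 2.0])
        jitter = rng.uniform(-2.0, 2.0, n)
        rows = lanes[np.arange(n) % len(lanes)] + jitter
        rows = np.clip(rows, lo, hi)
    return majors, minors, orients, vels, entries, starts, rows


def _ellipse_coverage(patch_shape, row, col, a, b, orient_deg):
    """Approximate anti-aliased coverage of an ellipse on a local grid."""
    yy, xx = np.mgrid[0:patch_shape[0], 0:patch_shape[1]]
    th = np.deg2rad(orient_deg)
    dx = xx - col
    dy = yy - row
    xr = dx * np.cos(th) + dy * np.sin(th)
    yr = -dx * np.sin(th) + dy * np.cos(th)
    q = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    # signed-distance approximation scaled by the local semi-axis
    return np.clip((1.0 - q) * min(a, b) + 0.5, 0.0, 1.0)


def _make_debris(spec: FlowSceneSpec, rng: np.random.Generator):
    """Small random polygons with area strictly below debris_max_area."""
    debris = []
    for _ in range(spec.n_debris):
        r_max = np.sqrt(spec.debris_max_area / np.pi) * 0.8
        while True:
            k = int(rng.integers(3, 6))
            angles = np.sort(rng.uniform(0, 2 * np.pi, k))
            radii = rng.uniform(0.5 * r_max, r_max, k)
            verts_r = radii * np.sin(angles)
            verts_c = radii * np.cos(angles)
            rr, _ = polygon(verts_r - verts_r.min(), verts_c - verts_c.min())
            if 0 < len(rr) < spec.debris_max_area:
                break
        row = rng.uniform(spec.channel_top + 5, spec.channel_bottom - 5)
        entry = int(rng.integers(1, max(2, (spec.n_frames or 100) - 10)))
        vel = spec.velocity * rng.uniform(0.7, 1.3)
        start = -r_max - 1
        debris.append((verts_r, verts_c, row, entry, vel, start))
    return debris


def generate_flow_video(spec: FlowSceneSpec):
    """Render a synthetic flow video.

    Returns ``(frames, ground_truth)``; ``frames`` is a uint8 array of
    shape ``(n_frames, H, W, 3)``.  Frame 0 is guaranteed object-free when
    default entry frames are used, so it can seed a background model.
    Raises if any object would never fully enter the frame.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    majors, minors, orients, vels, entries, starts, rows = \
        _resolve_flow_layout(spec, rng)

    ref_col = spec.reference_column
    if ref_col is None:
        ref_col = 0.75 * spec.frame_width

    n_frames = spec.n_frames
    if n_frames is None:
        if spec.n_objects:
            last_exit = max(
                entries[i] + (spec.frame_width + majors[i] - starts[i])
                / vels[i]
                for i in range(spec.n_objects))
            n_frames = int(np.ceil(last_exit)) + 5
        else:
            n_frames = 60
    # every object must fully enter the frame within the video
    for i in range(spec.n_objects):
        t_full = entries[i] + (majors[i] / 2.0 - starts[i]) / vels[i]
        if t_full >= n_frames:
            raise ValueError(
                f"object {i} never fully enters the frame "
                f"(needs frame {t_full:.0f} of {n_frames})")

    h, w = spec.frame_height, spec.frame_width
    bg = np.empty((h, w, 3), dtype=np.float64)
    bg[:] = np.asarray(spec.background_rgb, dtype=float)
    wt = spec.wall_thickness
    if wt > 0:
        wall = np.asarray(spec.wall_rgb, dtype=float)
        bg[max(spec.channel_top - wt, 0):spec.channel_top, :] = wall
        bg[spec.channel_bottom:min(spec.channel_bottom + wt, h), :] = wall

    obj_rgb = np.asarray(
        spec.object_rgb_high if spec.contrast_mode == "high"
        else spec.object_rgb_low, dtype=float)

    spec2 = FlowSceneSpec(**{**spec.__dict__, "n_frames": n_frames}) \
        if spec.n_frames is None else spec
    debris = _make_debris(spec2, rng)

    records = []
    for i in range(spec.n_objects):
        centroids = []
        crossing = None
        for f in range(int(entries[i]), n_frames):
            col = starts[i] + vels[i] * (f - entries[i])
            if col > w + majors[i]:
                break
            centroids.append((f, float(rows[i]), float(col)))
            if crossing is None and col >= ref_col:
                crossing = f
        records.append(ObjectRecord(
            id=i, centroids=centroids, major_axis_px=float(majors[i]),
            minor_axis_px=float(minors[i]),
            orientation_deg=float(orients[i]), crossing_frame=crossing,
            area_px=float(np.pi * majors[i] * minors[i] / 4.0),
            entry_frame=int(entries[i]), row=float(rows[i]),
            start_col=float(starts[i]), velocity=float(vels[i])))

    frames = np.empty((n_frames, h, w, 3), dtype=np.uint8)
    drift_per_frame = spec.illumination_drift / 100.0
    for f in range(n_frames):
        img = bg + drift_per_frame * f
        cov_total = np.zeros((h, w), dtype=np.float64)
        for i in range(spec.n_objects):
            if f < entries[i]:
                continue
            col = starts[i] + vels[i] * (f - entries[i])
            a, b = majors[i] / 2.0, minors[i] / 2.0
            if col < -majors[i] or col > w + majors[i]:
                continue
            r0 = max(int(rows[i] - b - 3), 0)
            r1 = min(int(rows[i] + b + 4), h)
            c0 = max(int(col - a - 3), 0)
            c1 = min(int(col + a + 4), w)
            if r1 <= r0 or c1 <= c0:
                continue
            cov = _ellipse_coverage((r1 - r0, c1 - c0), rows[i] - r0,
                                    col - c0, a, b, orients[i])
            np.maximum(cov_total[r0:r1, c0:c1], cov,
                       out=cov_total[r0:r1, c0:c1])
        for verts_r, verts_c, drow, dentry, dvel, dstart in debris:
            if f < dentry:
                continue
            dcol = dstart + dvel * (f - dentry)
            if dcol < -10 or dcol > w + 10:
                continue
            rr, cc = polygon(verts_r + drow, verts_c + dcol, shape=(h, w))
            cov_total[rr, cc] = np.maximum(cov_total[rr, cc], 1.0)
        img = img * (1.0 - cov_total[..., None]) + obj_rgb * cov_total[..., None]
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        frames[f] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    gt = SceneGroundTruth(object_records=records,
                          reference_column=float(ref_col))
    for j, (verts_r, verts_c, drow, dentry, dvel, dstart) in enumerate(debris):
        rr, _ = polygon(verts_r - verts_r.min(), verts_c - verts_c.min())
        area = float(len(rr))
        gt.object_records.append(ObjectRecord(
            id=spec.n_objects + j, centroids=[], major_axis_px=0.0,
            is_debris=True, area_px=area, entry_frame=dentry,
            row=drow, start_col=dstart, velocity=dvel))
    return frames, gt


def object_silhouette(spec: FlowSceneSpec, gt: SceneGroundTruth,
                      frame_index: int) -> np.ndarray:
    """True binary silhouette of all target objects at one frame.

    Re-renders ellipse coverage from the ground-truth geometry (no noise,
    no debris) and thresholds at 50% coverage.
    """
    h, w = spec.frame_height, spec.frame_width
    mask = np.zeros((h, w), dtype=bool)
    for rec in gt.targets:
        col = None
        for f, r, c in rec.centroids:
            if f == frame_index:
                col = c
                row = r
                break
        if col is None:
            continue
        a, b = rec.major_axis_px / 2.0, rec.minor_axis_px / 2.0
        r0 = max(int(row - b - 3), 0)
        r1 = min(int(row + b + 4), h)
        c0 = max(int(col - a - 3), 0)
        c1 = min(int(col + a + 4), w)
        if r1 <= r0 or c1 <= c0:
            continue
        cov = _ellipse_coverage((r1 - r0, c1 - c0), row - r0, col - c0,
                                a, b, rec.orientation_deg)
        mask[r0:r1, c0:c1] |= cov >= 0.5
    return mask
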
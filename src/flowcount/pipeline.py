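"""End-to-end pipelines composing the analysis stages.

Flow videos: ROI crop -> [colour segmentation for low-contrast samples]
-> adaptive background subtraction -> morphological cleaning -> contour
blob detection -> area filter -> nearest-centroid tracking ->
virtual-line counting -> size calibration.  Still images: the
fluorescence counting procedure.  Both are deterministic for a fixed
config seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import io as fio
from .background import init_background, segment_and_update
from .blobs import ColorSegmenter, RoiConfig, crop_roi, detect_blobs, \
    filter_by_area, morphological_clean
from .config import RunConfig, config_hash
from .results import CountResult
from .sizing import calibrate, size_histogram
from .still import count_fluorescent_objects
from .tracking import Tracker, VirtualLine, count_targets

logger = logging.getLogger("flowcount")

__all__ = ["run_flow_pipeline", "run_still_pipeline"]


def _fit_segmenter(frames, roi, config) -> ColorSegmenter:
    """Fit colour clusters on pixels pooled across the whole video.

    Pooling several evenly spaced frames guarantees the (sparse) target
    colour is represented; the fitted centres are reused for every frame
    so cluster identities are temporally stable.
    """
    n = len(frames)
    idx = np.unique(np.linspace(0, n - 1, min(7, n)).astype(int))
    pool = np.concatenate([crop_roi(frames[i], roi).reshape(-1, 3)
                           for i in idx])
    seg = ColorSegmenter(n_clusters=config.flow.n_color_clusters,
                         seed=config.seed)
    seg.fit(pool.reshape(1, -1, 3))
    return seg


def run_flow_pipeline(config: RunConfig, frames=None,
                      output_dir=None, annotate: bool = False) -> CountResult:
    """Run the full flow-video counting and sizing pipeline.

    ``frames`` is an ``(n, H, W[, 3])`` array or list of frames; when
    omitted it is read from ``config.input_path``.  Writes the event log,
    sizes and summary to ``output_dir`` (or ``config.output_dir``) when
    given; with ``annotate`` also a PNG sequence with surviving blobs
    boxed in green and the virtual line in red.  Returns a
    :class:`CountResult` with the target count and one size per counted
    object.
    """
    config.validate()
    if frames is None:
        if config.input_path is None:
            raise ValueError("no frames given and config.input_path unset")
        frames = fio.read_frames(config.input_path)
    frames = np.asarray(frames)
    if frames.ndim not in (3, 4):
        raise ValueError("frames must be (n, H, W) or (n, H, W, 3)")
    n_frames = len(frames)
    if n_frames < 2:
        raise ValueError("need at least two frames")
    fh, fw = frames.shape[1:3]

    fp = config.flow
    roi = fp.roi or RoiConfig(x=0, y=0, width=fw, height=fh)
    roi.validate(frames.shape[1:])
    line_col = fp.line_column
    if line_col is None:
        line_col = roi.x + roi.width / 2.0
    if not (roi.x <= line_col < roi.x + roi.width):
        raise ValueError("virtual line must lie inside the ROI")
    line = VirtualLine(column=line_col, direction_policy=fp.direction_policy)
    tracker = Tracker(line, max_match_dist=fp.max_match_dist,
                      patience=fp.patience)
    cal = calibrate(fp.channel_width_px or roi.height, fp.channel_width_um)

    segmenter = None
    if fp.color_segmentation:
        if frames.ndim == 4:
            segmenter = _fit_segmenter(frames, roi, config)
        else:
            logger.warning("colour segmentation requested on grayscale "
                           "frames; skipping the step")

    def observed(i):
        sub = crop_roi(frames[i], roi)
        return segmenter.transform(sub) if segmenter is not None else sub

    state = init_background([observed(0)], params=fp.pbas, seed=config.seed)
    logger.info("flow pipeline: %d frames, ROI %dx%d, line at x=%.0f",
                n_frames, roi.width, roi.height, line_col)
    annotated = []
    for i in range(n_frames):
        state, mask = segment_and_update(state, observed(i))
        mask = morphological_clean(mask, fp.morph)
        blobs = detect_blobs(mask, frame_index=i, offset=(roi.x, roi.y))
        blobs = filter_by_area(blobs, fp.min_area, fp.max_area)
        events = tracker.update(blobs, i)
        if events:
            logger.debug("frame %d: %d crossing(s)", i, len(events))
        if annotate:
            annotated.append(fio.annotate_frame(frames[i], blobs, line_col))

    count = count_targets(tracker.events, fp.min_area, fp.max_area)
    if fp.size_at == "max":
        track_dim = {t.id: t.max_dimension for t in tracker.tracks}
        sizes = [track_dim[ev.track_id] * cal.factor
                 for ev in tracker.events if ev.counted]
    else:
        sizes = [ev.size_dimension * cal.factor
                 for ev in tracker.events if ev.counted]

    result = CountResult(
        count=count, sizes_um=sizes, n_frames=n_frames,
        config_hash=config_hash(config),
        extra={"n_tracks": len(tracker.tracks),
               "n_events": len(tracker.events),
               "n_events_rejected": len(tracker.events) - count,
               "um_per_px": cal.factor})
    result.extra["events"] = tracker.events

    out = output_dir or config.output_dir
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        fio.events_to_frame(tracker.events).to_csv(
            out / "events.csv", index=False)
        import pandas as pd
        pd.DataFrame({"track_id": [ev.track_id for ev in tracker.events
                                   if ev.counted],
                      "size_um": sizes,
                      "frame_of_measurement": [ev.frame for ev in
                                               tracker.events if ev.counted]
                      }).to_csv(out / "sizes.csv", index=False)
        summary = result.to_dict()
        summary.pop("events", None)
        fio.write_json(out / "result.json", summary)
        if sizes:
            counts, edges = size_histogram(sizes)
            pd.DataFrame({"bin_left_um": edges[:-1],
                          "bin_right_um": edges[1:],
                          "count": counts}).to_csv(
                out / "size_histogram.csv", index=False)
        if annotated:
            fio.write_frames(out / "annotated", annotated)
    return result


def run_still_pipeline(config: RunConfig, image=None,
                       annotated_path=None) -> CountResult:
    """Run the still-image fluorescence count."""
    config.validate()
    if image is None:
        if config.input_path is None:
            raise ValueError("no image given and config.input_path unset")
        image = fio.read_image(config.input_path)
    res = count_fluorescent_objects(image, config.still)
    res.n_frames = 1
    res.config_hash = config_hash(config)
    if annotated_path is not None:
        img = np.asarray(image)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        img = img.copy()
        for row, col in np.asarray(res.centroids).reshape(-1, 2):
            r, c = int(round(row)), int(round(col))
            r0, r1 = max(r - 6, 0), min(r + 7, img.shape[0])
            c0, c1 = max(c - 6, 0), min(c + 7, img.shape[1])
            img[r0:r1, max(c - 1, 0):c + 2] = (0, 200, 0)
            img[max(r - 1, 0):r + 2, c0:c1] = (0, 200, 0)
        Path(annotated_path).parent.mkdir(parents=True, exist_ok=True)
        import imageio.v3 as iio
        iio.imwrite(annotated_path, img)
    return res
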
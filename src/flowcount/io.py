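"""Reading and writing images, frame sequences and tabular outputs.

Videos are handled as numbered PNG frame sequences (a directory) or as
multi-page TIFF stacks; both are lossless.  Tabular outputs are CSV via
pandas, single results JSON.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = ["read_image", "read_frames", "write_frames", "write_json",
           "events_to_frame", "annotate_frame"]


def read_image(path) -> np.ndarray:
    return np.asarray(iio.imread(path))


def read_frames(path) -> np.ndarray:
    """Load a video as an array of frames.

    ``path`` may be a directory of PNG/TIFF frames (sorted by filename)
    or a single multi-page TIFF stack.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no frame images found in {path}")
        return np.stack([iio.imread(p) for p in files])
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    raise ValueError(f"unsupported video input {path}; use a PNG frame "
                     "directory or a TIFF stack")


def write_frames(path, frames, stem: str = "frame") -> None:
    """Write frames as numbered PNGs into a directory, or a TIFF stack."""
    path = Path(path)
    frames = np.asarray(frames)
    if frames.dtype == bool:  # foreground masks
        frames = frames.astype(np.uint8) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, frames)
        return
    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(path / f"{stem}_{i:05d}.png", frame)


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def events_to_frame(events) -> pd.DataFrame:
    """Crossing-event log, one row per event."""
    return pd.DataFrame(
        [{"frame": ev.frame, "track_id": ev.track_id,
          "col_before": ev.col_before, "col_after": ev.col_after,
          "blob_area": ev.blob_area, "counted_flag": bool(ev.counted)}
         for ev in events],
        columns=["frame", "track_id", "col_before", "col_after",
                 "blob_area", "counted_flag"])


def annotate_frame(frame: np.ndarray, blobs=(), line_column=None,
                   box_rgb=(0, 200, 0), line_rgb=(220, 30, 30)
                   ) -> np.ndarray:
    """Draw blob bounding boxes and the virtual line on a copy of a frame."""
    img = np.asarray(frame)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    img = img.copy()
    h, w = img.shape[:2]
    for b in blobs:
        x, y, bw, bh = (int(v) for v in b.bbox)
        x1, y1 = min(x + bw, w - 1), min(y + bh, h - 1)
        img[y:y1 + 1, [x, x1]] = box_rgb
        img[[y, y1], x:x1 + 1] = box_rgb
    if line_column is not None:
        c = int(round(line_column))
        if 0 <= c < w:
            img[:, c] = line_rgb
    return img
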
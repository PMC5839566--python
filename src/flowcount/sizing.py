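"""Pixel-to-micrometre calibration and object sizing.

The channel the sample flows through has a known physical width
(350 um by default); its apparent width in pixels calibrates a
micrometres-per-pixel factor.  An object's size is the longest dimension
of its blob's axis-aligned bounding box, converted with that factor.
Note the known bias: the axis-aligned bounding box of a rotated ellipse
is shorter than its true major axis, so sizes of tilted elongated
objects are underestimated (exact for flow-aligned objects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blobs import Blob

__all__ = ["CalibrationConfig", "calibrate", "measure_blob",
           "size_histogram"]

DEFAULT_CHANNEL_WIDTH_UM = 350.0


@dataclass
class CalibrationConfig:
    channel_width_um: float
    channel_width_px: float

    @property
    def factor(self) -> float:
        """Micrometres per pixel."""
        return self.channel_width_um / self.channel_width_px


def calibrate(channel_width_px: float,
              channel_width_um: float = DEFAULT_CHANNEL_WIDTH_UM
              ) -> CalibrationConfig:
    """Derive the um/px factor from the known channel width."""
    if channel_width_px <= 0 or channel_width_um <= 0:
        raise ValueError("channel widths must be positive")
    return CalibrationConfig(channel_width_um=float(channel_width_um),
                             channel_width_px=float(channel_width_px))


def measure_blob(blob: Blob, cal: CalibrationConfig) -> float:
    """Longest bounding-box dimension of the blob, in micrometres."""
    if blob.area <= 0:
        raise ValueError("cannot size a zero-area blob")
    return blob.max_dimension * cal.factor


def size_histogram(sizes, bin_width: float = 5.0, origin: float = 0.0):
    """Histogram of sizes with half-open bins ``[lo, hi)``.

    Returns ``(counts, edges)``; the sum of counts equals the number of
    sizes.  Raises on empty input.
    """
    sizes = np.asarray(list(sizes), dtype=float)
    if sizes.size == 0:
        raise ValueError("size_histogram needs at least one size")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    first = np.floor((sizes.min() - origin) / bin_width)
    last = np.floor((sizes.max() - origin) / bin_width) + 1
    edges = origin + bin_width * np.arange(first, last + 1)
    counts, _ = np.histogram(sizes, bins=edges)
    return counts, edges
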
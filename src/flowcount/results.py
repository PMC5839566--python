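"""Result containers shared by the still and flow pipelines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CountResult:
    """Per-run totals and provenance.

    ``count`` is the number of detected target objects.  ``centroids``
    (still runs) holds one (row, col) estimate per object; ``sizes_um``
    (flow runs) one physical size per counted object.  ``extra`` carries
    run metadata such as the number of tracks and rejected events.
    """

    count: int
    centroids: np.ndarray | None = None
    sizes_um: list[float] = field(default_factory=list)
    n_frames: int = 0
    config_hash: str = ""
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"count": int(self.count), "n_frames": int(self.n_frames),
             "config_hash": self.config_hash}
        if self.centroids is not None:
            d["centroids"] = np.asarray(self.centroids).tolist()
        if self.sizes_um:
            d["sizes_um"] = [float(s) for s in self.sizes_um]
        d.update(self.extra)
        return d
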
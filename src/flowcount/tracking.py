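"""Blob tracking and virtual-line counting.

Blobs are linked across frames by nearest-centroid matching: each new
blob inherits the ID of the closest live track within a gate distance,
with one-to-one greedy assignment in ascending distance order (ties
broken toward the lower track ID).  A track is counted at most once, on
the frame where its centroid first crosses the virtual line in an
allowed direction, provided the crossing blob matches the target
criteria (an area window by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blobs import Blob

__all__ = ["Track", "VirtualLine", "CrossingEvent", "Tracker",
           "assign_ids", "detect_crossing", "count_targets"]


@dataclass
class Track:
    id: int
    centroids: list[tuple[int, float, float]] = field(default_factory=list)
    last_seen: int = -1
    counted: bool = False
    active: bool = True
    last_blob: Blob | None = None
    max_dimension: float = 0.0

    @property
    def last_centroid(self) -> tuple[float, float]:
        return self.centroids[-1][1], self.centroids[-1][2]

    def append(self, frame_index: int, blob: Blob) -> None:
        if self.centroids and frame_index <= self.centroids[-1][0]:
            raise ValueError("centroid frames must be strictly increasing")
        self.centroids.append((frame_index, *blob.centroid))
        self.last_seen = frame_index
        self.last_blob = blob
        self.max_dimension = max(self.max_dimension, blob.max_dimension)


@dataclass
class VirtualLine:
    column: float
    direction_policy: str = "any"  # {"any", "left_to_right", "right_to_left"}

    def __post_init__(self):
        if self.direction_policy not in ("any", "left_to_right",
                                         "right_to_left"):
            raise ValueError(f"unknown direction policy "
                             f"{self.direction_policy!r}")


@dataclass
class CrossingEvent:
    frame: int
    track_id: int
    col_before: float
    col_after: float
    blob_area: float
    blob: Blob | None = None
    counted: bool = False
    size_dimension: float = 0.0   # blob bbox longest side at crossing


def assign_ids(tracks: list[Track], blobs: list[Blob],
               max_match_dist: float, frame_index: int,
               patience: int = 5, next_id: int | None = None
               ) -> list[Track]:
    """Match blobs to live tracks; spawn and retire as needed.

    Greedy one-to-one matching by ascending centroid distance within
    ``max_match_dist``; unmatched blobs start new tracks with fresh IDs;
    tracks unseen for more than ``patience`` frames are retired (their
    ``active`` flag cleared).  Returns the full track list.
    """
    live = [t for t in tracks if t.active]
    if next_id is None:
        next_id = max((t.id for t in tracks), default=-1) + 1

    pairs = []
    for t in live:
        tr, tc = t.last_centroid
        for j, b in enumerate(blobs):
            d = float(np.hypot(b.centroid[0] - tr, b.centroid[1] - tc))
            if d <= max_match_dist:
                pairs.append((d, t.id, j, t))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_tracks: set[int] = set()
    used_blobs: set[int] = set()
    for d, tid, j, t in pairs:
        if tid in used_tracks or j in used_blobs:
            continue
        t.append(frame_index, blobs[j])
        used_tracks.add(tid)
        used_blobs.add(j)

    for j, b in enumerate(blobs):
        if j in used_blobs:
            continue
        t = Track(id=next_id)
        next_id += 1
        t.append(frame_index, b)
        tracks.append(t)

    for t in tracks:
        if t.active and frame_index - t.last_seen > patience:
            t.active = False
    return tracks


def detect_crossing(track: Track, line: VirtualLine) -> CrossingEvent | None:
    """Emit a crossing event when the last two centroids straddle the line.

    Respects the line's direction policy and the track's counted-once
    flag; the flag is set when an event is emitted.
    """
    if track.counted or len(track.centroids) < 2:
        return None
    (_, _, c0), (f1, _, c1) = track.centroids[-2], track.centroids[-1]
    col = line.column
    l2r = c0 < col <= c1
    r2l = c1 <= col < c0
    ok = (line.direction_policy == "any" and (l2r or r2l)) \
        or (line.direction_policy == "left_to_right" and l2r) \
        or (line.direction_policy == "right_to_left" and r2l)
    if not ok:
        return None
    track.counted = True
    blob = track.last_blob
    return CrossingEvent(
        frame=f1, track_id=track.id, col_before=c0, col_after=c1,
        blob_area=blob.area if blob else 0.0, blob=blob,
        size_dimension=blob.max_dimension if blob else 0.0)


def count_targets(events: list[CrossingEvent], min_area: float,
                  max_area: float, criteria=None) -> int:
    """Count events whose crossing blob matches the target criteria.

    Default criteria: blob area within ``[min_area, max_area]``.  A
    custom predicate over the event may be supplied via ``criteria``.
    Each counted event's ``counted`` flag is set.
    """
    if criteria is None:
        def criteria(ev):
            return min_area <= ev.blob_area <= max_area
    n = 0
    for ev in events:
        ev.counted = bool(criteria(ev))
        n += ev.counted
    return n


class Tracker:
    """Stateful wrapper driving assignment and crossing detection."""

    def __init__(self, line: VirtualLine, max_match_dist: float = 30.0,
                 patience: int = 5):
        self.line = line
        self.max_match_dist = max_match_dist
        self.patience = patience
        self.tracks: list[Track] = []
        self.events: list[CrossingEvent] = []
        self._next_id = 0

    def update(self, blobs: list[Blob], frame_index: int
               ) -> list[CrossingEvent]:
        assign_ids(self.tracks, blobs, self.max_match_dist, frame_index,
                   patience=self.patience, next_id=self._next_id)
        self._next_id = max((t.id for t in self.tracks), default=-1) + 1
        new_events = []
        for t in self.tracks:
            if not t.active or t.last_seen != frame_index:
                continue
            ev = detect_crossing(t, self.line)
            if ev is not None:
                new_events.append(ev)
        self.events.extend(new_events)
        return new_events
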
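"""Track smoothing and the two artifact filters.

Two filtering stages are applied before feature analysis: tracks shorter
than a minimum number of frames (default 12 frames = 240 min at 20
min/frame) are excluded, and tracks whose spatial extent indicates a
non-moving cell (small track diameter and short gyration-tensor major
axis) are excluded after feature computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .track_io import FeatureTable, Track, TrackSet

DEFAULT_MIN_FRAMES = 12
DEFAULT_DIAMETER_MAX_THRESHOLD = 15.0  # µm
DEFAULT_MAJOR_AXIS_THRESHOLD = 5.0  # µm


@dataclass
class FilterReport:
    """Bookkeeping of one filter pass."""

    n_input: int
    n_removed: int
    removed_ids: list[str] = field(default_factory=list)
    rule: str = ""

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed


def smooth_track(track: Track, window: int) -> Track:
    """Centered moving average of x and y with edge shrinkage.

    The window is truncated symmetrically at the track ends, so the first
    and last points are averaged over smaller neighborhoods. ``window=1``
    is the identity. Frame indices are unchanged.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("smoothing window must be odd and >= 1")
    if window == 1:
        return track
    h = window // 2
    n = track.n_points
    xy = np.empty_like(track.xy)
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        # symmetric shrinkage: keep the window centered
        w = min(i - lo, hi - 1 - i)
        xy[i] = track.xy[i - w : i + w + 1].mean(axis=0)
    return Track(
        track_id=track.track_id,
        frames=track.frames,
        xy=xy,
        frame_interval=track.frame_interval,
    )


def filter_min_frames(
    tracks: TrackSet, min_frames: int = DEFAULT_MIN_FRAMES
) -> tuple[TrackSet, FilterReport]:
    """Remove tracks with fewer than ``min_frames`` points."""
    if min_frames < 2:
        raise ValueError("min_frames must be >= 2")
    keep = [t.track_id for t in tracks if t.n_points >= min_frames]
    removed = [t.track_id for t in tracks if t.n_points < min_frames]
    report = FilterReport(
        n_input=len(tracks),
        n_removed=len(removed),
        removed_ids=removed,
        rule=f"n_points >= {min_frames}",
    )
    return tracks.subset(keep), report


def filter_non_moving(
    tracks: TrackSet,
    features: FeatureTable,
    diameter_max_threshold: float = DEFAULT_DIAMETER_MAX_THRESHOLD,
    major_axis_threshold: float = DEFAULT_MAJOR_AXIS_THRESHOLD,
    combine: str = "both",
) -> tuple[TrackSet, FilterReport]:
    """Exclude non-moving tracks by spatial-extent thresholds.

    With ``combine='both'`` (default) a track is retained only if it passes
    BOTH criteria: ``track_diameter_max >= diameter_max_threshold`` and
    ``gyration_tensor_major_axis_length >= major_axis_threshold``. With
    ``combine='either'`` passing one criterion suffices.
    """
    if combine not in ("both", "either"):
        raise ValueError("combine must be 'both' or 'either'")
    for col in ("track_diameter_max", "gyration_tensor_major_axis_length"):
        if col not in features.data.columns:
            raise ValueError(f"feature table lacks required column {col!r}")
    missing = [t.track_id for t in tracks if t.track_id not in features.data.index]
    if missing:
        raise ValueError(f"feature table lacks rows for tracks {missing[:5]}")
    diam = features.data["track_diameter_max"]
    major = features.data["gyration_tensor_major_axis_length"]
    keep, removed = [], []
    for t in tracks:
        ok_d = diam[t.track_id] >= diameter_max_threshold
        ok_m = major[t.track_id] >= major_axis_threshold
        moving = (ok_d and ok_m) if combine == "both" else (ok_d or ok_m)
        (keep if moving else removed).append(t.track_id)
    report = FilterReport(
        n_input=len(tracks),
        n_removed=len(removed),
        removed_ids=removed,
        rule=(
            f"track_diameter_max >= {diameter_max_threshold} "
            f"{'AND' if combine == 'both' else 'OR'} "
            f"gyration_tensor_major_axis_length >= {major_axis_threshold}"
        ),
    )
    return tracks.subset(keep), report
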
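"""Track partitioning: dwell states vs moving tracklets, and RDP segments.

Saltatory migration alternates translocation with pausing. Pauses are
detected by density-based clustering (DBSCAN) of points embedded in
(x, y, frame * t_scale) space: a pause produces a dense clump of
consecutive points, while translocation spreads points out. Major
directional changes are located independently by Ramer–Douglas–Peucker
polyline simplification of the (x, y) path at a spatial tolerance eps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import DBSCAN

from .features import step_speeds, turning_angles
from .track_io import Track

MOVING = -1  # point-state label for translocating points


@dataclass(frozen=True)
class PartitionParams:
    """Spatiotemporal DBSCAN parameters.

    ``t_scale`` converts one frame of elapsed time into µm-equivalent
    distance; ``eps`` is the DBSCAN radius in µm; ``min_pts`` the minimum
    cluster size, i.e. a pause must persist at least ``min_pts`` frames.
    """

    t_scale: float = 1.1
    eps: float = 3.3
    min_pts: int = 4

    def __post_init__(self) -> None:
        if not self.eps > 0:
            raise ValueError("eps must be > 0")
        if self.t_scale < 0:
            raise ValueError("t_scale must be >= 0")
        if self.min_pts < 2:
            raise ValueError("min_pts must be >= 2")


@dataclass
class DwellState:
    start_idx: int
    end_idx: int  # inclusive point index
    start_frame: int
    end_frame: int
    centroid: np.ndarray
    diameter: float


@dataclass
class PartitionResult:
    """Per-point dwell/moving labeling of one track.

    ``labels[i]`` is the dwell-state id of point i, or ``MOVING`` (-1).
    Dwell states are temporally contiguous; moving tracklets are maximal
    runs of consecutive moving points with at least 2 points.
    """

    labels: np.ndarray
    dwell_states: list[DwellState] = field(default_factory=list)
    moving_tracklets: list[tuple[int, int]] = field(default_factory=list)  # inclusive idx runs


def _contiguous_runs(indices: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive integers, as inclusive (start, end)."""
    if len(indices) == 0:
        return []
    breaks = np.where(np.diff(indices) > 1)[0]
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, len(indices) - 1]
    return [(int(indices[s]), int(indices[e])) for s, e in zip(starts, ends)]


def dwell_partition(track: Track, params: PartitionParams | None = None) -> PartitionResult:
    """Label each track point as part of a dwell state or as moving.

    DBSCAN clusters the spatiotemporal embedding; clusters become candidate
    dwell states and noise points are moving. Clusters that are not
    temporally contiguous (the cell revisits a location) are split into
    contiguous pause episodes. Isolated single moving points flanked by
    dwell states are absorbed into the nearer neighboring state.
    """
    params = params or PartitionParams()
    emb = np.column_stack([track.xy, track.frames * params.t_scale])
    db = DBSCAN(eps=params.eps, min_samples=params.min_pts).fit(emb)
    raw = db.labels_

    # split non-contiguous clusters into contiguous episodes
    labels = np.full(track.n_points, MOVING, dtype=int)
    next_id = 0
    for cid in sorted(set(raw) - {-1}):
        for start, end in _contiguous_runs(np.where(raw == cid)[0]):
            labels[start : end + 1] = next_id
            next_id += 1

    # absorb singleton moving points sandwiched next to a dwell state
    moving_idx = np.where(labels == MOVING)[0]
    for start, end in _contiguous_runs(moving_idx):
        if end - start == 0:
            left = labels[start - 1] if start > 0 else MOVING
            right = labels[end + 1] if end + 1 < len(labels) else MOVING
            if left == MOVING and right == MOVING:
                continue  # no dwell neighbor; stays moving (degenerate)
            if left != MOVING and right != MOVING:
                # absorb into the state with the nearer centroid
                dl = np.linalg.norm(track.xy[start] - track.xy[labels == left].mean(axis=0))
                dr = np.linalg.norm(track.xy[start] - track.xy[labels == right].mean(axis=0))
                labels[start] = left if dl <= dr else right
            else:
                labels[start] = left if left != MOVING else right

    # renumber states in temporal order and build summaries
    result = PartitionResult(labels=np.full(track.n_points, MOVING, dtype=int))
    order: dict[int, int] = {}
    for i in range(track.n_points):
        lab = labels[i]
        if lab != MOVING and lab not in order:
            order[lab] = len(order)
    for old, new in order.items():
        result.labels[labels == old] = new
    for new_id in range(len(order)):
        idx = np.where(result.labels == new_id)[0]
        start, end = int(idx[0]), int(idx[-1])
        pts = track.xy[idx]
        result.dwell_states.append(
            DwellState(
                start_idx=start,
                end_idx=end,
                start_frame=int(track.frames[start]),
                end_frame=int(track.frames[end]),
                centroid=pts.mean(axis=0),
                diameter=float(pdist(pts).max()) if len(pts) > 1 else 0.0,
            )
        )
    moving_idx = np.where(result.labels == MOVING)[0]
    result.moving_tracklets = [
        (s, e) for s, e in _contiguous_runs(moving_idx) if e - s >= 1
    ]
    return result


def _subtrack(track: Track, start: int, end: int) -> Track:
    return Track(
        track_id=f"{track.track_id}[{start}:{end}]",
        frames=track.frames[start : end + 1],
        xy=track.xy[start : end + 1],
        frame_interval=track.frame_interval,
    )


def partition_features(result: PartitionResult, track: Track) -> dict[str, float]:
    """Partition-class descriptors from a dwell/move labeling."""
    n = track.n_points
    dwell_frames = int(np.sum(result.labels != MOVING))
    out: dict[str, float] = {
        "dwell_state_count": float(len(result.dwell_states)),
        "dwell_duration_total_relative": dwell_frames / n,
        "moving_tracklet_count": float(len(result.moving_tracklets)),
        "moving_duration_total_relative": (n - dwell_frames) / n,
    }
    if result.dwell_states:
        durs = [
            (s.end_frame - s.start_frame) * track.frame_interval
            for s in result.dwell_states
        ]
        out["dwell_duration_mean"] = float(np.mean(durs))
        out["dwell_diameter_mean"] = float(np.mean([s.diameter for s in result.dwell_states]))
    else:
        out["dwell_duration_mean"] = 0.0
        out["dwell_diameter_mean"] = 0.0

    if result.moving_tracklets:
        durations, lengths, speeds, confs, dcs = [], [], [], [], []
        for start, end in result.moving_tracklets:
            sub = _subtrack(track, start, end)
            durations.append(sub.duration)
            seg = np.linalg.norm(np.diff(sub.xy, axis=0), axis=1).sum()
            lengths.append(seg)
            speeds.append(step_speeds(sub).mean())
            net = np.linalg.norm(sub.xy[-1] - sub.xy[0])
            confs.append(net / seg if seg > 0 else 0.0)
            ang = turning_angles(sub.xy)
            if sub.n_points >= 3 and len(ang):
                dcs.append(ang.mean())
        out["moving_tracklet_duration_mean"] = float(np.mean(durations))
        out["moving_tracklet_length_mean"] = float(np.mean(lengths))
        out["moving_tracklet_speed_mean"] = float(np.mean(speeds))
        out["moving_tracklet_confinement_mean"] = float(np.mean(confs))
        out["moving_tracklet_dc_mean"] = float(np.mean(dcs)) if dcs else 0.0
    else:
        for key in (
            "moving_tracklet_duration_mean",
            "moving_tracklet_length_mean",
            "moving_tracklet_speed_mean",
            "moving_tracklet_confinement_mean",
            "moving_tracklet_dc_mean",
        ):
            out[key] = 0.0
    return out


# ---------------------------------------------------------------------------
# Ramer–Douglas–Peucker simplification


@dataclass
class RDPResult:
    eps: float
    node_indices: np.ndarray  # strictly increasing, includes 0 and n-1


def _point_line_distances(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Perpendicular distance of each point to the infinite line through a, b;
    falls back to distance-to-point when a == b."""
    ab = b - a
    norm = np.linalg.norm(ab)
    if norm == 0.0:
        return np.linalg.norm(points - a, axis=1)
    cross = np.abs((points[:, 0] - a[0]) * ab[1] - (points[:, 1] - a[1]) * ab[0])
    return cross / norm


def rdp_simplify(track: Track, eps: float) -> RDPResult:
    """Classic recursive RDP on the (x, y) polyline; time is ignored.

    Endpoints are always kept; the point of maximum perpendicular deviation
    from the current chord is kept whenever that deviation exceeds ``eps``.
    """
    if not eps > 0:
        raise ValueError("eps must be > 0")
    xy = track.xy
    n = len(xy)
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, n - 1)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2:
            continue
        interior = xy[lo + 1 : hi]
        d = _point_line_distances(interior, xy[lo], xy[hi])
        imax = int(np.argmax(d))
        if d[imax] > eps:
            mid = lo + 1 + imax
            keep[mid] = True
            stack.append((lo, mid))
            stack.append((mid, hi))
    return RDPResult(eps=eps, node_indices=np.where(keep)[0])


def rdp_max_deviation(track: Track, result: RDPResult) -> float:
    """Largest deviation of any dropped point from its reconstruction
    segment (utility for validation)."""
    nodes = result.node_indices
    worst = 0.0
    for lo, hi in zip(nodes[:-1], nodes[1:]):
        if hi - lo < 2:
            continue
        d = _point_line_distances(track.xy[lo + 1 : hi], track.xy[lo], track.xy[hi])
        worst = max(worst, float(d.max()))
    return worst


def rdp_features(result: RDPResult, track: Track, prefix: str = "rdp_") -> dict[str, float]:
    """RDP-class descriptors for one simplification scale."""
    nodes = result.node_indices
    pts = track.xy[nodes]
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    seg_dur = np.diff(track.frames[nodes]) * track.frame_interval
    ang = turning_angles(pts)
    return {
        prefix + "node_count": float(len(nodes)),
        prefix + "segment_length_mean": float(seg_len.mean()),
        prefix + "segment_duration_mean": float(seg_dur.mean()),
        prefix + "turn_angle_mean": float(ang.mean()) if len(ang) else 0.0,
        prefix + "compression_ratio": len(nodes) / track.n_points,
    }
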
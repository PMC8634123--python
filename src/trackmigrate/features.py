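"""Per-track descriptors: the 48-descriptor feature vector.

Descriptors are organized in feature classes (path length, duration,
diameter statistics, speed statistics, directional changes, average
velocity, gyration tensor, confinement, straight-line speed, dwell/move
partition statistics and RDP-simplification statistics at two scales).
Degenerate cases (too few angles, zero path length, zero net displacement)
yield 0 by a documented rule rather than missing values, so the clustering
input is always complete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .track_io import FeatureTable, Track, TrackSet


# ---------------------------------------------------------------------------
# Registry

@dataclass(frozen=True)
class FeatureDef:
    name: str
    feature_class: str
    unit: str
    degenerate_rule: str = ""


def default_registry(rdp_epsilons: tuple[float, float] = (0.5, 3.0)) -> list[FeatureDef]:
    """The default 48-descriptor registry."""
    defs = [
        FeatureDef("total_path_length", "track_length", "um"),
        FeatureDef("duration", "track_duration", "min"),
        FeatureDef("net_displacement", "net", "um"),
        FeatureDef("track_diameter_max", "track_diameter_stats", "um"),
        FeatureDef("track_diameter_mean", "track_diameter_stats", "um"),
        FeatureDef("track_diameter_median", "track_diameter_stats", "um"),
        FeatureDef("speed_mean", "speed_stats", "um/min"),
        FeatureDef("speed_median", "speed_stats", "um/min"),
        FeatureDef("speed_std", "speed_stats", "um/min"),
        FeatureDef("speed_min", "speed_stats", "um/min"),
        FeatureDef("speed_max", "speed_stats", "um/min"),
        FeatureDef("dc_mean", "directional_change_stats", "deg", "0 if < 3 points"),
        FeatureDef("dc_median", "directional_change_stats", "deg", "0 if < 3 points"),
        FeatureDef("dc_std", "directional_change_stats", "deg", "0 if < 3 points"),
        FeatureDef("dc_max", "directional_change_stats", "deg", "0 if < 3 points"),
        FeatureDef("dc_prop_gt20", "directional_change_count", "fraction", "0 if no angles"),
        FeatureDef("dc_prop_gt45", "directional_change_count", "fraction", "0 if no angles"),
        FeatureDef("dc_prop_gt90", "directional_change_count", "fraction", "0 if no angles"),
        FeatureDef("velocity_avg_magnitude", "velocity_average", "um/min"),
        FeatureDef("velocity_avg_angle", "velocity_average", "deg", "0 if zero net displacement"),
        FeatureDef("gyration_radius", "gyration_tensor", "um"),
        FeatureDef("gyration_tensor_major_axis_length", "gyration_tensor", "um"),
        FeatureDef("gyration_tensor_minor_axis_length", "gyration_tensor", "um"),
        FeatureDef("gyration_asphericity", "gyration_tensor", "", "0 if degenerate"),
        FeatureDef("gyration_orientation", "gyration_tensor", "deg"),
        FeatureDef("confinement_ratio", "confinement_ratio", "", "0 if zero path length"),
        FeatureDef("mean_straight_line_speed", "mean_straight_line_speed", "um/min"),
        FeatureDef("dwell_state_count", "partition", "count"),
        FeatureDef("dwell_duration_total_relative", "partition", "fraction"),
        FeatureDef("dwell_duration_mean", "partition", "min", "0 if no dwell states"),
        FeatureDef("dwell_diameter_mean", "partition", "um", "0 if no dwell states"),
        FeatureDef("moving_tracklet_count", "partition", "count"),
        FeatureDef("moving_duration_total_relative", "partition", "fraction"),
        FeatureDef("moving_tracklet_duration_mean", "partition", "min", "0 if no tracklets"),
        FeatureDef("moving_tracklet_length_mean", "partition", "um", "0 if no tracklets"),
        FeatureDef("moving_tracklet_speed_mean", "partition", "um/min", "0 if no tracklets"),
        FeatureDef("moving_tracklet_dc_mean", "partition", "deg", "0 if no tracklet has >= 3 points"),
        FeatureDef("moving_tracklet_confinement_mean", "partition", "", "0 if no tracklets"),
    ]
    for eps in rdp_epsilons:
        prefix = _rdp_prefix(eps)
        defs += [
            FeatureDef(prefix + "node_count", "rdp_simplification", "count"),
            FeatureDef(prefix + "segment_length_mean", "rdp_simplification", "um"),
            FeatureDef(prefix + "segment_duration_mean", "rdp_simplification", "min"),
            FeatureDef(prefix + "turn_angle_mean", "rdp_simplification", "deg", "0 if no interior nodes"),
            FeatureDef(prefix + "compression_ratio", "rdp_simplification", "fraction"),
        ]
    return defs


def _rdp_prefix(eps: float) -> str:
    """rdp05_ for 0.5, rdp3_ for 3.0."""
    if eps == int(eps):
        tag = str(int(eps))
    else:
        tag = str(eps).replace(".", "")
        tag = tag.lstrip("0") if eps >= 1 else tag
    return f"rdp{tag}_"


# ---------------------------------------------------------------------------
# Elementary descriptors


def path_length(track: Track) -> float:
    """Total path length: sum of consecutive Euclidean step lengths, µm."""
    return float(np.linalg.norm(np.diff(track.xy, axis=0), axis=1).sum())


def net_displacement(track: Track) -> float:
    """Straight-line distance from first to last point, µm."""
    return float(np.linalg.norm(track.xy[-1] - track.xy[0]))


def duration(track: Track) -> float:
    """Track duration (last minus first frame) in minutes."""
    return track.duration


def diameter_stats(track: Track) -> tuple[float, float, float]:
    """Max, mean and median of all pairwise point distances, µm."""
    d = pdist(track.xy)
    return float(d.max()), float(d.mean()), float(np.median(d))


def step_speeds(track: Track) -> np.ndarray:
    """Instantaneous speeds between consecutive retained points, µm/min.

    Gaps are honored: each step is divided by its actual time difference.
    """
    disp = np.linalg.norm(np.diff(track.xy, axis=0), axis=1)
    dt = np.diff(track.frames) * track.frame_interval
    return disp / dt


def speed_stats(track: Track) -> tuple[float, float, float, float, float]:
    """Mean, median, population std, min, max of instantaneous speed."""
    s = step_speeds(track)
    return (
        float(s.mean()),
        float(np.median(s)),
        float(s.std(ddof=0)),
        float(s.min()),
        float(s.max()),
    )


def turning_angles(xy: np.ndarray) -> np.ndarray:
    """Unsigned angles in [0, 180] deg between consecutive displacement
    vectors; zero-length displacements are skipped."""
    steps = np.diff(xy, axis=0)
    lens = np.linalg.norm(steps, axis=1)
    steps = steps[lens > 0]
    if len(steps) < 2:
        return np.empty(0)
    a, b = steps[:-1], steps[1:]
    cosang = np.einsum("ij,ij->i", a, b) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def directional_change_stats(track: Track) -> tuple[float, float, float, float]:
    """Mean, median, population std and max turning angle, degrees."""
    ang = turning_angles(track.xy)
    if len(ang) == 0:
        return 0.0, 0.0, 0.0, 0.0
    return float(ang.mean()), float(np.median(ang)), float(ang.std(ddof=0)), float(ang.max())


def directional_change_count(
    track: Track, thresholds: tuple[float, ...] = (20.0, 45.0, 90.0)
) -> tuple[float, ...]:
    """Proportion of turning angles strictly greater than each threshold."""
    ang = turning_angles(track.xy)
    if len(ang) == 0:
        return tuple(0.0 for _ in thresholds)
    return tuple(float(np.mean(ang > t)) for t in thresholds)


def velocity_average(track: Track) -> tuple[float, float]:
    """Time-weighted mean velocity vector as (magnitude µm/min, angle deg).

    Weighting each step velocity by its time span makes this the net
    displacement divided by total duration. The angle is counter-clockwise
    from +x in [0, 360); a zero net displacement gives (0, 0) by convention.
    """
    net = track.xy[-1] - track.xy[0]
    v = net / track.duration
    mag = float(np.linalg.norm(v))
    if mag == 0.0:
        return 0.0, 0.0
    ang = float(np.degrees(np.arctan2(v[1], v[0])) % 360.0)
    return mag, ang


def gyration_tensor_features(track: Track) -> tuple[float, float, float, float, float]:
    """Gyration radius, major/minor axis lengths (2*sqrt(eigenvalue)),
    asphericity and principal-axis orientation.

    The gyration tensor is the unweighted second-moment tensor of the
    positions about their centroid, T = (1/N) sum (r - rbar)(r - rbar)^T.
    """
    centered = track.xy - track.xy.mean(axis=0)
    tensor = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(tensor)  # ascending
    lam2, lam1 = float(max(evals[0], 0.0)), float(max(evals[1], 0.0))
    trace = lam1 + lam2
    radius = float(np.sqrt(trace))
    asph = (lam1 - lam2) / trace if trace > 0 else 0.0
    principal = evecs[:, 1]
    orient = float(np.degrees(np.arctan2(principal[1], principal[0])) % 180.0)
    return radius, 2 * np.sqrt(lam1), 2 * np.sqrt(lam2), float(asph), orient


def confinement_ratio(track: Track) -> float:
    """Net displacement over path length in [0, 1]; 0 if path length is 0."""
    path = path_length(track)
    if path == 0.0:
        return 0.0
    return net_displacement(track) / path


def mean_straight_line_speed(track: Track) -> float:
    """Net displacement divided by track duration, µm/min."""
    return net_displacement(track) / track.duration


# ---------------------------------------------------------------------------
# Full feature table


def compute_feature_row(
    track: Track,
    partition_params=None,
    rdp_epsilons: tuple[float, float] = (0.5, 3.0),
) -> dict[str, float]:
    """All descriptors for one track, keyed by registry name."""
    from .partition import (
        PartitionParams,
        dwell_partition,
        partition_features,
        rdp_features,
        rdp_simplify,
    )

    row: dict[str, float] = {}
    row["total_path_length"] = path_length(track)
    row["duration"] = duration(track)
    row["net_displacement"] = net_displacement(track)
    dmax, dmean, dmed = diameter_stats(track)
    row["track_diameter_max"], row["track_diameter_mean"], row["track_diameter_median"] = dmax, dmean, dmed
    (
        row["speed_mean"],
        row["speed_median"],
        row["speed_std"],
        row["speed_min"],
        row["speed_max"],
    ) = speed_stats(track)
    row["dc_mean"], row["dc_median"], row["dc_std"], row["dc_max"] = directional_change_stats(track)
    row["dc_prop_gt20"], row["dc_prop_gt45"], row["dc_prop_gt90"] = directional_change_count(track)
    row["velocity_avg_magnitude"], row["velocity_avg_angle"] = velocity_average(track)
    (
        row["gyration_radius"],
        row["gyration_tensor_major_axis_length"],
        row["gyration_tensor_minor_axis_length"],
        row["gyration_asphericity"],
        row["gyration_orientation"],
    ) = gyration_tensor_features(track)
    row["confinement_ratio"] = confinement_ratio(track)
    row["mean_straight_line_speed"] = mean_straight_line_speed(track)

    params = partition_params if partition_params is not None else PartitionParams()
    part = dwell_partition(track, params)
    row.update(partition_features(part, track))
    for eps in rdp_epsilons:
        res = rdp_simplify(track, eps)
        row.update(rdp_features(res, track, prefix=_rdp_prefix(eps)))
    return row


def compute_feature_table(
    tracks: TrackSet,
    registry: list[FeatureDef] | None = None,
    partition_params=None,
    rdp_epsilons: tuple[float, float] = (0.5, 3.0),
) -> FeatureTable:
    """One row of descriptors per track, columns in registry order.

    The output has exactly the registry's descriptors — no more, no fewer —
    and contains no missing values (degenerate cases are imputed per the
    registry's documented rules).
    """
    registry = registry if registry is not None else default_registry(rdp_epsilons)
    names = [d.name for d in registry]
    rows = {}
    for track in tracks:
        row = compute_feature_row(track, partition_params, rdp_epsilons)
        missing = set(names) - set(row)
        if missing:
            raise ValueError(f"registry descriptors not computed: {sorted(missing)}")
        rows[track.track_id] = [row[n] for n in names]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    df.index.name = "track_id"
    df.insert(0, "group", [tracks.group[tid] for tid in df.index])
    if df[names].isna().any().any():
        raise AssertionError("feature table contains missing values")
    units = {d.name: d.unit for d in registry}
    return FeatureTable(data=df, units=units)
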
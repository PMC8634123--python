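"""Track and feature-table containers and their CSV dialects.

Tracks are 2D centroid trajectories in micrometers sampled at a fixed frame
interval (minutes). Two input dialects are supported: a generic long-format
CSV (``track_id, frame, x_um, y_um``) and the Imaris "Position" statistics
export, which carries a short preamble before the column-header row.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_FRAME_INTERVAL = 20.0  # minutes


class TrackFormatError(ValueError):
    """Input file does not conform to the expected dialect."""


class TrackIntegrityError(ValueError):
    """Parsed rows violate a track invariant (e.g. duplicated frames)."""


@dataclass(frozen=True)
class Track:
    """One cell's ordered 2D positions over frames.

    Parameters
    ----------
    track_id : str
        Unique identifier within a :class:`TrackSet`.
    frames : ndarray of int
        0-based frame indices, strictly increasing. Gaps are permitted;
        rate-like descriptors use the actual time difference between
        consecutive retained points.
    xy : ndarray of shape (n, 2)
        Positions in micrometers.
    frame_interval : float
        Minutes per frame; time at a point is ``frame * frame_interval``.
    """

    track_id: str
    frames: np.ndarray
    xy: np.ndarray
    frame_interval: float = DEFAULT_FRAME_INTERVAL

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        xy = np.asarray(self.xy, dtype=np.float64)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "xy", xy)
        if frames.ndim != 1 or xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("frames must be 1D and xy of shape (n, 2)")
        if len(frames) != len(xy):
            raise ValueError("frames and xy length mismatch")
        if len(frames) < 2:
            raise ValueError(f"track {self.track_id!r}: needs >= 2 points")
        if not np.all(np.diff(frames) > 0):
            raise ValueError(f"track {self.track_id!r}: frames not strictly increasing")
        if not np.all(np.isfinite(xy)):
            raise ValueError(f"track {self.track_id!r}: non-finite coordinates")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        """Time of each point in minutes."""
        return self.frames * self.frame_interval

    @property
    def duration(self) -> float:
        """Time span first to last point, minutes."""
        return float((self.frames[-1] - self.frames[0]) * self.frame_interval)

    def is_gapless(self) -> bool:
        return bool(np.all(np.diff(self.frames) == 1))


@dataclass
class TrackSet:
    """A collection of tracks with per-track treatment-group labels."""

    tracks: dict[str, Track] = field(default_factory=dict)
    group: dict[str, str] = field(default_factory=dict)
    source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid in self.tracks:
            self.group.setdefault(tid, "control")

    def add(self, track: Track, group: str = "control", source: str = "") -> None:
        if track.track_id in self.tracks:
            raise TrackIntegrityError(f"duplicate track_id {track.track_id!r}")
        self.tracks[track.track_id] = track
        self.group[track.track_id] = group
        if source:
            self.source[track.track_id] = source

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks.values())

    def __getitem__(self, track_id: str) -> Track:
        return self.tracks[track_id]

    def track_ids(self) -> list[str]:
        return list(self.tracks)

    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for tid in self.tracks:
            seen.setdefault(self.group[tid], None)
        return list(seen)

    def subset(self, track_ids: Iterable[str]) -> "TrackSet":
        ids = list(track_ids)
        return TrackSet(
            tracks={t: self.tracks[t] for t in ids},
            group={t: self.group[t] for t in ids},
            source={t: self.source[t] for t in ids if t in self.source},
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: track_id, frame, x_um, y_um, group."""
        parts = []
        for tr in self:
            parts.append(
                pd.DataFrame(
                    {
                        "track_id": tr.track_id,
                        "frame": tr.frames,
                        "x_um": tr.xy[:, 0],
                        "y_um": tr.xy[:, 1],
                        "group": self.group[tr.track_id],
                    }
                )
            )
        if not parts:
            return pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um", "group"])
        return pd.concat(parts, ignore_index=True)


@dataclass
class FeatureTable:
    """Per-track descriptor vectors plus the group label.

    ``data`` is indexed by track_id with a leading ``group`` column followed
    by the descriptor columns in registry order. ``units`` maps descriptor
    name to its physical unit. Unknown columns read from disk are kept in
    ``extra`` rather than silently merged with descriptors.
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)
    extra: pd.DataFrame | None = None

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c != "group"]

    @property
    def track_ids(self) -> list[str]:
        return list(self.data.index)

    def values(self) -> pd.DataFrame:
        """Numeric descriptor block, without the group column."""
        return self.data[self.feature_names]

    def group_of(self) -> pd.Series:
        return self.data["group"]


# ---------------------------------------------------------------------------
# Generic CSV dialect


DEFAULT_COLUMN_MAP = {
    "track_id": "track_id",
    "frame": "frame",
    "x": "x_um",
    "y": "y_um",
}


def _tracks_from_long(
    df: pd.DataFrame,
    frame_interval: float,
    source: str,
    group_col: str | None = None,
) -> TrackSet:
    ts = TrackSet()
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        dup = pd.Series(frames).duplicated()
        if dup.any():
            bad = int(frames[dup.to_numpy()][0])
            row = int(sub.index[dup.to_numpy()][0]) + 2  # 1-based incl. header
            raise TrackIntegrityError(
                f"track {tid!r}: duplicate frame {bad} (file row {row})"
            )
        track = Track(
            track_id=str(tid),
            frames=frames,
            xy=sub[["x", "y"]].to_numpy(),
            frame_interval=frame_interval,
        )
        group = str(sub[group_col].iloc[0]) if group_col else "control"
        ts.add(track, group=group, source=source)
    return ts


def read_generic_tracks(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> TrackSet:
    """Read a long-format track CSV.

    ``column_map`` maps the logical names ``track_id``, ``frame``, ``x``,
    ``y`` (and optionally ``group``) onto the file's column headers; default
    headers are ``track_id, frame, x_um, y_um``.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path)
    missing = [v for k, v in cmap.items() if k != "group" and v not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing required column(s) {missing}")
    rename = {v: k for k, v in cmap.items() if v in df.columns}
    df = df.rename(columns=rename)
    for col in ("frame", "x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 2
            raise TrackFormatError(
                f"{path}: non-numeric value {df.loc[df.index[bad][0], col]!r} "
                f"in column {col!r} at file row {row}"
            )
        df[col] = coerced
    if df[["frame", "x", "y"]].isna().any().any():
        row = int(df.index[df[["frame", "x", "y"]].isna().any(axis=1)][0]) + 2
        raise TrackFormatError(f"{path}: missing value at file row {row}")
    group_col = "group" if "group" in df.columns else None
    return _tracks_from_long(df, frame_interval, source=str(path), group_col=group_col)


# ---------------------------------------------------------------------------
# Imaris "Position" statistics export dialect

_IMARIS_REQUIRED = ("Position X", "Position Y", "Time", "TrackID")


def _find_imaris_header(lines: list[str]) -> int:
    for i, line in enumerate(lines):
        cells = [c.strip().strip('"') for c in line.split(",")]
        if any(c.startswith("Position X") for c in cells) and any(
            c.startswith("TrackID") for c in cells
        ):
            return i
    raise TrackFormatError(
        "Imaris dialect: no header row containing 'Position X' and 'TrackID' found"
    )


def read_imaris_spots(
    path: str | Path,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> TrackSet:
    """Read an Imaris statistics "Position" CSV export.

    The export carries title/unit preamble lines before the column header;
    the header row is auto-detected. Column names may carry suffixes
    (e.g. ``Position X [µm]``); matching is by prefix. The ``Time`` column
    (1-based frame number) is converted to a 0-based frame index.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    header_idx = _find_imaris_header(lines)
    # crude unit check on the preamble, warning only
    preamble = "\n".join(lines[:header_idx])
    if preamble and "um" not in preamble and "µm" not in preamble and "=" in preamble:
        logger.warning("%s: Imaris preamble does not mention micrometer units", path)
    df = pd.read_csv(io.StringIO("\n".join(lines[header_idx:])))
    df.columns = [str(c).strip() for c in df.columns]
    resolved: dict[str, str] = {}
    for want in _IMARIS_REQUIRED:
        hits = [c for c in df.columns if c.startswith(want)]
        if not hits:
            raise TrackFormatError(f"{path}: Imaris dialect lacks a {want!r} column")
        resolved[want] = hits[0]
    sub = pd.DataFrame(
        {
            "track_id": df[resolved["TrackID"]].astype(str),
            "frame": pd.to_numeric(df[resolved["Time"]]),
            "x": pd.to_numeric(df[resolved["Position X"]]),
            "y": pd.to_numeric(df[resolved["Position Y"]]),
        }
    ).dropna(subset=["track_id"])
    sub["frame"] = (sub["frame"] - sub["frame"].min()).astype(np.int64)
    return _tracks_from_long(sub, frame_interval, source=str(path))


# ---------------------------------------------------------------------------
# Feature-table CSV


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV with a unit sidecar comment line."""
    path = Path(path)
    units_line = "# units: " + ",".join(
        f"{name}={table.units.get(name, '')}" for name in table.feature_names
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(units_line + "\n")
        table.data.to_csv(fh, index_label="track_id")


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature-table CSV written by :func:`write_feature_table`.

    Columns beyond ``group`` and the unit-declared descriptors are preserved
    as metadata (``extra``) with a warning.
    """
    path = Path(path)
    units: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# units:"):
            for chunk in first[len("# units:"):].strip().split(","):
                if "=" in chunk:
                    k, _, v = chunk.partition("=")
                    units[k.strip()] = v.strip()
            df = pd.read_csv(fh, index_col="track_id")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, index_col="track_id", comment="#")
    df.index = df.index.astype(str)
    known = set(units) | {"group"}
    unknown = [c for c in df.columns if units and c not in known]
    extra = None
    if unknown:
        warnings.warn(
            f"{path}: unknown column(s) {unknown} preserved as metadata",
            stacklevel=2,
        )
        extra = df[unknown]
        df = df.drop(columns=unknown)
    return FeatureTable(data=df, units=units, extra=extra)
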
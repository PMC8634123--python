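"""Synthetic track generator with known motion models and ground truth.

Emulates the motion regimes seen in time-lapse recordings of migrating
cells sampled every 20 minutes: ballistic drift, uncorrelated and
persistent random walks, saltatory run/dwell alternation, confined
(tethered) wandering and stationary jitter. Every generated track carries a
ground-truth annotation so downstream partitioning, clustering and
statistics can be validated without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .track_io import DEFAULT_FRAME_INTERVAL, Track, TrackSet

MODELS = (
    "ballistic",
    "random_walk",
    "persistent_walk",
    "saltatory",
    "confined",
    "stationary",
)


@dataclass(frozen=True)
class MotionConfig:
    """Parameters of one motion model.

    Defaults describe a slowly migrating neuron imaged at 20 min/frame:
    run speed 0.5 µm/min, random-walk step scale 2 µm/frame, positional
    jitter 0.3 µm (segmentation noise), saltatory runs of ~8 frames
    alternating with dwells of ~6 frames, confinement tether 5 µm.
    """

    model: str = "random_walk"
    n_frames: int = 150
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    speed: float = 0.5  # µm/min, ballistic / run segments
    heading: float | None = None  # degrees; None = random
    step_sd: float = 2.0  # µm per frame, random-walk models
    persistence: float = 0.7  # AR(1) weight on previous step
    run_frames_mean: float = 8.0
    dwell_frames_mean: float = 6.0
    segment_min_frames: int = 1  # shifted-geometric floor for run/dwell lengths
    tether_sd: float = 5.0  # µm, stationary sd of confined model
    jitter_sd: float = 0.3  # µm, additive positional noise
    seed: int = 0

    def validate(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown motion model {self.model!r}; expected one of {MODELS}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not (0 <= self.persistence < 1):
            raise ValueError("persistence must be in [0, 1)")
        for name in ("speed", "step_sd", "run_frames_mean", "dwell_frames_mean", "tether_sd", "jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if self.segment_min_frames < 1:
            raise ValueError("segment_min_frames must be >= 1")


@dataclass(frozen=True)
class CohortConfig:
    """Groups of tracks, each drawn from one or more motion models."""

    groups: dict[str, Sequence[tuple[MotionConfig, int]]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for name, specs in self.groups.items():
            for cfg, count in specs:
                cfg.validate()
                if count < 1:
                    raise ValueError(f"group {name!r}: count must be >= 1")


@dataclass
class TrackAnnotation:
    """Ground truth for one generated track."""

    model: str
    group: str = "control"
    dwell_state: np.ndarray | None = None  # per-frame bool, saltatory only
    n_dwell_states: int | None = None


def _unit(theta: float) -> np.ndarray:
    return np.array([np.cos(theta), np.sin(theta)])


def _heading(cfg: MotionConfig, rng: np.random.Generator) -> float:
    if cfg.heading is None:
        return float(rng.uniform(0, 2 * np.pi))
    return float(np.deg2rad(cfg.heading))


def gen_track(config: MotionConfig, track_id: str = "t0") -> tuple[Track, TrackAnnotation]:
    """Generate one track; deterministic for a given config (seed included)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    dt = config.frame_interval
    step_len = config.speed * dt  # µm per frame for ballistic motion
    ann = TrackAnnotation(model=config.model)

    if config.model == "ballistic":
        direction = _unit(_heading(config, rng))
        base = np.outer(np.arange(n, dtype=float), direction * step_len)
    elif config.model == "random_walk":
        steps = rng.normal(0.0, config.step_sd, size=(n - 1, 2))
        base = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    elif config.model == "persistent_walk":
        # AR(1) step process: stationary per-axis sd equals step_sd
        phi = config.persistence
        noise = rng.normal(0.0, config.step_sd, size=(n - 1, 2)) * np.sqrt(1 - phi**2)
        steps = np.empty((n - 1, 2))
        prev = rng.normal(0.0, config.step_sd, size=2)
        for i in range(n - 1):
            prev = phi * prev + noise[i]
            steps[i] = prev
        base = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    elif config.model == "saltatory":
        base, dwell = _gen_saltatory(config, rng, step_len)
        ann.dwell_state = dwell
        # count contiguous dwell episodes
        ann.n_dwell_states = int(np.sum(np.diff(np.r_[0, dwell.astype(int)]) == 1))
    elif config.model == "confined":
        # Mean-reverting (AR(1) positions) with stationary sd = tether_sd
        if config.tether_sd > config.step_sd > 0:
            theta = np.sqrt(1.0 - (config.step_sd / config.tether_sd) ** 2)
        else:
            theta = 0.0
        innov_sd = config.step_sd if config.tether_sd > 0 else 0.0
        pos = np.zeros((n, 2))
        for i in range(1, n):
            pos[i] = theta * pos[i - 1] + rng.normal(0.0, innov_sd, size=2)
        base = pos
    elif config.model == "stationary":
        base = np.zeros((n, 2))
    else:  # pragma: no cover - guarded by validate
        raise ValueError(config.model)

    if config.jitter_sd > 0:
        base = base + rng.normal(0.0, config.jitter_sd, size=base.shape)
    track = Track(track_id=track_id, frames=np.arange(n), xy=base, frame_interval=dt)
    return track, ann


def _gen_saltatory(
    config: MotionConfig, rng: np.random.Generator, step_len: float
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating ballistic runs and dwells with geometric segment lengths."""
    n = config.n_frames
    # stationary start-state choice keeps the long-run dwell fraction at
    # dwell_mean / (run_mean + dwell_mean) even for short tracks
    p_dwell = config.dwell_frames_mean / (config.run_frames_mean + config.dwell_frames_mean)
    in_dwell = bool(rng.random() < p_dwell)
    pos = np.zeros((n, 2))
    dwell = np.zeros(n, dtype=bool)
    dwell[0] = in_dwell
    i = 1
    cur = np.zeros(2)
    floor = max(int(config.segment_min_frames), 1)
    while i < n:
        mean = config.dwell_frames_mean if in_dwell else config.run_frames_mean
        # shifted geometric: support >= floor, mean preserved at `mean`
        seg = floor - 1 + int(rng.geometric(1.0 / max(mean - floor + 1, 1.0)))
        if in_dwell:
            for _ in range(seg):
                if i >= n:
                    break
                pos[i] = cur  # jitter added globally afterwards
                dwell[i] = True
                i += 1
        else:
            direction = _unit(_heading(config, rng))  # fresh heading per run unless fixed
            for _ in range(seg):
                if i >= n:
                    break
                cur = cur + direction * step_len
                pos[i] = cur
                dwell[i] = False
                i += 1
        in_dwell = not in_dwell
    return pos, dwell


def gen_cohort(config: CohortConfig) -> tuple[TrackSet, pd.DataFrame]:
    """Generate a labeled cohort plus a ground-truth table.

    One global seed spawns independent per-track child seeds, so the cohort
    is reproducible regardless of generation order.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    trackset = TrackSet()
    truth_rows = []
    annotations: dict[str, TrackAnnotation] = {}
    counter = 0
    for group_name, specs in config.groups.items():
        for cfg, count in specs:
            children = ss.spawn(count)
            for child in children:
                seed = int(child.generate_state(1)[0] % (2**31))
                tid = f"{group_name}_{counter:05d}"
                counter += 1
                track, ann = gen_track(replace(cfg, seed=seed), track_id=tid)
                ann.group = group_name
                trackset.add(track, group=group_name, source=f"simulated:{cfg.model}")
                annotations[tid] = ann
                truth_rows.append(
                    {
                        "track_id": tid,
                        "group": group_name,
                        "model": cfg.model,
                        "n_frames": cfg.n_frames,
                        "short": cfg.n_frames < 12,
                        "n_dwell_states": ann.n_dwell_states,
                    }
                )
    truth = pd.DataFrame(truth_rows).set_index("track_id")
    truth.attrs["annotations"] = annotations
    return trackset, truth
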
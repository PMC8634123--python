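"""End-to-end screen orchestration.

Stage order: read → minimum-length filter → feature computation →
non-moving filter → control-anchored clustering → cluster/mode assignment
→ composition → per-descriptor group statistics → population MSD/VAC
curves per cluster. Every stage logs its counts into a manifest so the
filter bookkeeping is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, dynamics, features, group_stats, preprocess
from .partition import PartitionParams
from .track_io import FeatureTable, TrackSet, write_feature_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the standard analysis values."""

    frame_interval: float = 20.0  # minutes
    min_frames: int = 12
    diameter_max_threshold: float = 15.0  # µm
    major_axis_threshold: float = 5.0  # µm
    filter_combine: str = "both"
    smooth_window: int = 1  # 1 = no smoothing
    t_scale: float = 1.1
    partition_eps: float = 3.3
    min_pts: int = 4
    rdp_epsilons: tuple[float, float] = (0.5, 3.0)
    k: int = 10
    n_init: int = 20
    variance_threshold: float = 0.95
    feature_group_count: int = 9
    alpha: float = 0.05
    control_label: str = "control"
    mode_map: dict[int, str] | None = None
    cluster_all_groups: bool = False
    max_lag: float = 24 * 60.0  # minutes
    stats_center: str = "median"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rdp_epsilons"] = list(self.rdp_epsilons)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    features: FeatureTable
    filter_reports: list[preprocess.FilterReport]
    model: clustering.ClusterModel
    cluster_labels: pd.Series
    mode_labels: pd.Series
    composition: clustering.ModeComposition
    stats: group_stats.GroupStatsResult | None
    msd_by_cluster: dict[str, dynamics.LagCurve]
    vac_by_cluster: dict[str, dynamics.LagCurve]
    manifest: dict = field(default_factory=dict)


def run_pipeline(tracks: TrackSet, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis on a labeled track set."""
    config = config or PipelineConfig()
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "stages": [],
    }

    def stage(name: str, **info) -> None:
        manifest["stages"].append({"stage": name, **info})
        logger.info("stage %-22s %s", name, info)

    stage("input", n_tracks=len(tracks), groups=tracks.groups())

    if config.smooth_window > 1:
        smoothed = TrackSet()
        for t in tracks:
            smoothed.add(
                preprocess.smooth_track(t, config.smooth_window),
                group=tracks.group[t.track_id],
                source=tracks.source.get(t.track_id, ""),
            )
        tracks = smoothed
        stage("smooth", window=config.smooth_window)

    tracks, rep_len = preprocess.filter_min_frames(tracks, config.min_frames)
    stage("min_frames_filter", n_removed=rep_len.n_removed, n_retained=rep_len.n_retained)

    params = PartitionParams(
        t_scale=config.t_scale, eps=config.partition_eps, min_pts=config.min_pts
    )
    table = features.compute_feature_table(
        tracks, partition_params=params, rdp_epsilons=config.rdp_epsilons
    )
    stage("features", n_tracks=len(table.data), n_descriptors=len(table.feature_names))

    tracks, rep_mov = preprocess.filter_non_moving(
        tracks,
        table,
        diameter_max_threshold=config.diameter_max_threshold,
        major_axis_threshold=config.major_axis_threshold,
        combine=config.filter_combine,
    )
    table = FeatureTable(
        data=table.data.loc[tracks.track_ids()], units=table.units
    )
    stage("non_moving_filter", n_removed=rep_mov.n_removed, n_retained=rep_mov.n_retained)

    if not config.cluster_all_groups and config.control_label not in tracks.groups():
        raise ValueError(
            f"control group {config.control_label!r} absent; "
            "anchored clustering needs it (or set cluster_all_groups)"
        )
    model = clustering.fit_reference_model(
        table,
        reference_group=config.control_label,
        k=config.k,
        n_init=config.n_init,
        variance_threshold=config.variance_threshold,
        seed=config.seed,
        fit_on_all=config.cluster_all_groups,
    )
    if config.mode_map is not None:
        model.mode_map = dict(config.mode_map)
    labels = clustering.assign(model, table)
    modes = clustering.map_modes(labels, model.mode_map)
    stage(
        "clustering",
        k=model.k,
        n_components=model.components.shape[0],
        explained_variance=float(model.explained_variance_ratio.sum()),
    )

    composition = clustering.mode_composition(
        modes, table.group_of(), control_label=config.control_label
    )
    stage("composition", groups=list(composition.proportions.index))

    stats_result = None
    treatments = [g for g in tracks.groups() if g != config.control_label]
    if treatments and config.control_label in tracks.groups():
        stats_result = group_stats.mwu_vs_control(
            table,
            control_label=config.control_label,
            alpha=config.alpha,
            center=config.stats_center,
        )
        stage("group_stats", n_treatments=len(treatments))

    msd_curves, vac_curves, curve_labels = [], [], []
    for t in tracks:
        msd_curves.append(dynamics.msd_curve(t, max_lag=config.max_lag))
        vac_curves.append(dynamics.vac_curve(t, max_lag=config.max_lag))
        curve_labels.append(str(labels[t.track_id]))
    msd_by_cluster = dynamics.aggregate_curves(msd_curves, curve_labels)
    vac_by_cluster = dynamics.aggregate_curves(vac_curves, curve_labels)
    stage("population_dynamics", n_cluster_curves=len(msd_by_cluster))

    return PipelineResult(
        features=table,
        filter_reports=[rep_len, rep_mov],
        model=model,
        cluster_labels=labels,
        mode_labels=modes,
        composition=composition,
        stats=stats_result,
        msd_by_cluster=msd_by_cluster,
        vac_by_cluster=vac_by_cluster,
        manifest=manifest,
    )


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write all pipeline artifacts as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_feature_table(result.features, outdir / "features.csv")
    result.model.to_json(outdir / "cluster_model.json")
    pd.DataFrame(
        {"cluster": result.cluster_labels, "mode": result.mode_labels}
    ).to_csv(outdir / "assignments.csv", index_label="track_id")
    result.composition.proportions.to_csv(outdir / "mode_composition.csv")
    if result.composition.fold_change is not None:
        result.composition.fold_change.to_csv(outdir / "mode_fold_change.csv")
    if result.stats is not None:
        result.stats.table.to_csv(outdir / "group_stats.csv", index=False)
        result.stats.kruskal.to_csv(outdir / "kruskal_wallis.csv")
        effects, mask = group_stats.control_normalized_heatmap(result.stats)
        effects.to_csv(outdir / "heatmap_effects.csv")
        mask.to_csv(outdir / "heatmap_mask.csv")
    for kind, curves in (("msd", result.msd_by_cluster), ("vac", result.vac_by_cluster)):
        frames = [c.to_frame(label=lab) for lab, c in curves.items()]
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(outdir / f"{kind}_curves.csv", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=1, default=str), encoding="utf-8"
    )
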
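"""Control-anchored migration-mode clustering.

The normalization (z-score), PCA projection and K-means centers are fitted
on the reference (control) group only; every track — control or treated —
is then normalized with the control parameters, projected and assigned to
the nearest center. Clusters are relabeled by descending mean speed and
grouped into three migration modes: Directed (fast, straight), Exploratory
(fast with turns and pauses) and Confined (slow, restricted).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .track_io import FeatureTable

MODES = ("Directed", "Exploratory", "Confined")


@dataclass
class ClusterModel:
    """Frozen normalization + projection + K-means centers.

    ``feature_names`` are the retained descriptors (zero-variance ones are
    dropped); ``components`` is the PCA loading matrix (n_components x
    n_features) applied after z-scoring with the reference group's mean and
    sd; ``centers`` live in component space.
    """

    reference_group: str
    feature_names: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray
    centers: np.ndarray
    k: int
    mode_map: dict[int, str] = field(default_factory=dict)
    dropped_features: list[str] = field(default_factory=list)

    def transform(self, features: FeatureTable) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in features.data.columns]
        if missing:
            raise ValueError(f"feature table lacks descriptor(s) {missing}")
        x = features.data[self.feature_names].to_numpy(dtype=float)
        z = (x - self.feature_means) / self.feature_sds
        return z @ self.components.T

    def to_json(self, path: str | Path) -> None:
        doc = {
            "reference_group": self.reference_group,
            "feature_names": self.feature_names,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "centers": self.centers.tolist(),
            "k": self.k,
            "mode_map": {str(k): v for k, v in self.mode_map.items()},
            "dropped_features": self.dropped_features,
        }
        Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            reference_group=doc["reference_group"],
            feature_names=doc["feature_names"],
            feature_means=np.array(doc["feature_means"]),
            feature_sds=np.array(doc["feature_sds"]),
            components=np.array(doc["components"]),
            explained_variance_ratio=np.array(doc["explained_variance_ratio"]),
            centers=np.array(doc["centers"]),
            k=int(doc["k"]),
            mode_map={int(k): v for k, v in doc["mode_map"].items()},
            dropped_features=list(doc.get("dropped_features", [])),
        )


def default_mode_map(k: int) -> dict[int, str]:
    """Contiguous split of reordered cluster ids into the three modes.

    After speed reordering, the fastest block maps to Directed, the middle
    to Exploratory and the slowest to Confined; at k = 10 this is clusters
    0–3 / 4–6 / 7–9.
    """
    blocks = np.array_split(np.arange(k), 3)
    return {int(c): MODES[i] for i, ids in enumerate(blocks) for c in ids}


def _zscore_params(ref: pd.DataFrame) -> tuple[list[str], np.ndarray, np.ndarray, list[str]]:
    sds = ref.std(ddof=0)
    dropped = list(sds.index[sds == 0])
    if dropped:
        warnings.warn(f"dropping zero-variance descriptor(s): {dropped}", stacklevel=3)
    kept = [c for c in ref.columns if c not in dropped]
    return kept, ref[kept].mean().to_numpy(), sds[kept].to_numpy(), dropped


def fit_reference_model(
    features: FeatureTable,
    reference_group: str = "control",
    k: int = 10,
    n_init: int = 20,
    variance_threshold: float = 0.95,
    seed: int = 0,
    reorder: bool = True,
    fit_on_all: bool = False,
) -> ClusterModel:
    """Fit z-score + PCA + K-means on the reference group.

    The component count is the smallest reaching the cumulative
    explained-variance threshold; K-means runs ``n_init`` random restarts
    keeping the lowest inertia. With ``fit_on_all=True`` the model is
    fitted on every track regardless of group (sanity-check variant).
    """
    mask = (
        np.ones(len(features.data), dtype=bool)
        if fit_on_all
        else (features.group_of() == reference_group).to_numpy()
    )
    ref = features.values()[mask]
    if len(ref) < k:
        raise ValueError(f"reference group has {len(ref)} tracks, fewer than k={k}")
    kept, means, sds, dropped = _zscore_params(ref)
    z = (ref[kept].to_numpy(dtype=float) - means) / sds

    pca = PCA(svd_solver="full").fit(z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_threshold) + 1)
    n_comp = min(n_comp, len(cum))
    components = pca.components_[:n_comp]
    proj = z @ components.T

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd", tol=1e-6)
    km.fit(proj)
    model = ClusterModel(
        reference_group=reference_group,
        feature_names=kept,
        feature_means=means,
        feature_sds=sds,
        components=components,
        explained_variance_ratio=pca.explained_variance_ratio_[:n_comp],
        centers=km.cluster_centers_,
        k=k,
        dropped_features=dropped,
    )
    if reorder:
        model = reorder_clusters(model, features)
    model.mode_map = default_mode_map(k)
    return model


def assign(model: ClusterModel, features: FeatureTable) -> pd.Series:
    """Nearest-center cluster label for every track (ties → lowest id)."""
    proj = model.transform(features)
    d2 = ((proj[:, None, :] - model.centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)  # argmin takes the lowest index on ties
    return pd.Series(labels, index=features.data.index, name="cluster")


def elbow_scan(
    features: FeatureTable,
    k_range: list[int],
    reference_group: str | None = "control",
    n_init: int = 20,
    variance_threshold: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Best-of-n_init K-means inertia for each candidate k (advisory only)."""
    mask = (
        np.ones(len(features.data), dtype=bool)
        if reference_group is None
        else (features.group_of() == reference_group).to_numpy()
    )
    ref = features.values()[mask]
    kept, means, sds, _ = _zscore_params(ref)
    z = (ref[kept].to_numpy(dtype=float) - means) / sds
    pca = PCA(svd_solver="full").fit(z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = min(int(np.searchsorted(cum, variance_threshold) + 1), len(cum))
    proj = z @ pca.components_[:n_comp].T
    rows = []
    for k in k_range:
        if k > len(ref):
            raise ValueError(f"k={k} exceeds {len(ref)} reference tracks")
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd", tol=1e-6)
        km.fit(proj)
        rows.append({"k": k, "inertia": float(km.inertia_)})
    return pd.DataFrame(rows)


def reorder_clusters(
    model: ClusterModel,
    features: FeatureTable,
    key_feature: str = "speed_mean",
) -> ClusterModel:
    """Relabel clusters by descending mean ``key_feature`` of their
    reference members (fastest first); pure relabeling."""
    ref_mask = features.group_of() == model.reference_group
    ref = FeatureTable(data=features.data[ref_mask.to_numpy()], units=features.units)
    labels = assign(model, ref)
    key = ref.data[key_feature]
    order = []
    for c in range(model.k):
        members = key[labels == c]
        order.append(float(members.mean()) if len(members) else -np.inf)
    perm = np.argsort(order)[::-1]  # cluster ids sorted fastest-first
    new_centers = model.centers[perm]
    return ClusterModel(
        reference_group=model.reference_group,
        feature_names=model.feature_names,
        feature_means=model.feature_means,
        feature_sds=model.feature_sds,
        components=model.components,
        explained_variance_ratio=model.explained_variance_ratio,
        centers=new_centers,
        k=model.k,
        mode_map=dict(model.mode_map),
        dropped_features=list(model.dropped_features),
    )


def feature_dendrogram_groups(features: FeatureTable, n_groups: int = 9) -> dict[str, int]:
    """Group descriptors by Ward hierarchical clustering of their z-scored
    profiles across tracks, cut into exactly ``n_groups`` flat clusters."""
    vals = features.values()
    kept, means, sds, _ = _zscore_params(vals)
    if len(kept) < n_groups:
        raise ValueError(f"only {len(kept)} non-constant descriptors for {n_groups} groups")
    z = (vals[kept].to_numpy(dtype=float) - means) / sds
    link = linkage(z.T, method="ward")
    flat = fcluster(link, t=n_groups, criterion="maxclust")
    return {name: int(g) for name, g in zip(kept, flat)}


def map_modes(labels: pd.Series, mode_map: dict[int, str]) -> pd.Series:
    """Cluster id → migration-mode label."""
    missing = sorted(set(labels.unique()) - set(mode_map))
    if missing:
        raise ValueError(f"mode_map lacks cluster id(s) {missing}")
    return labels.map(mode_map).rename("mode")


@dataclass
class ModeComposition:
    """Per-group mode proportions and fold changes vs the control group."""

    proportions: pd.DataFrame  # groups x modes, rows sum to 1
    fold_change: pd.DataFrame | None  # vs control; None if control absent


def mode_composition(
    modes: pd.Series,
    groups: pd.Series,
    control_label: str = "control",
    mode_order: tuple[str, ...] = MODES,
) -> ModeComposition:
    """Relative distribution of tracks among modes, per treatment group."""
    df = pd.DataFrame({"mode": modes, "group": groups})
    counts = df.groupby(["group", "mode"], sort=False).size().unstack(fill_value=0)
    for m in mode_order:
        if m not in counts.columns:
            counts[m] = 0
    counts = counts[list(mode_order)]
    props = counts.div(counts.sum(axis=1), axis=0)
    if control_label not in props.index:
        warnings.warn(f"control group {control_label!r} absent; fold changes omitted", stacklevel=2)
        return ModeComposition(proportions=props, fold_change=None)
    ctrl = props.loc[control_label]
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = props.div(ctrl, axis=1)
    return ModeComposition(proportions=props, fold_change=fold)
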
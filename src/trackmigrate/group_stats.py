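"""Per-descriptor screening statistics across treatment groups.

For each descriptor a Kruskal–Wallis test assesses overall variation
across groups; each treatment is then compared against the control with a
two-sided Mann–Whitney U test, Bonferroni-corrected over the treatments.
Effects are summarized as log2 ratios of group central values over the
control, masked where non-significant or undefined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .track_io import FeatureTable

# descriptors on a circular scale: a ratio of central values is meaningless
ANGULAR_DESCRIPTORS = frozenset({"velocity_avg_angle", "gyration_orientation"})

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for thr, sym in STAR_THRESHOLDS:
        if p < thr:
            return sym
    return "ns"


@dataclass
class GroupStatsResult:
    """Long-format per (feature, group) effects and p-values plus
    per-feature Kruskal–Wallis results."""

    table: pd.DataFrame  # feature, group, effect_log2, p_raw, p_bonferroni, significant, stars
    kruskal: pd.DataFrame  # feature, H, p, flagged_constant
    control_label: str
    alpha: float


def kruskal_wallis_per_feature(
    features: FeatureTable, groups: pd.Series | None = None
) -> pd.DataFrame:
    """Kruskal–Wallis H (tie-corrected) and chi-square p per descriptor.

    A descriptor constant across all tracks gets p = 1 with a flag.
    """
    groups = groups if groups is not None else features.group_of()
    labels = groups.unique()
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    for name in features.feature_names:
        samples = [features.data.loc[groups == g, name].to_numpy() for g in labels]
        if any(len(s) < 2 for s in samples):
            raise ValueError("every group needs >= 2 tracks")
        if np.ptp(features.data[name].to_numpy()) == 0:
            rows.append({"feature": name, "H": 0.0, "p": 1.0, "flagged_constant": True})
            continue
        h, p = stats.kruskal(*samples)
        rows.append({"feature": name, "H": float(h), "p": float(p), "flagged_constant": False})
    return pd.DataFrame(rows).set_index("feature")


def _mwu_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann–Whitney U p-value.

    Exact null distribution when both samples are small (≤ 20) and tie-free;
    otherwise the normal approximation with tie and continuity correction.
    """
    small = max(len(x), len(y)) <= 20
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if small and not has_ties else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def mwu_vs_control(
    features: FeatureTable,
    groups: pd.Series | None = None,
    control_label: str = "control",
    alpha: float = 0.05,
    center: str = "median",
) -> GroupStatsResult:
    """Each treatment vs control per descriptor, Bonferroni-corrected.

    The Bonferroni family is the set of treatment-vs-control comparisons of
    one descriptor; effect sizes are log2 ratios of group central values
    (median by default) over the control.
    """
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    groups = groups if groups is not None else features.group_of()
    labels = [g for g in groups.unique() if g != control_label]
    if control_label not in set(groups):
        raise ValueError(f"control group {control_label!r} not present")
    usable = []
    for g in labels:
        if (groups == g).sum() < 2:
            warnings.warn(f"group {g!r} has < 2 tracks; skipped", stacklevel=2)
        else:
            usable.append(g)
    n_comp = len(usable)
    centerfun = np.median if center == "median" else np.mean
    kw = None
    if n_comp >= 1:
        kw_mask = groups.isin([control_label] + usable).to_numpy()
        kw_feats = FeatureTable(data=features.data[kw_mask], units=features.units)
        kw = kruskal_wallis_per_feature(kw_feats, groups[kw_mask])

    rows = []
    for name in features.feature_names:
        ctrl = features.data.loc[groups == control_label, name].to_numpy(dtype=float)
        c_ctrl = float(centerfun(ctrl))
        for g in usable:
            vals = features.data.loc[groups == g, name].to_numpy(dtype=float)
            if np.ptp(np.concatenate([ctrl, vals])) == 0:
                p_raw = 1.0
            else:
                p_raw = _mwu_p(vals, ctrl)
            p_corr = min(1.0, p_raw * n_comp)
            c_grp = float(centerfun(vals))
            if name in ANGULAR_DESCRIPTORS or c_ctrl <= 0 or c_grp <= 0:
                effect = np.nan
            else:
                effect = float(np.log2(c_grp / c_ctrl))
            rows.append(
                {
                    "feature": name,
                    "group": g,
                    "effect_log2": effect,
                    "p_raw": p_raw,
                    "p_bonferroni": p_corr,
                    "significant": p_corr < alpha,
                    "stars": _stars(p_corr) if p_corr < alpha else "ns",
                }
            )
    table = pd.DataFrame(rows)
    return GroupStatsResult(table=table, kruskal=kw, control_label=control_label, alpha=alpha)


def control_normalized_heatmap(
    stats_result: GroupStatsResult,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wide effect matrix (features x groups, log2 ratios vs control) and a
    parallel boolean mask, True where the entry is non-significant or
    undefined (angular descriptor, non-positive center)."""
    t = stats_result.table
    effects = t.pivot(index="feature", columns="group", values="effect_log2")
    sig = t.pivot(index="feature", columns="group", values="significant").astype(bool)
    mask = (~sig) | effects.isna()
    return effects, mask
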
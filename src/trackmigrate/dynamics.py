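"""Mean-squared displacement and velocity autocorrelation curves.

Both curves are time-averaged per track (overlapping windows) and then
averaged without weighting across the tracks of a cluster, so tracks of
unequal length contribute equally to a population curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .track_io import Track

DEFAULT_MAX_LAG = 24 * 60.0  # minutes


@dataclass
class LagCurve:
    """A per-lag summary curve.

    ``lags`` are minutes (multiples of the frame interval), ``values`` are
    µm² for MSD or dimensionless for VAC, ``n_pairs`` counts the averaged
    pairs (or contributing tracks after aggregation).
    """

    lags: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray
    kind: str = "msd"

    def to_frame(self, label: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {"label": label, "lag_min": self.lags, "value": self.values, "n": self.n_pairs}
        )


def _frame_positions(track: Track) -> dict[int, np.ndarray]:
    return {int(f): track.xy[i] for i, f in enumerate(track.frames)}


def msd_curve(track: Track, max_lag: float = DEFAULT_MAX_LAG) -> LagCurve:
    """Time-averaged MSD(τ) = <|r(t+τ) − r(t)|²> over all valid pairs.

    Pairs spanning frame gaps are simply absent (no interpolation). Lags run
    from one frame interval up to min(max_lag, duration − Δt).
    """
    dt = track.frame_interval
    span = int(track.frames[-1] - track.frames[0])
    max_k = min(int(max_lag // dt), span - 1)
    pos = _frame_positions(track)
    frames = sorted(pos)
    lags, vals, ns = [], [], []
    for k in range(1, max_k + 1):
        sq = [
            np.sum((pos[f + k] - pos[f]) ** 2)
            for f in frames
            if f + k in pos
        ]
        if not sq:
            continue
        lags.append(k * dt)
        vals.append(float(np.mean(sq)))
        ns.append(len(sq))
    return LagCurve(np.array(lags), np.array(vals), np.array(ns), kind="msd")


def vac_curve(track: Track, max_lag: float = DEFAULT_MAX_LAG) -> LagCurve:
    """Velocity autocorrelation normalized per track so VAC(0) = 1.

    Step velocities v_i between consecutive frames are correlated at frame
    lags and normalized by the track's mean squared speed. An all-zero
    velocity track yields a curve of zeros.
    """
    if track.n_points < 3:
        raise ValueError("vac_curve needs >= 3 points")
    if not track.is_gapless():
        raise ValueError("vac_curve requires a gapless track")
    dt = track.frame_interval
    v = np.diff(track.xy, axis=0) / dt
    denom = float(np.mean(np.einsum("ij,ij->i", v, v)))
    max_k = min(int(max_lag // dt), len(v) - 1)
    lags = np.arange(0, max_k + 1) * dt
    vals = np.zeros(len(lags))
    ns = np.zeros(len(lags), dtype=int)
    for k in range(0, max_k + 1):
        dots = np.einsum("ij,ij->i", v[: len(v) - k], v[k:])
        ns[k] = len(dots)
        vals[k] = float(np.mean(dots)) / denom if denom > 0 else 0.0
    return LagCurve(lags, vals, ns, kind="vac")


def aggregate_curves(
    curves: Sequence[LagCurve],
    labels: Sequence[str] | None = None,
    min_tracks: int = 3,
) -> dict[str, LagCurve]:
    """Unweighted per-label mean curve across tracks.

    Lags with fewer than ``min_tracks`` contributing tracks are dropped.
    """
    labels = list(labels) if labels is not None else ["all"] * len(curves)
    if len(labels) != len(curves):
        raise ValueError("labels and curves length mismatch")
    out: dict[str, LagCurve] = {}
    for lab in dict.fromkeys(labels):
        group = [c for c, l in zip(curves, labels) if l == lab]
        if not group:
            continue
        acc: dict[float, list[float]] = {}
        for c in group:
            for lag, val in zip(c.lags, c.values):
                acc.setdefault(float(lag), []).append(float(val))
        lags = sorted(lag for lag, vals in acc.items() if len(vals) >= min_tracks)
        if not lags:
            continue
        out[lab] = LagCurve(
            lags=np.array(lags),
            values=np.array([np.mean(acc[l]) for l in lags]),
            n_pairs=np.array([len(acc[l]) for l in lags]),
            kind=group[0].kind,
        )
    return out


def fit_msd_exponent(curve: LagCurve, fit_range: tuple[float, float] | None = None) -> float:
    """Log-log slope of an MSD curve (≈2 ballistic, ≈1 diffusive).

    Non-positive values are excluded; at least 3 points must remain.
    """
    mask = curve.values > 0
    if fit_range is not None:
        lo, hi = fit_range
        mask &= (curve.lags >= lo) & (curve.lags <= hi)
    if mask.sum() < 3:
        raise ValueError("need >= 3 positive MSD values in fit range")
    res = stats.linregress(np.log(curve.lags[mask]), np.log(curve.values[mask]))
    return float(res.slope)
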
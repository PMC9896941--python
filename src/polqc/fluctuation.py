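"""Anchored time-shifted cross-correlation over cluster tracks.

Each track's signals are z-scored, correlated against an anchor signal
(default: elongation) on a symmetric lag grid, and aggregated over tracks
with a percentile bootstrap that resamples whole tracks — preserving
within-track autocorrelation.  Sign convention: a positive lag means the
signal's event follows the anchor's.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def normalize_track(series: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance copy of a track signal (ddof=1).

    Affine-invariant: ``a*x + b`` with ``a > 0`` normalizes identically to
    ``x``.  Constant series raise (callers exclude the track, with reason).
    """
    x = np.asarray(series, dtype=np.float64)
    if x.size < 3:
        raise ValueError("series must have length >= 3")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("constant or non-finite series cannot be normalized")
    return (x - x.mean()) / sd


def lagged_correlation(
    anchor: np.ndarray,
    other: np.ndarray,
    max_lag: int,
    min_overlap: int = 3,
) -> np.ndarray:
    """Pearson correlation of ``anchor(t)`` with ``other(t + k)`` per lag k.

    Lags run over ``-max_lag .. +max_lag`` (frames); only the overlapping
    segment enters each correlation, and lags whose overlap is shorter than
    ``min_overlap`` are returned as nan (missing), never as zero.
    """
    a = np.asarray(anchor, dtype=np.float64)
    b = np.asarray(other, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("anchor and other must be equal-length 1D series")
    n = a.size
    out = np.full(2 * max_lag + 1, np.nan)
    for i, k in enumerate(range(-max_lag, max_lag + 1)):
        if k >= 0:
            seg_a, seg_b = a[: n - k], b[k:]
        else:
            seg_a, seg_b = a[-k:], b[: n + k]
        if seg_a.size < min_overlap:
            continue
        sa = seg_a.std()
        sb = seg_b.std()
        if sa == 0 or sb == 0:
            continue
        out[i] = float(
            ((seg_a - seg_a.mean()) * (seg_b - seg_b.mean())).mean() / (sa * sb)
        )
    if np.all(np.isnan(out)):
        raise ValueError("no valid lag had sufficient overlap")
    return out


def aggregate_with_bootstrap(
    curves: np.ndarray,
    n_bootstrap: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean curve and percentile-bootstrap CI band over tracks.

    ``curves`` is (n_tracks, n_lags), nan marking missing lags; the mean
    omits missing entries.  Bootstrap resamples *tracks* with replacement
    and takes per-lag ``alpha/2`` and ``1 - alpha/2`` percentiles.
    """
    curves = np.asarray(curves, dtype=np.float64)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise ValueError("need >= 2 track curves")
    if n_bootstrap < 100:
        warnings.warn(f"n_bootstrap={n_bootstrap} < 100: CI will be unstable")
    rng = np.random.default_rng(seed)
    n_tracks = curves.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_curve = np.nanmean(curves, axis=0)
        idx = rng.integers(0, n_tracks, size=(n_bootstrap, n_tracks))
        boot_means = np.nanmean(curves[idx], axis=1)  # (n_bootstrap, n_lags)
        ci_low = np.nanpercentile(boot_means, 100 * alpha / 2, axis=0)
        ci_high = np.nanpercentile(boot_means, 100 * (1 - alpha / 2), axis=0)
    return mean_curve, ci_low, ci_high


def extract_extrema(
    mean_curve: np.ndarray, lags_s: np.ndarray
) -> Tuple[float, float]:
    """Lags (seconds) of the global maximum and minimum of a mean curve.

    Ties are broken toward the smallest ``|lag|``, then toward the negative
    lag.
    """
    curve = np.asarray(mean_curve, dtype=np.float64)
    lags_s = np.asarray(lags_s, dtype=np.float64)
    finite = np.isfinite(curve)
    if not finite.any():
        raise ValueError("all-missing mean curve")

    def best(extremum: np.ndarray) -> float:
        cand = np.where(finite & np.isclose(curve, extremum, rtol=0, atol=1e-12))[0]
        order = sorted(cand, key=lambda i: (abs(lags_s[i]), lags_s[i]))
        return float(lags_s[order[0]])

    return best(np.nanmax(curve)), best(np.nanmin(curve))


@dataclass
class CrossCorrelation:
    """Aggregated lagged correlation of one signal against the anchor."""

    anchor_name: str
    signal_name: str
    lags_s: np.ndarray
    per_track_curves: np.ndarray
    mean_curve: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_tracks: int
    n_bootstrap: int
    seed: int

    def extrema(self) -> Tuple[float, float]:
        return extract_extrema(self.mean_curve, self.lags_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "signal": self.signal_name,
                "lag_s": self.lags_s,
                "mean": self.mean_curve,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_tracks": self.n_tracks,
            }
        )


def _detrend(x: np.ndarray) -> np.ndarray:
    t = np.arange(x.size, dtype=np.float64)
    slope, intercept = np.polyfit(t, x, 1)
    return x - (slope * t + intercept)


def cross_correlate_tracks(
    tracks_df: pd.DataFrame,
    signals: Sequence[str] = ("ser5p_mean", "ser2p_mean", "solidity"),
    anchor: str = "elongation",
    frame_interval: float = 1.0,
    max_lag_s: float = 30.0,
    min_track_length: int = 10,
    n_bootstrap: int = 1000,
    detrend: bool = False,
    seed: int = 0,
) -> Dict[str, CrossCorrelation]:
    """Anchored cross-correlation analysis over a tracks table.

    ``tracks_df`` follows the cluster-analysis CSV schema (``track_id``,
    ``frame``, per-signal columns).  Tracks shorter than
    ``min_track_length`` frames, or with a constant anchor/signal, are
    excluded with a logged reason.
    """
    max_lag = int(round(max_lag_s / frame_interval))
    results: Dict[str, CrossCorrelation] = {}
    track_series: List[Dict[str, np.ndarray]] = []
    for tid, grp in tracks_df.groupby("track_id"):
        grp = grp.sort_values("frame")
        if len(grp) < max(min_track_length, 3):
            logger.info("track %s excluded: length %d too short", tid, len(grp))
            continue
        series: Dict[str, np.ndarray] = {}
        try:
            for name in {anchor, *signals}:
                x = grp[name].to_numpy(dtype=np.float64)
                if not np.all(np.isfinite(x)):
                    raise ValueError(f"non-finite values in {name}")
                if detrend:
                    x = _detrend(x)
                series[name] = normalize_track(x)
        except ValueError as exc:
            logger.info("track %s excluded: %s", tid, exc)
            continue
        track_series.append(series)
    if len(track_series) < 2:
        raise ValueError("fewer than 2 usable tracks for cross-correlation")

    lags_s = np.arange(-max_lag, max_lag + 1) * frame_interval
    for name in signals:
        curves = []
        for series in track_series:
            try:
                curves.append(
                    lagged_correlation(series[anchor], series[name], max_lag)
                )
            except ValueError as exc:
                logger.info("track excluded for %s: %s", name, exc)
        curves_arr = np.array(curves)
        mean_curve, lo, hi = aggregate_with_bootstrap(
            curves_arr, n_bootstrap=n_bootstrap, seed=seed
        )
        results[name] = CrossCorrelation(
            anchor_name=anchor,
            signal_name=name,
            lags_s=lags_s,
            per_track_curves=curves_arr,
            mean_curve=mean_curve,
            ci_low=lo,
            ci_high=hi,
            n_tracks=curves_arr.shape[0],
            n_bootstrap=n_bootstrap,
            seed=seed,
        )
    return results


def results_to_frame(results: Dict[str, CrossCorrelation]) -> pd.DataFrame:
    """Tidy CSV-ready table: signal, lag_s, mean, ci_low, ci_high, n_tracks."""
    return pd.concat([r.to_frame() for r in results.values()], ignore_index=True)
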
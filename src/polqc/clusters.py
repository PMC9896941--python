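"""3D cluster segmentation, shape quantification, and proximity tracking.

Clusters are segmented from the Ser5P channel (Gaussian smoothing, robust
global threshold, 26-connected components, size filter).  From the
Ser5P-derived masks both channels contribute mean intensities; shape is
quantified in 3D physical units by *elongation* (principal-axis ratio of
the voxel covariance tensor) and *solidity* (volume over convex-hull
volume).  Tracking links clusters across consecutive frames by
mutual-nearest centroids within a linking radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters as skfilters
from skimage import measure as skmeasure
from skimage import morphology as skmorph

logger = logging.getLogger(__name__)


@dataclass
class ClusterObservation:
    frame_index: int
    label: int
    centroid_nm: Tuple[float, float, float]  # (z, y, x), intensity-weighted
    volume_voxels: int
    volume_um3: float
    ser5p_mean: float
    ser2p_mean: float
    elongation: float
    solidity: float
    degenerate_axes: bool = False


@dataclass
class ClusterTrack:
    track_id: int
    observations: List[ClusterObservation]
    gap_count: int = 0

    def __len__(self) -> int:
        return len(self.observations)

    def series(self, attr: str) -> np.ndarray:
        return np.array([getattr(o, attr) for o in self.observations], dtype=float)

    @property
    def frames(self) -> np.ndarray:
        return np.array([o.frame_index for o in self.observations], dtype=int)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_clusters(
    ser5p_stack: np.ndarray,
    smoothing_sigma: float = 1.0,
    threshold_method: str = "otsu",
    min_volume: int = 5,
    threshold_value: Optional[float] = None,
) -> np.ndarray:
    """Label raster of Ser5P-enriched clusters in a 3D stack.

    Gaussian smoothing (sigma in voxels) -> global threshold (Otsu by
    default, or an explicit ``threshold_value``) -> 26-connected components
    -> removal of components below ``min_volume`` voxels.  An empty result
    (zero clusters) is legitimate.
    """
    stack = np.asarray(ser5p_stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("segment_clusters expects a 3D single-channel stack")
    if not np.all(np.isfinite(stack)):
        raise ValueError("non-finite voxels in input stack")
    smoothed = (
        ndimage.gaussian_filter(stack, smoothing_sigma)
        if smoothing_sigma > 0
        else stack
    )
    if threshold_value is not None:
        thr = float(threshold_value)
    elif smoothed.max() == smoothed.min():
        return np.zeros(stack.shape, dtype=np.int32)
    elif threshold_method == "otsu":
        thr = float(skfilters.threshold_otsu(smoothed))
    elif threshold_method == "li":
        thr = float(skfilters.threshold_li(smoothed))
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    mask = smoothed > thr
    labels = skmeasure.label(mask, connectivity=3).astype(np.int32)
    if min_volume > 1 and labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        keep = np.flatnonzero(sizes >= min_volume)
        keep = keep[keep != 0]
        remap = np.zeros(sizes.size, dtype=np.int32)
        remap[keep] = np.arange(1, keep.size + 1)
        labels = remap[labels]
    return labels


# ---------------------------------------------------------------------------
# Shape quantifiers
# ---------------------------------------------------------------------------

def elongation(
    region_coords: np.ndarray,
    voxel_size: Tuple[float, float, float],
) -> Tuple[float, bool]:
    """Principal-axis ratio sqrt(lambda_max / lambda_min) of a voxel region.

    ``region_coords`` is an (N, 3) array of (z, y, x) voxel indices; the
    covariance tensor is computed over voxel-center coordinates in physical
    units, making the measure rotation-invariant and anisotropy-aware.
    Degenerate regions (coplanar or collinear voxel sets) are evaluated on
    the non-degenerate eigen-subspace and flagged.

    Returns ``(value, degenerate_flag)``; value >= 1.
    """
    coords = np.asarray(region_coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("region_coords must be (N, 3)")
    if coords.shape[0] < 4:
        raise ValueError("elongation needs >= 4 voxels")
    phys = coords * np.asarray(voxel_size, dtype=np.float64)
    cov = np.cov(phys, rowvar=False, ddof=0)
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    # eigenvalues below a sliver of the leading one signal a degenerate axis
    tol = max(eigvals[0] * 1e-9, 1e-12)
    nondeg = eigvals[eigvals > tol]
    degenerate = len(nondeg) < 3
    if len(nondeg) < 2:
        logger.warning("collinear region: elongation on 1D subspace undefined, returning 1")
        return 1.0, True
    if degenerate:
        logger.warning("degenerate (coplanar) region: elongation from 2D subspace")
    return float(np.sqrt(nondeg[0] / nondeg[-1])), degenerate


def solidity(region_mask: np.ndarray) -> float:
    """Region volume over its 3D convex-hull volume, both in voxels.

    The hull volume is counted as the voxels whose centers lie inside the
    convex hull of the region's voxel set, so a filled convex body scores
    exactly 1.  Degenerate voxel sets (coplanar/collinear, no 3D hull)
    raise with a message naming the degeneracy.
    """
    mask = np.asarray(region_mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("solidity expects a 3D mask")
    n = int(mask.sum())
    if n < 4:
        raise ValueError("solidity needs >= 4 voxels")
    coords = np.argwhere(mask)
    spans = coords.max(axis=0) - coords.min(axis=0)
    if np.any(spans == 0):
        raise ValueError(
            "degenerate convex hull: region voxels are coplanar "
            f"(extent {tuple(int(s) + 1 for s in spans)} voxels)"
        )
    # work on the tight bounding box
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    sub = mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    # hull of voxel centers; voxels whose centers fall inside are counted,
    # so a filled digital convex body scores exactly 1
    hull = skmorph.convex_hull_image(sub, offset_coordinates=False)
    hull_n = int(hull.sum())
    if hull_n == 0:
        raise ValueError("degenerate convex hull: empty hull image")
    return n / hull_n


# ---------------------------------------------------------------------------
# Measurement
# ---------------------------------------------------------------------------

def measure_clusters(
    labels: np.ndarray,
    ser5p: np.ndarray,
    ser2p: np.ndarray,
    voxel_size: Tuple[float, float, float],
    frame_index: int = 0,
) -> List[ClusterObservation]:
    """Per-cluster intensities, weighted centroid, and 3D shape.

    The Ser2P channel contributes its mean intensity within the
    Ser5P-derived mask only; shape is quantified from the mask alone.
    Centroids are Ser5P-intensity-weighted, in nm, voxel-center based.
    Labels smaller than 4 voxels are skipped with a warning (no shape).
    """
    labels = np.asarray(labels)
    if labels.shape != np.asarray(ser5p).shape or labels.shape != np.asarray(ser2p).shape:
        raise ValueError("labels and channel stacks must share shape")
    vsize = np.asarray(voxel_size, dtype=np.float64)
    voxel_um3 = float(np.prod(vsize)) / 1e9  # nm^3 -> um^3
    out: List[ClusterObservation] = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        n = int(mask.sum())
        if n < 4:
            logger.warning("label %d has %d voxels (<4): skipped", lab, n)
            continue
        coords = np.argwhere(mask)
        w5 = np.asarray(ser5p, dtype=np.float64)[mask]
        w2 = np.asarray(ser2p, dtype=np.float64)[mask]
        weights = w5.clip(min=0)
        if weights.sum() <= 0:
            weights = np.ones_like(w5)
        centroid_vox = (coords * weights[:, None]).sum(axis=0) / weights.sum()
        centroid_nm = tuple((centroid_vox + 0.5) * vsize)
        elong, degenerate = elongation(coords, tuple(vsize))
        try:
            sol = solidity(mask)
        except ValueError as exc:
            logger.warning("label %d solidity failed: %s", lab, exc)
            sol = float("nan")
        out.append(
            ClusterObservation(
                frame_index=frame_index,
                label=int(lab),
                centroid_nm=centroid_nm,  # type: ignore[arg-type]
                volume_voxels=n,
                volume_um3=n * voxel_um3,
                ser5p_mean=float(w5.mean()),
                ser2p_mean=float(w2.mean()),
                elongation=elong,
                solidity=sol,
                degenerate_axes=degenerate,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tracking
# ---------------------------------------------------------------------------

def track_clusters(
    observations_per_frame: Sequence[Sequence[ClusterObservation]],
    linking_radius_nm: float,
    max_gap: int = 0,
) -> List[ClusterTrack]:
    """Greedy mutual-nearest-neighbor tracking across consecutive frames.

    Two observations in consecutive (or gap-bridged, up to ``max_gap``
    missing frames) frames are linked when each is the other's nearest
    centroid and their distance is at most ``linking_radius_nm``.
    Unmatched observations open new tracks.
    """
    if linking_radius_nm <= 0:
        raise ValueError("linking_radius_nm must be > 0")
    tracks: List[ClusterTrack] = []
    # open tracks: (track, frame index of last observation)
    open_tracks: List[ClusterTrack] = []

    for fi, obs in enumerate(observations_per_frame):
        obs = list(obs)
        labs = [o.label for o in obs]
        if len(set(labs)) != len(labs):
            raise ValueError(f"duplicate labels within frame {fi}: {labs}")
        # candidates: open tracks whose last frame is within the gap window
        candidates = [t for t in open_tracks if fi - t.observations[-1].frame_index <= max_gap + 1]
        matched_obs: Dict[int, ClusterTrack] = {}
        if candidates and obs:
            prev_pos = np.array([t.observations[-1].centroid_nm for t in candidates])
            cur_pos = np.array([o.centroid_nm for o in obs])
            d = np.linalg.norm(prev_pos[:, None, :] - cur_pos[None, :, :], axis=2)
            nearest_cur = d.argmin(axis=1)  # per track
            nearest_prev = d.argmin(axis=0)  # per observation
            for ti, ci in enumerate(nearest_cur):
                if nearest_prev[ci] == ti and d[ti, ci] <= linking_radius_nm:
                    matched_obs[ci] = candidates[ti]
        next_open: List[ClusterTrack] = []
        for ci, o in enumerate(obs):
            if ci in matched_obs:
                track = matched_obs[ci]
                gap = fi - track.observations[-1].frame_index - 1
                track.gap_count += max(gap, 0)
                track.observations.append(o)
                next_open.append(track)
            else:
                track = ClusterTrack(track_id=len(tracks), observations=[o])
                tracks.append(track)
                next_open.append(track)
        # keep unmatched-but-still-bridgeable tracks open
        for t in open_tracks:
            if t not in next_open and fi - t.observations[-1].frame_index <= max_gap:
                next_open.append(t)
        open_tracks = next_open
    return tracks


# ---------------------------------------------------------------------------
# Tabular interchange
# ---------------------------------------------------------------------------

TRACK_COLUMNS = [
    "track_id",
    "frame",
    "t_seconds",
    "label",
    "z_nm",
    "y_nm",
    "x_nm",
    "volume_voxels",
    "volume_um3",
    "ser5p_mean",
    "ser2p_mean",
    "elongation",
    "solidity",
]


def tracks_to_dataframe(
    tracks: Sequence[ClusterTrack], frame_interval: float = 1.0
) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for o in t.observations:
            rows.append(
                {
                    "track_id": t.track_id,
                    "frame": o.frame_index,
                    "t_seconds": o.frame_index * frame_interval,
                    "label": o.label,
                    "z_nm": o.centroid_nm[0],
                    "y_nm": o.centroid_nm[1],
                    "x_nm": o.centroid_nm[2],
                    "volume_voxels": o.volume_voxels,
                    "volume_um3": o.volume_um3,
                    "ser5p_mean": o.ser5p_mean,
                    "ser2p_mean": o.ser2p_mean,
                    "elongation": o.elongation,
                    "solidity": o.solidity,
                }
            )
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def analyze_timelapse(
    movie: np.ndarray,
    voxel_size: Tuple[float, float, float],
    linking_radius_nm: float,
    frame_interval: float = 1.0,
    smoothing_sigma: float = 1.0,
    min_volume: int = 5,
    max_gap: int = 0,
    threshold_method: str = "otsu",
) -> pd.DataFrame:
    """Segment, measure, and track a (T, C, Z, Y, X) two-channel movie."""
    movie = np.asarray(movie)
    if movie.ndim != 5 or movie.shape[1] < 2:
        raise ValueError("expected movie with axes (T, C>=2, Z, Y, X)")
    per_frame: List[List[ClusterObservation]] = []
    for ti in range(movie.shape[0]):
        labels = segment_clusters(
            movie[ti, 0],
            smoothing_sigma=smoothing_sigma,
            min_volume=min_volume,
            threshold_method=threshold_method,
        )
        per_frame.append(
            measure_clusters(labels, movie[ti, 0], movie[ti, 1], voxel_size, frame_index=ti)
        )
    tracks = track_clusters(per_frame, linking_radius_nm, max_gap=max_gap)
    return tracks_to_dataframe(tracks, frame_interval=frame_interval)
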
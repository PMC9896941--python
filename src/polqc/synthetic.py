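"""Synthetic microscopy data with known ground truth.

Everything the pipeline consumes can be generated here: two-channel 3D
time-lapses of ellipsoidal clusters whose intensities and shape follow a
stereotyped cycle with configurable lags, a Poisson–Gaussian camera model
scaled by exposure time, phase-A/B acquisition sets, band-limited image
pairs for resolution tests, and interaction-pair tables lying on a noisy
closed cycle in feature space.

All randomness flows from one explicit seed per call; identical parameters
and seed reproduce outputs bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .acquisition import AcquisitionSet, PlaneImages

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# Parameter types
# ---------------------------------------------------------------------------

@dataclass
class SceneParams:
    """Geometry and dynamics of a rendered cluster scene.

    Each cluster is an ellipsoid whose semi-axes, intensities, and waist
    pinch vary sinusoidally over a cycle of ``cycle_period`` seconds:

    * channel-0 (Ser5P) intensity peaks at phase zero of each cluster,
    * channel-1 (Ser2P) intensity follows ``lag_ser2p`` seconds later,
    * the shape excursion (elongation up, solidity down via the waist
      pinch) follows ``lag_shape`` seconds after that same reference.

    ``voxel_size`` is (z, y, x) in nm; the default is anisotropic 2:1
    (z coarser), as typical for confocal stacks.
    """

    volume_shape: Tuple[int, int, int] = (16, 96, 96)
    voxel_size: Tuple[float, float, float] = (200.0, 100.0, 100.0)
    n_clusters: int = 3
    cluster_axes: Tuple[float, float, float] = (800.0, 550.0, 550.0)
    shape_amplitude: float = 0.25
    pinch_amplitude: float = 0.35
    intensity_amplitude: float = 0.4
    cycle_period: float = 30.0
    lag_ser2p: float = 5.0
    lag_shape: float = 10.0
    frame_interval: float = 2.0
    n_frames: int = 60
    background: float = 10.0
    peak_signal: float = 100.0
    psf_sigma_nm: float = 0.0
    random_orientation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.volume_shape):
            raise ValueError("volume_shape entries must be > 0")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be > 0")
        if any(a <= 0 for a in self.cluster_axes):
            raise ValueError("cluster_axes must be > 0")
        if not (0 <= self.lag_ser2p < self.lag_shape < self.cycle_period):
            raise ValueError("require lag_ser2p < lag_shape < cycle_period")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval <= 0 or self.cycle_period <= 0:
            raise ValueError("time parameters must be > 0")
        if not (0 <= self.intensity_amplitude < 1):
            raise ValueError("intensity_amplitude must be in [0, 1)")
        if not (0 <= self.pinch_amplitude < 0.8):
            raise ValueError("pinch_amplitude must be in [0, 0.8)")
        if self.background < 0 or self.peak_signal <= 0:
            raise ValueError("background >= 0 and peak_signal > 0 required")


@dataclass
class NoiseParams:
    """Poisson–Gaussian camera model scaled by exposure time.

    Output counts = ``gain * Poisson(clean * t_exp / t_ref) + offset +
    Normal(0, read_noise_sd)``, pixelwise independent (the assumption the
    self-supervised denoising class requires).
    """

    exposure_time: float = 50.0
    reference_exposure: float = 200.0
    read_noise_sd: float = 2.0
    gain: float = 1.0
    offset: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exposure_time > self.reference_exposure:
            raise ValueError("exposure_time must be <= reference_exposure")
        for name in ("exposure_time", "reference_exposure", "read_noise_sd", "gain", "offset"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.reference_exposure == 0:
            raise ValueError("reference_exposure must be > 0")


@dataclass
class GroundTruth:
    """Exact per-cluster state for every rendered frame.

    ``labels`` is a (T, Z, Y, X) integer raster (0 = background, cluster k
    carries label k); ``table`` has one row per cluster per frame with the
    true centroid, phase, intensities, elongation, and pinch.
    """

    labels: np.ndarray
    table: pd.DataFrame
    phases: np.ndarray

    def cluster_frame(self, frame: int, label: int) -> pd.Series:
        sel = self.table[(self.table.frame == frame) & (self.table.label == label)]
        if sel.empty:
            raise KeyError(f"no ground truth for frame={frame} label={label}")
        return sel.iloc[0]


@dataclass
class PairCycleParams:
    """Noisy closed cycle of interaction-pair features.

    Each feature j of pair i is ``mean_j + amplitude_j * cos(theta_i +
    offset_j) + Normal(0, noise_sd_j)`` with ``theta_i`` uniform on
    [0, 2pi).  At least two features need distinct phase offsets, otherwise
    the cycle collapses to a line in PC space.
    """

    n_pairs: int = 200
    feature_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: {
            "ser5p_mean": 1.0,
            "ser2p_mean": 1.0,
            "elongation": 1.0,
            "solidity": 1.0,
            "distance_nm": 1.0,
            "gene_intensity": 1.0,
        }
    )
    feature_phase_offsets: Mapping[str, float] = field(
        default_factory=lambda: {
            "ser5p_mean": 0.0,
            "ser2p_mean": np.pi / 3,
            "elongation": 2 * np.pi / 3,
            "solidity": np.pi + 2 * np.pi / 3,
            "distance_nm": np.pi,
            "gene_intensity": np.pi / 6,
        }
    )
    feature_means: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float | Mapping[str, float] = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 8:
            raise ValueError("n_pairs must be >= 8")
        names = list(self.feature_amplitudes)
        if len(names) < 2:
            raise ValueError("need at least 2 features")
        if set(names) != set(self.feature_phase_offsets):
            raise ValueError("feature_amplitudes and feature_phase_offsets must share keys")
        offsets = [self.feature_phase_offsets[n] % TWO_PI for n in names]
        if np.allclose(offsets, offsets[0]):
            logger.warning(
                "all feature phase offsets equal: cycle is degenerate "
                "(PCA plane collapses to a line)"
            )

    def sd_for(self, feature: str) -> float:
        if isinstance(self.noise_sd, Mapping):
            return float(self.noise_sd.get(feature, 0.0))
        return float(self.noise_sd)


# ---------------------------------------------------------------------------
# Band-limited image pairs (FRC fixture)
# ---------------------------------------------------------------------------

def make_band_limited_pair(
    shape: Tuple[int, int],
    cutoff: float,
    pixel_size: float,
    snr: float,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Two independent-noise realizations of one band-limited image.

    The shared signal is a Gaussian random field whose spectrum is hard-cut
    at ``cutoff`` (1/nm), standardized to unit variance and offset to be
    positive.  White Gaussian noise of variance ``1/snr`` is added
    independently to each copy.  ``snr = inf`` gives identical noise-free
    images; ``snr = 0`` gives pure noise (zero signal amplitude).
    """
    nyquist = 1.0 / (2.0 * pixel_size)
    if not (0 < cutoff <= nyquist + 1e-12):
        raise ValueError(f"cutoff {cutoff} above Nyquist {nyquist}")
    if snr < 0:
        raise ValueError("snr must be >= 0")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    white = rng.standard_normal(shape)
    fy = np.fft.fftfreq(ny, d=pixel_size)
    fx = np.fft.fftfreq(nx, d=pixel_size)
    radius = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    spectrum = np.fft.fft2(white)
    spectrum[radius > cutoff] = 0.0
    signal = np.fft.ifft2(spectrum).real
    sd = signal.std()
    if sd > 0:
        signal = signal / sd
    if snr == 0:
        signal = np.zeros_like(signal)
        noise_sd = 1.0
    elif np.isinf(snr):
        noise_sd = 0.0
    else:
        noise_sd = np.sqrt(1.0 / snr)
    base = signal + 10.0  # positive offset, photon-like
    img1 = base + noise_sd * rng.standard_normal(shape)
    img2 = base + noise_sd * rng.standard_normal(shape)
    return img1, img2


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation via QR of a Gaussian matrix."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _place_centers(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Random cluster centers (nm, z/y/x) with non-overlap guarantees."""
    extent = np.array(params.volume_shape) * np.array(params.voxel_size)
    max_semi = max(params.cluster_axes) * (1.0 + params.shape_amplitude)
    margin = max_semi * 1.1
    min_gap = 2.0 * max_semi * 1.2
    lo, hi = margin, extent - margin
    if np.any(hi <= lo):
        raise ValueError(
            "volume too small to place clusters with the required margin "
            f"(extent {extent} nm, margin {margin:.0f} nm per side)"
        )
    centers: List[np.ndarray] = []
    for _ in range(5000):
        cand = rng.uniform(lo, hi)
        if all(np.linalg.norm(cand - c) > min_gap for c in centers):
            centers.append(cand)
            if len(centers) == params.n_clusters:
                return np.array(centers)
    raise RuntimeError(
        f"could not place {params.n_clusters} clusters with pairwise gap "
        f"> {min_gap:.0f} nm inside {extent} nm after bounded retries"
    )


def _cluster_mask(
    shape: Tuple[int, int, int],
    voxel_size: Tuple[float, float, float],
    center_nm: np.ndarray,
    axes_nm: np.ndarray,
    rotation: np.ndarray,
    pinch: float,
) -> Tuple[np.ndarray, Tuple[slice, slice, slice]]:
    """Voxelized pinched ellipsoid; returns (mask, bounding slices).

    A voxel center p is inside when, in the cluster frame u = R^T (p - c)
    scaled by the semi-axes, ``u1^2 + (u2^2 + u3^2) / w(u1)^2 <= 1`` with
    waist ``w(u1) = 1 - pinch * (1 - u1^2)^3``.  The cubic localizes the
    pinch at the equator sharply enough to beat the ellipsoid's own taper,
    so the cross-section profile becomes non-monotone (a peanut): solidity
    genuinely drops as pinch grows, while overall elongation stays set by
    the axes ratio.  The clip keeps the two lobes connected.
    """
    vz, vy, vx = voxel_size
    pad = float(np.max(axes_nm)) * 1.05
    zlo = max(int((center_nm[0] - pad) / vz), 0)
    zhi = min(int((center_nm[0] + pad) / vz) + 2, shape[0])
    ylo = max(int((center_nm[1] - pad) / vy), 0)
    yhi = min(int((center_nm[1] + pad) / vy) + 2, shape[1])
    xlo = max(int((center_nm[2] - pad) / vx), 0)
    xhi = min(int((center_nm[2] + pad) / vx) + 2, shape[2])
    zz = (np.arange(zlo, zhi) + 0.5) * vz - center_nm[0]
    yy = (np.arange(ylo, yhi) + 0.5) * vy - center_nm[1]
    xx = (np.arange(xlo, xhi) + 0.5) * vx - center_nm[2]
    gz, gy, gx = np.meshgrid(zz, yy, xx, indexing="ij")
    pts = np.stack([gz, gy, gx], axis=-1) @ rotation  # into cluster frame
    u = pts / axes_nm  # semi-axis ordering (major, minor, minor)
    u1 = u[..., 0]
    rho2 = u[..., 1] ** 2 + u[..., 2] ** 2
    waist = np.clip(1.0 - pinch * (1.0 - np.clip(u1, -1, 1) ** 2) ** 3, 0.2, None)
    inside = u1**2 + rho2 / waist**2 <= 1.0
    return inside, (slice(zlo, zhi), slice(ylo, yhi), slice(xlo, xhi))


def _cycle_signals(params: SceneParams, phase: float, t: float) -> Dict[str, float]:
    """True cycle state of one cluster at time ``t`` (seconds)."""
    w = TWO_PI / params.cycle_period
    a = params.intensity_amplitude
    ser5p = 1.0 + a * np.cos(w * t + phase)
    ser2p = 1.0 + a * np.cos(w * (t - params.lag_ser2p) + phase)
    stretch = float(np.cos(w * (t - params.lag_shape) + phase))
    return {"ser5p": float(ser5p), "ser2p": float(ser2p), "stretch": stretch}


def render_scene(params: SceneParams) -> Tuple[np.ndarray, GroundTruth]:
    """Render a clean two-channel time-lapse with exact ground truth.

    Returns ``(movie, truth)`` where ``movie`` has axes (T, C, Z, Y, X) in
    photon units (channel 0: Ser5P, channel 1: Ser2P) and ``truth`` carries
    the per-frame label raster plus a per-cluster-per-frame table of the
    exact configured values.  The Ser2P series of every cluster equals its
    Ser5P series delayed by ``lag_ser2p`` by construction.
    """
    rng = np.random.default_rng(params.seed)
    centers = _place_centers(params, rng)
    phases = rng.uniform(0, TWO_PI, size=params.n_clusters)
    rotations = [
        _random_rotation(rng) if params.random_orientation else np.eye(3)
        for _ in range(params.n_clusters)
    ]

    T = params.n_frames
    shape = tuple(params.volume_shape)
    movie = np.zeros((T, 2) + shape, dtype=np.float64)
    labels = np.zeros((T,) + shape, dtype=np.uint16)
    base_axes = np.asarray(params.cluster_axes, dtype=np.float64)
    rows = []
    for ti in range(T):
        t = ti * params.frame_interval
        movie[ti] += params.background
        for k in range(params.n_clusters):
            sig = _cycle_signals(params, phases[k], t)
            m = 1.0 + params.shape_amplitude * sig["stretch"]
            # volume-preserving stretch: major axis * m^(2/3), minors * m^(-1/3)
            axes = base_axes * np.array([m ** (2.0 / 3.0), m ** (-1.0 / 3.0), m ** (-1.0 / 3.0)])
            pinch = params.pinch_amplitude * (1.0 + sig["stretch"]) / 2.0
            mask, sl = _cluster_mask(
                shape, params.voxel_size, centers[k], axes, rotations[k], pinch
            )
            movie[ti, 0][sl][mask] += params.peak_signal * sig["ser5p"]
            movie[ti, 1][sl][mask] += params.peak_signal * sig["ser2p"]
            labels[ti][sl][mask] = k + 1
            rows.append(
                {
                    "frame": ti,
                    "t_s": t,
                    "label": k + 1,
                    "phase": phases[k],
                    "centroid_z_nm": centers[k][0],
                    "centroid_y_nm": centers[k][1],
                    "centroid_x_nm": centers[k][2],
                    "axis_major_nm": axes[0],
                    "axis_minor_nm": axes[1],
                    "ser5p_true": params.background + params.peak_signal * sig["ser5p"],
                    "ser2p_true": params.background + params.peak_signal * sig["ser2p"],
                    "elongation_true": (base_axes[0] / base_axes[1]) * m,
                    "stretch": sig["stretch"],
                    "pinch": pinch,
                }
            )
    if params.psf_sigma_nm > 0:
        from scipy import ndimage

        sigma_vox = [params.psf_sigma_nm / v for v in params.voxel_size]
        for ti in range(T):
            for c in range(2):
                movie[ti, c] = ndimage.gaussian_filter(movie[ti, c], sigma_vox)
    truth = GroundTruth(labels=labels, table=pd.DataFrame(rows), phases=phases)
    return movie, truth


# ---------------------------------------------------------------------------
# Camera noise
# ---------------------------------------------------------------------------

def apply_noise(
    clean: np.ndarray,
    params: NoiseParams,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Corrupt a photon raster with exposure-scaled Poisson + read noise.

    ``E[out] = gain * clean * t_exp/t_ref + offset`` and
    ``Var[out] = gain^2 * clean * t_exp/t_ref + read_noise_sd^2``.
    """
    clean = np.asarray(clean, dtype=np.float64)
    if np.any(clean < 0):
        raise ValueError("clean photon raster must be non-negative")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    scale = params.exposure_time / params.reference_exposure
    out = params.gain * rng.poisson(clean * scale).astype(np.float64) + params.offset
    if params.read_noise_sd > 0:
        out += rng.normal(0.0, params.read_noise_sd, size=clean.shape)
    return out


def make_acquisition_set(
    clean_planes: Sequence[np.ndarray],
    phase_b_clean: Sequence[np.ndarray],
    noise: NoiseParams,
    position_id: str = "pos0",
    pixel_size_nm: float = 100.0,
    frame_interval: Optional[float] = None,
) -> AcquisitionSet:
    """Draw a full two-phase acquisition from clean photon images.

    Per phase-A plane: one low-quality image and two test images at
    ``exposure_time``, plus two high-quality references at
    ``reference_exposure`` — five independent noise draws.  Phase-B frames
    are drawn at ``exposure_time`` only.  Everything flows from
    ``noise.seed``, so a fixed seed regenerates byte-identical data.
    """
    if len(phase_b_clean) < 1:
        raise ValueError("phase B needs >= 1 frame")
    rng = np.random.default_rng(noise.seed)
    hq = replace(noise, exposure_time=noise.reference_exposure)
    planes = []
    for clean in clean_planes:
        planes.append(
            PlaneImages(
                low_quality=apply_noise(clean, noise, rng),
                high_quality_1=apply_noise(clean, hq, rng),
                high_quality_2=apply_noise(clean, hq, rng),
                test_1=apply_noise(clean, noise, rng),
                test_2=apply_noise(clean, noise, rng),
            )
        )
    phase_b = [apply_noise(f, noise, rng) for f in phase_b_clean]
    timestamps = (
        [i * frame_interval for i in range(len(phase_b))]
        if frame_interval is not None
        else None
    )
    return AcquisitionSet(
        position_id=position_id,
        planes=planes,
        phase_b=phase_b,
        exposure_time=noise.exposure_time,
        reference_exposure=noise.reference_exposure,
        pixel_size_nm=pixel_size_nm,
        timestamps=timestamps,
    )


# ---------------------------------------------------------------------------
# Interaction-pair tables
# ---------------------------------------------------------------------------

def make_pair_table(params: PairCycleParams) -> Tuple[pd.DataFrame, np.ndarray]:
    """Interaction-pair feature table on a noisy closed cycle.

    Returns ``(table, theta)``: one row per pair with the configured
    features, plus the true phase for recovery scoring.  The table also
    carries ``nucleus_id``/``gene_id`` columns for schema compatibility
    with the pseudo-time stage.
    """
    rng = np.random.default_rng(params.seed)
    theta = rng.uniform(0, TWO_PI, size=params.n_pairs)
    data: Dict[str, np.ndarray] = {
        "nucleus_id": np.arange(params.n_pairs),
        "gene_id": np.zeros(params.n_pairs, dtype=int),
    }
    for name, amp in params.feature_amplitudes.items():
        mean = float(params.feature_means.get(name, 0.0))
        offset = params.feature_phase_offsets[name]
        values = mean + amp * np.cos(theta + offset)
        sd = params.sd_for(name)
        if sd > 0:
            values = values + rng.normal(0.0, sd, size=params.n_pairs)
        data[name] = values
    table = pd.DataFrame(data)
    table["true_phase"] = theta
    return table, theta
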
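"""End-to-end synthetic experiments composed from the pipeline stages.

These are the reference workflows used by the acceptance checks: render a
ground-truth scene, corrupt it with the camera model, denoise, segment,
track, and correlate — then compare recovered quantities against the
configured truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import acquisition, clusters, fluctuation, synthetic


@dataclass
class LagRecoveryResult:
    ser2p_max_lag_s: float
    solidity_min_lag_s: float
    elongation_max_lag_s: float
    n_tracks: int
    scene: synthetic.SceneParams


def default_lag_scene(seed: int, n_frames: int = 60) -> synthetic.SceneParams:
    """Scene used for lag-recovery experiments: 2 s frames, 5 s / 10 s lags.

    Cluster size matters here: small clusters have a large boundary-voxel
    fraction, and the resulting shape-dependent dilution of the measured
    mean intensities biases the recovered intensity lags late by 1-2
    frames.  The ~1 µm clusters below keep that bias inside one frame.
    """
    return synthetic.SceneParams(
        volume_shape=(24, 160, 160),
        voxel_size=(150.0, 100.0, 100.0),
        n_clusters=3,
        cluster_axes=(1100.0, 750.0, 750.0),
        shape_amplitude=0.3,
        pinch_amplitude=0.6,
        intensity_amplitude=0.4,
        cycle_period=30.0,
        lag_ser2p=5.0,
        lag_shape=10.0,
        frame_interval=2.0,
        n_frames=n_frames,
        peak_signal=150.0,
        seed=seed,
    )


def lag_recovery_experiment(
    seed: int,
    scene: Optional[synthetic.SceneParams] = None,
    exposure_time: float = 50.0,
    read_noise_sd: float = 2.0,
    denoiser: Optional[acquisition.Denoiser] = None,
    anchor: str = "ser5p_mean",
    max_lag_s: float = 14.0,
    n_bootstrap: int = 200,
) -> LagRecoveryResult:
    """Full pipeline: render -> noise -> denoise -> segment -> track -> correlate.

    The cross-correlation is anchored on the Ser5P intensity (the cycle's
    phase reference), so the recovered Ser2P maximum sits at ``lag_ser2p``
    and the solidity minimum / elongation maximum at ``lag_shape``.
    ``max_lag_s`` must stay below half the cycle period to keep the global
    extremum unique.
    """
    scene = scene if scene is not None else default_lag_scene(seed)
    if denoiser is None:
        denoiser = acquisition.GaussianDenoiser(1.0)
    movie, _ = synthetic.render_scene(scene)
    noise = synthetic.NoiseParams(
        exposure_time=exposure_time,
        reference_exposure=200.0,
        read_noise_sd=read_noise_sd,
        offset=100.0,
        seed=seed + 10_000,
    )
    rng = np.random.default_rng(noise.seed)
    noisy = np.stack([synthetic.apply_noise(frame, noise, rng) for frame in movie])
    recon = np.stack(
        [
            np.stack([denoiser(noisy[t, c]) for c in range(2)])
            for t in range(noisy.shape[0])
        ]
    )
    tracks = clusters.analyze_timelapse(
        recon,
        voxel_size=scene.voxel_size,
        linking_radius_nm=1500.0,
        frame_interval=scene.frame_interval,
        min_volume=20,
    )
    results = fluctuation.cross_correlate_tracks(
        tracks,
        signals=("ser2p_mean", "solidity", "elongation"),
        anchor=anchor,
        frame_interval=scene.frame_interval,
        max_lag_s=max_lag_s,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )
    ser2p_max, _ = results["ser2p_mean"].extrema()
    _, sol_min = results["solidity"].extrema()
    elong_max, _ = results["elongation"].extrema()
    return LagRecoveryResult(
        ser2p_max_lag_s=ser2p_max,
        solidity_min_lag_s=sol_min,
        elongation_max_lag_s=elong_max,
        n_tracks=int(tracks.track_id.nunique()),
        scene=scene,
    )


def qc_separation_experiment(seed: int) -> Tuple[str, str]:
    """One low-noise and one high-noise position through the QC gate.

    Thresholds sit between the two constructed outcomes; returns the
    (low-noise decision, high-noise decision) pair.
    """
    thresholds = acquisition.QCThresholds(
        min_resolution_nm=600.0,
        min_ssim=0.6,
        max_local_error_fraction=0.3,
        local_ssim_floor=0.2,
    )
    denoiser = acquisition.GaussianDenoiser(1.0)

    def make_set(read_sd: float, peak: float, sub_seed: int):
        sig, _ = synthetic.make_band_limited_pair(
            (128, 128), 1 / 300.0, 100.0, np.inf, seed=sub_seed
        )
        clean = (sig - sig.min()) * peak
        noise = synthetic.NoiseParams(
            exposure_time=20.0,
            reference_exposure=200.0,
            read_noise_sd=read_sd,
            offset=100.0,
            seed=sub_seed,
        )
        return synthetic.make_acquisition_set(
            [clean], [clean], noise, pixel_size_nm=100.0
        )

    low = acquisition.qc_gate(make_set(1.0, 100.0, seed), denoiser, thresholds)
    high = acquisition.qc_gate(make_set(40.0, 8.0, seed + 50_000), denoiser, thresholds)
    return low.decision, high.decision


def bootstrap_coverage_experiment(
    n_replicates: int = 50,
    n_tracks: int = 30,
    track_length: int = 80,
    max_lag: int = 7,
    noise_sd: float = 1.0,
    delta_frames: int = 3,
    n_bootstrap: int = 300,
    seed: int = 0,
) -> float:
    """Pooled fraction of (replicate, lag) cells whose 95% CI covers truth.

    Tracks are noisy phase-randomized sinusoid pairs with a known lag; the
    population mean cross-correlation curve is estimated once from a large
    ensemble, then ``n_replicates`` small datasets are aggregated with the
    track bootstrap and their bands checked against the population curve.
    """

    def curves(n: int, sub_seed: int) -> np.ndarray:
        rng = np.random.default_rng(sub_seed)
        out = []
        t = np.arange(track_length)
        for _ in range(n):
            phase = rng.uniform(0, 2 * np.pi)
            a = np.cos(2 * np.pi * t / 15 + phase) + noise_sd * rng.standard_normal(
                track_length
            )
            b = np.cos(
                2 * np.pi * (t - delta_frames) / 15 + phase
            ) + noise_sd * rng.standard_normal(track_length)
            out.append(
                fluctuation.lagged_correlation(
                    fluctuation.normalize_track(a),
                    fluctuation.normalize_track(b),
                    max_lag,
                )
            )
        return np.array(out)

    population = curves(3000, seed + 999_983).mean(axis=0)
    covered = []
    for rep in range(n_replicates):
        c = curves(n_tracks, seed + rep)
        _, lo, hi = fluctuation.aggregate_with_bootstrap(
            c, n_bootstrap=n_bootstrap, seed=seed + rep
        )
        covered.append((population >= lo) & (population <= hi))
    return float(np.mean(covered))
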
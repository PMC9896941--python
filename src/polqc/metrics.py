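"""Image-quality metrics for reconstruction assessment.

Two metrics drive the quality-control workflow:

* the *structural term* of the structural similarity index (SSIM), computed
  both as a global score and as a local per-window map, used to detect
  reconstruction errors against reference images;
* Fourier ring correlation (FRC) between two independent-noise realizations
  of the same scene, from which an *effective resolution* is read off at the
  conventional 1/7 threshold.

Both operate on 2D planes; 3D stacks are evaluated plane-wise (lateral
resolution), with the median over signal-bearing planes reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal.windows import tukey

logger = logging.getLogger(__name__)

#: Conventional FRC resolution threshold.
FRC_THRESHOLD = 1.0 / 7.0


# ---------------------------------------------------------------------------
# SSIM (structural term)
# ---------------------------------------------------------------------------

@dataclass
class SsimResult:
    """Structural-term SSIM between two images.

    Attributes
    ----------
    global_value : float
        Mean of the local map; in ``[-1, 1]``.
    local_map : np.ndarray
        Per-window structural similarity, same shape as the inputs.
    window_size : int
        Side length of the (uniform, odd) local window in pixels.
    stabilizer_c3 : float
        Stabilizing constant added to numerator and denominator
        (units of intensity squared).
    """

    global_value: float
    local_map: np.ndarray
    window_size: int
    stabilizer_c3: float


def default_c3(x: np.ndarray, y: np.ndarray) -> float:
    """Conventional SSIM stabilizer ``(0.03 L)^2 / 2`` for dynamic range L."""
    lo = min(float(np.min(x)), float(np.min(y)))
    hi = max(float(np.max(x)), float(np.max(y)))
    L = hi - lo
    if L <= 0:
        L = 1.0
    return max((0.03 * L) ** 2 / 2.0, np.finfo(np.float64).tiny)


def ssim_structural(
    x: np.ndarray,
    y: np.ndarray,
    window: int = 7,
    c3: Optional[float] = None,
) -> SsimResult:
    """Structural-term SSIM ``(cov_xy + C3) / (sigma_x sigma_y + C3)``.

    Luminance and contrast terms are deliberately omitted: the score is
    invariant to mean shifts and (for ``c3 -> 0``) to intensity rescaling,
    and responds to *structural* disagreement only.  Statistics are computed
    over a sliding uniform window; the map has the same shape as the inputs
    (reflect padding at the borders).

    Parameters
    ----------
    x, y : np.ndarray
        Images of identical shape.
    window : int
        Odd window side length, >= 3.
    c3 : float, optional
        Stabilizer; defaults to :func:`default_c3` of the joint dynamic range.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if c3 is None:
        c3 = default_c3(x, y)
    if c3 < 0:
        raise ValueError("c3 must be >= 0")

    # global centering: covariances are shift-invariant, and working near
    # zero avoids catastrophic cancellation in the moment differences
    x = x - x.mean()
    y = y - y.mean()

    def win_mean(a: np.ndarray) -> np.ndarray:
        return ndimage.uniform_filter(a, size=window, mode="reflect")

    mu_x = win_mean(x)
    mu_y = win_mean(y)
    # population (ddof=0) moments within each window
    var_x = np.clip(win_mean(x * x) - mu_x * mu_x, 0.0, None)
    var_y = np.clip(win_mean(y * y) - mu_y * mu_y, 0.0, None)
    cov = win_mean(x * y) - mu_x * mu_y

    denom = np.sqrt(var_x * var_y) + c3
    with np.errstate(invalid="ignore", divide="ignore"):
        local = (cov + c3) / denom
    # constant-vs-constant windows: cov = 0, sigmas = 0 -> c3/c3 = 1 when
    # c3 > 0; with c3 == 0 the ratio is undefined and reported as nan.
    local = np.where(denom > 0, local, np.nan)
    # guard round-off excursions beyond the Cauchy-Schwarz bound
    local = np.clip(local, -1.0, 1.0)

    return SsimResult(
        global_value=float(np.nanmean(local)),
        local_map=local,
        window_size=window,
        stabilizer_c3=float(c3),
    )


def local_error_fraction(result: SsimResult, floor: float) -> float:
    """Share of the local-SSIM map that falls below ``floor``.

    Used as a reconstruction-error flag: isolated denoising artifacts show
    up as localized dips in the map even when the global score stays high.
    """
    finite = result.local_map[np.isfinite(result.local_map)]
    if finite.size == 0:
        return 1.0
    return float(np.mean(finite < floor))


# ---------------------------------------------------------------------------
# Fourier ring correlation
# ---------------------------------------------------------------------------

@dataclass
class FRCCurve:
    """Ring-binned frequency-space correlation between two images.

    ``ring_frequencies`` are bin-center spatial frequencies in 1/nm,
    strictly increasing up to Nyquist.  Ring 0 is the DC bin and equals 1
    for images with nonzero mean.
    """

    ring_frequencies: np.ndarray
    correlations: np.ndarray
    pixel_size: float
    threshold: float = FRC_THRESHOLD
    n_points_per_ring: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def ring_width(self) -> float:
        """Frequency spacing between rings, 1/nm."""
        return float(self.ring_frequencies[1] - self.ring_frequencies[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_per_nm": self.ring_frequencies,
                "frc": self.correlations,
                "n_points": self.n_points_per_ring,
            }
        )


def _center_crop_square(img: np.ndarray) -> np.ndarray:
    n = min(img.shape)
    r0 = (img.shape[0] - n) // 2
    c0 = (img.shape[1] - n) // 2
    return img[r0 : r0 + n, c0 : c0 + n]


def _taper(n: int, window_fn: str) -> np.ndarray:
    if window_fn == "none":
        return np.ones((n, n))
    if window_fn == "tukey":
        w = tukey(n, alpha=0.25)
        return np.outer(w, w)
    raise ValueError(f"unknown window_fn {window_fn!r}; use 'tukey' or 'none'")


def frc_curve(
    img1: np.ndarray,
    img2: np.ndarray,
    pixel_size: float,
    bin_width: int = 1,
    window_fn: str = "tukey",
) -> FRCCurve:
    """Fourier ring correlation between two same-scene images.

    For every ring of radius ``r`` (annuli ``bin_width`` frequency pixels
    wide, ring index = nearest integer multiple of ``bin_width``)::

        FRC(r) = Re( sum F1 conj(F2) ) / sqrt( sum |F1|^2 * sum |F2|^2 )

    A Tukey taper (alpha = 0.25) is applied before the transform by default
    to suppress edge leakage; pass ``window_fn='none'`` to disable.
    Non-square inputs are center-cropped to square with a logged warning.
    """
    img1 = np.asarray(img1, dtype=np.float64)
    img2 = np.asarray(img2, dtype=np.float64)
    if img1.shape != img2.shape:
        raise ValueError(f"shape mismatch: {img1.shape} vs {img2.shape}")
    if img1.ndim != 2:
        raise ValueError("frc_curve expects 2D planes")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if not np.any(img1) or not np.any(img2):
        raise ValueError("all-zero image has no spectrum to correlate")
    if img1.shape[0] != img1.shape[1]:
        logger.warning(
            "non-square inputs %s center-cropped to square for FRC", img1.shape
        )
        img1 = _center_crop_square(img1)
        img2 = _center_crop_square(img2)

    n = img1.shape[0]
    w = _taper(n, window_fn)
    f1 = np.fft.fftshift(np.fft.fft2(img1 * w))
    f2 = np.fft.fftshift(np.fft.fft2(img2 * w))

    # integer frequency-pixel coordinates relative to the DC bin
    ax = np.arange(n) - n // 2
    ky, kx = np.meshgrid(ax, ax, indexing="ij")
    radius = np.hypot(kx, ky)
    ring = np.rint(radius / bin_width).astype(np.intp)

    n_rings = n // 2 // bin_width + 1
    keep = ring < n_rings
    ring_flat = ring[keep]
    num = np.bincount(
        ring_flat, weights=(f1 * np.conj(f2)).real[keep], minlength=n_rings
    )
    p1 = np.bincount(ring_flat, weights=np.abs(f1[keep]) ** 2, minlength=n_rings)
    p2 = np.bincount(ring_flat, weights=np.abs(f2[keep]) ** 2, minlength=n_rings)
    counts = np.bincount(ring_flat, minlength=n_rings)

    denom = np.sqrt(p1 * p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / denom, np.nan)

    freqs = np.arange(n_rings) * bin_width / (n * pixel_size)
    return FRCCurve(
        ring_frequencies=freqs,
        correlations=corr,
        pixel_size=float(pixel_size),
        n_points_per_ring=counts,
    )


@dataclass
class EffectiveResolution:
    """Threshold-crossing readout of an FRC curve.

    ``status`` is one of:

    * ``"resolved"`` — the curve crosses below the threshold; ``value_nm``
      is ``1/f*`` with ``f*`` linearly interpolated between the bracketing
      rings.
    * ``"unresolved_at_nyquist"`` — the curve never falls below threshold;
      ``value_nm`` holds the Nyquist bound ``2 * pixel_size`` (the true
      resolution is at least this good).
    * ``"unresolvable"`` — the curve starts below the threshold already at
      the first non-DC ring; ``value_nm`` is nan.
    """

    value_nm: float
    status: str
    nyquist_bound_nm: float

    @property
    def resolved(self) -> bool:
        return self.status == "resolved"

    def comparable_nm(self) -> float:
        """Value usable in ordering/threshold comparisons.

        Unresolved-at-Nyquist maps to the Nyquist bound (best measurable);
        unresolvable maps to +inf (worst).
        """
        if self.status == "unresolvable":
            return float("inf")
        return self.value_nm


def effective_resolution(
    curve: FRCCurve,
    threshold: Optional[float] = None,
    smooth_window: int = 0,
) -> EffectiveResolution:
    """Extract the effective resolution from an FRC curve.

    The first crossing below ``threshold`` (default: the curve's stored
    threshold, 1/7) is located, scanning outward from the first non-DC
    ring; the crossing frequency is linearly interpolated between the
    bracketing rings.  ``smooth_window`` > 1 applies a centered moving
    average before thresholding (off by default).
    """
    corr = np.asarray(curve.correlations, dtype=np.float64)
    freqs = np.asarray(curve.ring_frequencies, dtype=np.float64)
    if corr.size == 0:
        raise ValueError("empty FRC curve")
    thr = curve.threshold if threshold is None else threshold
    nyq = 2.0 * curve.pixel_size

    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        finite = np.isfinite(corr)
        tmp = np.where(finite, corr, 0.0)
        norm = np.convolve(finite.astype(float), kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.convolve(tmp, kernel, mode="same") / norm

    # ring 0 is the DC bin; the threshold scan starts at ring 1
    valid = np.isfinite(corr)
    idx = None
    for i in range(1, corr.size):
        if not valid[i]:
            continue
        if corr[i] < thr:
            idx = i
            break
    if idx is None:
        return EffectiveResolution(
            value_nm=nyq, status="unresolved_at_nyquist", nyquist_bound_nm=nyq
        )
    # previous valid ring above threshold?
    prev = None
    for j in range(idx - 1, 0, -1):
        if valid[j]:
            prev = j
            break
    if prev is None or corr[prev] < thr:
        return EffectiveResolution(
            value_nm=float("nan"), status="unresolvable", nyquist_bound_nm=nyq
        )
    c0, c1 = corr[prev], corr[idx]
    f0, f1 = freqs[prev], freqs[idx]
    f_cross = f0 + (c0 - thr) / (c0 - c1) * (f1 - f0)
    return EffectiveResolution(
        value_nm=float(1.0 / f_cross), status="resolved", nyquist_bound_nm=nyq
    )


def stack_effective_resolution(
    stack1: np.ndarray,
    stack2: np.ndarray,
    pixel_size: float,
    threshold: float = FRC_THRESHOLD,
    min_plane_energy: float = 0.0,
    **frc_kwargs,
) -> EffectiveResolution:
    """Median plane-wise lateral resolution of a 3D stack pair.

    Planes whose summed intensity does not exceed ``min_plane_energy`` in
    both stacks are skipped.  Unresolvable planes propagate as +inf into
    the median.
    """
    stack1 = np.asarray(stack1, dtype=np.float64)
    stack2 = np.asarray(stack2, dtype=np.float64)
    if stack1.ndim == 2:
        curve = frc_curve(stack1, stack2, pixel_size, **frc_kwargs)
        return effective_resolution(curve, threshold=threshold)
    values = []
    for z in range(stack1.shape[0]):
        if stack1[z].sum() <= min_plane_energy or stack2[z].sum() <= min_plane_energy:
            continue
        curve = frc_curve(stack1[z], stack2[z], pixel_size, **frc_kwargs)
        values.append(effective_resolution(curve, threshold=threshold))
    if not values:
        raise ValueError("no signal-bearing planes for FRC")
    comparable = np.array([v.comparable_nm() for v in values])
    order = np.argsort(comparable)
    return values[order[len(order) // 2]]


# ---------------------------------------------------------------------------
# Exposure sweep
# ---------------------------------------------------------------------------

def exposure_sweep_report(
    sets: Mapping[float, "polqc.acquisition.AcquisitionSet"],  # noqa: F821
    denoiser: Callable[[np.ndarray], np.ndarray],
    ssim_window: int = 7,
    local_error_floor: float = 0.5,
    frc_threshold: float = FRC_THRESHOLD,
    plane: str = "central",
) -> pd.DataFrame:
    """Tabulate effective resolution and SSIM diagnostics across exposures.

    ``sets`` maps exposure time (ms) to a phase-A/B acquisition set.  For
    each exposure the report holds: FRC resolution of the raw low-quality
    test pair, FRC resolution of the denoised test pair, SSIM of the raw
    test pair, SSIM of the denoised test against the first high-quality
    reference, and the local-SSIM error fraction of that comparison.
    Positions whose phase-A data are incomplete produce an error row and
    the sweep continues.
    """
    if len(sets) < 2:
        raise ValueError("exposure sweep needs >= 2 exposure levels")
    rows = []
    for t_exp in sorted(sets):
        acq = sets[t_exp]
        row: dict = {"t_exp_ms": float(t_exp)}
        try:
            pl = acq.plane(plane)
            px = acq.pixel_size_nm
            res_raw = effective_resolution(
                frc_curve(pl.test_1, pl.test_2, px), threshold=frc_threshold
            )
            den1 = denoiser(pl.test_1)
            den2 = denoiser(pl.test_2)
            res_den = effective_resolution(
                frc_curve(den1, den2, px), threshold=frc_threshold
            )
            ssim_pair = ssim_structural(pl.test_1, pl.test_2, window=ssim_window)
            ssim_ref = ssim_structural(den1, pl.high_quality_1, window=ssim_window)
            row.update(
                resolution_raw_nm=res_raw.comparable_nm(),
                resolution_denoised_nm=res_den.comparable_nm(),
                ssim_test_pair=ssim_pair.global_value,
                ssim_denoised_vs_reference=ssim_ref.global_value,
                local_error_fraction=local_error_fraction(
                    ssim_ref, local_error_floor
                ),
                error="",
            )
        except Exception as exc:  # per-position failure, sweep continues
            logger.warning("exposure %s ms failed: %s", t_exp, exc)
            row.update(
                resolution_raw_nm=np.nan,
                resolution_denoised_nm=np.nan,
                ssim_test_pair=np.nan,
                ssim_denoised_vs_reference=np.nan,
                local_error_fraction=np.nan,
                error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)
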
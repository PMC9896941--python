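"""Two-phase acquisition data model, pluggable denoisers, and the QC gate.

Phase A of an acquisition collects, for every z plane, one low-quality
image, two high-quality references at the reference exposure, and two more
low-quality test images.  Phase B is the fast time-lapse of low-quality
frames only.  The QC gate denoises the phase-A test pair, measures effective
resolution (FRC) and structural similarity against the references, and
accepts or rejects the position before any phase-B frame is touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
from scipy import ndimage

from . import metrics

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class PlaneImages:
    """Phase-A images for one z plane: 1 low-quality, 2 references, 2 tests."""

    low_quality: np.ndarray
    high_quality_1: np.ndarray
    high_quality_2: np.ndarray
    test_1: np.ndarray
    test_2: np.ndarray

    def __post_init__(self) -> None:
        shapes = {
            np.asarray(img).shape
            for img in (
                self.low_quality,
                self.high_quality_1,
                self.high_quality_2,
                self.test_1,
                self.test_2,
            )
        }
        if len(shapes) != 1:
            raise ValueError(f"phase-A images of one plane differ in shape: {shapes}")


@dataclass
class AcquisitionSet:
    """All data recorded at one sample position.

    ``planes`` holds the phase-A quality-control images per z plane;
    ``phase_b`` the time-ordered low-quality stacks (each ``(Z, Y, X)`` or a
    single 2D plane).  Exposure metadata is uniform across phase B.
    """

    position_id: str
    planes: List[PlaneImages]
    phase_b: List[np.ndarray]
    exposure_time: float
    reference_exposure: float
    pixel_size_nm: float
    timestamps: Optional[List[float]] = None

    def __post_init__(self) -> None:
        if not self.planes:
            raise ValueError("acquisition set needs at least one phase-A plane")
        if self.exposure_time > self.reference_exposure:
            raise ValueError("exposure_time must be <= reference_exposure")
        if self.timestamps is not None and len(self.timestamps) != len(self.phase_b):
            raise ValueError("timestamps must match phase-B frame count")
        b_shapes = {np.asarray(f).shape for f in self.phase_b}
        if len(b_shapes) > 1:
            raise ValueError(f"phase-B frames differ in shape: {b_shapes}")

    @property
    def n_phase_b_frames(self) -> int:
        return len(self.phase_b)

    def plane(self, which: str = "central") -> PlaneImages:
        if which == "central":
            return self.planes[len(self.planes) // 2]
        raise ValueError(f"unknown plane selector {which!r}")


# ---------------------------------------------------------------------------
# Denoiser contract
# ---------------------------------------------------------------------------

class DenoiserError(RuntimeError):
    pass


class Denoiser:
    """Shape-preserving image-restoration callable.

    Implementations must return an array of the same shape and floating
    dtype class, and be deterministic given fixed state.  2D inputs are
    handled natively; 3D stacks are processed plane-wise unless a subclass
    overrides :meth:`denoise_stack`.
    """

    name: str = "denoiser"

    def denoise_plane(self, img: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def denoise_stack(self, stack: np.ndarray) -> np.ndarray:
        return np.stack([self.denoise_plane(p) for p in stack])

    def __call__(self, img: np.ndarray) -> np.ndarray:
        img = np.asarray(img, dtype=np.float64)
        if not np.all(np.isfinite(img)):
            raise DenoiserError("denoiser input must be finite")
        out = self.denoise_plane(img) if img.ndim == 2 else self.denoise_stack(img)
        if out.shape != img.shape:
            raise DenoiserError(
                f"denoiser {self.name!r} changed shape {img.shape} -> {out.shape}"
            )
        return out


class IdentityDenoiser(Denoiser):
    name = "identity"

    def denoise_plane(self, img: np.ndarray) -> np.ndarray:
        return np.array(img, dtype=np.float64, copy=True)

    def denoise_stack(self, stack: np.ndarray) -> np.ndarray:
        return np.array(stack, dtype=np.float64, copy=True)


class GaussianDenoiser(Denoiser):
    """Gaussian smoothing baseline; sigma in pixels."""

    def __init__(self, sigma: float = 1.0):
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        self.sigma = float(sigma)
        self.name = f"gaussian(sigma={self.sigma:g})"

    def denoise_plane(self, img: np.ndarray) -> np.ndarray:
        return ndimage.gaussian_filter(img, self.sigma)


class MedianDenoiser(Denoiser):
    def __init__(self, size: int = 3):
        if size < 2:
            raise ValueError("size must be >= 2")
        self.size = int(size)
        self.name = f"median(size={self.size})"

    def denoise_plane(self, img: np.ndarray) -> np.ndarray:
        return ndimage.median_filter(img, size=self.size)


class NonLocalMeansDenoiser(Denoiser):
    def __init__(self, h: float = 0.1, patch_size: int = 5, patch_distance: int = 6):
        self.h = float(h)
        self.patch_size = int(patch_size)
        self.patch_distance = int(patch_distance)
        self.name = f"nlm(h={self.h:g})"

    def denoise_plane(self, img: np.ndarray) -> np.ndarray:
        from skimage.restoration import denoise_nl_means

        scale = float(img.max()) or 1.0
        out = denoise_nl_means(
            img / scale,
            h=self.h,
            patch_size=self.patch_size,
            patch_distance=self.patch_distance,
        )
        return out * scale


class ExternalDenoiserAdapter(Denoiser):
    """Adapter stub for an external self-supervised denoising backend.

    Training and inference happen in the external package; this class only
    wires whole phase-A image groups through.  Instantiating it without the
    backend installed raises a registration error naming the backend.
    """

    def __init__(self, backend: str = "n2v"):
        self.backend = backend
        self.name = f"external({backend})"
        try:
            __import__(backend)
        except ImportError as exc:
            raise DenoiserError(
                f"external denoiser backend {backend!r} is not installed"
            ) from exc


_DENOISER_FACTORIES: Dict[str, Callable[..., Denoiser]] = {
    "identity": IdentityDenoiser,
    "gaussian": GaussianDenoiser,
    "median": MedianDenoiser,
    "nlm": NonLocalMeansDenoiser,
    "n2v": lambda **kw: ExternalDenoiserAdapter(backend="n2v", **kw),
}


def get_denoiser(name: str, **kwargs) -> Denoiser:
    """Instantiate a registered denoiser; probe-checks shape preservation."""
    try:
        factory = _DENOISER_FACTORIES[name]
    except KeyError:
        raise DenoiserError(
            f"unknown denoiser {name!r}; available: {sorted(_DENOISER_FACTORIES)}"
        ) from None
    den = factory(**kwargs)
    probe = np.zeros((8, 8))
    out = den(probe)
    if out.shape != probe.shape:
        raise DenoiserError(f"denoiser {name!r} failed shape-preservation probe")
    return den


def register_denoiser(name: str, factory: Callable[..., Denoiser]) -> None:
    den = factory()
    probe = np.zeros((8, 8))
    if den(probe).shape != probe.shape:
        raise DenoiserError(f"denoiser {name!r} is not shape-preserving")
    _DENOISER_FACTORIES[name] = factory


# ---------------------------------------------------------------------------
# QC gate
# ---------------------------------------------------------------------------

@dataclass
class QCThresholds:
    """Acceptance thresholds; config-mandatory, no silent defaults.

    ``min_resolution_nm`` is the worst acceptable effective resolution
    (accept requires measured resolution <= this many nm).
    """

    min_resolution_nm: float
    min_ssim: float
    max_local_error_fraction: float
    local_ssim_floor: float = 0.5


@dataclass
class QCReport:
    """Auditable per-position QC outcome.

    The decision is derivable from the stored numbers and thresholds alone
    (see :func:`decide`); ``reasons`` lists machine-readable codes for a
    rejection ("resolution", "ssim", "local-error", "metric-error").
    """

    position_id: str
    effective_resolution_reconstructed_nm: float
    effective_resolution_raw_nm: float
    ssim_pairwise: float
    ssim_vs_reference: float
    local_error_fraction: float
    thresholds: QCThresholds
    decision: str = "reject"
    reasons: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "position_id": self.position_id,
            "effective_resolution_reconstructed_nm": self.effective_resolution_reconstructed_nm,
            "effective_resolution_raw_nm": self.effective_resolution_raw_nm,
            "ssim_pairwise": self.ssim_pairwise,
            "ssim_vs_reference": self.ssim_vs_reference,
            "local_error_fraction": self.local_error_fraction,
            "thresholds": vars(self.thresholds),
            "decision": self.decision,
            "reasons": list(self.reasons),
        }


def decide(report: QCReport) -> tuple[str, List[str]]:
    """Recompute the accept/reject decision from a report's stored numbers."""
    t = report.thresholds
    reasons: List[str] = []
    res = report.effective_resolution_reconstructed_nm
    if not np.isfinite(res) or res > t.min_resolution_nm:
        reasons.append("resolution")
    if not np.isfinite(report.ssim_vs_reference) or report.ssim_vs_reference < t.min_ssim:
        reasons.append("ssim")
    if (
        not np.isfinite(report.local_error_fraction)
        or report.local_error_fraction > t.max_local_error_fraction
    ):
        reasons.append("local-error")
    return ("accept" if not reasons else "reject"), reasons


def qc_gate(
    acq: AcquisitionSet,
    denoiser: Denoiser,
    thresholds: QCThresholds,
    plane: str = "central",
    ssim_window: int = 7,
) -> QCReport:
    """Run the per-position QC gate on a phase-A set.

    Reconstructs the two low-quality test images, measures the FRC
    effective resolution of the reconstructed pair, the structural SSIM of
    the reconstructed pair, the SSIM of reconstruction vs the first
    high-quality reference, and the local-SSIM error fraction of that
    comparison.  Accept requires all three thresholds to pass.  Any metric
    failure yields a reject with reason ``"metric-error"`` — never a silent
    accept.  Phase-B frames are never read here.
    """
    try:
        pl = acq.plane(plane)
        px = acq.pixel_size_nm
        den1 = denoiser(pl.test_1)
        den2 = denoiser(pl.test_2)
        res_rec = metrics.effective_resolution(metrics.frc_curve(den1, den2, px))
        res_raw = metrics.effective_resolution(
            metrics.frc_curve(pl.test_1, pl.test_2, px)
        )
        ssim_pair = metrics.ssim_structural(den1, den2, window=ssim_window)
        ssim_ref = metrics.ssim_structural(den1, pl.high_quality_1, window=ssim_window)
        err_frac = metrics.local_error_fraction(ssim_ref, thresholds.local_ssim_floor)
        report = QCReport(
            position_id=acq.position_id,
            effective_resolution_reconstructed_nm=res_rec.comparable_nm(),
            effective_resolution_raw_nm=res_raw.comparable_nm(),
            ssim_pairwise=ssim_pair.global_value,
            ssim_vs_reference=ssim_ref.global_value,
            local_error_fraction=err_frac,
            thresholds=thresholds,
        )
    except Exception as exc:
        logger.warning("QC metrics failed for %s: %s", acq.position_id, exc)
        report = QCReport(
            position_id=acq.position_id,
            effective_resolution_reconstructed_nm=float("nan"),
            effective_resolution_raw_nm=float("nan"),
            ssim_pairwise=float("nan"),
            ssim_vs_reference=float("nan"),
            local_error_fraction=float("nan"),
            thresholds=thresholds,
            decision="reject",
            reasons=["metric-error"],
        )
        return report
    report.decision, report.reasons = decide(report)
    return report


# ---------------------------------------------------------------------------
# Phase-B reconstruction
# ---------------------------------------------------------------------------

@dataclass
class ReconstructedTimelapse:
    frames: List[np.ndarray]
    timestamps: Optional[List[float]]
    provenance: dict


class QCRejectedError(RuntimeError):
    pass


def reconstruct_timelapse(
    acq: AcquisitionSet,
    denoiser: Denoiser,
    report: QCReport,
    override: bool = False,
) -> ReconstructedTimelapse:
    """Apply the denoiser to every phase-B frame of an accepted position.

    Frame count, shapes, and timestamps are preserved; provenance records
    the denoiser id and the QC decision.  Running on a rejected position
    raises unless ``override=True`` (which is logged).
    """
    if report.decision != "accept":
        if not override:
            raise QCRejectedError(
                f"position {acq.position_id!r} rejected by QC "
                f"(reasons: {report.reasons}); pass override=True to force"
            )
        logger.warning(
            "QC override: reconstructing rejected position %s", acq.position_id
        )
    frames = [denoiser(np.asarray(f, dtype=np.float64)) for f in acq.phase_b]
    provenance = {
        "denoiser": denoiser.name,
        "position_id": acq.position_id,
        "qc_decision": report.decision,
        "qc_reasons": list(report.reasons),
        "qc_override": bool(override and report.decision != "accept"),
    }
    return ReconstructedTimelapse(
        frames=frames,
        timestamps=list(acq.timestamps) if acq.timestamps is not None else None,
        provenance=provenance,
    )
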
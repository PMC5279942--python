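"""Subpixel pillar localization and deflection measurement.

Each pilus of the elastomeric array acts as a light guide, appearing in
bright-field images as a bright spot.  The spot center is localized by
least-squares fitting an isotropic 2D Gaussian

    I(x, y) = A · exp(−((x − x0)² + (y − y0)²) / (2σ²)) + B

to the intensity values in a region of interest, giving subpixel
precision.  Deflection of the pilus is the displacement of its fitted
center between the frame taken *before* the stimulus and the frame taken
*during* it, converted to nm through the camera pixel size; the frame
taken *after* release verifies elastic recovery.

Coordinates are 0-based with the pixel-center convention: integer
coordinate (i, j) is the center of pixel row i, column j.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

__all__ = [
    "Roi",
    "PillarLocalization",
    "DeflectionMeasurement",
    "GaussianSpot2D",
    "fit_pillar_center",
    "detect_pillars",
    "measure_deflection",
    "LocalizationError",
]


class LocalizationError(RuntimeError):
    """Raised when a spot fit fails to converge or escapes its ROI."""


@dataclass(frozen=True)
class Roi:
    """Rectangular region of interest: half-open pixel ranges."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError("empty ROI")

    @classmethod
    def centered(cls, center_rc: tuple[float, float], half_width: int,
                 shape: tuple[int, int]) -> "Roi":
        r, c = int(round(center_rc[0])), int(round(center_rc[1]))
        return cls(max(0, r - half_width), min(shape[0], r + half_width + 1),
                   max(0, c - half_width), min(shape[1], c + half_width + 1))

    def contains(self, point_rc: tuple[float, float]) -> bool:
        r, c = point_rc
        return (self.row_start - 0.5 <= r <= self.row_stop - 0.5
                and self.col_start - 0.5 <= c <= self.col_stop - 0.5)


@dataclass(frozen=True)
class PillarLocalization:
    """Converged 2D Gaussian fit of one pilus spot in one frame.

    ``center`` is (row, col) in continuous pixel coordinates; the
    ``fit_residual`` is the RMS residual normalized by the fitted
    amplitude.
    """

    frame_role: str
    center: tuple[float, float]
    amplitude: float
    sigma: float
    background: float
    fit_residual: float
    pilus_id: str = ""

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write(f"2D Gaussian spot fit ({self.frame_role or 'frame'})\n")
        buf.write("-" * 35 + "\n")
        buf.write(f"{'center (row, col) px':<24}({self.center[0]:.4f}, {self.center[1]:.4f})\n")
        buf.write(f"{'amplitude (counts)':<24}{self.amplitude:.2f}\n")
        buf.write(f"{'sigma (px)':<24}{self.sigma:.3f}\n")
        buf.write(f"{'background (counts)':<24}{self.background:.2f}\n")
        buf.write(f"{'norm. RMS residual':<24}{self.fit_residual:.4g}\n")
        return buf.getvalue()


@dataclass(frozen=True)
class DeflectionMeasurement:
    """Deflection of one pilus across the before/during/after frames.

    ``d_vector_nm`` is the during-minus-before center displacement in nm
    (drift-corrected when reference pillars were supplied);
    ``recovery_residual_nm`` is the after-vs-before mismatch, which
    should be small for an elastic pilus that returned to rest.
    """

    d_vector_nm: tuple[float, float]
    d_magnitude_nm: float
    recovery_residual_nm: float
    reference_drift_nm: tuple[float, float]
    pilus_id: str = ""
    recovered: bool = True


class GaussianSpot2D:
    """Isotropic (optionally anisotropic) 2D Gaussian spot model.

    ``GaussianSpot2D(image, roi).fit()`` returns a
    :class:`PillarLocalization`.  Initialization uses the
    background-subtracted intensity centroid of the ROI for the center
    and max − min for the amplitude; a non-converged fit or a center
    escaping the ROI raises :class:`LocalizationError` rather than
    returning a silent value.
    """

    def __init__(self, image: np.ndarray, roi: Roi, *, frame_role: str = "",
                 pilus_id: str = "", anisotropic: bool = False):
        image = np.asarray(image, dtype=float)
        if image.ndim != 2:
            raise ValueError("image must be 2-D")
        self.image = image
        self.roi = roi
        self.frame_role = frame_role
        self.pilus_id = pilus_id
        self.anisotropic = anisotropic

    def fit(self) -> PillarLocalization:
        roi = self.roi
        patch = self.image[roi.row_start:roi.row_stop, roi.col_start:roi.col_stop]
        rows = np.arange(roi.row_start, roi.row_stop, dtype=float)
        cols = np.arange(roi.col_start, roi.col_stop, dtype=float)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")

        background0 = float(patch.min())
        amplitude0 = float(patch.max() - patch.min())
        if amplitude0 <= 0:
            raise LocalizationError("flat ROI: no spot to fit")
        weights = patch - background0
        total = weights.sum()
        r0 = float((weights * rr).sum() / total)
        c0 = float((weights * cc).sum() / total)
        sigma0 = max(0.25 * min(patch.shape), 1.0)

        y = patch.ravel()
        r_flat, c_flat = rr.ravel(), cc.ravel()

        if self.anisotropic:
            def model(p):
                a, r_c, c_c, s_r, s_c, b = p
                return a * np.exp(-((r_flat - r_c) ** 2 / (2 * s_r**2)
                                    + (c_flat - c_c) ** 2 / (2 * s_c**2))) + b
            p0 = [amplitude0, r0, c0, sigma0, sigma0, background0]
            lower = [0, rows[0] - 1, cols[0] - 1, 0.1, 0.1, -np.inf]
            upper = [np.inf, rows[-1] + 1, cols[-1] + 1,
                     patch.shape[0], patch.shape[1], np.inf]
        else:
            def model(p):
                a, r_c, c_c, s, b = p
                return a * np.exp(-((r_flat - r_c) ** 2 + (c_flat - c_c) ** 2)
                                  / (2 * s**2)) + b
            p0 = [amplitude0, r0, c0, sigma0, background0]
            lower = [0, rows[0] - 1, cols[0] - 1, 0.1, -np.inf]
            upper = [np.inf, rows[-1] + 1, cols[-1] + 1, max(patch.shape), np.inf]

        sol = least_squares(lambda p: model(p) - y, p0, bounds=(lower, upper),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not sol.success:
            raise LocalizationError("2D Gaussian fit did not converge")
        if self.anisotropic:
            a, r_c, c_c, s_r, s_c, b = sol.x
            sigma = float(np.sqrt(s_r * s_c))
        else:
            a, r_c, c_c, sigma, b = sol.x
        center = (float(r_c), float(c_c))
        if not roi.contains(center):
            raise LocalizationError(f"fitted center {center} escaped ROI {roi}")
        residual = float(np.sqrt(np.mean(sol.fun**2)) / max(a, 1e-12))
        return PillarLocalization(self.frame_role, center, float(a), float(sigma),
                                  float(b), residual, self.pilus_id)


def fit_pillar_center(image: np.ndarray, roi: Roi, *, frame_role: str = "",
                      pilus_id: str = "", anisotropic: bool = False) -> PillarLocalization:
    """Fit one pilus spot: ``GaussianSpot2D(image, roi).fit()``."""
    return GaussianSpot2D(image, roi, frame_role=frame_role, pilus_id=pilus_id,
                          anisotropic=anisotropic).fit()


def detect_pillars(image: np.ndarray, *, k_noise: float = 5.0,
                   half_width: int = 8, min_separation: int = 5) -> list[Roi]:
    """Candidate spot ROIs from local-maximum detection.

    A pixel is a candidate when it is the maximum of its
    ``min_separation``-neighbourhood and exceeds the image background
    (median) by ``k_noise`` times a robust noise scale (MAD).  Returns
    one centered ROI per detection, ordered by row then column
    (ties between equal maxima resolve to the lowest row/column index);
    an empty list when nothing is found.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    background = float(np.median(image))
    mad = float(np.median(np.abs(image - background)))
    noise = 1.4826 * mad
    threshold = background + k_noise * noise

    size = 2 * min_separation + 1
    footprint_max = ndimage.maximum_filter(image, size=size, mode="nearest")
    peaks = (image == footprint_max) & (image > threshold)
    labels, n = ndimage.label(peaks)
    rois = []
    for idx in range(1, n + 1):
        rs, cs = np.nonzero(labels == idx)
        order = np.lexsort((cs, rs))  # plateau tie-break: lowest row, then col
        r, c = int(rs[order[0]]), int(cs[order[0]])
        rois.append(Roi.centered((r, c), half_width, image.shape))
    return rois


def measure_deflection(
    before: PillarLocalization,
    during: PillarLocalization,
    after: PillarLocalization,
    pixel_size_nm: float,
    reference_centers: dict[str, tuple[tuple[float, float], tuple[float, float]]] | None = None,
    recovery_limit_nm: float = 50.0,
) -> DeflectionMeasurement:
    """Deflection vector and magnitude of one stimulated pilus.

    Parameters
    ----------
    before, during, after : PillarLocalization
        Fits of the same pilus in the three frames.
    pixel_size_nm : float
        Camera pixel size on the specimen, nm/px.
    reference_centers : dict, optional
        Per-reference-pilus (before_center, during_center) pairs for
        non-stimulated pillars.  When given, the median reference
        displacement (stage drift) is subtracted from the deflection.
    recovery_limit_nm : float
        After-vs-before mismatch above which the measurement is flagged
        as non-recovering (pilus did not return to rest).
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be positive")
    ids = {before.pilus_id, during.pilus_id, after.pilus_id}
    if len(ids) > 1:
        raise ValueError(f"frames belong to different pili: {sorted(ids)}")

    b = np.asarray(before.center)
    drift = np.zeros(2)
    if reference_centers:
        disp = np.asarray([np.asarray(dur) - np.asarray(bef)
                           for bef, dur in reference_centers.values()])
        drift = np.median(disp, axis=0)
    d_px = np.asarray(during.center) - b - drift
    d_nm = d_px * pixel_size_nm
    recovery = float(np.linalg.norm(np.asarray(after.center) - b) * pixel_size_nm)
    return DeflectionMeasurement(
        d_vector_nm=(float(d_nm[0]), float(d_nm[1])),
        d_magnitude_nm=float(np.linalg.norm(d_nm)),
        recovery_residual_nm=recovery,
        reference_drift_nm=(float(drift[0] * pixel_size_nm), float(drift[1] * pixel_size_nm)),
        pilus_id=before.pilus_id,
        recovered=recovery <= recovery_limit_nm,
    )
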
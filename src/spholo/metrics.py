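"""Image-quality metrics used to characterise reconstructions.

ROIs are given either as boolean masks or as half-open rectangles
``(row0, row1, col0, col1)`` in 0-based pixel coordinates.  Phase ROIs
are averaged circularly so steps near +-pi are handled correctly, and
all phase comparisons use differences only — the reconstruction carries
an arbitrary global phase from the reference arm.
"""

from __future__ import annotations

import numpy as np
from skimage.measure import profile_line

from .exceptions import InvalidArgumentError, UndefinedMetricError
from .image import ComplexImage, wrap_phase

__all__ = ["line_profile", "phase_error", "cnr", "complex_correlation"]


def _as_array(image) -> np.ndarray:
    if isinstance(image, ComplexImage):
        raise InvalidArgumentError(
            "pass a single component (image.amplitude or image.phase)"
        )
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidArgumentError("image component must be 2-D")
    return arr


def _as_mask(roi, shape) -> np.ndarray:
    if isinstance(roi, np.ndarray) and roi.dtype == bool:
        if roi.shape != shape:
            raise InvalidArgumentError("ROI mask shape does not match image")
        mask = roi
    else:
        try:
            r0, r1, c0, c1 = (int(x) for x in roi)
        except (TypeError, ValueError):
            raise InvalidArgumentError(
                "ROI must be a boolean mask or a (row0, row1, col0, col1) rectangle"
            ) from None
        if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
            raise InvalidArgumentError(f"ROI rectangle {roi} outside image {shape}")
        mask = np.zeros(shape, dtype=bool)
        mask[r0:r1, c0:c1] = True
    if not mask.any():
        raise InvalidArgumentError("ROI is empty")
    return mask


def line_profile(image, start_px, end_px, width_px: int = 1) -> np.ndarray:
    """1-D profile between two pixels, averaged over a perpendicular width.

    ``start_px`` and ``end_px`` are (row, col) pixel coordinates; the
    profile is sampled without interpolation (nearest pixel) so plateaus
    of piecewise-constant images are preserved.
    """
    arr = _as_array(image)
    for p in (start_px, end_px):
        r, c = p
        if not (0 <= r < arr.shape[0] and 0 <= c < arr.shape[1]):
            raise InvalidArgumentError(f"profile endpoint {p} outside image {arr.shape}")
    if width_px < 1:
        raise InvalidArgumentError("width_px must be >= 1")
    return profile_line(
        arr,
        start_px,
        end_px,
        linewidth=int(width_px),
        order=0,
        mode="reflect",
        reduce_func=np.mean,
    )


def _circular_mean(phases: np.ndarray) -> float:
    z = np.mean(np.exp(1j * phases))
    if abs(z) < 1e-12:
        raise UndefinedMetricError("circular mean undefined (phases fully dispersed)")
    return float(np.angle(z))


def phase_error(recon, roi_bar, roi_bg, nominal: float) -> dict:
    """Phase-step accuracy against a nominal step.

    Returns ``measured_step`` (circular mean of the bar ROI minus that of
    the background ROI, wrapped) and ``error = |measured_step - nominal|``
    wrapped into [0, pi].  Invariant to a global phase offset.
    """
    phase = recon.phase if isinstance(recon, ComplexImage) else _as_array(recon)
    bar = _as_mask(roi_bar, phase.shape)
    bg = _as_mask(roi_bg, phase.shape)
    if np.any(bar & bg):
        raise InvalidArgumentError("bar and background ROIs must be disjoint")
    step = float(wrap_phase(_circular_mean(phase[bar]) - _circular_mean(phase[bg])))
    err = abs(float(wrap_phase(step - nominal)))
    return {"measured_step": step, "error": err}


def cnr(amplitude, roi_sig, roi_bg) -> float:
    """Contrast-to-noise ratio: (mean(sig) - mean(bg)) / std(bg).

    The background standard deviation uses the unbiased (ddof=1)
    estimator; a zero background spread leaves the metric undefined.
    """
    arr = _as_array(amplitude)
    sig = _as_mask(roi_sig, arr.shape)
    bg = _as_mask(roi_bg, arr.shape)
    if bg.sum() < 2:
        raise InvalidArgumentError("background ROI needs at least 2 pixels")
    std = float(np.std(arr[bg], ddof=1))
    if std == 0.0:
        raise UndefinedMetricError("background std is zero; CNR undefined")
    return float((np.mean(arr[sig]) - np.mean(arr[bg])) / std)


def complex_correlation(a: ComplexImage, b: ComplexImage) -> float:
    """Global-phase-invariant fidelity |<a, b>| / (||a|| * ||b||) in [0, 1]."""
    if a.side != b.side:
        raise InvalidArgumentError("images must share side")
    fa, fb = a.field, b.field
    na = np.linalg.norm(fa)
    nb = np.linalg.norm(fb)
    if na == 0.0 or nb == 0.0:
        raise UndefinedMetricError("zero-norm image; correlation undefined")
    return float(np.abs(np.vdot(fa, fb)) / (na * nb))
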
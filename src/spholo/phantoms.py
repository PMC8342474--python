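"""Synthetic complex-valued test objects.

Three families mirror the samples used to characterise the holographic
system: positive three-bar resolution targets (amplitude contrast),
quantitative phase-step targets (pure phase contrast), and tissue-like
smoothed random fields (weak amplitude contrast with rich phase, as for
unstained brain slices).  Phantoms are noise-free; all measurement
stochasticity lives in the forward model.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import InvalidArgumentError
from .image import ComplexImage, wrap_phase

__all__ = ["bar_target", "phase_step_target", "tissue_phantom", "bar_mask"]


def _element_mask(side: int, w: int, top: int, left: int, horizontal: bool) -> np.ndarray:
    """Boolean mask of one three-bar element with top-left corner (top, left).

    Element geometry follows the 1951-USAF convention: three bars of
    width w and length 5w separated by gaps of width w, so the element
    occupies a 5w x 5w square.
    """
    ext = 5 * w
    if top < 0 or left < 0 or top + ext > side or left + ext > side:
        raise InvalidArgumentError("bar element overflows the grid")
    mask = np.zeros((side, side), dtype=bool)
    for k in range(3):
        off = 2 * k * w
        if horizontal:
            mask[top + off : top + off + w, left : left + ext] = True
        else:
            mask[top : top + ext, left + off : left + off + w] = True
    return mask


def bar_mask(
    side: int,
    bar_width_px: int,
    n_elements: int = 1,
    orientation_mix: str = "both",
) -> np.ndarray:
    """Boolean bright-bar mask for :func:`bar_target` (also used for ROIs).

    Elements are laid out on a grid aligned to multiples of the bar
    width, starting at offset (2w, 2w), alternating orientation when
    ``orientation_mix="both"``.
    """
    if bar_width_px < 1:
        raise InvalidArgumentError("bar width must be >= 1 pixel")
    if n_elements < 1:
        raise InvalidArgumentError("need at least one element")
    if orientation_mix not in ("horizontal", "vertical", "both"):
        raise InvalidArgumentError(f"unknown orientation_mix {orientation_mix!r}")
    w = int(bar_width_px)
    ext = 5 * w
    pitch = 7 * w  # element plus 2w of clearance
    start = 2 * w
    per_row = max((side - start) // pitch, 0)
    if per_row == 0 or n_elements > per_row * per_row:
        raise InvalidArgumentError(
            f"{n_elements} element(s) of bar width {w} do not fit on side {side}"
        )
    mask = np.zeros((side, side), dtype=bool)
    for i in range(n_elements):
        r, c = divmod(i, per_row)
        top = start + r * pitch
        left = start + c * pitch
        if orientation_mix == "horizontal":
            horizontal = True
        elif orientation_mix == "vertical":
            horizontal = False
        else:
            horizontal = i % 2 == 0
        mask |= _element_mask(side, w, top, left, horizontal)
    return mask


def bar_target(
    side: int,
    bar_width_px: int,
    n_elements: int = 1,
    orientation_mix: str = "both",
) -> ComplexImage:
    """Positive three-bar amplitude target: unit amplitude on bars, zero
    elsewhere, phase zero everywhere."""
    mask = bar_mask(side, bar_width_px, n_elements, orientation_mix)
    return ComplexImage(amplitude=mask.astype(np.float64), phase=np.zeros((side, side)))


def phase_step_target(
    side: int,
    delta_phi: float,
    bar_width_px: int = 8,
    n_elements: int = 1,
    orientation_mix: str = "both",
) -> ComplexImage:
    """Quantitative phase target: uniform unit amplitude, phase step of
    ``delta_phi`` radians on the bar regions against a zero background.

    Steps beyond pi would alias after wrapping and are rejected.
    """
    if abs(delta_phi) > np.pi:
        raise InvalidArgumentError(
            f"|delta_phi| must not exceed pi (got {delta_phi}); larger steps alias"
        )
    mask = bar_mask(side, bar_width_px, n_elements, orientation_mix)
    phase = np.where(mask, float(delta_phi), 0.0)
    return ComplexImage(amplitude=np.ones((side, side)), phase=phase)


def tissue_phantom(
    side: int,
    seed: int,
    amp_contrast: float = 0.3,
    phase_range: float = 2.0,
    correlation_len_px: float = 8.0,
) -> ComplexImage:
    """Tissue-like smoothed random field.

    Two independent seeded Gaussian random fields are low-pass filtered to
    the requested correlation length and rescaled: amplitude into
    ``[1 - amp_contrast, 1]``, phase into ``[-phase_range/2, phase_range/2]``.
    ``amp_contrast`` near 0 with a generous ``phase_range`` emulates
    unstained tissue (little amplitude contrast, informative phase).
    Deterministic for a fixed seed.
    """
    if correlation_len_px < 1:
        raise InvalidArgumentError("correlation length must be >= 1 pixel")
    if not (0.0 <= amp_contrast <= 1.0):
        raise InvalidArgumentError("amp_contrast must be in [0, 1]")
    if not (0.0 <= phase_range <= 2.0 * np.pi):
        raise InvalidArgumentError("phase_range must be in [0, 2*pi]")
    rng = np.random.default_rng(seed)

    def _smooth_unit(shape):
        f = gaussian_filter(rng.standard_normal(shape), sigma=correlation_len_px, mode="wrap")
        lo, hi = f.min(), f.max()
        if hi - lo < 1e-300:  # flat field; degenerate but well-defined
            return np.zeros(shape)
        return (f - lo) / (hi - lo)

    amp_field = _smooth_unit((side, side))
    phase_field = _smooth_unit((side, side))
    amplitude = 1.0 - amp_contrast + amp_contrast * amp_field
    phase = wrap_phase(phase_range * (phase_field - 0.5))
    return ComplexImage(amplitude=amplitude, phase=phase)
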
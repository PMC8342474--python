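"""Complex-valued object images.

The sample is described by a complex transmission function
``O(r) = A(r) * exp(i * phi(r))`` where ``A`` is the spatially varying
amplitude transmissivity and ``phi`` the accumulated optical phase.
Amplitude and phase are stored as separate real rasters; the phase is
always kept wrapped to the interval (-pi, pi], matching how quantitative
phase images are displayed (no unwrapping anywhere in the pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError

__all__ = ["ComplexImage", "wrap_phase"]


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase values into the interval (-pi, pi]."""
    wrapped = np.mod(phi, 2.0 * np.pi)
    # mod gives [0, 2*pi); fold the upper half down so pi itself survives
    return np.where(wrapped > np.pi, wrapped - 2.0 * np.pi, wrapped)


@dataclass
class ComplexImage:
    """A square complex field stored as an amplitude/phase raster pair.

    Parameters
    ----------
    amplitude
        Dimensionless transmissivity, non-negative.  Objects produced by
        the phantom generators stay within [0, 1]; reconstructions may
        slightly exceed 1 in the presence of measurement noise.
    phase
        Phase in radians; wrapped to (-pi, pi] on construction.
    """

    amplitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        self.phase = np.asarray(self.phase, dtype=np.float64)
        if self.amplitude.ndim != 2 or self.amplitude.shape[0] != self.amplitude.shape[1]:
            raise InvalidArgumentError("amplitude must be a square 2-D array")
        if self.phase.shape != self.amplitude.shape:
            raise InvalidArgumentError(
                f"amplitude {self.amplitude.shape} and phase {self.phase.shape} "
                "rasters must share shape"
            )
        if not np.all(np.isfinite(self.amplitude)) or not np.all(np.isfinite(self.phase)):
            raise InvalidArgumentError("non-finite values in image")
        if np.any(self.amplitude < 0):
            raise InvalidArgumentError("amplitude must be non-negative")
        self.phase = np.asarray(wrap_phase(self.phase), dtype=np.float64)

    @property
    def side(self) -> int:
        return self.amplitude.shape[0]

    @property
    def field(self) -> np.ndarray:
        """The complex field A * exp(i * phi)."""
        return self.amplitude * np.exp(1j * self.phase)

    @classmethod
    def from_field(cls, field: np.ndarray) -> "ComplexImage":
        field = np.asarray(field, dtype=np.complex128)
        return cls(amplitude=np.abs(field), phase=np.angle(field))

    def copy(self) -> "ComplexImage":
        return ComplexImage(self.amplitude.copy(), self.phase.copy())
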
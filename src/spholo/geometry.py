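"""Optical and temporal system calculators for the operational modes.

The DMD (13.68 um mirror pitch, mounted at 45 degrees so a sqrt(2)
diagonal factor applies) is binned into superpixels and imaged onto the
sample through a 4f lens pair; the lateral resolution is the projected
superpixel size and the field of view is ``n_super`` superpixels.  The
45-degree tilt also makes the y resolution a fixed fraction of the x
resolution (the printed pair 43.1/58.0 um fixes the default anisotropy;
numerically this ratio is close to cos 41.92 deg, the diffracted-beam
angle, but it is treated as configuration here).  The throughput
figure of merit SBP-T counts reconstructed pixels delivered per second,
with a factor 2 because amplitude and phase both carry information:
``sbp_t = 2 / refresh_time``, independent of lens pair and binning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import InvalidArgumentError
from .forward import AcquisitionConfig

__all__ = [
    "SystemConfig",
    "GeometryReport",
    "TimingReport",
    "derive_geometry",
    "timing_report",
    "round_sig",
]


def round_sig(x: float, sig: int = 3) -> float:
    """Round to a number of significant figures (display convention)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass
class SystemConfig:
    """Hardware constants of the optical train."""

    mirror_pitch: float = 13.68  # um, DMD mirror pitch
    binning: int = 3  # mirrors per superpixel edge
    n_super: int = 256  # superpixels per image edge
    f_front: float = 125.0  # mm, 4f front focal length
    f_rear: float = 125.0  # mm, 4f rear focal length (magnification f_rear/f_front)
    diag_factor: float = math.sqrt(2.0)  # 45-degree DMD mounting
    anisotropy: float = 43.1 / 58.0  # y-to-x resolution ratio

    def __post_init__(self) -> None:
        if self.mirror_pitch <= 0 or self.f_front <= 0 or self.f_rear <= 0:
            raise InvalidArgumentError("lengths and focal lengths must be positive")
        if self.binning < 1 or self.n_super < 1:
            raise InvalidArgumentError("binning and n_super must be positive integers")
        if self.binning * self.n_super > 768:
            raise InvalidArgumentError(
                f"binning * n_super = {self.binning * self.n_super} exceeds the "
                "768-mirror short edge of the DMD"
            )
        if self.diag_factor <= 0 or self.anisotropy <= 0:
            raise InvalidArgumentError("diag_factor and anisotropy must be positive")


@dataclass
class GeometryReport:
    """Derived optical parameters of one operational mode."""

    res_x: float  # um
    res_y: float  # um
    fov_x: float  # mm
    fov_y: float  # mm
    sbp_t: float  # pixels / s

    def as_dict(self) -> dict:
        return {
            "res_x_um": self.res_x,
            "res_y_um": self.res_y,
            "fov_x_mm": self.fov_x,
            "fov_y_mm": self.fov_y,
            "sbp_t_pixels_per_s": self.sbp_t,
        }


@dataclass
class TimingReport:
    """Derived temporal parameters of the acquisition."""

    cycles_per_pattern: float
    samples_per_cycle: float
    samples_per_pattern: float
    total_time: float  # s
    beat_period: float  # s

    def as_dict(self) -> dict:
        return {
            "cycles_per_pattern": self.cycles_per_pattern,
            "samples_per_cycle": self.samples_per_cycle,
            "samples_per_pattern": self.samples_per_pattern,
            "total_time_s": self.total_time,
            "beat_period_s": self.beat_period,
        }


def derive_geometry(sys: SystemConfig, acq: AcquisitionConfig) -> GeometryReport:
    """Resolution, field of view and throughput of one operational mode.

    res_x = diag_factor * binning * mirror_pitch * (f_rear / f_front);
    res_y = anisotropy * res_x; fov = n_super * res; sbp_t = 2 / refresh_time.
    Stored values are full precision; round only for display.
    """
    magnification = sys.f_rear / sys.f_front
    res_x = sys.diag_factor * sys.binning * sys.mirror_pitch * magnification
    res_y = sys.anisotropy * res_x
    return GeometryReport(
        res_x=res_x,
        res_y=res_y,
        fov_x=sys.n_super * res_x * 1e-3,  # um -> mm
        fov_y=sys.n_super * res_y * 1e-3,
        sbp_t=2.0 / acq.refresh_time,
    )


def timing_report(acq: AcquisitionConfig, n_patterns: int = 65_536) -> TimingReport:
    """Beat-cycle and sampling arithmetic for a full acquisition."""
    if n_patterns < 1:
        raise InvalidArgumentError("n_patterns must be positive")
    return TimingReport(
        cycles_per_pattern=acq.refresh_time * acq.beat_freq,
        samples_per_cycle=acq.sample_rate / acq.beat_freq,
        samples_per_pattern=acq.sample_rate * acq.refresh_time,
        total_time=n_patterns * acq.refresh_time,
        beat_period=1.0 / acq.beat_freq,
    )
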
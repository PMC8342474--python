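"""Forward model of the heterodyne single-pixel measurement.

A binary Hadamard-like pattern displayed on the DMD multiplies the
object field; the single-pixel detector sees the interference of the
spatially summed transmitted field with a frequency-shifted reference
beam, so each pattern yields a digitized beat record

    V(t) = dc_reference + dc_signal_n
           + 2 * gain * |c_n| * cos(2*pi*beat_freq*t + arg(c_n)) + noise,

where ``c_n = (1/sqrt(N)) * sum_r O(r) * Ht_n(r)`` is the binary-pattern
coefficient, ``dc_signal_n`` is the transmitted intensity of that
pattern, and the noise is zero-mean Gaussian with standard deviation
``noise_rel`` times the noiseless sample (the measured 0.1 % relative
noise level by default).  The carrier phase is referenced to the global
clock t = 0, so the absolute coefficient phase is encoded in time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .coefficients import SamplingPlan
from .exceptions import InvalidArgumentError
from .hadamard import HadamardPlan, Pattern, _fwht2_grid, basis_pattern
from .image import ComplexImage

__all__ = ["AcquisitionConfig", "BeatRecord", "project_and_sum", "synthesize_beat", "acquire"]


@dataclass
class AcquisitionConfig:
    """Acquisition constants of the heterodyne system.

    Defaults are the reference operating point: a 62,500 Hz beat between
    the two acousto-optic modulators, a 1.25 Ms/s digitizer and a 48 us
    pattern refresh time, giving 3 beat cycles and 60 samples per
    displayed pattern, with measurement noise of 0.1 % of the signal.
    """

    beat_freq: float = 62_500.0  # Hz
    sample_rate: float = 1.25e6  # samples / s
    refresh_time: float = 48e-6  # s per displayed pattern
    noise_rel: float = 0.001  # relative noise std (0.1 %)
    dc_reference: float = 1.0  # detector DC from the reference beam, arb. units
    gain: float = 1.0  # interference scaling constant
    seed: int | None = 0  # default noise stream
    discard_first: int = 0  # settling samples dropped per record

    def __post_init__(self) -> None:
        if self.beat_freq <= 0 or self.sample_rate <= 0 or self.refresh_time <= 0:
            raise InvalidArgumentError("beat_freq, sample_rate and refresh_time must be positive")
        if self.noise_rel < 0:
            raise InvalidArgumentError("noise_rel must be non-negative")
        if self.discard_first < 0:
            raise InvalidArgumentError("discard_first must be non-negative")
        if self.beat_freq > self.sample_rate / 2:
            raise InvalidArgumentError(
                f"beat_freq {self.beat_freq} violates Nyquist for sample_rate {self.sample_rate}"
            )
        cycles = self.cycles_per_pattern
        if abs(cycles - round(cycles)) > 1e-9:
            warnings.warn(
                f"refresh_time * beat_freq = {cycles:.4f} is not an integer; "
                "an integer number of beat cycles per pattern is preferred",
                stacklevel=2,
            )

    @property
    def cycles_per_pattern(self) -> float:
        return self.refresh_time * self.beat_freq

    @property
    def samples_per_record(self) -> int:
        return int(math.floor(self.refresh_time * self.sample_rate))

    @property
    def integer_cycles(self) -> bool:
        c = self.cycles_per_pattern
        return abs(c - round(c)) <= 1e-9


@dataclass
class BeatRecord:
    """Digitized detector samples for one displayed pattern."""

    order: int
    t_start: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise InvalidArgumentError("samples must be a 1-D array")

    def times(self, config: AcquisitionConfig) -> np.ndarray:
        """Absolute sample times on the global clock."""
        return self.t_start + np.arange(len(self.samples)) / config.sample_rate


def project_and_sum(obj: ComplexImage, pattern: Pattern) -> complex:
    """Spatial sum of the patterned transmitted field, (1/sqrt(N)) * sum O*P.

    For a binary pattern this is the measured coefficient a~_n; for a
    bipolar pattern it is the orthogonal-basis coefficient a_n.
    """
    if pattern.values.shape != (obj.side, obj.side):
        raise InvalidArgumentError(
            f"pattern shape {pattern.values.shape} does not match object side {obj.side}"
        )
    return complex(np.sum(obj.field * pattern.values) / obj.side)


def _beat_samples(
    coeffs: np.ndarray,
    t_starts: np.ndarray,
    dc_signals: np.ndarray,
    config: AcquisitionConfig,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Vectorised beat synthesis; rows are records, columns samples."""
    m = config.samples_per_record
    tau = np.arange(m) / config.sample_rate
    t = t_starts[:, None] + tau[None, :]
    carrier = np.cos(
        2.0 * np.pi * config.beat_freq * t + np.angle(coeffs)[:, None]
    )
    v = (
        config.dc_reference
        + dc_signals[:, None]
        + 2.0 * config.gain * np.abs(coeffs)[:, None] * carrier
    )
    if config.noise_rel > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        v = v + rng.standard_normal(v.shape) * (config.noise_rel * np.abs(v))
    return v


def synthesize_beat(
    coeff: complex,
    order: int,
    config: AcquisitionConfig,
    rng: np.random.Generator | None = None,
    t_start: float = 0.0,
    dc_signal: float = 0.0,
) -> BeatRecord:
    """Synthesize the digitized beat record for one measured coefficient."""
    if not np.isfinite(coeff):
        raise InvalidArgumentError("coefficient must be finite")
    samples = _beat_samples(
        np.array([coeff], dtype=np.complex128),
        np.array([t_start]),
        np.array([float(dc_signal)]),
        config,
        rng,
    )[0]
    return BeatRecord(order=int(order), t_start=float(t_start), samples=samples)


def _binary_coefficients_fast(obj: ComplexImage, plan: HadamardPlan, orders: np.ndarray):
    """All binary-pattern coefficients and per-pattern DC levels at once.

    Uses Ht_n = (H_n + H_1)/2: the binary coefficient is (a_n + a_1)/2
    where a_n comes from the fast transform of the field, and the
    transmitted intensity is the same combination of the transform of
    |O|^2.
    """
    u, v = plan.index_map(orders)
    a_grid = _fwht2_grid(obj.field, plan)
    coeffs = 0.5 * (a_grid[u, v] + a_grid[0, 0])
    i_grid = _fwht2_grid(np.abs(obj.field) ** 2, plan)
    dc = 0.5 * np.real(i_grid[u, v] + i_grid[0, 0])
    return coeffs, dc


def _binary_coefficients_direct(obj: ComplexImage, plan: HadamardPlan, orders: np.ndarray):
    """Per-pattern projection; O(N) per order, oracle for the fast path."""
    coeffs = np.empty(len(orders), dtype=np.complex128)
    dc = np.empty(len(orders))
    intensity = np.abs(obj.field) ** 2
    for i, n in enumerate(orders):
        pat = basis_pattern(plan, int(n), polarity="binary")
        coeffs[i] = project_and_sum(obj, pat)
        dc[i] = float(np.sum(intensity * pat.values) / obj.side)
    return coeffs, dc


def acquire(
    obj: ComplexImage,
    plan: HadamardPlan | None = None,
    sampling: SamplingPlan | None = None,
    config: AcquisitionConfig | None = None,
    seed: int | None = None,
    method: str = "fast",
) -> list[BeatRecord]:
    """Simulate a full acquisition: one beat record per sampled order.

    Records share one continuous global clock with
    ``t_start = (k-1) * refresh_time`` in sampling-path order.  The DC
    order 1 must be included (its record anchors the DC correction).

    ``method="fast"`` computes every coefficient at once with the fast
    transform; ``method="direct"`` projects pattern by pattern and serves
    as the brute-force oracle on small grids.
    """
    if plan is None:
        plan = HadamardPlan(obj.side)
    if obj.side != plan.side:
        raise InvalidArgumentError("object side does not match plan")
    if config is None:
        config = AcquisitionConfig()
    if sampling is None:
        sampling = SamplingPlan(plan, 1.0)
    orders = np.asarray(sampling.orders, dtype=np.int64)
    if 1 not in orders:
        raise InvalidArgumentError("sampling plan must include the DC order 1")
    if method == "fast":
        coeffs, dc = _binary_coefficients_fast(obj, plan, orders)
    elif method == "direct":
        coeffs, dc = _binary_coefficients_direct(obj, plan, orders)
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")
    t_starts = np.arange(len(orders)) * config.refresh_time
    rng = np.random.default_rng(config.seed if seed is None else seed)
    samples = _beat_samples(coeffs, t_starts, dc, config, rng)
    if config.discard_first:
        samples = samples[:, config.discard_first :]
        t_starts = t_starts + config.discard_first / config.sample_rate
    return [
        BeatRecord(order=int(n), t_start=float(t0), samples=row)
        for n, t0, row in zip(orders, t_starts, samples)
    ]
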
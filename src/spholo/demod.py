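"""Quadrature demodulation of beat records.

Phase stepping happens naturally in time: each record oscillates as
``a~_n * cos(2*pi*beat_freq*t + phi~_n)`` on top of a DC level, so a
three-parameter linear least-squares fit (DC plus a cosine/sine
quadrature pair at the known beat frequency, evaluated at the absolute
sample times) recovers the complex coefficient exactly when a record
spans an integer number of beat cycles and is noise-free.  The sign and
rotation convention is fixed here once: with fitted samples
``c0 + cc*cos(w t) + cs*sin(w t)`` the coefficient is
``(cc - i*cs) / (2*gain)``, which makes synthesize -> demodulate the
identity.
"""

from __future__ import annotations

import numpy as np

from .coefficients import CoefficientSet
from .exceptions import DegenerateFitError, InvalidArgumentError
from .forward import AcquisitionConfig, BeatRecord

__all__ = ["demodulate", "batch_demodulate"]

_MIN_SAMPLES = 3


def _design(times: np.ndarray, beat_freq: float) -> np.ndarray:
    w = 2.0 * np.pi * beat_freq * times
    return np.column_stack([np.ones_like(times), np.cos(w), np.sin(w)])


def _solve(design: np.ndarray, samples: np.ndarray, gain: float) -> complex:
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateFitError(
            "singular demodulation design (beat frequency zero or aliased sampling)"
        )
    sol, *_ = np.linalg.lstsq(design, samples, rcond=None)
    _, cc, cs = sol
    return complex((cc - 1j * cs) / (2.0 * gain))


def demodulate(record: BeatRecord, config: AcquisitionConfig) -> complex:
    """Recover the complex coefficient a~_n * exp(i*phi~_n) of one record.

    The fit uses absolute times from the record's ``t_start``, so the
    returned phase is referenced to the global clock t = 0.
    """
    if len(record.samples) < _MIN_SAMPLES:
        raise InvalidArgumentError(
            f"need at least {_MIN_SAMPLES} samples, got {len(record.samples)}"
        )
    if config.beat_freq <= 0:
        raise DegenerateFitError("beat frequency must be positive for demodulation")
    design = _design(record.times(config), config.beat_freq)
    return _solve(design, record.samples, config.gain)


def _shared_grid(records: list[BeatRecord], config: AcquisitionConfig) -> bool:
    """True when every record sees the same carrier phase grid.

    Holds when all records are equally long and each t_start contains an
    integer number of beat cycles, so a single design-matrix
    pseudoinverse applies to the whole batch.
    """
    m = len(records[0].samples)
    if any(len(r.samples) != m for r in records):
        return False
    starts = np.array([r.t_start for r in records])
    cycles = starts * config.beat_freq
    return bool(np.all(np.abs(cycles - np.round(cycles)) < 1e-6))


def batch_demodulate(records: list[BeatRecord], config: AcquisitionConfig) -> CoefficientSet:
    """Demodulate a full acquisition into a binary-kind coefficient set.

    When the pattern refresh locks an integer number of beat cycles, all
    records share one time grid modulo the beat period, and a single
    shared pseudoinverse is applied to the stacked samples; otherwise
    each record is fit individually with its absolute times.
    """
    if not records:
        raise InvalidArgumentError("no records to demodulate")
    orders = np.array([r.order for r in records], dtype=np.int64)
    if 1 not in orders:
        raise InvalidArgumentError("the DC record (order 1) is required")
    if any(len(r.samples) < _MIN_SAMPLES for r in records):
        raise InvalidArgumentError(f"every record needs at least {_MIN_SAMPLES} samples")
    if _shared_grid(records, config):
        design = _design(records[0].times(config), config.beat_freq)
        if np.linalg.matrix_rank(design) < 3:
            raise DegenerateFitError("singular demodulation design")
        pinv = np.linalg.pinv(design)
        stacked = np.stack([r.samples for r in records])  # (n_records, m)
        sol = pinv @ stacked.T  # (3, n_records)
        values = (sol[1] - 1j * sol[2]) / (2.0 * config.gain)
    else:
        values = np.array([demodulate(r, config) for r in records], dtype=np.complex128)
    return CoefficientSet(orders=orders, values=values, kind="binary")
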
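"""Coefficient containers and compressive sampling plans."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError

__all__ = ["CoefficientSet", "SamplingPlan"]

#: Coefficients measured with binary (0/1) patterns: the ``a~_n`` values.
KIND_BINARY = "binary"
#: Coefficients over the orthogonal bipolar basis: the ``a_n`` values.
KIND_BIPOLAR = "bipolar"


@dataclass
class CoefficientSet:
    """Complex pattern coefficients indexed by linear order.

    ``kind`` distinguishes coefficients measured with binary 0/1 patterns
    (``"binary"``, written a~_n) from orthogonal-basis coefficients
    (``"bipolar"``, written a_n); the two are related through the DC
    correction ``a_n = 2*a~_n - a~_1``.
    """

    orders: np.ndarray
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.orders = np.asarray(self.orders, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.orders.ndim != 1 or self.orders.shape != self.values.shape:
            raise InvalidArgumentError("orders and values must be matching 1-D arrays")
        if self.kind not in (KIND_BINARY, KIND_BIPOLAR):
            raise InvalidArgumentError(f"unknown coefficient kind {self.kind!r}")
        if np.any(self.orders < 1):
            raise InvalidArgumentError("orders are 1-based")
        if len(np.unique(self.orders)) != len(self.orders):
            raise InvalidArgumentError("duplicate orders")

    def __len__(self) -> int:
        return len(self.orders)

    def has(self, n: int) -> bool:
        return bool(np.any(self.orders == n))

    def value(self, n: int) -> complex:
        idx = np.flatnonzero(self.orders == n)
        if len(idx) == 0:
            raise InvalidArgumentError(f"order {n} not present")
        return complex(self.values[idx[0]])

    def subset(self, orders: np.ndarray) -> "CoefficientSet":
        """Restrict to the given orders (all must be present)."""
        orders = np.asarray(orders, dtype=np.int64)
        pos = {int(n): i for i, n in enumerate(self.orders)}
        try:
            idx = np.array([pos[int(n)] for n in orders], dtype=np.int64)
        except KeyError as e:  # pragma: no cover - message detail
            raise InvalidArgumentError(f"order {e.args[0]} not present") from None
        return CoefficientSet(orders=orders, values=self.values[idx], kind=self.kind)


class SamplingPlan:
    """Compressive sampling at ratio ``sr``: a prefix of the square path.

    ``sr`` is the ratio between the number of measured coefficients and
    the number of pixels in the reconstructed image; the retained orders
    are the first ``ceil(sr * N)`` entries of the square sampling path,
    which always include the DC order 1.
    """

    def __init__(self, plan, sr: float = 1.0):
        if not (0.0 < sr <= 1.0):
            raise InvalidArgumentError(f"sampling ratio must be in (0, 1], got {sr}")
        self.sr = float(sr)
        n_keep = int(np.ceil(self.sr * plan.n_total))
        self.orders = plan.path[:n_keep].copy()

    def __len__(self) -> int:
        return len(self.orders)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SamplingPlan(sr={self.sr}, n={len(self.orders)})"
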
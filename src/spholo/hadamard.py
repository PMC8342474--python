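"""Walsh-Hadamard bases, the 2-D fast transform and the square sampling path.

The object is decomposed over a complete set of N = side**2 orthogonal
bipolar (+1/-1) Hadamard patterns ``H_n``,

    O(r) = (1/sqrt(N)) * sum_n a_n * exp(i*phi_n) * H_n(r),

with symmetric normalisation so that the forward and inverse transforms
are unitary (Parseval holds).  Patterns are indexed in *sequency* order:
each 2-D basis is the outer product of two 1-D Walsh rows, identified by
a sequency pair (u, v), and the linear order n enumerates pairs along an
expanding square-shell path so that low spatial frequencies come first.
The binary (0/1) counterparts that a digital micromirror device can
display are related by ``H_n = 2*Ht_n - Ht_1`` where ``Ht_1`` is the
all-ones pattern.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from scipy.linalg import hadamard as _sylvester_hadamard

from .coefficients import CoefficientSet
from .exceptions import InvalidArgumentError
from .image import ComplexImage

__all__ = [
    "HadamardPlan",
    "Pattern",
    "walsh_sequency_matrix",
    "basis_pattern",
    "fwht2",
    "ifwht2",
    "square_path",
]


def _require_power_of_two(side: int) -> None:
    if side < 1 or (side & (side - 1)) != 0:
        raise InvalidArgumentError(f"side must be a positive power of 2, got {side}")


def walsh_sequency_matrix(m: int) -> np.ndarray:
    """Return the 2**m x 2**m Walsh matrix in sequency order.

    Row ``k`` (0-based) has exactly ``k`` sign changes; rows are mutually
    orthogonal with squared norm 2**m.
    """
    if m != int(m) or m < 0:
        raise InvalidArgumentError(f"m must be a non-negative integer, got {m}")
    n = 1 << int(m)
    h = _sylvester_hadamard(n)
    changes = np.count_nonzero(np.diff(h, axis=1), axis=1)
    return h[np.argsort(changes)]


@functools.lru_cache(maxsize=16)
def _sequency_perm(side: int) -> np.ndarray:
    """Permutation q with walsh_row[k] == sylvester_row[q[k]]."""
    h = _sylvester_hadamard(side)
    changes = np.count_nonzero(np.diff(h, axis=1), axis=1)
    q = np.argsort(changes)
    q.flags.writeable = False
    return q


@functools.lru_cache(maxsize=16)
def _square_path_pairs(side: int) -> np.ndarray:
    """Sequency pairs (u, v) in expanding square shells.

    Shell k holds all pairs with max(u, v) == k, visited (0,k)..(k,k)
    then (k,k-1)..(k,0).  The first pair is (0, 0), the DC basis.
    """
    pairs = [(0, 0)]
    for k in range(1, side):
        pairs.extend((u, k) for u in range(0, k + 1))
        pairs.extend((k, v) for v in range(k - 1, -1, -1))
    out = np.array(pairs, dtype=np.int64)
    out.flags.writeable = False
    return out


class HadamardPlan:
    """Indexing plan tying linear pattern orders to 2-D sequency pairs.

    Parameters
    ----------
    side
        Pixels per image edge; must be a power of 2.  Default 256, the
        superpixel count of the reference system.
    ordering
        ``"sequency"`` (default) uses Walsh rows ordered by sign-change
        count, so the linear order tracks spatial frequency.
        ``"natural"`` keeps raw Sylvester rows; intended for testing.

    The linear order ``n`` in 1..N enumerates sequency pairs along the
    square sampling path itself, so truncating at the first ``ceil(sr*N)``
    orders keeps exactly the low-frequency shells.
    """

    def __init__(self, side: int = 256, ordering: str = "sequency"):
        _require_power_of_two(side)
        if ordering not in ("sequency", "natural"):
            raise InvalidArgumentError(f"unknown ordering {ordering!r}")
        self.side = int(side)
        self.ordering = ordering
        self.n_total = self.side * self.side
        self.pairs = _square_path_pairs(self.side)  # (N, 2): pairs[n-1] = (u, v)
        self._order_of = np.empty((self.side, self.side), dtype=np.int64)
        self._order_of[self.pairs[:, 0], self.pairs[:, 1]] = np.arange(1, self.n_total + 1)

    @property
    def path(self) -> np.ndarray:
        """Square sampling path as linear orders (identity by construction)."""
        return np.arange(1, self.n_total + 1, dtype=np.int64)

    def index_map(self, n: int | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Sequency pair(s) (u, v) for linear order(s) n in 1..N."""
        n = np.asarray(n)
        if np.any(n < 1) or np.any(n > self.n_total):
            raise InvalidArgumentError(f"order out of range 1..{self.n_total}")
        uv = self.pairs[n - 1]
        return uv[..., 0], uv[..., 1]

    def order_of(self, u: int, v: int) -> int:
        """Linear order for a sequency pair."""
        if not (0 <= u < self.side and 0 <= v < self.side):
            raise InvalidArgumentError("sequency indices out of range")
        return int(self._order_of[u, v])

    def rows(self) -> np.ndarray:
        """The 1-D basis rows (sequency or natural ordering)."""
        if self.ordering == "sequency":
            return walsh_sequency_matrix(int(np.log2(self.side)))
        return _sylvester_hadamard(self.side)

    def __repr__(self) -> str:  # pragma: no cover
        return f"HadamardPlan(side={self.side}, ordering={self.ordering!r})"


@dataclass(frozen=True)
class Pattern:
    """One illumination pattern.

    ``polarity="bipolar"`` holds +1/-1 entries (the orthogonal basis);
    ``polarity="binary"`` holds 0/1 entries (displayable on a DMD).  The
    two forms of the same order satisfy ``binary == (bipolar + 1) / 2``.
    """

    values: np.ndarray
    polarity: str
    order: int


def basis_pattern(plan: HadamardPlan, n: int, polarity: str = "bipolar") -> Pattern:
    """Build the 2-D pattern of linear order ``n``.

    The bipolar pattern is the outer product of the 1-D rows picked by the
    plan's sequency pair (u, v); the binary pattern is ``(bipolar + 1)/2``.
    """
    if polarity not in ("bipolar", "binary"):
        raise InvalidArgumentError(f"unknown polarity {polarity!r}")
    if not (1 <= n <= plan.n_total):
        raise InvalidArgumentError(f"order {n} out of range 1..{plan.n_total}")
    u, v = plan.index_map(n)
    rows = plan.rows()
    bipolar = np.outer(rows[int(u)], rows[int(v)]).astype(np.int8)
    if polarity == "binary":
        return Pattern(values=((bipolar + 1) // 2).astype(np.int8), polarity="binary", order=n)
    return Pattern(values=bipolar, polarity="bipolar", order=n)


def _fwht1(a: np.ndarray) -> np.ndarray:
    """Unnormalised fast Walsh-Hadamard butterfly along axis 0 (natural order)."""
    n = a.shape[0]
    a = np.array(a, copy=True)
    trailing = a.shape[1:]
    h = 1
    while h < n:
        a = a.reshape(n // (2 * h), 2, h, *trailing)
        top = a[:, 0] + a[:, 1]
        bot = a[:, 0] - a[:, 1]
        a[:, 0] = top
        a[:, 1] = bot
        a = a.reshape(n, *trailing)
        h *= 2
    return a


def _fwht2_grid(x: np.ndarray, plan: HadamardPlan) -> np.ndarray:
    """Sequency-indexed 2-D transform grid C[u, v] = (W x W^T / side)[u, v]."""
    t = _fwht1(_fwht1(x).T).T
    if plan.ordering == "sequency":
        q = _sequency_perm(plan.side)
        t = t[np.ix_(q, q)]
    return t / plan.side


def _ifwht2_grid(c: np.ndarray, plan: HadamardPlan) -> np.ndarray:
    """Inverse of :func:`_fwht2_grid` (symmetric normalisation)."""
    if plan.ordering == "sequency":
        q = _sequency_perm(plan.side)
        t = np.zeros_like(c)
        t[np.ix_(q, q)] = c
    else:
        t = c
    return _fwht1(_fwht1(t).T).T / plan.side


def _as_field(image: ComplexImage | np.ndarray) -> np.ndarray:
    if isinstance(image, ComplexImage):
        return image.field
    return np.asarray(image, dtype=np.complex128)


def fwht2(image: ComplexImage | np.ndarray, plan: HadamardPlan | None = None) -> CoefficientSet:
    """Forward 2-D fast Walsh-Hadamard transform to bipolar coefficients.

    Symmetric normalisation: the returned coefficient of order n equals
    ``(1/sqrt(N)) * sum_r x(r) * H_n(r)``, so ``ifwht2(fwht2(x)) == x``
    and total energy is preserved.  Runs in O(N log N).
    """
    x = _as_field(image)
    if x.ndim != 2 or x.shape[0] != x.shape[1]:
        raise InvalidArgumentError("image must be square")
    if plan is None:
        plan = HadamardPlan(x.shape[0])
    if x.shape[0] != plan.side:
        raise InvalidArgumentError(
            f"image side {x.shape[0]} does not match plan side {plan.side}"
        )
    grid = _fwht2_grid(x, plan)
    values = grid[plan.pairs[:, 0], plan.pairs[:, 1]]
    return CoefficientSet(orders=plan.path, values=values, kind="bipolar")


def ifwht2(coeffs: CoefficientSet, plan: HadamardPlan) -> ComplexImage:
    """Inverse transform; orders absent from ``coeffs`` are treated as zero."""
    grid = np.zeros((plan.side, plan.side), dtype=np.complex128)
    u, v = plan.index_map(coeffs.orders)
    grid[u, v] = coeffs.values
    field = _ifwht2_grid(grid, plan)
    return ComplexImage.from_field(field)


def square_path(plan: HadamardPlan) -> np.ndarray:
    """Linear orders along the square (shell-by-shell) sampling path.

    Shells of constant max(u, v) are visited in order of increasing shell
    index, so spatial frequency is non-decreasing shell by shell; the
    first element is the DC order 1.
    """
    return plan.path
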
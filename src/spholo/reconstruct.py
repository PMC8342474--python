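"""DC correction and compressive image reconstruction.

Binary 0/1 patterns are not orthogonal, but their coefficients map onto
the orthogonal bipolar basis through the DC measurement alone:

    a_n = 2 * a~_n - a~_1          (identity at n = 1).

Reconstruction is the direct inverse fast Hadamard transform of the
corrected coefficients, with unmeasured orders zero-filled — the
compressive-sensing strategy of truncating the square sampling path at a
chosen sampling ratio.  The output phase stays wrapped in (-pi, pi].
"""

from __future__ import annotations

import numpy as np

from .coefficients import CoefficientSet, SamplingPlan
from .exceptions import InvalidArgumentError
from .hadamard import HadamardPlan, ifwht2
from .image import ComplexImage

__all__ = ["dc_correct", "reconstruct_image", "SamplingPlan", "CoefficientSet"]


def dc_correct(coeffs: CoefficientSet) -> CoefficientSet:
    """Convert binary-pattern coefficients a~_n to bipolar a_n = 2 a~_n - a~_1."""
    if coeffs.kind != "binary":
        raise InvalidArgumentError("dc_correct expects binary-kind coefficients")
    if not coeffs.has(1):
        raise InvalidArgumentError("DC coefficient (order 1) required for correction")
    a1 = coeffs.value(1)
    values = 2.0 * coeffs.values - a1
    values[coeffs.orders == 1] = a1  # n = 1 reduces to the identity
    return CoefficientSet(orders=coeffs.orders.copy(), values=values, kind="bipolar")


def reconstruct_image(
    coeffs: CoefficientSet,
    plan: HadamardPlan,
    sampling: SamplingPlan | None = None,
) -> ComplexImage:
    """Zero-filled inverse transform of corrected coefficients.

    When a sampling plan is given the coefficients must cover its orders
    and only those orders are used; everything else is exactly zero.
    """
    if coeffs.kind != "bipolar":
        raise InvalidArgumentError(
            "reconstruct_image expects bipolar (DC-corrected) coefficients"
        )
    used = coeffs if sampling is None else coeffs.subset(sampling.orders)
    return ifwht2(used, plan)
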
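"""Scalar measured values with 1-sigma uncertainties.

Uncertainties are propagated to first order assuming independent Gaussian
errors; relative errors of products combine in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError


@dataclass(frozen=True)
class Measurement:
    """A central value with a 1-sigma uncertainty."""

    value: float
    err: float = 0.0

    def __post_init__(self):
        if self.err < 0:
            raise InvalidParameterError("uncertainty must be >= 0")

    @property
    def rel(self) -> float:
        """Relative error |err/value|."""
        if self.value == 0:
            return math.inf if self.err else 0.0
        return abs(self.err / self.value)

    def scaled(self, factor: float) -> "Measurement":
        return Measurement(self.value * factor, self.err * abs(factor))

    def __format__(self, spec: str) -> str:
        spec = spec or ".3g"
        return f"{self.value:{spec}} ± {self.err:{spec}}"

    def __str__(self) -> str:
        return format(self)


def as_measurement(x) -> Measurement:
    """Coerce a float, (value, err) pair or Measurement to a Measurement."""
    if isinstance(x, Measurement):
        return x
    if isinstance(x, (tuple, list)) and len(x) == 2:
        return Measurement(float(x[0]), float(x[1]))
    return Measurement(float(x))


def propagate_product_uncertainty(x: Measurement, y: Measurement) -> float:
    """1-sigma error of x*y with independent errors: |xy|*sqrt((sx/x)^2+(sy/y)^2)."""
    if x.value <= 0 or y.value <= 0:
        raise InvalidParameterError("central values must be positive")
    return abs(x.value * y.value) * math.hypot(x.rel, y.rel)


def product(x: Measurement, y: Measurement, scale: float = 1.0) -> Measurement:
    """Product of two independent measurements, optionally rescaled."""
    return Measurement(x.value * y.value * scale,
                       propagate_product_uncertainty(x, y) * abs(scale))
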
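"""Geometric bridge between steric coverage, adhesive coverage and flat fraction.

An adsorbed vesicle blocks its projection area A_ex on the plane but is in
molecular contact only over its flat patch A_f = alpha_f * A.  With N vesicles
on a plane of area A_tot:

    rho = N A_ex / A_tot    (steric coverage, what RSA jams)
    eta = N A_f  / A_tot    (adhesive coverage, what reflectivity measures)

A_ex interpolates almost linearly between the sphere (A/4) and the fully
flattened limit (A/2): A_ex ~= A (1 + 2 alpha_f) / 4, which inverts to

    alpha_f ~= 1 / (4 rho/eta - 2).

Uncertainties are propagated to first order assuming independent errors.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import CoverageDomainError, InvalidParameterError
from .measurement import Measurement, as_measurement

__all__ = [
    "steric_coverage",
    "adhesive_coverage_from_solvent",
    "extension_area_linear",
    "alpha_from_coverages",
    "eta_from_rho",
]


def steric_coverage(n: int, a_ex, a_tot: float) -> float:
    """rho = sum of projection areas / total area.

    ``a_ex`` may be a single area (equal disks: rho = n*a_ex/a_tot) or an
    array of per-vesicle projection areas of length n.
    """
    if a_tot <= 0:
        raise InvalidParameterError("a_tot must be positive")
    if n < 0:
        raise InvalidParameterError("n must be >= 0")
    a_ex = np.asarray(a_ex, dtype=float)
    if a_ex.ndim == 0:
        total = n * float(a_ex)
    else:
        if len(a_ex) != n:
            raise InvalidParameterError("len(a_ex) must equal n")
        total = float(np.sum(a_ex))
    rho = total / a_tot
    if rho >= 1.0:
        raise CoverageDomainError(f"steric coverage {rho:.3f} >= 1 is inconsistent")
    return rho


def adhesive_coverage_from_solvent(h_chain2) -> Measurement:
    """eta = 1 - h_chain2: coverage of the second bilayer from its chain-slab
    solvent fraction (the hydrophobic chains of a covered patch are water-free).
    """
    h = as_measurement(h_chain2)
    if not 0.0 <= h.value <= 1.0:
        raise InvalidParameterError("solvent fraction must be within [0, 1]")
    return Measurement(1.0 - h.value, h.err)


def extension_area_linear(alpha_f: float, area: float) -> float:
    """A_ex ~= area * (1 + 2 alpha_f) / 4 (exact at both endpoints)."""
    if not 0.0 <= alpha_f <= 0.5:
        raise InvalidParameterError("alpha_f must be within [0, 0.5]")
    if area <= 0:
        raise InvalidParameterError("area must be positive")
    return area * (1.0 + 2.0 * alpha_f) / 4.0


def alpha_from_coverages(rho, eta) -> Measurement:
    """Flat-area fraction alpha_f = 1/(4 rho/eta - 2) with propagated error.

    Requires rho/eta > 1/2 (a contact patch cannot exceed its projection;
    physically rho >= eta so the ratio is >= 1).
    """
    rho = as_measurement(rho)
    eta = as_measurement(eta)
    if rho.value <= 0 or eta.value <= 0:
        raise InvalidParameterError("coverages must be positive")
    u = rho.value / eta.value
    if u <= 0.5:
        raise CoverageDomainError(
            f"rho/eta = {u:.3f} <= 1/2: physically impossible coverage pair")
    alpha = 1.0 / (4.0 * u - 2.0)
    # d(alpha)/du = -4 alpha^2; independent errors on rho and eta
    s_u = u * math.hypot(rho.rel, eta.rel)
    return Measurement(alpha, 4.0 * alpha * alpha * s_u)


def eta_from_rho(rho: float, alpha_f: float) -> float:
    """Forward map eta = rho * 4 alpha_f / (1 + 2 alpha_f) (inverse of
    :func:`alpha_from_coverages` at central values)."""
    if not 0.0 <= alpha_f <= 0.5:
        raise InvalidParameterError("alpha_f must be within [0, 0.5]")
    return rho * 4.0 * alpha_f / (1.0 + 2.0 * alpha_f)
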
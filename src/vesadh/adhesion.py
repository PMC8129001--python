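"""Adhesion energy per MBP molecule.

The adhesion constant k_a (energy gain per unit contact area, mJ/m^2) times
the membrane area occupied by one myelin basic protein, A_MBP (nm^2), gives
the adhesion energy contributed by a single protein:

    eps_MBP = k_a * A_MBP        (1 mJ/m^2 * 1 nm^2 = 1e-21 J)

reported in units of 1e-19 J (a few k_B T).  Relative errors combine in
quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import InvalidParameterError
from .measurement import Measurement, as_measurement, product
from .measurement import propagate_product_uncertainty  # noqa: F401  (re-export)

__all__ = ["AdhesionResult", "energy_per_mbp", "propagate_product_uncertainty"]

_MJ_M2_NM2_TO_1E19_J = 1e-2  # 1 mJ/m^2 * nm^2 = 1e-21 J = 1e-2 * 1e-19 J


def energy_per_mbp(ka, a_mbp) -> Measurement:
    """Adhesion energy per protein, in 1e-19 J, from k_a (mJ/m^2) and A_MBP (nm^2)."""
    ka = as_measurement(ka)
    a_mbp = as_measurement(a_mbp)
    if ka.value < 0 or a_mbp.value < 0:
        raise InvalidParameterError("ka and a_mbp must be non-negative")
    if a_mbp.value == 0 or ka.value == 0:
        return Measurement(0.0, 0.0)
    return product(ka, a_mbp, scale=_MJ_M2_NM2_TO_1E19_J)


@dataclass(frozen=True)
class AdhesionResult:
    """One membrane's row of the adhesion analysis (all errors 1 sigma)."""

    label: str
    eta: Measurement              # adhesive coverage
    alpha_f: Measurement          # flat-area fraction
    ka: Measurement               # mJ/m^2
    a_mbp: Measurement            # nm^2
    eps_mbp: Measurement          # 1e-19 J
    rho: Optional[Measurement] = None   # steric coverage used
    caveat: str = ""

    def __post_init__(self):
        for name in ("eta", "alpha_f", "ka", "a_mbp", "eps_mbp"):
            if getattr(self, name).value <= 0:
                raise InvalidParameterError(f"{name} central value must be positive")

    def report(self) -> str:
        lines = [
            f"membrane        : {self.label}",
            f"eta             : {self.eta:.3f}",
            f"alpha_f         : {self.alpha_f:.3f}",
            f"k_a   (mJ/m^2)  : {self.ka:.3f}",
            f"A_MBP (nm^2)    : {self.a_mbp:.3g}",
            f"eps_MBP (1e-19J): {self.eps_mbp:.3f}",
        ]
        if self.rho is not None:
            lines.insert(1, f"rho_inf         : {self.rho:.3f}")
        if self.caveat:
            lines.append(f"caveat          : {self.caveat}")
        return "\n".join(lines)

    def row(self) -> dict:
        out = {"label": self.label}
        for name in ("rho", "eta", "alpha_f", "ka", "a_mbp", "eps_mbp"):
            m = getattr(self, name)
            if m is None:
                continue
            out[name] = m.value
            out[name + "_err"] = m.err
        if self.caveat:
            out["caveat"] = self.caveat
        return out
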
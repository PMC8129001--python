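"""Least-energy axisymmetric shapes of vesicles adhered to a plane.

Model
-----
A vesicle of fixed membrane area A (no volume constraint, no spontaneous
curvature) adheres to a flat substrate over a circular contact disk covering
the fraction ``alpha_f`` of its area.  Its free energy is

    E_free = -k_a * alpha_f * A  +  E_b,
    E_b    = (kappa/2) * integral (c1 + c2)^2 dA,

the Helfrich bending energy over the curved part (the flat disk contributes
nothing).  The least-energy surface is a solid of revolution; its generatrix
is described by the tangent angle psi(s) versus arclength s, running from the
contact line (psi = 0, r = r_c) to the apex on the axis (psi = pi, r = 0).
Curvature continuity with the flat disk imposes dpsi/ds = 0 at the contact
line.  The principal curvatures are c1 = dpsi/ds and c2 = sin(psi)/r, with
the regular limit c2 -> c1 at the apex.

In reduced units (lengths in R0 = sqrt(A/4pi), energies in kappa) the reduced
bending energy depends on alpha_f only, so a single E_b(alpha_f) curve serves
every (kappa, R) pair.  The sphere is the unconstrained minimum with
E_b(0) = 8 pi kappa, and E_b grows monotonically with alpha_f.

Numerics
--------
psi is parametrized spectrally on t = s/L in [0, 1]:

    psi(t) = pi (3 t^2 - 2 t^3) + sum_k a_k t sin(k pi t),

which satisfies psi(0) = 0, psi'(0) = 0, psi(1) = pi identically for any
coefficients.  The unknowns (a_1..a_K, L) are found by SLSQP minimization of
the quadrature energy under two equality constraints: closure of the profile
on the axis, r(L) = 0, and conservation of the curved area.  A continuation
sweep in alpha_f warm-starts each solve from the previous one.  (Direct
minimization over nodal psi values and Euler-Lagrange shooting were both
found numerically fragile for this boundary-value problem.)

The inversion measured-alpha_f -> k_a uses the stationarity of E_free:
k_a = (1/A) dE_b/dalpha_f, evaluated by central differences on the
minimized-energy curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, minimize

from .errors import InvalidParameterError, InvalidShapeError, SolverError
from .measurement import Measurement, as_measurement

__all__ = [
    "MembraneMechanics",
    "ShapeSolution",
    "EnergyCurve",
    "EnergyLandscape",
    "SPHERE_REDUCED_ENERGY",
    "minimize_shape",
    "bending_energy",
    "bending_energy_reduced",
    "extension_area",
    "bending_energy_curve",
    "free_energy",
    "ka_from_alpha",
    "alpha_from_ka",
    "build_energy_landscape",
]

SPHERE_REDUCED_ENERGY = 8.0 * np.pi
ALPHA_MAX_VALIDATED = 0.45

_MJ_M2 = 1e-3  # J/m^2 per mJ/m^2


@dataclass(frozen=True)
class MembraneMechanics:
    """Membrane bending rigidity and vesicle size.

    ``kappa`` is the Helfrich mean-curvature modulus in J (may carry an
    uncertainty); ``vesicle_radius`` is the radius (nm) of the sphere with the
    same membrane area, which stays fixed on adhesion.
    """

    kappa: Measurement
    vesicle_radius: float  # nm

    def __post_init__(self):
        object.__setattr__(self, "kappa", as_measurement(self.kappa))
        if self.kappa.value <= 0:
            raise InvalidParameterError("kappa must be positive")
        if self.vesicle_radius <= 0:
            raise InvalidParameterError("vesicle_radius must be positive")

    @property
    def area(self) -> float:
        """Total membrane area in nm^2 (= 4 pi R^2)."""
        return 4.0 * np.pi * self.vesicle_radius ** 2

    @property
    def area_m2(self) -> float:
        return self.area * 1e-18


@dataclass
class ShapeSolution:
    """Discretized least-energy generatrix at a given flat fraction.

    Geometry is stored in reduced units (lengths in R0 = sqrt(area/4pi)).
    ``bending_energy_reduced`` is in units of kappa; 8 pi for the sphere.
    """

    alpha_f: float
    arc_mesh: np.ndarray        # arclength s, reduced
    psi: np.ndarray             # tangent angle (rad)
    r: np.ndarray               # generatrix radius, reduced
    z: np.ndarray               # generatrix height, reduced
    bending_energy_reduced: float
    contact_radius: float       # reduced
    coefficients: Optional[np.ndarray] = None  # spectral coefficients + L

    def __post_init__(self):
        if not 0.0 <= self.alpha_f < 0.5:
            raise InvalidShapeError("alpha_f must lie in [0, 0.5)")
        if np.any(self.r < -1e-9):
            raise InvalidShapeError("generatrix radius must be non-negative")
        if np.any(np.diff(self.arc_mesh) <= 0):
            raise InvalidShapeError("arclength mesh must be strictly increasing")

    @property
    def extension_radius(self) -> float:
        """Maximum in-plane radius (reduced units)."""
        return float(np.max(self.r))

    @property
    def area_reduced(self) -> float:
        """Total reduced area: flat disk + curved surface of revolution."""
        curved = np.trapezoid(2.0 * np.pi * self.r, self.arc_mesh)
        return float(np.pi * self.contact_radius ** 2 + curved)


# ---------------------------------------------------------------------------
# spectral discretization


@lru_cache(maxsize=8)
def _basis(n_modes: int, n_nodes: int):
    t = np.linspace(0.0, 1.0, n_nodes + 1)
    carrier = np.pi * (3.0 * t ** 2 - 2.0 * t ** 3)
    modes = np.stack([t * np.sin(k * np.pi * t) for k in range(1, n_modes + 1)])
    return t, carrier, modes


def _fields(x: np.ndarray, rc: float, carrier, modes, n_nodes: int):
    a, L = x[:-1], x[-1]
    psi = carrier + a @ modes
    h = L / n_nodes
    c = np.cos(psi)
    r = rc + h * np.concatenate(([0.0], np.cumsum(0.5 * (c[1:] + c[:-1]))))
    return psi, r, h


def _reduced_energy(psi: np.ndarray, r: np.ndarray, h: float) -> float:
    u = np.gradient(psi, h)
    rsafe = np.where(np.abs(r) < 1e-9, 1e-9, r)
    c2 = np.sin(psi) / rsafe
    c2[-1] = u[-1]  # apex: sin(psi)/r -> dpsi/ds
    integrand = (u + c2) ** 2 * 2.0 * np.pi * np.abs(r)
    return 0.5 * float(np.trapezoid(integrand, dx=h))


def _sphere_solution(alpha_f: float, n_nodes: int) -> ShapeSolution:
    s = np.linspace(0.0, np.pi, n_nodes + 1)
    psi = s.copy()
    r = np.sin(s)
    z = 1.0 - np.cos(s)
    return ShapeSolution(alpha_f=alpha_f, arc_mesh=s, psi=psi, r=r, z=z,
                         bending_energy_reduced=SPHERE_REDUCED_ENERGY,
                         contact_radius=0.0)


def _solve_reduced(alpha_f: float, n_modes: int, n_nodes: int,
                   tol: float, x0: Optional[np.ndarray]):
    rc = 2.0 * np.sqrt(alpha_f)
    target_area = 4.0 * np.pi * (1.0 - alpha_f)
    t, carrier, modes = _basis(n_modes, n_nodes)

    def fields(x):
        return _fields(x, rc, carrier, modes, n_nodes)

    def objective(x):
        psi, r, h = fields(x)
        return _reduced_energy(psi, r, h)

    def closure(x):
        return fields(x)[1][-1]

    def area(x):
        psi, r, h = fields(x)
        return float(np.trapezoid(2.0 * np.pi * r, dx=h)) - target_area

    if x0 is None:
        x0 = np.concatenate([np.zeros(n_modes), [np.pi * (1.0 - alpha_f / 2.0)]])
    constraints = [{"type": "eq", "fun": closure},
                   {"type": "eq", "fun": area}]
    bounds = [(-4.0, 4.0)] * n_modes + [(0.5, 8.0)]
    x, success = x0, False
    for ftol in (tol, tol * 100.0):
        res = minimize(objective, x, method="SLSQP", constraints=constraints,
                       bounds=bounds, options={"maxiter": 800, "ftol": ftol})
        x = res.x
        if res.success:
            success = True
            break
    resid = abs(closure(x)) + abs(area(x)) / (4.0 * np.pi)
    if resid > 1e-6 or not np.isfinite(res.fun):
        raise SolverError(
            f"shape solve at alpha_f={alpha_f:.3f} violates constraints "
            f"({res.message})", residual=resid)
    if not success:
        # SLSQP stalled below its ftol with numerical gradients; constraints
        # hold, so the stalled point is the minimum to within gradient noise
        warnings.warn(f"shape solve at alpha_f={alpha_f:.3f} stalled at the "
                      f"iteration limit (constraints satisfied; accepted)")
    psi, r, h = fields(x)
    return x, psi, r, h, objective(x)


def minimize_shape(alpha_f: float, mech: Optional[MembraneMechanics] = None,
                   n_nodes: int = 600, tol: float = 1e-10,
                   n_modes: int = 32,
                   x0: Optional[np.ndarray] = None) -> ShapeSolution:
    """Least-energy adhered-vesicle shape at fixed area and flat fraction.

    ``alpha_f = 0`` returns the analytic sphere.  For 0 < alpha_f <= 0.45 the
    reduced problem is solved as described in the module docstring; a cold
    start sweeps up from small alpha_f internally, so calling with ``x0=None``
    is always safe (warm starts via ``x0`` are just faster).
    """
    if not 0.0 <= alpha_f <= ALPHA_MAX_VALIDATED:
        raise InvalidParameterError(
            f"alpha_f={alpha_f} outside validated range [0, {ALPHA_MAX_VALIDATED}]")
    if n_nodes < 50:
        raise InvalidParameterError("n_nodes must be >= 50")
    if alpha_f == 0.0:
        return _sphere_solution(0.0, n_nodes)

    if x0 is None and alpha_f > 0.061:
        # continuation from small alpha for robustness
        for a in np.arange(0.04, alpha_f - 1e-12, 0.02):
            x0, *_ = _solve_reduced(float(a), n_modes, n_nodes, tol, x0)
    x, psi, r, h, energy = _solve_reduced(alpha_f, n_modes, n_nodes, tol, x0)
    s = np.arange(n_nodes + 1) * h
    z = np.concatenate(([0.0], np.cumsum(
        0.5 * (np.sin(psi[1:]) + np.sin(psi[:-1])) * h)))
    return ShapeSolution(alpha_f=alpha_f, arc_mesh=s, psi=psi,
                         r=np.clip(r, 0.0, None), z=z,
                         bending_energy_reduced=energy,
                         contact_radius=2.0 * np.sqrt(alpha_f),
                         coefficients=x)


def bending_energy_reduced(shape: ShapeSolution) -> float:
    """Reduced Helfrich bending energy of a discretized shape (units of kappa).

    Re-evaluates the quadrature on the stored mesh; accepts any valid shape
    (e.g. an exact sphere discretization), not only solver output.
    """
    if np.any(shape.r < -1e-12):
        raise InvalidShapeError("generatrix radius must be non-negative")
    ds = np.diff(shape.arc_mesh)
    if np.any(ds <= 0):
        raise InvalidShapeError("duplicate or non-monotone mesh nodes")
    h = float(ds[0])
    return _reduced_energy(shape.psi, shape.r, h)


def bending_energy(shape: ShapeSolution, mech: MembraneMechanics) -> float:
    """Physical bending energy in J: kappa times the reduced energy."""
    return mech.kappa.value * bending_energy_reduced(shape)


def extension_area(shape: ShapeSolution,
                   mech: Optional[MembraneMechanics] = None) -> float:
    """Projection area pi * r_max^2; in nm^2 if mechanics given, else reduced."""
    a = np.pi * shape.extension_radius ** 2
    if mech is not None:
        a *= mech.vesicle_radius ** 2
    return float(a)


# ---------------------------------------------------------------------------
# the E_b(alpha_f) curve and the k_a <-> alpha_f inversion


@dataclass
class EnergyCurve:
    """Reduced bending-energy curve E_b(alpha_f)/kappa with interpolation."""

    alphas: np.ndarray
    energies: np.ndarray   # units of kappa
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.alphas = np.asarray(self.alphas, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.alphas.size < 4:
            raise InvalidParameterError("energy curve needs >= 4 grid points")
        if np.any(np.diff(self.alphas) <= 0):
            raise InvalidParameterError("alpha grid must be strictly increasing")
        self._interp = PchipInterpolator(self.alphas, self.energies)
        self._deriv = self._interp.derivative()

    def energy(self, alpha_f: float) -> float:
        self._check_range(alpha_f)
        return float(self._interp(alpha_f))

    def slope(self, alpha_f: float) -> float:
        """dE_b/dalpha_f in units of kappa."""
        self._check_range(alpha_f)
        return float(self._deriv(alpha_f))

    def _check_range(self, alpha_f) -> None:
        if np.any(alpha_f < self.alphas[0] - 1e-12) or \
                np.any(alpha_f > self.alphas[-1] + 1e-12):
            raise InvalidParameterError(
                f"alpha_f={alpha_f} outside curve domain "
                f"[{self.alphas[0]:.3f}, {self.alphas[-1]:.3f}]")

    @property
    def domain(self):
        return float(self.alphas[0]), float(self.alphas[-1])

    def save(self, path) -> None:
        header = "\n".join(
            [f"{k} = {v}" for k, v in sorted(self.metadata.items())]
            + ["columns: alpha_f  E_b_over_kappa"])
        np.savetxt(path, np.column_stack([self.alphas, self.energies]),
                   header=header)

    @classmethod
    def load(cls, path) -> "EnergyCurve":
        data = np.atleast_2d(np.loadtxt(path))
        return cls(alphas=data[:, 0], energies=data[:, 1])


def bending_energy_curve(alpha_min: float = 0.02, alpha_max: float = 0.25,
                         step: float = 0.005, n_modes: int = 32,
                         n_nodes: int = 600, tol: float = 1e-10,
                         include_sphere: bool = True) -> EnergyCurve:
    """Sweep alpha_f with warm-started solves and return the reduced E_b curve.

    The sweep is the expensive step of the whole analysis (seconds per grid
    point); the returned curve can be cached to disk with
    :meth:`EnergyCurve.save` and reused for any (kappa, R).
    """
    if alpha_max > ALPHA_MAX_VALIDATED:
        raise InvalidParameterError(
            f"alpha_max > validated limit {ALPHA_MAX_VALIDATED}")
    alphas = np.round(np.arange(alpha_min, alpha_max + step / 2, step), 10)
    energies = []
    x0 = None
    for a in alphas:
        x0, psi, r, h, e = _solve_reduced(float(a), n_modes, n_nodes, tol, x0)
        energies.append(e)
    alphas = list(alphas)
    if include_sphere and alphas[0] > 0.0:
        alphas = [0.0] + alphas
        energies = [SPHERE_REDUCED_ENERGY] + energies
    return EnergyCurve(np.array(alphas), np.array(energies),
                       metadata={"n_modes": n_modes, "n_nodes": n_nodes,
                                 "tol": tol})


def _ka_from_reduced_slope(slope: float, mech: MembraneMechanics) -> float:
    """Convert dE_b/dalpha (kappa units) to k_a in mJ/m^2."""
    return mech.kappa.value * slope / mech.area_m2 / _MJ_M2


def ka_from_alpha(alpha_f: float, mech: MembraneMechanics,
                  curve: Optional[EnergyCurve] = None,
                  dalpha: float = 0.005, n_modes: int = 32,
                  n_nodes: int = 600) -> Measurement:
    """Adhesion constant from a measured flat fraction: k_a = (1/A) dE_b/dalpha_f.

    The derivative is a central difference with step ``dalpha`` on the
    minimized-energy curve (fresh warm-started solves if no precomputed curve
    is supplied).  The uncertainty reflects kappa's relative error only;
    use :func:`vesadh.pipeline.run_pipeline` for full propagation including
    the alpha_f error.
    """
    if dalpha <= 1e-4:
        raise InvalidParameterError("dalpha too small: solver noise dominates")
    if alpha_f - dalpha <= 0 or alpha_f + dalpha > ALPHA_MAX_VALIDATED:
        raise InvalidParameterError("alpha_f +/- dalpha outside validated range")
    if curve is not None:
        lo, hi = curve.domain
        if not (lo <= alpha_f - dalpha and alpha_f + dalpha <= hi):
            raise InvalidParameterError("alpha_f outside precomputed curve domain")
        e_lo = curve.energy(alpha_f - dalpha)
        e_hi = curve.energy(alpha_f + dalpha)
    else:
        x0 = None
        for a in np.arange(0.04, alpha_f - dalpha - 1e-12, 0.02):
            x0, *_ = _solve_reduced(float(a), n_modes, n_nodes, 1e-10, x0)
        x0, _, _, _, e_lo = _solve_reduced(alpha_f - dalpha, n_modes, n_nodes,
                                           1e-10, x0)
        x1, *_ = _solve_reduced(alpha_f, n_modes, n_nodes, 1e-10, x0)
        e_hi = _solve_reduced(alpha_f + dalpha, n_modes, n_nodes, 1e-10, x1)[4]
    slope = (e_hi - e_lo) / (2.0 * dalpha)
    if slope <= 0:
        raise SolverError("non-positive dE_b/dalpha_f: curve not convex here",
                          residual=slope)
    ka = _ka_from_reduced_slope(slope, mech)
    return Measurement(ka, ka * mech.kappa.rel)


def free_energy(alpha_f: float, ka: float, mech: MembraneMechanics,
                eb_curve: EnergyCurve) -> float:
    """E_free(alpha_f; k_a) = -k_a alpha_f A + E_b(alpha_f), in J."""
    adhesion = -ka * _MJ_M2 * alpha_f * mech.area_m2
    return adhesion + mech.kappa.value * eb_curve.energy(alpha_f)


def alpha_from_ka(ka: float, mech: MembraneMechanics,
                  eb_curve: EnergyCurve) -> float:
    """Flat fraction minimizing E_free at a given adhesion constant.

    Solves the stationarity condition dE_b/dalpha = k_a A on the precomputed
    curve (monotone slope: E_b is convex).  k_a outside the slope range spanned
    by the curve returns the grid edge with a warning, never a silent clamp.
    """
    if ka < 0:
        raise InvalidParameterError("ka must be >= 0")
    if ka == 0:
        return 0.0
    target = ka * _MJ_M2 * mech.area_m2 / mech.kappa.value  # reduced slope
    lo, hi = eb_curve.domain
    # restrict to the solved part of the grid (exclude the analytic 0 point
    # where the pchip slope is not meaningful)
    solved_lo = eb_curve.alphas[1] if eb_curve.alphas[0] == 0.0 else lo
    f = lambda a: eb_curve.slope(a) - target
    f_lo, f_hi = f(solved_lo), f(hi)
    if f_lo > 0:
        warnings.warn(f"ka={ka:.3g} mJ/m^2 below the curve's slope range; "
                      f"returning grid edge alpha={solved_lo:.3f}")
        return float(solved_lo)
    if f_hi < 0:
        warnings.warn(f"ka={ka:.3g} mJ/m^2 above the curve's slope range; "
                      f"returning grid edge alpha={hi:.3f}")
        return float(hi)
    return float(brentq(f, solved_lo, hi, xtol=1e-6))


@dataclass
class EnergyLandscape:
    """E_free on a (alpha_f, k_a) grid; the valley floor tracks alpha(k_a)."""

    alpha_grid: np.ndarray
    eb_curve: np.ndarray        # J
    ka_grid: np.ndarray         # mJ/m^2
    free_energy: np.ndarray     # J, shape (len(alpha_grid), len(ka_grid))


def build_energy_landscape(curve: EnergyCurve, mech: MembraneMechanics,
                           ka_grid) -> EnergyLandscape:
    ka_grid = np.asarray(ka_grid, dtype=float)
    alpha = curve.alphas
    eb = mech.kappa.value * curve.energies
    adhesion = -np.outer(alpha, ka_grid) * _MJ_M2 * mech.area_m2
    return EnergyLandscape(alpha_grid=alpha, eb_curve=eb, ka_grid=ka_grid,
                           free_energy=adhesion + eb[:, None])
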
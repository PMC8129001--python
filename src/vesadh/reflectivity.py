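"""Synthetic specular neutron reflectivity of supported-membrane slab stacks.

Forward model
-------------
Specular reflectivity R(q) of a stratified medium is computed by the Abeles /
Parratt recursion with Gaussian-roughness (Nevot-Croce) interface damping.
Each slab carries a dry scattering length density (SLD); solvent penetration
mixes it linearly with the buffer SLD of the measurement contrast:

    SLD_eff = (1 - solvent_fraction) * SLD_dry + solvent_fraction * SLD_buffer

Three stages of the vesicle-adhesion experiment are modelled (fronting is
always Si | SiO2, backing is buffer):

* ``membrane``       : head | chain | head  (single supported bilayer)
* ``membrane_mbp``   : membrane | MBP layer (protein adsorbed on top)
* ``double``         : membrane | MBP | second membrane | diffuse vesicle layer

The second membrane is only partially formed: a coverage ``eta`` enters the
model exclusively through the solvent fractions of the second-membrane slabs,
with the chain slab exactly at solvent = 1 - eta (hydrophobic chains of a
covered patch are water-free), so a fit of that solvent fraction measures eta.
An 800 A diffuse layer (SLD 0.7e-6 A^-2, high roughness and hydration)
represents the out-of-plane body of unfused adsorbed vesicles.

Instrument emulation
--------------------
Gaussian resolution smearing with dQ/Q interpolated from 2% to 10% linearly in
log q across the measured range, a multiplicative scale, a flat background and
counting noise with dR = sqrt(R / count_scale) per point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (ConfigurationError, FitFailureError,
                     InvalidParameterError)
from .measurement import Measurement

__all__ = [
    "Slab", "LayerStack", "Contrast", "ReflectivityDataset", "StageParameters",
    "CONTRASTS", "NATIVE01", "MODIFIED01", "MODIFIED1",
    "abeles", "reflectivity", "build_stage_stack", "resolution_sigma",
    "smear_reflectivity", "smear_and_noise", "fit_coverage", "CoverageFit",
    "STATIC_COUNT_SCALE", "KINETIC_COUNT_SCALE",
    "simulate_kinetic_series", "write_dataset", "read_dataset",
    "DEFAULT_Q_GRID",
]

SI_SLD = 2.07       # 1e-6 A^-2
SIO2_SLD = 3.47
WATER_HEAD_SLD = 1.85   # dry lipid head groups
CHAIN_SLD = -0.40       # dry acyl chains
DIFFUSE_SLD = 0.70
Q_MIN, Q_MAX = 0.006, 0.35          # A^-1, instrument q-range
DEFAULT_Q_GRID = np.geomspace(Q_MIN, Q_MAX, 193)


@dataclass(frozen=True)
class Contrast:
    """Buffer contrast: name, buffer SLD and the MBP SLD at that contrast.

    MBP's SLD varies with the buffer because of labile-hydrogen exchange.
    All SLDs in 1e-6 A^-2.
    """

    name: str
    buffer_sld: float
    mbp_sld: float


CONTRASTS: Dict[str, Contrast] = {
    "D2O": Contrast("D2O", 6.36, 3.45),
    "SMW": Contrast("SMW", 2.07, 2.55),   # silicon-matched water, 38% D2O
    "H2O": Contrast("H2O", -0.56, 2.00),
}


@dataclass(frozen=True)
class Slab:
    """One layer: thickness (A), dry SLD (1e-6 A^-2), roughness (A) of the
    interface to the preceding layer, and solvent volume fraction."""

    thickness: float
    sld_dry: float
    roughness: float = 3.0
    solvent_fraction: float = 0.0
    name: str = ""

    def __post_init__(self):
        if self.thickness < 0 or self.roughness < 0:
            raise InvalidParameterError("thickness and roughness must be >= 0")
        if not 0.0 <= self.solvent_fraction <= 1.0:
            raise InvalidParameterError("solvent_fraction must be in [0, 1]")

    def effective_sld(self, buffer_sld: float) -> float:
        return ((1.0 - self.solvent_fraction) * self.sld_dry
                + self.solvent_fraction * buffer_sld)


@dataclass(frozen=True)
class LayerStack:
    """Ordered slabs from the Si fronting to the buffer backing."""

    slabs: tuple
    stage: str = ""
    fronting_sld: float = SI_SLD
    backing_roughness: float = 3.0

    def effective_slds(self, contrast: Contrast) -> np.ndarray:
        """SLDs of fronting | slabs | backing at the given contrast."""
        mids = [s.effective_sld(contrast.buffer_sld) for s in self.slabs]
        return np.array([self.fronting_sld] + mids + [contrast.buffer_sld])

    def thicknesses(self) -> np.ndarray:
        return np.array([s.thickness for s in self.slabs])

    def roughnesses(self) -> np.ndarray:
        return np.array([s.roughness for s in self.slabs]
                        + [self.backing_roughness])


@dataclass
class ReflectivityDataset:
    """A measured-like reflectivity curve: q (A^-1), R, dR (1 sigma), dq (sigma)."""

    q: np.ndarray
    R: np.ndarray
    dR: np.ndarray
    dq: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.dR = np.asarray(self.dR, dtype=float)
        if self.dq is not None:
            self.dq = np.asarray(self.dq, dtype=float)
        if np.any(self.q <= 0):
            raise InvalidParameterError("q must be positive")
        if np.any(self.R <= 0) or np.any(self.dR <= 0):
            raise InvalidParameterError("R and dR must be positive")


# ---------------------------------------------------------------------------
# optical matrix / Parratt recursion


def abeles(q, slds, thicknesses, roughnesses):
    """Specular reflectivity of a stratified medium (Parratt recursion).

    ``slds`` (1e-6 A^-2) has n+2 entries (fronting, n slabs, backing);
    ``thicknesses`` has n; ``roughnesses`` has n+1 (one per interface),
    applied as Nevot-Croce factors exp(-2 kz_i kz_{i+1} sigma^2).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    slds = np.asarray(slds, dtype=complex) * 1e-6
    thicknesses = np.asarray(thicknesses, dtype=float)
    roughnesses = np.asarray(roughnesses, dtype=float)
    if len(slds) != len(thicknesses) + 2 or len(roughnesses) != len(thicknesses) + 1:
        raise InvalidParameterError("inconsistent stack arrays")

    kz0_sq = (q / 2.0) ** 2
    kz = np.sqrt(kz0_sq[:, None] - 4.0 * np.pi * (slds[None, :] - slds[0]))
    # recursion from the backing up
    r = np.zeros(q.shape, dtype=complex)
    n_int = len(roughnesses)
    for i in range(n_int - 1, -1, -1):
        k1, k2 = kz[:, i], kz[:, i + 1]
        denom = k1 + k2
        denom = np.where(denom == 0, 1e-30, denom)
        r01 = (k1 - k2) / denom * np.exp(-2.0 * k1 * k2 * roughnesses[i] ** 2)
        if i == n_int - 1:
            r = r01
        else:
            beta = np.exp(2j * k2 * thicknesses[i])
            r = (r01 + r * beta) / (1.0 + r01 * r * beta)
    return np.clip(np.abs(r) ** 2, 0.0, 1.0)


def reflectivity(stack: LayerStack, contrast: Contrast, q) -> np.ndarray:
    """R(q) of a stack at a given buffer contrast (unsmeared, noiseless)."""
    return abeles(q, stack.effective_slds(contrast), stack.thicknesses(),
                  stack.roughnesses())


# ---------------------------------------------------------------------------
# stage stacks


@dataclass(frozen=True)
class StageParameters:
    """Structural parameters of one sample's slab model (A unless noted).

    Defaults are typical for a phospholipid bilayer on SiO2; per-sample
    presets carry the fitted thicknesses and MBP volume fractions.
    """

    d_sio2: float = 12.0
    d_head_inner: float = 7.9
    d_head_outer: float = 9.8
    d_chain: float = 31.2
    d_mbp_sbl: float = 77.0       # MBP layer on the single bilayer
    d_mbp_dbl: float = 30.6       # compressed MBP layer inside the double bilayer
    c_mbp_sbl: float = 0.03       # protein volume fraction
    c_mbp_dbl: float = 0.01
    d_diffuse: float = 800.0
    head_sld: float = WATER_HEAD_SLD
    chain_sld: float = CHAIN_SLD
    head_solvent: float = 0.25
    chain_solvent: float = 0.0
    sio2_solvent: float = 0.10
    diffuse_solvent: float = 0.90
    diffuse_roughness: float = 100.0
    roughness: float = 3.0
    eta: float = 0.26             # nominal second-bilayer coverage
    label: str = ""


NATIVE01 = StageParameters(d_head_inner=7.9, d_head_outer=9.8, d_chain=31.2,
                           d_mbp_sbl=77.0, d_mbp_dbl=30.6, c_mbp_sbl=0.03,
                           c_mbp_dbl=0.01, eta=0.26, label="Native01")
MODIFIED01 = StageParameters(d_head_inner=11.1, d_head_outer=11.5, d_chain=32.6,
                             d_mbp_sbl=64.0, d_mbp_dbl=26.4, c_mbp_sbl=0.05,
                             c_mbp_dbl=0.0, eta=0.34, label="Modified01")
MODIFIED1 = StageParameters(d_head_inner=8.1, d_head_outer=11.3, d_chain=31.6,
                            d_mbp_sbl=72.0, d_mbp_dbl=24.6, c_mbp_sbl=0.07,
                            c_mbp_dbl=0.11, eta=0.39, label="Modified1")

STAGES = ("membrane", "membrane_mbp", "double")


def build_stage_stack(stage: str, params: Optional[StageParameters] = None,
                      eta: Optional[float] = None,
                      contrast: Contrast = CONTRASTS["D2O"],
                      diffuse_solvent: Optional[float] = None,
                      diffuse_roughness: Optional[float] = None) -> LayerStack:
    """Assemble the slab stack of one experimental stage.

    For the ``double`` stage, coverage ``eta`` enters through the solvent
    fractions of the adhered-vesicle slabs: the second chain slab at exactly
    1 - eta, the second head slabs and the intramembrane MBP slab at
    1 - eta * (dry fraction).  Second-membrane thicknesses are tied to the
    first membrane's chain and outer-head values.  The MBP slab's dry SLD is
    contrast dependent (H/D exchange).
    """
    if stage not in STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}; expected one of {STAGES}")
    p = params or NATIVE01
    if eta is None:
        eta = p.eta
    if not 0.0 <= eta <= 1.0:
        raise InvalidParameterError("eta must be within [0, 1]")
    rough = p.roughness
    sio2 = Slab(p.d_sio2, SIO2_SLD, rough, p.sio2_solvent, "SiO2")
    head_in = Slab(p.d_head_inner, p.head_sld, rough, p.head_solvent, "head1_in")
    chain1 = Slab(p.d_chain, p.chain_sld, rough, p.chain_solvent, "chain1")
    head_out = Slab(p.d_head_outer, p.head_sld, rough, p.head_solvent, "head1_out")
    slabs = [sio2, head_in, chain1, head_out]

    if stage == "membrane_mbp":
        slabs.append(Slab(p.d_mbp_sbl, contrast.mbp_sld, rough,
                          1.0 - p.c_mbp_sbl, "MBP_sbl"))
    elif stage == "double":
        slabs.append(Slab(p.d_mbp_dbl, contrast.mbp_sld, rough,
                          1.0 - eta * p.c_mbp_dbl, "MBP_dbl"))
        # second membrane: thicknesses tied to the first (chain, outer head)
        head_dry = 1.0 - p.head_solvent
        slabs.append(Slab(p.d_head_outer, p.head_sld, rough,
                          1.0 - eta * head_dry, "head2_in"))
        slabs.append(Slab(p.d_chain, p.chain_sld, rough, 1.0 - eta, "chain2"))
        slabs.append(Slab(p.d_head_outer, p.head_sld, rough,
                          1.0 - eta * head_dry, "head2_out"))
        slabs.append(Slab(p.d_diffuse, DIFFUSE_SLD,
                          diffuse_roughness if diffuse_roughness is not None
                          else p.diffuse_roughness,
                          diffuse_solvent if diffuse_solvent is not None
                          else p.diffuse_solvent, "diffuse"))
    return LayerStack(slabs=tuple(slabs), stage=stage)


# ---------------------------------------------------------------------------
# instrument emulation


def resolution_sigma(q, dqq_min: float = 0.02, dqq_max: float = 0.10,
                     q_min: float = Q_MIN, q_max: float = Q_MAX) -> np.ndarray:
    """Gaussian resolution sigma_q: dQ/Q (FWHM) linear in log q from 2% to 10%."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    frac = (np.log(q) - np.log(q_min)) / (np.log(q_max) - np.log(q_min))
    dqq = dqq_min + np.clip(frac, 0.0, 1.0) * (dqq_max - dqq_min)
    return q * dqq / 2.3548  # FWHM -> sigma


_SMEAR_NODES = np.linspace(-2.5, 2.5, 17)
_SMEAR_W = np.exp(-0.5 * _SMEAR_NODES ** 2)
_SMEAR_W = _SMEAR_W / _SMEAR_W.sum()


def smear_reflectivity(stack: LayerStack, contrast: Contrast, q,
                       dq=None) -> np.ndarray:
    """Resolution-smeared R(q): Gaussian quadrature over the sigma_q kernel."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if dq is None:
        dq = resolution_sigma(q)
    dq = np.broadcast_to(np.asarray(dq, dtype=float), q.shape)
    if np.all(dq == 0):
        return reflectivity(stack, contrast, q)
    qs = q[None, :] + _SMEAR_NODES[:, None] * dq[None, :]
    qs = np.clip(qs, 1e-5, None)
    rs = reflectivity(stack, contrast, qs.ravel()).reshape(qs.shape)
    return _SMEAR_W @ rs


#: counts per unit reflectivity for a long static measurement
STATIC_COUNT_SCALE = 2e5
#: counts per unit reflectivity for one 1-minute kinetic frame; calibrated so
#: a single-frame coverage fit carries the ~+-0.02 error of the measured eta
KINETIC_COUNT_SCALE = 2e3


def smear_and_noise(stack: LayerStack, contrast: Contrast,
                    rng: np.random.Generator, q=None,
                    count_scale: float = STATIC_COUNT_SCALE, scale: float = 1.0,
                    background: float = 2e-7,
                    metadata: Optional[dict] = None) -> ReflectivityDataset:
    """Generate one instrument-like dataset from a stack.

    Counting statistics: the detected counts per point are
    Poisson(count_scale * R), so R_obs is unbiased and non-negative, with
    dR = sqrt(R/count_scale) (from the smooth curve, as a reduction pipeline
    would assign).  Scale and flat background are applied before counting.
    Reproducible from the supplied rng.
    """
    if count_scale <= 0:
        raise InvalidParameterError("count_scale must be positive")
    q = DEFAULT_Q_GRID if q is None else np.asarray(q, dtype=float)
    dq = resolution_sigma(q)
    r_smooth = scale * smear_reflectivity(stack, contrast, q, dq) + background
    counts = rng.poisson(count_scale * r_smooth)
    dr = np.sqrt(r_smooth / count_scale)
    r_obs = np.maximum(counts / count_scale, 1e-15)
    meta = {"stage": stack.stage, "contrast": contrast.name,
            "scale": scale, "background": background,
            "count_scale": count_scale}
    if metadata:
        meta.update(metadata)
    return ReflectivityDataset(q=q, R=r_obs, dR=dr, dq=dq, metadata=meta)


# ---------------------------------------------------------------------------
# coverage fitting


@dataclass
class CoverageFit:
    eta: Measurement
    scale: float
    diffuse_solvent: float
    diffuse_roughness: float
    chi2_reduced: float


def fit_coverage(dataset: ReflectivityDataset, params: StageParameters,
                 contrast: Optional[Contrast] = None,
                 background: Optional[float] = None,
                 chi2_max: float = 25.0) -> CoverageFit:
    """Recover the second-bilayer coverage eta from a ``double``-stage dataset.

    Only {eta, diffuse-layer solvent fraction, diffuse-layer roughness, scale}
    are fitted; every structural parameter stays fixed, mirroring the kinetic
    fitting protocol.  The error on eta comes from the Jacobian covariance.
    A reduced chi^2 above ``chi2_max`` raises: a grossly misspecified template
    must fail loudly rather than return a silent answer.
    """
    if contrast is None:
        contrast = CONTRASTS[dataset.metadata.get("contrast", "D2O")]
    if background is None:
        background = float(dataset.metadata.get("background", 2e-7))
    q, r_obs, dr = dataset.q, dataset.R, dataset.dR
    dq = dataset.dq

    def model(theta):
        eta, dsolv, drough, scale = theta
        stack = build_stage_stack("double", params, eta=eta, contrast=contrast,
                                  diffuse_solvent=dsolv, diffuse_roughness=drough)
        return scale * smear_reflectivity(stack, contrast, q, dq) + background

    def resid(theta):
        return (model(theta) - r_obs) / dr

    x0 = np.array([0.3, 0.9, 100.0, 1.0])
    lb = np.array([0.0, 0.5, 10.0, 0.3])
    ub = np.array([1.0, 1.0, 400.0, 2.0])
    res = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
    if not res.success:
        raise FitFailureError("coverage fit did not converge",
                              residual=float(np.sum(res.fun ** 2)))
    dof = max(len(q) - len(x0), 1)
    chi2_red = float(np.sum(res.fun ** 2)) / dof
    if chi2_red > chi2_max:
        raise FitFailureError(
            f"coverage fit left reduced chi^2 = {chi2_red:.1f} > {chi2_max}: "
            "template likely misspecified", residual=chi2_red)
    # covariance from the Jacobian at the solution
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * chi2_red
        eta_err = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        eta_err = np.nan
    eta, dsolv, drough, scale = res.x
    return CoverageFit(eta=Measurement(float(eta), eta_err), scale=float(scale),
                       diffuse_solvent=float(dsolv),
                       diffuse_roughness=float(drough), chi2_reduced=chi2_red)


# ---------------------------------------------------------------------------
# kinetic series


def simulate_kinetic_series(trace, params: StageParameters, alpha_f: float,
                            cadence: float, rng: np.random.Generator,
                            contrast: Contrast = CONTRASTS["D2O"],
                            q=None, count_scale: float = KINETIC_COUNT_SCALE,
                            t_start: float = 0.0) -> List[ReflectivityDataset]:
    """One synthetic dataset per cadence point along a coverage trace.

    The steric coverage rho(t) maps to the adhesive coverage
    eta(t) = rho 4 alpha_f / (1 + 2 alpha_f) at the configured flat fraction.
    """
    from .coverage import eta_from_rho

    times = np.asarray(trace.times, dtype=float)
    if cadence <= 0:
        raise InvalidParameterError("cadence must be positive")
    if times[-1] < t_start:
        raise InvalidParameterError("trace does not cover the requested span")
    sample_t = np.arange(t_start, times[-1] + cadence / 2, cadence)
    rho_interp = np.interp(sample_t, times, trace.rho)
    out = []
    for t, rho in zip(sample_t, rho_interp):
        eta = float(np.clip(eta_from_rho(rho, alpha_f), 0.0, 1.0))
        stack = build_stage_stack("double", params, eta=eta, contrast=contrast)
        ds = smear_and_noise(stack, contrast, rng, q=q, count_scale=count_scale,
                             metadata={"time_s": float(t), "eta_true": eta,
                                       "alpha_f": alpha_f})
        out.append(ds)
    return out


# ---------------------------------------------------------------------------
# file IO: 4-column ASCII (q, R, dR, dq), '#' metadata header


def write_dataset(path, dataset: ReflectivityDataset) -> None:
    header = "\n".join(f"{k} = {v}" for k, v in sorted(dataset.metadata.items()))
    header += "\ncolumns: q_A^-1 R dR dq_sigma"
    dq = dataset.dq if dataset.dq is not None else np.zeros_like(dataset.q)
    np.savetxt(path, np.column_stack([dataset.q, dataset.R, dataset.dR, dq]),
               header=header)


def read_dataset(path) -> ReflectivityDataset:
    """Read a 4-column (q, R, dR, dq) or 3-column (dq omitted) ASCII dataset."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line[1:].strip()
            if "=" in text:
                k, _, v = text.partition("=")
                meta[k.strip()] = v.strip()
    data = np.atleast_2d(np.loadtxt(path))
    if data.shape[1] < 3:
        raise InvalidParameterError("dataset needs at least q, R, dR columns")
    dq = data[:, 3] if data.shape[1] >= 4 else None
    return ReflectivityDataset(q=data[:, 0], R=data[:, 1], dR=data[:, 2],
                               dq=dq, metadata=meta)
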
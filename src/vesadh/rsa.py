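"""Random sequential adsorption of vesicles onto an adhesive plane.

Two engines are provided:

``run_diffusion_rsa``
    One-dimensional Brownian motion of a polydisperse vesicle population
    towards the adhesive plane at z = 0.  A vesicle that reaches (or crosses)
    the plane adsorbs with a rate-limited probability; on adsorption it is
    assigned a uniform in-plane position and is accepted only if its projected
    hard disk overlaps no previously adsorbed disk (periodic boundaries).
    Rejected vesicles keep diffusing.  This reproduces the diffusion-limited
    approach to the jammed state observed in vesicle-adhesion kinetics.

``run_geometric_rsa``
    Classic ballistic RSA: sequential uniform placement attempts with
    rejection on overlap.  Serves as the fast oracle for the jamming limit,
    decoupled from the diffusive transport.

Coverage here is always the *steric* coverage: the fraction of the plane
blocked by the projected disks (pi/4 d^2 per vesicle of diameter d).
The jammed state of equal disks covers ~54.7-55.5% of the plane and is
approached as t^(-1/2) (Feder's law); polydispersity raises the limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import constants
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from scipy.special import erfinv

from .errors import ConfigurationError, FitFailureError, InvalidParameterError
from .measurement import Measurement

__all__ = [
    "SimulationConfig",
    "CoverageTrace",
    "DiskSurface",
    "JammingFit",
    "stokes_einstein_diffusion",
    "number_density_from_mass",
    "sample_diameters",
    "diffusion_step",
    "adsorption_probability",
    "active_layer_depth",
    "place_disk",
    "run_diffusion_rsa",
    "run_geometric_rsa",
    "extrapolate_jamming",
]

_ERFINV_099 = float(erfinv(0.99))  # ~1.8214


def stokes_einstein_diffusion(diameter_nm: float,
                              temperature_k: float = 310.0,
                              viscosity_pa_s: float = 0.85e-3) -> float:
    """Stokes-Einstein diffusion coefficient (m^2/s) of a sphere in water.

    Defaults correspond to 37 degC and the viscosity of aqueous buffer at that
    temperature; ~5.3e-12 m^2/s for a 100 nm vesicle.
    """
    if diameter_nm <= 0:
        raise InvalidParameterError("diameter must be positive")
    radius_m = diameter_nm * 1e-9 / 2.0
    return constants.k * temperature_k / (6 * np.pi * viscosity_pa_s * radius_m)


@dataclass
class SimulationConfig:
    """Parameters of a diffusion-RSA run.

    Lengths: box_x/box_y in um, box_z in mm, diameters in nm.  ``P`` is the
    adsorption rate constant (1/s) so that P*dt is the per-contact sticking
    probability.  ``D`` (m^2/s) defaults to the Stokes-Einstein value for the
    mean diameter at 37 degC.  The vesicle mass model (two leaflets,
    area_per_lipid, lipid_molar_mass) converts the mass concentration into a
    number density.
    """

    box_x: float = 1.0            # um
    box_y: float = 1.0            # um
    box_z: float = 1.0            # mm
    dt: float = 10.0              # s
    P: float = 0.015              # 1/s
    mass_concentration: float = 1.0   # mg/ml
    diameter_mean: float = 100.0  # nm
    diameter_sd: float = 30.0     # nm
    D: Optional[float] = None     # m^2/s
    t_max: float = 86400.0        # s
    n_replicates: int = 10
    seed: int = 0
    area_per_lipid: float = 0.65      # nm^2
    lipid_molar_mass: float = 750.0   # g/mol

    def __post_init__(self):
        for name in ("box_x", "box_y", "box_z", "dt",
                     "mass_concentration", "diameter_mean", "t_max",
                     "area_per_lipid", "lipid_molar_mass"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if self.P < 0:
            raise InvalidParameterError("P must be >= 0")
        if self.diameter_sd < 0:
            raise InvalidParameterError("diameter_sd must be >= 0")
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")
        if self.D is None:
            self.D = stokes_einstein_diffusion(self.diameter_mean)
        if self.D <= 0:
            raise InvalidParameterError("D must be strictly positive")
        if self.P * self.dt > 1.0:
            raise ConfigurationError(
                f"P*dt = {self.P * self.dt:.3g} > 1: adsorption probability overflows")


@dataclass
class CoverageTrace:
    """Time series of steric coverage, averaged over replicates."""

    times: np.ndarray          # s (or attempt count for geometric RSA)
    rho: np.ndarray            # steric coverage, replicate mean
    n_adsorbed: np.ndarray     # count, replicate mean
    replicate_sd: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.n_adsorbed = np.asarray(self.n_adsorbed, dtype=float)

    @property
    def final_coverage(self) -> Measurement:
        sd = float(self.replicate_sd[-1]) if self.replicate_sd is not None else 0.0
        return Measurement(float(self.rho[-1]), sd)

    def save(self, path) -> None:
        header_lines = [f"{k} = {v}" for k, v in sorted(self.metadata.items())]
        header = "\n".join(header_lines + ["columns: time_s rho_mean rho_sd n_adsorbed"])
        sd = self.replicate_sd if self.replicate_sd is not None else np.zeros_like(self.rho)
        np.savetxt(path, np.column_stack([self.times, self.rho, sd, self.n_adsorbed]),
                   header=header)

    @classmethod
    def load(cls, path) -> "CoverageTrace":
        data = np.loadtxt(path)
        data = np.atleast_2d(data)
        return cls(times=data[:, 0], rho=data[:, 1],
                   n_adsorbed=data[:, 3], replicate_sd=data[:, 2])


@dataclass
class JammingFit:
    """Result of the rho(t) = rho_inf - c * t^exponent extrapolation."""

    rho_inf: Measurement
    c: float
    exponent: float
    exponent_err: float = 0.0
    window_start: float = 0.0


def number_density_from_mass(mass_concentration: float, diameter_mean: float,
                             area_per_lipid: float = 0.65,
                             lipid_molar_mass: float = 750.0) -> float:
    """Vesicle number density (1/cm^3) from a mass concentration (mg/ml).

    The single-vesicle mass is that of a two-leaflet spherical shell:
    2 * (4 pi (d/2)^2 / area_per_lipid) lipids of the given molar mass.
    """
    for name, v in (("mass_concentration", mass_concentration),
                    ("diameter_mean", diameter_mean),
                    ("area_per_lipid", area_per_lipid),
                    ("lipid_molar_mass", lipid_molar_mass)):
        if v <= 0:
            raise InvalidParameterError(f"{name} must be strictly positive")
    n_lipids = 2.0 * 4.0 * np.pi * (diameter_mean / 2.0) ** 2 / area_per_lipid
    vesicle_mass_g = n_lipids * lipid_molar_mass / constants.Avogadro
    mass_per_cm3_g = mass_concentration * 1e-3  # mg/ml -> g/cm^3
    return mass_per_cm3_g / vesicle_mass_g


def sample_diameters(n: int, mean: float, sd: float, rng: np.random.Generator,
                     min_diameter: float = 10.0) -> np.ndarray:
    """Sample vesicle diameters (nm) from a truncated normal distribution.

    Truncation (rejection sampling at > ``min_diameter``) avoids non-physical
    diameters at large polydispersity; at cv = 0.3 the truncation loss is
    ~0.13% so sample moments remain essentially (mean, sd).
    """
    if n <= 0:
        raise InvalidParameterError("n must be >= 1")
    if mean <= 0:
        raise InvalidParameterError("mean must be strictly positive")
    if sd < 0:
        raise InvalidParameterError("sd must be >= 0")
    if sd == 0:
        return np.full(n, float(mean))
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 64))
        draw = draw[draw > min_diameter]
        take = min(len(draw), n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def diffusion_step(z_old, D: float, dt: float, rng: np.random.Generator,
                   chi=None):
    """One Brownian step normal to the plane: z_new = z_old + sqrt(2 D dt) chi.

    ``z_old`` in nm (scalar or array), ``D`` in m^2/s, ``dt`` in s.  ``chi``
    (standard normal) may be supplied explicitly for testing.
    """
    if D <= 0 or dt <= 0:
        raise InvalidParameterError("D and dt must be strictly positive")
    z_old = np.asarray(z_old, dtype=float)
    if chi is None:
        chi = rng.standard_normal(z_old.shape)
    step_nm = np.sqrt(2.0 * D * dt) * 1e9
    return z_old + step_nm * chi


def adsorption_probability(z_old, z_new, D: float, dt: float, P: float):
    """Probability that a vesicle adsorbs during a step from z_old to z_new (nm).

    A step ending below the plane adsorbs with p = P*dt; a step that stays
    above may still have crossed the plane in between, with the standard
    Brownian-bridge crossing weight exp(-z_old*z_new/(D*dt)).  Results are
    clamped to [0, 1].
    """
    if D <= 0 or dt <= 0:
        raise InvalidParameterError("D and dt must be strictly positive")
    if P < 0:
        raise InvalidParameterError("P must be >= 0")
    if P * dt > 1.0:
        raise ConfigurationError(f"P*dt = {P * dt:.3g} > 1: probability overflow")
    z_old = np.asarray(z_old, dtype=float)
    z_new = np.asarray(z_new, dtype=float)
    d_nm2 = D * 1e18  # nm^2/s
    p_base = P * dt
    crossing = np.exp(-np.clip(z_old * z_new / (d_nm2 * dt), 0.0, 700.0)) * p_base
    p = np.where(z_new < 0.0, p_base, crossing)
    # a step that starts below the plane is already in contact
    p = np.where(z_old < 0.0, p_base, p)
    return np.clip(p, 0.0, 1.0)


def active_layer_depth(t: float, D: float) -> float:
    """Depth (nm) of the near-surface layer perturbed by adsorption after time t.

    L(t) = 2 erfinv(0.99) sqrt(D t): 99% of the vesicles that could have
    reached the plane by diffusion within t started inside L(t).
    """
    if t < 0:
        raise InvalidParameterError("t must be >= 0")
    if D <= 0:
        raise InvalidParameterError("D must be strictly positive")
    return 2.0 * _ERFINV_099 * np.sqrt(D * t) * 1e9


class DiskSurface:
    """Immutable-once-placed hard disks on a periodic rectangle (nm units)."""

    def __init__(self, box_x: float, box_y: float):
        if box_x <= 0 or box_y <= 0:
            raise InvalidParameterError("box sides must be positive")
        self.box = np.array([box_x, box_y], dtype=float)
        self.x = np.empty(0)
        self.y = np.empty(0)
        self.d = np.empty(0)

    def __len__(self) -> int:
        return self.x.size

    def would_overlap(self, x: float, y: float, d: float) -> bool:
        if self.x.size == 0:
            return False
        dx = np.abs(self.x - x)
        dy = np.abs(self.y - y)
        dx = np.minimum(dx, self.box[0] - dx)
        dy = np.minimum(dy, self.box[1] - dy)
        return bool(np.any(dx * dx + dy * dy < (0.5 * (self.d + d)) ** 2))

    def add(self, x: float, y: float, d: float) -> None:
        self.x = np.append(self.x, x % self.box[0])
        self.y = np.append(self.y, y % self.box[1])
        self.d = np.append(self.d, d)

    @property
    def coverage(self) -> float:
        return float(np.sum(0.25 * np.pi * self.d ** 2) / (self.box[0] * self.box[1]))


def place_disk(surface: DiskSurface, x: float, y: float, d: float) -> bool:
    """Attempt to place a disk; returns True (and places it) iff no overlap."""
    if d <= 0:
        raise InvalidParameterError("diameter must be positive")
    if surface.would_overlap(x, y, d):
        return False
    surface.add(x, y, d)
    return True


def _check_box(box_x_nm: float, box_y_nm: float, d_max: float) -> None:
    if d_max > min(box_x_nm, box_y_nm) / 2.0:
        raise ConfigurationError(
            "box too small: largest disk diameter exceeds half the box side")


def run_diffusion_rsa(config: SimulationConfig,
                      record_every: int = 1) -> CoverageTrace:
    """Simulate diffusion-limited RSA of vesicles and return the coverage trace.

    The bulk is represented explicitly: vesicles are distributed uniformly in
    z up to box_z at the configured number density, and only those inside the
    growing diffusion-active layer L(t) are stepped (the remainder of the bulk
    is still unperturbed).  Since only O(100) vesicles adsorb out of O(10^4)
    in the box, the bulk concentration stays effectively constant.
    Reproducible: the trace is a pure function of the config (incl. seed).
    """
    box_x_nm = config.box_x * 1e3
    box_y_nm = config.box_y * 1e3
    box_z_nm = config.box_z * 1e6
    area_nm2 = box_x_nm * box_y_nm

    density_nm3 = number_density_from_mass(
        config.mass_concentration, config.diameter_mean,
        config.area_per_lipid, config.lipid_molar_mass) / 1e21
    n_vesicles = int(round(density_nm3 * area_nm2 * box_z_nm))
    if n_vesicles < 1:
        raise ConfigurationError("no vesicles in the box at this concentration")

    n_steps = int(np.ceil(config.t_max / config.dt))
    rec_idx = np.arange(0, n_steps + 1, record_every)
    times = rec_idx * config.dt

    rho_runs = np.zeros((config.n_replicates, rec_idx.size))
    nad_runs = np.zeros_like(rho_runs)

    ss = np.random.SeedSequence(config.seed)
    for rep, child in enumerate(ss.spawn(config.n_replicates)):
        rng = np.random.default_rng(child)
        z = rng.uniform(0.0, box_z_nm, size=n_vesicles)
        diam = sample_diameters(n_vesicles, config.diameter_mean,
                                config.diameter_sd, rng)
        _check_box(box_x_nm, box_y_nm, float(diam.max()))
        order = np.argsort(z)  # activation order: nearest to the plane first
        z = z[order]
        diam = diam[order]
        surface = DiskSurface(box_x_nm, box_y_nm)
        alive = np.zeros(n_vesicles, dtype=bool)   # activated and not adsorbed
        n_active = 0  # vesicles ever activated (prefix of the sorted arrays)

        rho_t = np.zeros(n_steps + 1)
        nad_t = np.zeros(n_steps + 1)
        for step in range(1, n_steps + 1):
            t = step * config.dt
            depth = min(active_layer_depth(t, config.D), box_z_nm)
            new_active = np.searchsorted(z[n_active:], depth) + n_active
            if new_active > n_active:
                alive[n_active:new_active] = True
                n_active = new_active
            idx = np.nonzero(alive[:n_active])[0]
            if idx.size:
                z_old = z[idx]
                z_new = diffusion_step(z_old, config.D, config.dt, rng)
                p = adsorption_probability(z_old, z_new, config.D,
                                           config.dt, config.P)
                stick = rng.random(idx.size) < p
                for j in idx[stick]:
                    x = rng.uniform(0.0, box_x_nm)
                    y = rng.uniform(0.0, box_y_nm)
                    if place_disk(surface, x, y, diam[j]):
                        alive[j] = False
                # survivors (incl. blocked placements) stay in the bulk
                still = alive[idx]
                z[idx[still]] = np.abs(z_new[still])
                over = z > 2 * box_z_nm  # stray reflections, keep in box
                if np.any(over):
                    z[over] = 2 * box_z_nm - (z[over] % (2 * box_z_nm))
            rho_t[step] = surface.coverage
            nad_t[step] = len(surface)
        rho_runs[rep] = rho_t[rec_idx]
        nad_runs[rep] = nad_t[rec_idx]

    sd = rho_runs.std(axis=0, ddof=1) if config.n_replicates > 1 else None
    return CoverageTrace(times=times, rho=rho_runs.mean(axis=0),
                         n_adsorbed=nad_runs.mean(axis=0), replicate_sd=sd,
                         metadata={"engine": "diffusion", "seed": config.seed,
                                   "n_replicates": config.n_replicates,
                                   "n_vesicles": n_vesicles,
                                   "dt_s": config.dt, "P_per_s": config.P,
                                   "D_m2_s": config.D})


def run_geometric_rsa(diameter_sampler: Callable[[int, np.random.Generator], np.ndarray],
                      box: Sequence[float], n_attempts: int, seed: int,
                      batch_size: int = 100_000,
                      n_record: int = 200) -> CoverageTrace:
    """Classic ballistic RSA on a periodic rectangle.

    ``diameter_sampler(n, rng)`` returns n diameters (nm); ``box`` is
    (box_x_nm, box_y_nm).  Attempts are processed in batches: each candidate
    is first screened against all previously accepted disks (KD-tree with
    periodic wrap), and the rare survivors are then resolved sequentially
    among themselves, which is exactly equivalent to one-at-a-time RSA.
    The trace's ``times`` axis is the cumulative attempt count.
    """
    if n_attempts < 1:
        raise InvalidParameterError("n_attempts must be >= 1")
    box_x, box_y = float(box[0]), float(box[1])
    boxarr = np.array([box_x, box_y])
    area = box_x * box_y
    rng = np.random.default_rng(seed)

    xs = np.empty(0)
    ys = np.empty(0)
    ds = np.empty(0)
    area_sum = 0.0
    k_query = 12

    times, rhos, nads = [], [], []
    done = 0
    while done < n_attempts:
        # small batches while acceptance is frequent, full batches once jammed
        n = int(min(batch_size, max(1000, 2 * xs.size + 1000), n_attempts - done))
        px = rng.uniform(0.0, box_x, n)
        py = rng.uniform(0.0, box_y, n)
        pd = np.asarray(diameter_sampler(n, rng), dtype=float)
        _check_box(box_x, box_y, float(pd.max()))
        if xs.size:
            # prescreen against all previously accepted disks
            tree = cKDTree(np.column_stack([xs, ys]), boxsize=boxarr)
            dmax = float(ds.max())
            pts = np.column_stack([px, py])
            k = min(k_query, xs.size)
            bound = 0.5 * (float(pd.max()) + dmax)
            dist, idx = tree.query(pts, k=k, distance_upper_bound=bound)
            dist = np.atleast_2d(dist.reshape(n, -1))
            idx = np.atleast_2d(idx.reshape(n, -1))
            hit = idx < xs.size
            dj = np.where(hit, ds[np.where(hit, idx, 0)], 0.0)
            overlap = np.any(hit & (dist < 0.5 * (pd[:, None] + dj)), axis=1)
            # rare overflow: all k neighbours within bound -> exact re-check
            crowded = np.nonzero(~overlap & hit.all(axis=1))[0] \
                if k == k_query and xs.size > k else []
            for i in crowded:
                nb = tree.query_ball_point(pts[i], r=0.5 * (pd[i] + dmax))
                dx = np.abs(xs[nb] - px[i])
                dy = np.abs(ys[nb] - py[i])
                dx = np.minimum(dx, box_x - dx)
                dy = np.minimum(dy, box_y - dy)
                if np.any(dx * dx + dy * dy < (0.5 * (ds[nb] + pd[i])) ** 2):
                    overlap[i] = True
            cand = np.nonzero(~overlap)[0]
        else:
            cand = np.arange(n)
        # sequential resolution among this batch's survivors (exact RSA order)
        new_x, new_y, new_d = [], [], []
        for i in cand:
            if new_x:
                dx = np.abs(np.array(new_x) - px[i])
                dy = np.abs(np.array(new_y) - py[i])
                dx = np.minimum(dx, box_x - dx)
                dy = np.minimum(dy, box_y - dy)
                if np.any(dx * dx + dy * dy <
                          (0.5 * (np.array(new_d) + pd[i])) ** 2):
                    continue
            new_x.append(px[i])
            new_y.append(py[i])
            new_d.append(pd[i])
        if new_x:
            xs = np.concatenate([xs, new_x])
            ys = np.concatenate([ys, new_y])
            ds = np.concatenate([ds, new_d])
            area_sum = float(np.sum(0.25 * np.pi * ds ** 2))
        done += n
        times.append(done)
        rhos.append(area_sum / area)
        nads.append(xs.size)

    return CoverageTrace(times=np.array(times, dtype=float),
                         rho=np.array(rhos), n_adsorbed=np.array(nads, dtype=float),
                         metadata={"engine": "geometric", "seed": seed,
                                   "box_x_nm": box_x, "box_y_nm": box_y,
                                   "n_attempts": n_attempts})


def extrapolate_jamming(trace: CoverageTrace, window: float = 0.9,
                        free_exponent: bool = False) -> JammingFit:
    """Extrapolate the jamming coverage from the late-time Feder tail.

    Fits rho(t) = rho_inf - c t^(-1/2) by linear least squares on the late
    part of the trace, t >= (1 - window) * t_max, excluding the early
    transient where the power law has not set in.  With ``free_exponent`` the
    exponent is fitted as well (nonlinear).  The full trace must span at
    least one decade in time.
    """
    if not 0 < window <= 1:
        raise InvalidParameterError("window must be in (0, 1]")
    t = np.asarray(trace.times, dtype=float)
    rho = np.asarray(trace.rho, dtype=float)
    mask = t > 0
    t, rho = t[mask], rho[mask]
    if len(t) < 8:
        raise FitFailureError("trace too short for a late-time fit")
    if t[-1] / t[0] < 10.0:
        raise FitFailureError("trace covers less than one decade in time")
    keep = t >= (1.0 - window) * t[-1]
    t, rho = t[keep], rho[keep]
    if len(t) < 8:
        raise FitFailureError("late-time window has too few points")
    drop = np.diff(rho)
    if np.any(drop < -1e-12):
        raise FitFailureError("coverage trace is not monotone")

    x = t ** (-0.5)
    A = np.column_stack([np.ones_like(x), -x])
    coef, res, *_ = np.linalg.lstsq(A, rho, rcond=None)
    rho_inf, c = float(coef[0]), float(coef[1])
    dof = max(len(t) - 2, 1)
    s2 = float(res[0]) / dof if res.size else 0.0
    cov = s2 * np.linalg.inv(A.T @ A)
    rho_inf_err = float(np.sqrt(max(cov[0, 0], 0.0)))

    exponent, exponent_err = -0.5, 0.0
    if free_exponent:
        def model(tt, r_inf, cc, g):
            return r_inf - cc * tt ** g

        p0 = [float(np.clip(rho_inf, 1e-6, 1.0)), max(c, 1e-12), -0.5]
        popt, pcov = curve_fit(model, t, rho, p0=p0, maxfev=20000,
                               bounds=([0.0, 0.0, -1.5], [1.0, np.inf, -0.05]))
        rho_inf, c, exponent = float(popt[0]), float(popt[1]), float(popt[2])
        perr = np.sqrt(np.diag(pcov))
        rho_inf_err = float(perr[0])
        exponent_err = float(perr[2])

    return JammingFit(rho_inf=Measurement(rho_inf, rho_inf_err), c=c,
                      exponent=exponent, exponent_err=exponent_err,
                      window_start=float(t[0]))
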
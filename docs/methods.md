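# Methods

This note documents the models implemented in `vesadh`, the numerical choices
behind them, and what the synthetic-data tests do and do not demonstrate.

## Physical picture

Large unilamellar vesicles (LUVs, ~100 nm) diffuse from a buffer reservoir
onto a supported lipid bilayer coated with myelin basic protein (MBP).  A
vesicle that touches the protein layer adheres irreversibly, flattens until
the bending stiffness of its membrane balances the adhesion gain, and blocks
a patch of the surface against later arrivals.  Three observables connect to
the adhesion strength:

* the **steric coverage** ρ — the fraction of the plane blocked by vesicle
  projections, which a random-sequential-adsorption (RSA) process drives
  towards a jamming limit;
* the **adhesive coverage** η — the fraction of the plane in flat molecular
  contact, which specular neutron reflectometry reads off the hydration of
  the second bilayer's chain region (η = 1 − h_chain,2);
* the **flat fraction** α_f — the portion of one vesicle's membrane area that
  is flat against the surface.

The chain of relations implemented here is

    ρ = N·A_ex/A_tot,   η = N·A_f/A_tot,   A_f = α_f·A,
    A_ex ≈ A·(1 + 2α_f)/4      ⇒      α_f ≈ 1/(4ρ/η − 2),

and the inversion of the measured α_f into the adhesion constant k_a through
the least-energy shape of an adhered vesicle, followed by ε_MBP = k_a·A_MBP.

## RSA simulators

**Diffusion engine** (`rsa.run_diffusion_rsa`).  Only the coordinate normal
to the plane is stochastic: z is advanced as z′ = z + √(2DΔt)·χ.  A step
ending below the plane adsorbs with probability PΔt; a step that stays above
may still have crossed, with the Brownian-bridge weight
exp(−z_old·z_new/(DΔt))·PΔt.  On adsorption the vesicle receives a uniform
(x, y) and is accepted only if its projected hard disk overlaps no earlier
disk (periodic wrap); a blocked vesicle returns to the bulk and keeps
diffusing.  Only vesicles inside the growing active layer
L(t) = 2·erf⁻¹(0.99)·√(Dt) are stepped; the rest of the column is still
unperturbed bulk.  Defaults are the study conditions: 1 µm × 1 µm × 1 mm box,
1 mg/ml vesicles of diameter 100 ± 30 nm (normal, rejection-truncated at
10 nm), Δt = 10 s, P = 0.015 s⁻¹, 24 h, 10 replicates.  Two defaults the
study leaves open are chosen once here: D from Stokes–Einstein at 310 K with
0.85 mPa·s viscosity (5.3 µm²/s for 100 nm), and a vesicle mass model of two
leaflets at 0.65 nm² and 750 g/mol per lipid (≈8×10¹² vesicles/cm³ at
1 mg/ml).  Vesicles reflect at the plane when they fail to adsorb and at the
top of the box.  Under these conditions the surface is supply-saturated well
within a day, so the 24 h coverage is a jamming-limited, not transport-limited,
quantity (~0.60 for cv = 0.3).

**Geometric engine** (`rsa.run_geometric_rsa`).  Classic ballistic RSA —
uniform placement attempts, reject on overlap — used as the fast oracle for
the jamming limit.  Attempts are processed in batches: a periodic KD-tree
prescreen against all previously accepted disks (k-nearest with an exact
fallback when the neighbourhood overflows), then strict sequential resolution
among the batch's survivors.  This is exactly equivalent to one-at-a-time
RSA; the equivalence and the overlap test itself are checked against an
all-pairs brute-force oracle in the tests.

**Jamming extrapolation** (`rsa.extrapolate_jamming`).  The jamming deficit
of disk RSA decays as t^(−1/2) (Feder's law).  ρ_∞ is obtained by linear
least squares of ρ against t^(−1/2) on the late window t ≥ (1−w)·t_max
(default w = 0.9, i.e. the first 10% of the trace is excluded).  A finite
periodic box departs from the −1/2 law once its last holes fill (roughly
exponential saturation), so jamming runs use boxes ≥ 80 disk diameters where
the fitted window stays inside the scaling regime; with 5 seeds of 10⁷
attempts the extrapolated equal-disk jamming is 0.546 ± 0.003, consistent
with the accepted 0.547 for equal disks.  The free-exponent variant fits
ρ_∞ − c·t^γ and is most stable on a seed-averaged trace (window 0.95); this
is how the −1/2 law is verified.

## Adhered-vesicle shape and the k_a inversion

The free energy of an adhered vesicle of fixed membrane area A (no volume
constraint, no spontaneous curvature) is

    E_free(α_f; k_a) = −k_a·α_f·A + (κ/2)∮(c₁+c₂)² dA.

The least-energy surface is a solid of revolution; its generatrix is
parametrized by the tangent angle ψ(s) from the contact line (ψ = 0,
r = r_c, and dψ/ds = 0 — curvature continuity with the flat disk) to the
apex (r = 0, ψ = π, where sinψ/r → dψ/ds).  In reduced units
(R₀ = √(A/4π), energies in κ) the curve E_b(α_f) is universal; the sphere is
the α_f = 0 limit with E_b = 8πκ.

**Numerics.**  ψ is expanded as ψ(t) = π(3t² − 2t³) + Σₖ aₖ·t·sin(kπt) on
t = s/L ∈ [0,1], which satisfies all three boundary conditions identically.
The coefficients (a₁…a₃₂) and the arclength L are found by SLSQP under two
equality constraints — closure r(L) = 0 and curved-area conservation — on a
600-point trapezoidal quadrature mesh, warm-started by continuation in α_f.
This parametrization was chosen after direct nodal minimization (hundreds of
unknowns) proved ill-conditioned and Euler–Lagrange shooting from the contact
line proved unstable (the adjoint variable grows exponentially).  Validation:
the sphere energy is exact to <10⁻⁴; the total area of every solution is
conserved to 10⁻⁴ relative; doubling the quadrature mesh moves E_b by
<5×10⁻⁴ relative.  Basis-refinement (K = 24→40) shows the energy converges
from above with a residual truncation bias of order 1% in E_b and up to ~5%
in its slope dE_b/dα_f; the validated range is capped at α_f ≤ 0.45, where
the curved part of the shape degenerates.

**Inversion.**  Stationarity of E_free gives k_a = (1/A)·dE_b/dα_f, evaluated
by central differences with Δα = 0.005 on the minimized-energy curve;
`alpha_from_ka` solves the same condition in the other direction on the
monotone (convex) curve by bracketed root finding.  The round trip closes to
better than 10⁻⁴ in α_f.  At the measured flat fractions this yields
k_a ≈ 0.39 mJ/m² (α_f = 0.138, κ = 1.44×10⁻¹⁹ J, R = 50 nm) and
k_a ≈ 0.49 mJ/m² (α_f = 0.198, κ = 1.16×10⁻¹⁹ J) — within the experimental
error bars of the reference values 0.36 ± 0.06 and 0.45 ± 0.10.  The nominal
radius (50 nm, the mean of the size distribution) is an explicit parameter:
k_a scales as 1/R², so its choice matters and is reported, not hidden.

**Uncertainties.**  k_a inherits κ's relative error and, in the pipeline, the
α_f error mapped through the local curvature of E_b, combined in quadrature.
ε_MBP = k_a·A_MBP combines relative errors in quadrature
(1 mJ/m²·nm² = 10⁻²¹ J).  First-order propagation is used throughout; the
tests validate it against Monte-Carlo sampling (within 15% for α_f, 10% for
ε_MBP at the reference inputs).

## Synthetic reflectivity

Specular reflectivity of the three experimental stages is computed with the
Parratt/Abeles recursion and Névot–Croce roughness factors, validated to
10⁻¹⁰ against the analytic Fresnel form and an independently coded two-layer
interference formula.  Stacks (fronting Si | SiO₂, backing buffer):

1. `membrane`: head | chain | head;
2. `membrane_mbp`: membrane plus an MBP slab (60–100 Å, 3–7 vol%);
3. `double`: membrane | compressed MBP slab (~25–31 Å) | second membrane |
   800 Å diffuse vesicle layer (SLD 0.7×10⁻⁶ Å⁻², high roughness and
   hydration) standing in for the out-of-plane vesicle bodies.

Per-sample structural presets carry the fitted thicknesses of the three
characterized samples.  Solvent mixes linearly into each slab's dry SLD;
the MBP SLD is contrast-dependent (3.45/2.55/2.00 ×10⁻⁶ Å⁻² in D₂O/SMW/H₂O)
because of labile-hydrogen exchange.  Buffer SLDs are the standard
6.36/−0.56 ×10⁻⁶ Å⁻² for D₂O/H₂O and 2.07 for silicon-matched water; dry
lipid SLDs default to 1.85 (heads) and −0.40 (chains) ×10⁻⁶ Å⁻², typical
phospholipid values — only the realism of the synthetic data depends on them.
Coverage enters stage 3 only through solvent fractions of the vesicle slabs,
with the second chain slab at exactly 1 − η, so η is identified with the
complement of the fitted chain hydration.  At η = 0 those slabs are pure
buffer and the stage-3 curve reduces exactly to the bare membrane plus
diffuse layer (pure-buffer slabs are optically invisible) — a limiting case
the tests assert.

**Instrument emulation.**  Gaussian resolution smearing with ΔQ/Q (FWHM)
interpolated linearly in log q from 2% at 0.006 Å⁻¹ to 10% at 0.35 Å⁻¹
(17-node kernel over ±2.5σ); a multiplicative scale and flat background; and
Poisson counting statistics — counts ~ Poisson(count_scale·R), dR = √(R/cs) —
which keeps R non-negative *and unbiased* (Gaussian noise truncated at zero
was found to inflate the high-q tail and bias fitted coverages upward by
~0.02).  Two count scales are used: 2×10⁵ for static-like curves and 2×10³
for 1-minute kinetic frames, the latter calibrated so a single-frame coverage
fit carries the ±0.02 uncertainty of the measured η values.

**Coverage fitting.**  Only {η, diffuse-layer solvent, diffuse-layer
roughness, scale} are fitted (trust-region least squares on (R_model−R)/dR),
all structural parameters fixed — the kinetic-protocol convention.  Errors
come from the Jacobian covariance.  A reduced χ² above 25 raises instead of
returning a silently wrong coverage (misspecified-template guard).  Recovery
at kinetic-frame noise: |bias| < 0.01, spread ≤ 0.02 across η ∈ 0.1–0.39.

## What the synthetic data do and do not show

The generator emulates counting noise, instrument resolution and solvent
contrast, but real measurements additionally contain alignment and footprint
systematics, imperfect background subtraction, diffuse-scattering losses
(here absorbed into a free scale factor without modelling their origin), and
true lateral inhomogeneity that an effective-medium slab model only
approximates.  Passing the recovery tests therefore demonstrates the
*internal consistency* of the analysis chain — that the coverage written into
a stack is the coverage the fitting protocol reads back — not the accuracy of
any particular instrument's systematics.  Likewise the single-effective-
vesicle use of the ρ/η/α_f relations is a mean-field treatment of a
polydisperse population, and vesicle rupture/fusion (suspected at the highest
protein concentration, flagged in the pipeline output) is outside the model.

## Problem sizes

Defaults were sized for a desk run: jamming uses 5 seeds × 10⁷ attempts on an
80-diameter periodic box; the 24 h diffusion run uses 10 replicates of ~8000
explicit vesicles at Δt = 10 s; the bending-energy sweep uses a Δα = 0.005
grid with 32 basis modes and 600 quadrature nodes.  Each piece completes in
minutes on one CPU; all random numbers derive from explicit seeds and every
result is bit-reproducible given the seed.
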
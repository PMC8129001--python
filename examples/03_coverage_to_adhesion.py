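"""From measured coverages to the adhesion energy per protein.

Takes the steric coverage rho_inf (from RSA simulation) and the adhesive
coverage eta (from reflectivity) of the native membrane, computes the flat
fraction alpha_f, inverts the shape-energy curve to the adhesion constant
k_a, and multiplies by the area per MBP to get the energy per protein.
"""

import warnings

from vesadh.adhesion import energy_per_mbp
from vesadh.coverage import alpha_from_coverages
from vesadh.measurement import Measurement
from vesadh.shape import MembraneMechanics, bending_energy_curve, ka_from_alpha

warnings.simplefilter("ignore")

rho = Measurement(0.60, 0.05)    # steric coverage, RSA after 1 day
eta = Measurement(0.26, 0.02)    # adhesive coverage, reflectivity fit
kappa = Measurement(1.44e-19, 0.10e-19)   # J, bending rigidity (NSE)
a_mbp = Measurement(86.0, 17.0)  # nm^2 per MBP molecule

alpha = alpha_from_coverages(rho, eta)
print(f"flat fraction        alpha_f = {alpha:.3f}")

print("sweeping the bending-energy curve (takes a couple of minutes)...")
curve = bending_energy_curve(alpha_min=0.02, alpha_max=0.18, step=0.005)
mech = MembraneMechanics(kappa=kappa, vesicle_radius=50.0)
ka = ka_from_alpha(alpha.value, mech, curve=curve)
print(f"adhesion constant    k_a     = {ka:.3f} mJ/m^2")

eps = energy_per_mbp(ka, a_mbp)
print(f"energy per protein   eps_MBP = {eps:.3f} x 1e-19 J")
print()
print("eps_MBP is a few k_B T (k_B T = 0.043 x 1e-19 J at 37 degC): each MBP")
print("molecule contributes a weak, reversible cross-bridge between the")
print("vesicle membrane and the supported bilayer.")
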
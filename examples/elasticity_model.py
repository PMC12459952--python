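"""Fit the harmonic-spring elasticity model to a tension series.

Builds a per-tension table of protein height change Dz, excess area DA,
and bending energy E_b, fits the three linear responses, computes the
vertical membrane force F = dE_b/dDz + gamma dDA/dDz at each tension, and
fits F(Dz) to locate the protein's force constant and force-free state.
"""

import numpy as np

from nanodome.elasticity import TensionSeries, build_force_model

# a tension series of the kind the pipeline produces (gamma in mN/m,
# Dz in nm, DA in nm^2, E_b in kappa units)
series = TensionSeries(
    gamma=np.array([0.0, 1.4, 2.8, 5.5]),
    dz=np.array([0.0, 0.37, 0.68, 1.40]),
    dz_err=np.full(4, 0.05),
    dA=np.array([40.0, 34.3, 30.1, 19.6]),
    dA_err=np.full(4, 3.0),
    eb=np.array([1.95, 1.70, 1.39, 0.82]),
    eb_err=np.full(4, 0.2),
)
model = build_force_model(series, kappa=25.0, T=310.0)

s = model.slopes
print(f"dDz/dgamma = {s.dz_dgamma.value:.3f} +- {s.dz_dgamma.se:.3f} nm/(mN/m)")
print(f"dDA/dDz    = {s.dA_ddz.value:.1f} +- {s.dA_ddz.se:.1f} nm")
print(f"dE_b/dDz   = {s.deb_ddz.value:.2f} +- {s.deb_ddz.se:.2f} kappa/nm")
for g, dz, F in zip(model.gamma, model.dz_points, model.F_points):
    print(f"  gamma {g:4.1f} mN/m: Dz = {dz:.2f} nm, |F| = {F:.0f} pN")
r = model.relation
print(f"F0 (tensionless force on the protein) = {r.F0:.0f} +- {r.F0_se:.0f} pN")
print(f"k_F (protein force constant)          = {r.k_F:.0f} +- {r.k_F_se:.0f} pN/nm")
print(f"Dz_free (force-free state)            = {r.dz_free:.2f} +- "
      f"{r.dz_free_se:.2f} nm")
print("negative Dz_free: the force-free protein is more curved than its "
      "relaxed membrane-embedded state")
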
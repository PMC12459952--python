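"""Average aligned shapes and compute excess area and bending energy.

Averages a 20-frame synthetic ensemble (with threefold symmetrization),
then evaluates the discretized Monge-gauge observables: the excess area
DA relative to the planar projection, the density-weighted Helfrich
bending energy E_b in units of kappa, and the radially averaged
mean-curvature profile M(r).
"""

import numpy as np

from nanodome.averaging import average_shapes
from nanodome.geometry import bending_energy, excess_area, radial_mean_curvature_profile
from nanodome.pipeline import aligned_shapes_for_frames
from nanodome.synthetic import SurfaceSpec, make_surface, make_topology, sample_bilayer_frame

spec = SurfaceSpec()
surf, truth = make_surface(spec)
topology = make_topology(spec)

frames = [sample_bilayer_frame(surf, spec, seed=s)[0] for s in range(20)]
shapes, _ = aligned_shapes_for_frames(frames, topology)
avg = average_shapes(shapes, a=1.0)

dA = excess_area(avg)
eb = bending_energy(avg, kappa=25.0)
profile, curvature, eb_2d = radial_mean_curvature_profile(avg)

print(f"averaged {avg.n_frames} aligned shapes on a {avg.a} nm lattice, "
      f"disk diameter {avg.d_m:.0f} nm")
print(f"excess area DA = {dA:.1f} nm^2   (surface truth {truth.excess_area:.1f})")
print(f"bending energy E_b = {eb:.2f} kappa (density-weighted)")
print(f"2D-profile cross-check E_b = {eb_2d:.2f} kappa")
imax = np.argmax(curvature.M)
print(f"mean curvature peaks at r = {curvature.r[imax]:.1f} nm with "
      f"M = {curvature.M[imax]:.3f} 1/nm; M ~ 0 in the catenoid-like far field")
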
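"""Observables from a trajectory table: density, marginals, boundary modes.

Builds a synthetic track table localized at a known angle, estimates the
coarse-grained density, and recovers the excavation site from the angular
marginal; then shows the Fourier signature of an elliptically deformed
corral boundary.
"""

import numpy as np

from antcavate import (BoundaryShape, boundary_shape_spectrum,
                       coarse_grain_density, localization_index,
                       marginal_profiles, synthetic_tracks)

phi0 = 1.0
tracks = synthetic_tracks(phi0=phi0, n_agents=12, duration=300.0, seed=2)
dens = coarse_grain_density(tracks, window=(0.0, 300.0), extent=6.0, nbins=96)
(phi, P_phi), (r, P_r) = marginal_profiles(dens)

print(f"density integral: {dens.integral():.2f} agents (12 simulated)")
print(f"angular peak at phi = {phi[np.argmax(P_phi)]:+.2f} rad "
      f"(site placed at {phi0:+.2f})")
print(f"localization index: {localization_index(dens):.1f} "
      "(1 = isotropic, >3 = strongly localized)")

m = 256
angles = 2 * np.pi * np.arange(m) / m
shape = BoundaryShape(3.0 * (1 + 0.1 * np.cos(2 * angles)))
power = boundary_shape_spectrum(shape, K=5)
print("\nboundary mode powers |R_hat(k)|^2, k=0..5:",
      np.array2string(power, precision=4))
print("The k=2 (elliptic) mode dominates the deformation — the signature "
      "of a single localized tunnel stretching the corral.")
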
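"""The morphoelastic constitutive core on single material points.

Multiplicative growth split F = A G: growth G = g I changes volume without
stress; the elastic part A = F G^{-1} carries the neo-Hookean stress with a
volumetric penalty pressure enforcing near-incompressibility.
"""

import numpy as np

from gyrogen import Material, cauchy_stress, elastic_tensor, growth_tensor

mat = Material(mu=330.0)  # Pa, cortex and core alike

# free growth: the body simply gets bigger, A = I, sigma = 0
G = growth_tensor(1.2)
F_free = G.copy()
A = elastic_tensor(F_free, G)
sigma, p = cauchy_stress(A, mat)
print(f"free growth g=1.2   : det G = {np.linalg.det(G):.3f}, "
      f"max |sigma| = {np.abs(sigma).max():.1e} Pa")

# fully confined growth: the grown material is squeezed back, A = I/g
A = elastic_tensor(np.eye(3), G)
sigma, p = cauchy_stress(A, mat)
print(f"confined growth     : det A = {np.linalg.det(A):.3f}, "
      f"pressure p = {p:.0f} Pa (compressive)")

# isochoric plane-strain stretch: sigma_11 - sigma_22 = mu (lam^2 - lam^-2)
lam = 1.4
sigma, _ = cauchy_stress(np.diag([lam, 1 / lam]), mat)
print(f"plane strain lam={lam}: sigma11-sigma22 = "
      f"{sigma[0, 0] - sigma[1, 1]:.1f} Pa "
      f"(closed form {mat.mu * (lam**2 - lam**-2):.1f} Pa)")
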
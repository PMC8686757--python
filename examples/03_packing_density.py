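"""Monte-Carlo check of the cubic-close-packing density.

The 12 cone directions come from the CCP/FCC sphere arrangement, the
densest packing of equal spheres.  Sampling one FCC unit cell (spheres at
the 8 cube corners and 6 face centers) recovers the closed-form density
pi / (3 sqrt 2) ~ 0.74048 — the arrangement fills ~74% of space.
"""

import numpy as np

from dpc12 import fcc_packing_density_mc

exact = np.pi / (3 * np.sqrt(2))
for n in (10_000, 100_000, 1_000_000):
    est = fcc_packing_density_mc(n, seed=0)
    print(f"n = {n:>9,}: estimate {est:.5f}  (exact {exact:.5f}, error {abs(est-exact):.5f})")

half = fcc_packing_density_mc(500_000, seed=0, radius=0.5)
print(f"\nhalved sphere radius: {half:.5f} ~ exact/8 = {exact / 8:.5f}")
print("(density scales with radius cubed below the touching radius)")
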
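"""Shape selectivity of the blob-structure-enhancement (BSE) filter.

Applies the Hessian-eigenvalue filter to a bright sphere, plate and tube of
identical amplitude: only near-isotropic negative curvature (a blob)
survives the eigenvalue-ratio weights, which is why lung tumors are
enhanced while ribs and vessels are suppressed.
"""

import numpy as np

from tumorloc import BSEParams, Volume, bse_filter, sobel3d

shape = (32, 32, 32)
x, y, z = np.meshgrid(*[np.arange(32) - 15.5] * 3, indexing="ij")

sphere = Volume(data=(x**2 + y**2 + z**2 <= 25.0).astype(float) * 100.0)
plate = Volume(data=((np.abs(z) <= 2.5)).astype(float) * 100.0)
tube = Volume(data=(x**2 + y**2 <= 25.0).astype(float) * 100.0)

p = BSEParams(sigma_mm=2.5, gamma=1.0)  # sigma = d/4 for a 10 mm tumor
print(f"BSE filter, sigma = {p.sigma_mm} mm, gamma = {p.gamma}")
print(f"{'structure':10s} {'BSE peak':>10s} {'Sobel peak':>12s}")
for name, v in [("sphere", sphere), ("plate", plate), ("tube", tube)]:
    print(f"{name:10s} {bse_filter(v, p).data.max():10.2f} "
          f"{sobel3d(v).data.max():12.1f}")
print("The sphere dominates the BSE response; the edge filter rates all")
print("three structures alike, which is what makes Sobel templates fragile.")
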
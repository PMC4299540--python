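"""Full pipeline on the validation phantom: all three template modes.

Simulates the three-station phantom and one degraded MV-CBCT with a known
setup shift, then runs registration + template matching + Otsu + centroid
for raw, Sobel-filtered and BSE-filtered templates and prints the
localization error of each station (estimated minus true tumor position).
"""

import numpy as np

from tumorloc import DegradationSpec, PhantomSpec, degrade_to_cbct, localize, make_phantom_ct
from tumorloc.pipeline import coarse_register
from tumorloc.preprocess import preprocess_cbct

ct, gtvs, truth = make_phantom_ct(PhantomSpec().default_validation_tumors())
shift = np.array([4.0, -3.0, 6.0])
cbct, record = degrade_to_cbct(ct, DegradationSpec(shift_mm=tuple(shift), seed=42))

tr = coarse_register(ct, cbct)
pre = preprocess_cbct(cbct)

print(f"applied shift {shift} mm; coarse registration {np.round(tr.translation_mm, 1)} mm")
print(f"{'station':14s} {'mode':6s} {'error LR/AP/SI (mm)':>24s} {'|e| (mm)':>9s} {'NCC':>6s}")
for g in gtvs:
    ref = np.asarray(truth[g.name]) + shift
    for mode in ("none", "sobel", "bse"):
        res = localize(ct, cbct, g, tr, mode=mode, cbct_pre=pre)
        err = np.asarray(res.centroid_mm) - ref
        print(f"{g.name:14s} {mode:6s} "
              f"{err[0]:7.2f} {err[1]:7.2f} {err[2]:7.2f} "
              f"{np.linalg.norm(err):9.2f} {res.score:6.3f}")
print("Sub-millimetre errors mean the framework recovered the setup shift")
print("(including its sub-voxel part, via the binarized-GTV centroid).")
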
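"""Generate one intermittent and one linear-stochastic epoch and compare
their recurrence statistics at the fixed 1% recurrence-rate operating point.

LAM/RAD — laminarity normalized by the solved radius — is the quantity that
separates intermittent dynamics from a Gaussian AR null of equal variance.
"""

import numpy as np

from lamflow import generate_ar_linear, generate_intermittent_map, measures_for_epoch

xm = generate_intermittent_map(4800, seed=21)
xa = generate_ar_linear(4800, (0.9,), seed=21)
xa = xa / np.std(xa) * np.std(xm)  # variance-matched null

for name, x in (("intermittent map", xm), ("AR(1) null", xa)):
    m = measures_for_epoch(x)
    print(f"{name:16s} tau={m.tau:2d} RAD={m.rad_pct:6.3f}% "
          f"REC={m.rec_pct:5.3f}% LAM={m.lam:.3f} "
          f"LAM/RAD={m.lam_over_rad:8.4f} VMAX={m.vmax:3d} "
          f"TT={m.tt:5.2f} DET={m.det:.3f}")

print("\nLAM/RAD is orders of magnitude larger for the intermittent epoch:")
print("laminar phases produce long vertical lines in its recurrence plot,")
print("while the AR epoch of identical variance shows almost none.")
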
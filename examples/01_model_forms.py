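"""Evaluate the four CO2-response model forms at a few CO2 levels.

Every empirical form returns exactly -Rp at zero CO2 (the fitted
respiration intercept); the biochemical form returns -Rd at its
photorespiratory compensation point gamma*.
"""

import numpy as np

import photoresp as pr

ca = np.array([0.0, 100.0, 400.0, 800.0, 1200.0])

rect = pr.RectHyperbolaParams(alpha=0.05, pnmax=30, rp=5)
mm = pr.MichaelisMentenParams(pnmax=30, k=30 / 0.05, rp=5)  # K = Pnmax/alpha
modrect = pr.ModRectHyperbolaParams(a=0.06, b=0.0003, c=0.001, rp=5)
fvcb = pr.FvCBParams(vcmax=100, j=150, tpu=11.5, rd=1.5)

print("C_a      rect      MM   modrect    FvCB   (umol CO2 m-2 s-1)")
for c in ca:
    row = [pr.eval_rect_hyperbola(rect, c),
           pr.eval_michaelis_menten(mm, c),
           pr.eval_mod_rect_hyperbola(modrect, c),
           pr.eval_fvcb(fvcb, c) if c > 0 else float("nan")]
    print(f"{c:5.0f} " + " ".join(f"{v:8.3f}" for v in row))

dq = pr.derived_quantities(modrect)
print(f"\nmodified hyperbola: intercept {dq.intercept_at_zero:.3f} (= -Rp), "
      f"CO2 compensation point {dq.co2_compensation_point:.1f} umol mol-1, "
      f"realized maximum {dq.pn_max_realized:.3f}")
print("Rect and MM columns agree because K = Pnmax/alpha makes the two "
      "forms algebraically identical.")
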
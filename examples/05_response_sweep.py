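"""Sweep the three numerical responses over abundance.

Predator consumption is anchored at the contemporary state (20% of peak,
36,000 animals) and the pre-decline state (180,000) and interpolated by a
flat, linear or sigmoid (Type III-like) rule.  The pup difference — seed
minus births at natality 0.69 — is positive where the population declines.
"""

import numpy as np

from lhxpop import ResponseModel, anchors_from_schedules, calibrate_sigmoid, find_equilibria, sweep
from lhxpop.reference import calibrated, mass_schedule

schedules = calibrated()
anchors = anchors_from_schedules(schedules.lhx_egoa, schedules.hfys_pre)
mass = {s: mass_schedule(s) for s in ("female", "male")}
params = calibrate_sigmoid(anchors, mass)

for kind in ("flat", "linear", "sigmoid"):
    model = ResponseModel(kind=kind, anchors=anchors, mass_schedule=mass, sigmoid=params)
    tab = sweep(model, np.round(np.arange(0.2, 1.01, 0.05), 3))
    eqs = find_equilibria(tab)
    eq_txt = ", ".join(f"{a:.2f} ({s})" for a, s in eqs) or "none"
    print(f"{kind:8s} consumed at 20%: {tab.total_consumed.iloc[0]:7.0f}  "
          f"juvenile peak: {tab.consumed_juveniles.max():7.0f}  equilibria: {eq_txt}")

print()
print("Only the sigmoid response — predators shifting onto juveniles as")
print("adults thin out — holds the population at the observed 20% level;")
print("flat and linear responses would let it recover.")
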